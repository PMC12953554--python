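"""Cell-cycle kinetics estimation from cumulative labeling curves.

Two estimators are provided, both reading a per-field labeling curve
(fractions of label-positive nuclei over continuous exposure time):

* ``paper_breakpoint`` (default) — a three-segment flat–linear–flat
  least-squares fit. The first breakpoint (end of the initial constant
  phase) is read as the S-phase duration Ts; the second breakpoint (the
  saturation point, at which every cycling cell has traversed S) equals
  Tc − Ts, so Tc = break1 + break2; the plateau level is the growth
  fraction GF.
* ``linear_rise`` — the classical cumulative-labeling model
  index(t) = GF·(t + Ts)/Tc before saturation and GF after, inverted from
  an ordinary least-squares line through the pre-plateau points:
  Tc = GF/slope, Ts = intercept/slope.

Confidence intervals come from a field-level bootstrap (resampling fields
with replacement within each replicate × timepoint cell).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .errors import (
    InsufficientDataError,
    NoGrowthError,
    NoSaturationError,
    UnstableFitError,
    ValidationError,
)
from .synthdata import validate_curve

__all__ = [
    "SegmentedFit",
    "KineticEstimate",
    "ConditionComparison",
    "aggregate_curve",
    "fit_segmented",
    "estimate_paper_breakpoint",
    "estimate_linear_rise",
    "bootstrap_estimate",
    "compare_conditions",
]

METHODS = ("paper_breakpoint", "linear_rise")


@dataclass(frozen=True)
class SegmentedFit:
    """Result of the three-segment (flat–linear–flat) least-squares fit."""

    break1: float
    break2: float
    level0: float
    plateau: float
    rss: float
    n_points: int


@dataclass
class KineticEstimate:
    """Point estimates of the cell-cycle kinetic parameters.

    ``tsat_hat`` is the saturation time and satisfies
    ``tc_hat = ts_hat + tsat_hat`` exactly. Confidence intervals are
    (lower, upper) tuples, NaN-bounded when no bootstrap was run.
    """

    method: str
    gf_hat: float
    ts_hat: float
    tc_hat: float
    tsat_hat: float
    ci_ts: tuple[float, float] = (float("nan"), float("nan"))
    ci_tc: tuple[float, float] = (float("nan"), float("nan"))
    ci_gf: tuple[float, float] = (float("nan"), float("nan"))
    n_boot: int = 0
    n_boot_failed: int = 0
    boot_samples: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValidationError(f"unknown method {self.method!r}")
        if not self.tc_hat > self.ts_hat > 0:
            raise ValidationError(
                f"need tc_hat > ts_hat > 0 (got tc={self.tc_hat}, ts={self.ts_hat})"
            )
        if not np.isclose(self.tsat_hat, self.tc_hat - self.ts_hat, rtol=0, atol=1e-9):
            raise ValidationError("tsat_hat must equal tc_hat - ts_hat")


@dataclass(frozen=True)
class ConditionComparison:
    """Bootstrap contrast of two kinetic estimates (B minus A)."""

    delta_ts: float
    delta_tc: float
    p_ts: float
    p_tc: float


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


def aggregate_curve(curve: pd.DataFrame) -> pd.DataFrame:
    """Per-timepoint mean labeling index and SEM over all fields.

    Fields across replicates are pooled as independent observations (the
    SEM-over-fields convention). Returns a frame with columns
    ``time_h``, ``mean_index``, ``sem``, ``n_fields``, sorted by time.
    """
    validate_curve(curve)
    idx = curve["n_pos"] / curve["n_total"]
    tmp = curve[["time_h"]].assign(index=idx)
    agg = (
        tmp.groupby("time_h")["index"]
        .agg(mean_index="mean", sem=lambda s: s.std(ddof=1) / np.sqrt(len(s)) if len(s) > 1 else 0.0, n_fields="size")
        .reset_index()
        .sort_values("time_h", ignore_index=True)
    )
    return agg


# ---------------------------------------------------------------------------
# segmented (flat-linear-flat) fit
# ---------------------------------------------------------------------------


def _segmented_rss(
    t: np.ndarray, y: np.ndarray, w: np.ndarray, b1: float, b2: float
) -> tuple[float, float, float]:
    """RSS and segment levels of the flat–linear–flat model at (b1, b2).

    ``level0``/``plateau`` are the w-weighted means of the points at
    t <= b1 / t >= b2; the middle segment is the straight line joining
    (b1, level0) to (b2, plateau). Returns inf for inadmissible pairs
    (empty flat segment, b1 >= b2, or plateau below level0).
    """
    if not b1 < b2:
        return np.inf, np.nan, np.nan
    left = t <= b1
    right = t >= b2
    if not left.any() or not right.any() or left.all() or right.all():
        return np.inf, np.nan, np.nan
    level0 = float(np.average(y[left], weights=w[left]))
    plateau = float(np.average(y[right], weights=w[right]))
    if plateau < level0:
        return np.inf, np.nan, np.nan
    pred = np.where(
        left,
        level0,
        np.where(right, plateau, level0 + (plateau - level0) * (t - b1) / (b2 - b1)),
    )
    rss = float(np.sum(w * (y - pred) ** 2))
    return rss, level0, plateau


def _fit_segmented_arrays(
    t: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    grid_step: float,
    refine: bool,
    plateau_tolerance: float,
) -> SegmentedFit:
    m = len(t)
    if m < 5:
        raise InsufficientDataError(f"segmented fit needs >= 5 timepoints (got {m})")
    if y[-1] - y[-2] > plateau_tolerance:
        raise NoSaturationError(
            "curve is still rising between the last two timepoints; "
            "no saturation plateau detectable"
        )
    t0, tmax = t[0], t[-1]
    # candidate breakpoints on a regular grid; break2 stays strictly below
    # the last sample time so the plateau always contains the final point
    cand = np.round(np.arange(t0, tmax - grid_step * 0.5, grid_step) + 0.0, 10)
    if len(cand) < 2:
        raise InsufficientDataError("grid too coarse for the sampled time range")

    # plateau level depends on b2 only
    right_masks = t[None, :] >= cand[:, None]          # (k, m)
    w_right = right_masks * w[None, :]
    plateau_all = (w_right * y[None, :]).sum(axis=1) / w_right.sum(axis=1)

    best = (np.inf, np.nan, np.nan, np.nan, np.nan)    # rss, b1, b2, level0, plateau
    for i, b1 in enumerate(cand):
        left = t <= b1
        n_left = int(left.sum())
        if n_left == 0 or n_left == m:
            continue
        level0 = float(np.average(y[left], weights=w[left]))
        j0 = i + 1
        if j0 >= len(cand):
            break
        b2s = cand[j0:]
        plats = plateau_all[j0:]
        rights = right_masks[j0:]
        with np.errstate(invalid="ignore"):
            pred_mid = level0 + (plats[:, None] - level0) * (t[None, :] - b1) / (
                b2s[:, None] - b1
            )
        resid_sq = np.where(
            left[None, :],
            (y - level0) ** 2,
            np.where(rights, (y[None, :] - plats[:, None]) ** 2, (y[None, :] - pred_mid) ** 2),
        )
        rss = (w[None, :] * resid_sq).sum(axis=1)
        rss = np.where(plats >= level0, rss, np.inf)
        rss = np.where(rights.all(axis=1), np.inf, rss)
        jbest = int(np.argmin(rss))          # first minimum -> smallest b2
        if rss[jbest] < best[0]:             # strict -> smallest b1 kept on ties
            best = (float(rss[jbest]), float(b1), float(b2s[jbest]),
                    level0, float(plats[jbest]))

    rss_best, b1, b2, level0, plateau = best
    if not np.isfinite(rss_best):
        raise NoSaturationError("no admissible breakpoint pair (no rise segment)")

    if refine:
        def objective(x: np.ndarray) -> float:
            r, _, _ = _segmented_rss(t, y, w, float(x[0]), float(x[1]))
            return r if np.isfinite(r) else 1e9

        res = minimize(objective, x0=[b1, b2], method="Nelder-Mead",
                       options={"xatol": 1e-4, "fatol": 1e-12})
        r, l0, pl = _segmented_rss(t, y, w, float(res.x[0]), float(res.x[1]))
        if np.isfinite(r) and r <= rss_best:
            rss_best, b1, b2, level0, plateau = r, float(res.x[0]), float(res.x[1]), l0, pl

    if plateau - level0 <= plateau_tolerance:
        raise NoSaturationError(
            "fitted rise amplitude is within tolerance of zero (flat curve)"
        )
    return SegmentedFit(break1=b1, break2=b2, level0=level0,
                        plateau=plateau, rss=rss_best, n_points=m)


def fit_segmented(
    aggregated: pd.DataFrame,
    grid_step: float = 0.1,
    refine: bool = False,
    plateau_tolerance: float = 0.03,
) -> SegmentedFit:
    """Least-squares three-segment fit of an aggregated labeling curve.

    The breakpoint pair is found by exhaustive search on a regular grid of
    spacing ``grid_step`` hours (global optimum; ties resolved toward the
    smallest break1, then the smallest break2), optionally followed by a
    continuous Nelder–Mead refinement that is only accepted if it does not
    increase the RSS. Points are weighted by the number of fields behind
    each timepoint mean.
    """
    t = aggregated["time_h"].to_numpy(dtype=float)
    y = aggregated["mean_index"].to_numpy(dtype=float)
    w = aggregated["n_fields"].to_numpy(dtype=float)
    order = np.argsort(t)
    return _fit_segmented_arrays(t[order], y[order], w[order], grid_step, refine,
                                 plateau_tolerance)


def estimate_paper_breakpoint(fit: SegmentedFit) -> KineticEstimate:
    """Kinetic parameters under the breakpoint reading of the curve:
    Ts = break1, Tsat = break2, Tc = break1 + break2, GF = plateau."""
    return KineticEstimate(
        method="paper_breakpoint",
        gf_hat=fit.plateau,
        ts_hat=fit.break1,
        tc_hat=fit.break1 + fit.break2,
        tsat_hat=fit.break2,
    )


# ---------------------------------------------------------------------------
# classical linear-rise estimator
# ---------------------------------------------------------------------------


def estimate_linear_rise(
    aggregated: pd.DataFrame,
    plateau_tolerance: float = 0.03,
) -> KineticEstimate:
    """Invert the classical model index(t) = GF·min(1, (t + Ts)/Tc).

    The plateau size (number of trailing saturated points) is chosen by
    least squares: for every admissible split, the rise is an OLS line
    through the pre-plateau points and the plateau the mean of the rest;
    the split minimising the total RSS wins. This recovers noiseless
    curves exactly. ``plateau_tolerance`` governs only the no-saturation
    check (the curve must not still be rising at the end).
    Then GF = plateau mean, Tc = GF/slope, Ts = intercept/slope.
    """
    agg = aggregated.sort_values("time_h")
    t = agg["time_h"].to_numpy(dtype=float)
    y = agg["mean_index"].to_numpy(dtype=float)
    m = len(t)
    if m < 5:
        raise InsufficientDataError(
            f"linear-rise fit needs >= 3 pre-plateau and >= 2 plateau points (got {m} total)"
        )
    if y[-1] - y[-2] > plateau_tolerance:
        raise NoSaturationError(
            "curve is still rising between the last two timepoints; no plateau"
        )
    best: tuple[float, float, float, float] | None = None   # rss, a, b, gf
    for k in range(2, m - 2):                               # k = plateau size
        t_pre, y_pre = t[: m - k], y[: m - k]
        t_pl, y_pl = t[m - k:], y[m - k:]
        b, a = np.polyfit(t_pre, y_pre, 1)
        if b <= 0:
            continue
        gf = float(np.mean(y_pl))
        rss = float(np.sum((y_pre - (a + b * t_pre)) ** 2) + np.sum((y_pl - gf) ** 2))
        if best is None or rss < best[0]:
            best = (rss, float(a), float(b), gf)
    if best is None:
        raise NoGrowthError("no split yields a positive rise slope")
    _, a, b, gf = best
    ts = a / b
    tc = gf / b
    if not tc > ts > 0:
        raise NoGrowthError(
            f"inverted parameters violate Tc > Ts > 0 (ts={ts:.3g}, tc={tc:.3g})"
        )
    return KineticEstimate(
        method="linear_rise", gf_hat=gf, ts_hat=ts, tc_hat=tc, tsat_hat=tc - ts
    )


# ---------------------------------------------------------------------------
# bootstrap and condition comparison
# ---------------------------------------------------------------------------


def _estimate_from_arrays(
    t: np.ndarray, y: np.ndarray, w: np.ndarray, method: str,
    grid_step: float, plateau_tolerance: float,
) -> KineticEstimate:
    if method == "paper_breakpoint":
        fit = _fit_segmented_arrays(t, y, w, grid_step, False, plateau_tolerance)
        return estimate_paper_breakpoint(fit)
    agg = pd.DataFrame({"time_h": t, "mean_index": y, "n_fields": w})
    return estimate_linear_rise(agg, plateau_tolerance)


def bootstrap_estimate(
    curve: pd.DataFrame,
    method: str = "paper_breakpoint",
    n_boot: int = 200,
    seed: int = 0,
    grid_step: float = 0.1,
    boot_grid_step: float = 0.25,
    plateau_tolerance: float = 0.03,
    refine: bool = False,
    max_failure_frac: float = 0.2,
) -> KineticEstimate:
    """Field-level bootstrap confidence intervals for a kinetic estimate.

    The point estimate is computed on the full data (grid spacing
    ``grid_step``). Each bootstrap replicate resamples fields with
    replacement independently within every (replicate, timepoint) cell and
    refits (grid spacing ``boot_grid_step``, coarser by default for speed);
    95% percentile intervals are reported, expanded if necessary to contain
    the point estimate. Replicates that fail to fit are dropped and counted;
    more than ``max_failure_frac`` failures raises ``UnstableFitError``.
    """
    if method not in METHODS:
        raise ValidationError(f"unknown method {method!r}")
    if n_boot < 100:
        raise ValidationError(f"n_boot must be >= 100 (got {n_boot})")
    validate_curve(curve)

    agg = aggregate_curve(curve)
    t = agg["time_h"].to_numpy(dtype=float)
    point = _estimate_from_arrays(
        t, agg["mean_index"].to_numpy(dtype=float),
        agg["n_fields"].to_numpy(dtype=float),
        method, grid_step, plateau_tolerance,
    )
    if refine and method == "paper_breakpoint":
        fit = fit_segmented(agg, grid_step, refine=True,
                            plateau_tolerance=plateau_tolerance)
        point = estimate_paper_breakpoint(fit)

    # pivot to (timepoint, replicate) cells of per-field indices
    df = curve.assign(index=curve["n_pos"] / curve["n_total"])
    cells: list[list[np.ndarray]] = []
    for tp in t:
        sub = df[df["time_h"] == tp]
        cells.append([g["index"].to_numpy() for _, g in sub.groupby("replicate")])

    rng = np.random.default_rng(seed)
    samples: list[tuple[float, float, float]] = []
    n_failed = 0
    w = agg["n_fields"].to_numpy(dtype=float)
    for _ in range(n_boot):
        means = np.empty(len(t))
        for k, reps in enumerate(cells):
            vals = [v[rng.integers(0, len(v), size=len(v))] for v in reps]
            means[k] = np.concatenate(vals).mean()
        try:
            est = _estimate_from_arrays(t, means, w, method, boot_grid_step,
                                        plateau_tolerance)
        except (NoSaturationError, NoGrowthError, InsufficientDataError,
                ValidationError):
            n_failed += 1
            continue
        samples.append((est.ts_hat, est.tc_hat, est.gf_hat))

    if n_failed > max_failure_frac * n_boot:
        raise UnstableFitError(
            f"{n_failed}/{n_boot} bootstrap replicates failed to fit"
        )
    boot = pd.DataFrame(samples, columns=["ts_hat", "tc_hat", "gf_hat"])

    def ci(col: str, point_val: float) -> tuple[float, float]:
        lo, hi = np.percentile(boot[col], [2.5, 97.5])
        return (min(float(lo), point_val), max(float(hi), point_val))

    point.ci_ts = ci("ts_hat", point.ts_hat)
    point.ci_tc = ci("tc_hat", point.tc_hat)
    point.ci_gf = ci("gf_hat", point.gf_hat)
    point.n_boot = n_boot
    point.n_boot_failed = n_failed
    point.boot_samples = boot
    return point


def compare_conditions(
    est_a: KineticEstimate,
    est_b: KineticEstimate,
    boot_a: pd.DataFrame | None = None,
    boot_b: pd.DataFrame | None = None,
) -> ConditionComparison:
    """Contrast two conditions (B minus A) with bootstrap exceedance
    probabilities: for a positive observed delta, the fraction of bootstrap
    delta draws at or below zero (symmetrically for a negative delta)."""
    if est_a.method != est_b.method:
        raise ValidationError(
            f"estimates use different methods ({est_a.method!r} vs {est_b.method!r})"
        )
    boot_a = est_a.boot_samples if boot_a is None else boot_a
    boot_b = est_b.boot_samples if boot_b is None else boot_b
    delta_ts = est_b.ts_hat - est_a.ts_hat
    delta_tc = est_b.tc_hat - est_a.tc_hat

    def exceedance(col: str, observed: float) -> float:
        if boot_a is None or boot_b is None or len(boot_a) == 0 or len(boot_b) == 0:
            return float("nan")
        n = min(len(boot_a), len(boot_b))
        d = boot_b[col].to_numpy()[:n] - boot_a[col].to_numpy()[:n]
        if observed > 0:
            return float(np.mean(d <= 0))
        if observed < 0:
            return float(np.mean(d >= 0))
        return 1.0

    return ConditionComparison(
        delta_ts=delta_ts,
        delta_tc=delta_tc,
        p_ts=exceedance("ts_hat", delta_ts),
        p_tc=exceedance("tc_hat", delta_tc),
    )
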