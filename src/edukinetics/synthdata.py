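"""Synthetic data generators for cumulative-labeling kinetics.

This module emulates the three kinds of raw data the analysis consumes:

* cumulative EdU labeling curves — per-field counts of label-positive vs
  total nuclei at a series of continuous-exposure timepoints, either from an
  explicit agent-based population of cycling cells (``agent`` mode) or from a
  phenomenological flat–linear–flat curve shape (``lagged_rise`` mode);
* marker-index count tables (Ki67, phospho-histone H3, mitotic figures)
  under a simple phase-occupancy model;
* qPCR Ct tables with a housekeeping gene, technical replicates and
  biological replicates, generated from known true fold changes.

All randomness flows through explicit integer seeds; there is no global
random state anywhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "CellCycleParams",
    "LabelingProtocol",
    "LaggedRiseShape",
    "DEFAULT_SAMPLE_TIMES",
    "simulate_population",
    "simulate_cumulative_labeling",
    "expected_labeling_index",
    "lagged_rise_expectation",
    "generate_lagged_rise_curve",
    "generate_marker_counts",
    "generate_ct_table",
    "validate_curve",
]

#: Cumulative-exposure sampling grid (hours) used throughout: 11 timepoints
#: spanning 1 h to 60 h of continuous label exposure.
DEFAULT_SAMPLE_TIMES: tuple[float, ...] = (1, 4, 8, 10, 12, 14, 16, 20, 24, 38, 60)

MARKERS = ("ki67", "ph3", "mitotic")


@dataclass(frozen=True)
class CellCycleParams:
    """Generative truth for a cycling population.

    Parameters
    ----------
    tc_mean : float
        Mean total cell-cycle length in hours.
    tc_cv : float
        Coefficient of variation of per-cell cycle length (lognormal).
    ts : float
        S-phase duration in hours.
    tg2m : float
        Combined G2+M duration in hours (used by the marker generators and to
        place the S window within the cycle).
    growth_fraction : float
        Fraction of cells actively cycling (the plateau of a cumulative
        labeling curve), in [0, 1].
    label_efficiency : float
        Probability that a cell which traverses S during exposure is scored
        positive. Default 1.0 — appropriate for a saturating label dose.
    """

    tc_mean: float
    tc_cv: float = 0.15
    ts: float = 10.0
    tg2m: float = 3.0
    growth_fraction: float = 1.0
    label_efficiency: float = 1.0

    def __post_init__(self) -> None:
        if not self.ts > 0:
            raise ValidationError(f"ts must be > 0 (got {self.ts})")
        if self.tg2m < 0:
            raise ValidationError(f"tg2m must be >= 0 (got {self.tg2m})")
        if not self.ts + self.tg2m < self.tc_mean:
            raise ValidationError(
                f"ts + tg2m must be < tc_mean (got {self.ts} + {self.tg2m} "
                f">= {self.tc_mean})"
            )
        if not 0.0 <= self.growth_fraction <= 1.0:
            raise ValidationError(
                f"growth_fraction must lie in [0, 1] (got {self.growth_fraction})"
            )
        if self.tc_cv < 0:
            raise ValidationError(f"tc_cv must be >= 0 (got {self.tc_cv})")
        if not 0.0 <= self.label_efficiency <= 1.0:
            raise ValidationError(
                f"label_efficiency must lie in [0, 1] (got {self.label_efficiency})"
            )


@dataclass(frozen=True)
class LabelingProtocol:
    """Sampling design of a cumulative-labeling experiment."""

    sample_times: tuple[float, ...] = DEFAULT_SAMPLE_TIMES
    n_fields: int = 5
    n_replicates: int = 3
    cells_per_field_mean: int = 200
    mode: str = "agent"

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.sample_times)
        object.__setattr__(self, "sample_times", times)
        if len(times) == 0:
            raise ValidationError("sample_times must be non-empty")
        if any(t <= 0 for t in times):
            raise ValidationError("sample_times must all be > 0")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValidationError("sample_times must be strictly increasing")
        for name in ("n_fields", "n_replicates", "cells_per_field_mean"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if self.mode not in ("agent", "lagged_rise", "linear_rise"):
            raise ValidationError(f"unknown protocol mode {self.mode!r}")


@dataclass(frozen=True)
class LaggedRiseShape:
    """Phenomenological flat–linear–flat cumulative-labeling curve.

    The expected labeling index is ``level0`` up to ``break1`` hours, rises
    linearly to ``plateau`` at ``break2`` hours, and stays there. Under the
    breakpoint reading of such curves, ``break1`` is the S-phase duration and
    ``break1 + break2`` the total cycle length.
    """

    level0: float
    break1: float
    break2: float
    plateau: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.level0 <= self.plateau <= 1.0:
            raise ValidationError(
                f"need 0 <= level0 <= plateau <= 1 (got level0={self.level0}, "
                f"plateau={self.plateau})"
            )
        if not 0.0 < self.break1 < self.break2:
            raise ValidationError(
                f"need 0 < break1 < break2 (got {self.break1}, {self.break2})"
            )


# ---------------------------------------------------------------------------
# agent-based population
# ---------------------------------------------------------------------------


def _draw_cycle_lengths(params: CellCycleParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """Lognormal cycle lengths with mean tc_mean and CV tc_cv (degenerate at CV=0)."""
    if params.tc_cv == 0:
        return np.full(n, params.tc_mean, dtype=float)
    sigma2 = np.log1p(params.tc_cv**2)
    mu = np.log(params.tc_mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n)


def _draw_phase_positions(
    lengths: np.ndarray, rng: np.random.Generator, age_distribution: str
) -> np.ndarray:
    """Position (hours since cycle start) of each cell within its own cycle.

    ``uniform`` is the simple steady state; ``exponential_growth`` weights
    young cells, f(a) = (2 ln 2 / L) 2^(-a/L), as in an exponentially
    expanding population where each division creates two newborns.
    """
    u = rng.uniform(size=lengths.shape)
    if age_distribution == "uniform":
        return u * lengths
    if age_distribution == "exponential_growth":
        return -lengths * np.log2(1.0 - u / 2.0)
    raise ValidationError(f"unknown age_distribution {age_distribution!r}")


def simulate_population(
    params: CellCycleParams,
    n_cells: int,
    seed: int,
    age_distribution: str = "uniform",
) -> pd.DataFrame:
    """Draw a snapshot of an asynchronous population.

    Returns a DataFrame with one row per cell: ``cycling`` (bool),
    ``cycle_length_h`` (NaN for non-cycling cells) and ``phase_position_h``
    (hours since the current cycle started; NaN for non-cycling cells).
    """
    if n_cells < 1:
        raise ValidationError(f"n_cells must be >= 1 (got {n_cells})")
    rng = np.random.default_rng(seed)
    cycling = rng.uniform(size=n_cells) < params.growth_fraction
    lengths = np.full(n_cells, np.nan)
    positions = np.full(n_cells, np.nan)
    n_cyc = int(cycling.sum())
    if n_cyc:
        lengths[cycling] = _draw_cycle_lengths(params, n_cyc, rng)
        positions[cycling] = _draw_phase_positions(lengths[cycling], rng, age_distribution)
    return pd.DataFrame(
        {"cycling": cycling, "cycle_length_h": lengths, "phase_position_h": positions}
    )


def _time_to_s_entry(lengths: np.ndarray, positions: np.ndarray, ts: float, tg2m: float) -> np.ndarray:
    """Waiting time until a cycling cell next enters (or is already in) S.

    The cycle runs G1 -> S -> G2 -> M, so the S window of a cell with length L
    is [L - ts - tg2m, L - tg2m). Cells currently inside the window wait 0 h;
    cells past it wait through M, division and the daughter's G1.
    """
    s_start = lengths - ts - tg2m
    s_end = lengths - tg2m
    wait = np.where(
        positions < s_start,
        s_start - positions,
        np.where(positions < s_end, 0.0, lengths - positions + s_start),
    )
    return wait


def expected_labeling_index(params: CellCycleParams, t: float | np.ndarray) -> np.ndarray:
    """Closed-form expected labeling index at exposure time ``t`` for the
    zero-CV, uniform-age case: GF * eff * min(1, (Ts + t) / Tc)."""
    t = np.asarray(t, dtype=float)
    frac = np.minimum(1.0, (params.ts + t) / params.tc_mean)
    return params.growth_fraction * params.label_efficiency * frac


def simulate_cumulative_labeling(
    params: CellCycleParams,
    protocol: LabelingProtocol,
    seed: int,
    condition: str = "sim",
    age_distribution: str = "uniform",
) -> pd.DataFrame:
    """Agent-mode cumulative labeling curve.

    Each (replicate, field, timepoint) is an independent sample of cells, as
    in the real protocol where every exposure duration is a separate
    coverslip. A cell is scored positive at exposure time t iff it is cycling
    and spends any time in its S window during [0, t], thinned by
    ``label_efficiency``.
    """
    if protocol.mode != "agent":
        raise ValidationError(f"protocol.mode must be 'agent' (got {protocol.mode!r})")
    rng = np.random.default_rng(seed)
    rows: list[tuple] = []
    for rep in range(1, protocol.n_replicates + 1):
        for fld in range(1, protocol.n_fields + 1):
            for t in protocol.sample_times:
                n = max(1, int(rng.poisson(protocol.cells_per_field_mean)))
                cycling = rng.uniform(size=n) < params.growth_fraction
                n_cyc = int(cycling.sum())
                n_pos = 0
                if n_cyc:
                    lengths = _draw_cycle_lengths(params, n_cyc, rng)
                    positions = _draw_phase_positions(lengths, rng, age_distribution)
                    wait = _time_to_s_entry(lengths, positions, params.ts, params.tg2m)
                    hits = wait < t
                    if params.label_efficiency < 1.0:
                        hits &= rng.uniform(size=n_cyc) < params.label_efficiency
                    n_pos = int(hits.sum())
                rows.append((condition, rep, fld, float(t), n_pos, n))
    return pd.DataFrame(
        rows, columns=["condition", "replicate", "field", "time_h", "n_pos", "n_total"]
    )


# ---------------------------------------------------------------------------
# phenomenological lagged-rise curves
# ---------------------------------------------------------------------------


def lagged_rise_expectation(shape: LaggedRiseShape, t: float | np.ndarray) -> np.ndarray:
    """Expected labeling index of the flat–linear–flat shape at time ``t``."""
    t = np.asarray(t, dtype=float)
    slope = (shape.plateau - shape.level0) / (shape.break2 - shape.break1)
    mid = shape.level0 + slope * (t - shape.break1)
    return np.clip(mid, shape.level0, shape.plateau)


def generate_lagged_rise_curve(
    shape: LaggedRiseShape,
    protocol: LabelingProtocol,
    seed: int,
    condition: str = "sim",
) -> pd.DataFrame:
    """Per-field binomial counts around the lagged-rise expectation."""
    if protocol.mode != "lagged_rise":
        raise ValidationError(
            f"protocol.mode must be 'lagged_rise' (got {protocol.mode!r})"
        )
    rng = np.random.default_rng(seed)
    expectation = lagged_rise_expectation(shape, np.array(protocol.sample_times))
    rows: list[tuple] = []
    for rep in range(1, protocol.n_replicates + 1):
        for fld in range(1, protocol.n_fields + 1):
            for t, p in zip(protocol.sample_times, expectation):
                n = max(1, int(rng.poisson(protocol.cells_per_field_mean)))
                n_pos = int(rng.binomial(n, p))
                rows.append((condition, rep, fld, float(t), n_pos, n))
    return pd.DataFrame(
        rows, columns=["condition", "replicate", "field", "time_h", "n_pos", "n_total"]
    )


# ---------------------------------------------------------------------------
# marker counts and Ct tables
# ---------------------------------------------------------------------------


def marker_probability(
    params: CellCycleParams,
    marker: str,
    mitotic_window_h: float = 1.0,
    ph3_window_h: float | None = None,
) -> float:
    """Phase-occupancy probability that a random nucleus scores positive.

    Ki67 marks every actively cycling cell, so P = GF. pH3 marks late G2 and
    mitosis (window defaults to the G2+M duration); a mitotic figure is
    morphologically visible for roughly the M phase only (default 1 h).
    """
    if marker == "ki67":
        return params.growth_fraction
    if marker == "ph3":
        window = params.tg2m if ph3_window_h is None else ph3_window_h
        return params.growth_fraction * window / params.tc_mean
    if marker == "mitotic":
        return params.growth_fraction * mitotic_window_h / params.tc_mean
    raise ValidationError(f"unknown marker {marker!r}; expected one of {MARKERS}")


def generate_marker_counts(
    params: CellCycleParams,
    marker: str,
    n_fields: int = 5,
    n_replicates: int = 3,
    seed: int = 0,
    cells_per_field_mean: int = 200,
    condition: str = "sim",
    mitotic_window_h: float = 1.0,
    ph3_window_h: float | None = None,
) -> pd.DataFrame:
    """Binomial per-field marker-positive counts under the occupancy model."""
    p = marker_probability(params, marker, mitotic_window_h, ph3_window_h)
    rng = np.random.default_rng(seed)
    rows: list[tuple] = []
    for rep in range(1, n_replicates + 1):
        for fld in range(1, n_fields + 1):
            n = max(1, int(rng.poisson(cells_per_field_mean)))
            rows.append((condition, marker, rep, fld, int(rng.binomial(n, p)), n))
    return pd.DataFrame(
        rows, columns=["condition", "marker", "replicate", "field", "n_pos", "n_total"]
    )


def generate_ct_table(
    gene_effects: Mapping[str, float],
    base_ct: float = 24.0,
    noise_sd: float = 0.2,
    n_bio: int = 4,
    n_tech: int = 2,
    seed: int = 0,
    housekeeping: str = "GAPDH",
    housekeeping_ct: float = 18.0,
    control_condition: str = "control",
    treated_condition: str = "treated",
) -> pd.DataFrame:
    """qPCR Ct table for a control vs treated contrast with known truth.

    Each target gene has control-condition mean Ct ``base_ct``; in the
    treated condition the mean Ct shifts by −log2(fold change), so a true
    fold change of 0.5 costs exactly one extra cycle. The housekeeping gene
    (true fold change 1) sits at ``housekeeping_ct`` in both conditions.
    Independent Gaussian noise of SD ``noise_sd`` cycles is added to every
    single measurement (every technical replicate of every well).
    """
    for gene, fc in gene_effects.items():
        if not fc > 0:
            raise ValidationError(f"fold change for {gene!r} must be > 0 (got {fc})")
    if n_bio < 1 or n_tech < 1:
        raise ValidationError("n_bio and n_tech must be >= 1")
    if housekeeping in gene_effects:
        raise ValidationError(
            f"housekeeping gene {housekeeping!r} must not appear in gene_effects"
        )
    rng = np.random.default_rng(seed)
    rows: list[tuple] = []
    for condition in (control_condition, treated_condition):
        treated = condition == treated_condition
        for bio in range(1, n_bio + 1):
            sample = f"{condition}_b{bio}"
            for gene in (housekeeping, *gene_effects):
                if gene == housekeeping:
                    mean_ct = housekeeping_ct
                else:
                    mean_ct = base_ct - (np.log2(gene_effects[gene]) if treated else 0.0)
                for tech in range(1, n_tech + 1):
                    ct = mean_ct + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                    rows.append((sample, condition, bio, tech, gene, float(ct)))
    return pd.DataFrame(
        rows, columns=["sample", "condition", "bio_rep", "tech_rep", "gene", "ct"]
    )


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

CURVE_COLUMNS = ("condition", "replicate", "field", "time_h", "n_pos", "n_total")


def validate_curve(curve: pd.DataFrame) -> pd.DataFrame:
    """Check the labeling-curve invariants; returns the frame for chaining."""
    missing = [c for c in CURVE_COLUMNS if c not in curve.columns]
    if missing:
        raise ValidationError(f"labeling curve is missing columns {missing}")
    if len(curve) == 0:
        raise ValidationError("labeling curve is empty")
    bad_total = curve[curve["n_total"] < 1]
    if len(bad_total):
        rec = bad_total.iloc[0]
        raise ValidationError(
            f"n_total must be >= 1; first offender: condition={rec['condition']} "
            f"replicate={rec['replicate']} field={rec['field']} time_h={rec['time_h']}"
        )
    bad_pos = curve[(curve["n_pos"] < 0) | (curve["n_pos"] > curve["n_total"])]
    if len(bad_pos):
        rec = bad_pos.iloc[0]
        raise ValidationError(
            f"need 0 <= n_pos <= n_total; first offender: replicate={rec['replicate']} "
            f"field={rec['field']} time_h={rec['time_h']}"
        )
    grids = curve.groupby(["condition", "replicate", "field"])["time_h"].apply(
        lambda s: tuple(sorted(s))
    )
    if grids.nunique() > 1:
        raise ValidationError("every (replicate, field) must cover the same time grid")
    return curve
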