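"""Marker labeling indices and two-sample t-tests.

Percent-positive indices (Ki67, phospho-histone H3, mitotic figures, EdU at
a fixed timepoint) are summarised as mean ± SEM over fields, pooling fields
across replicates as independent observations by default (a per-replicate
means option is available). Group comparisons use the two-tailed Student's
t-test with pooled variance (Welch's by flag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

__all__ = [
    "TTestResult",
    "marker_index",
    "student_t_two_tailed",
    "timecourse_tests",
]


@dataclass(frozen=True)
class TTestResult:
    t_stat: float
    df: float
    p_two_tailed: float
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float


def _percent_indices(counts: pd.DataFrame, unit: str) -> np.ndarray:
    if len(counts) == 0:
        raise ValidationError("empty count table")
    if (counts["n_total"] < 1).any():
        raise ValidationError("n_total must be >= 1 in every field")
    if ((counts["n_pos"] < 0) | (counts["n_pos"] > counts["n_total"])).any():
        raise ValidationError("need 0 <= n_pos <= n_total in every field")
    pct = 100.0 * counts["n_pos"] / counts["n_total"]
    if unit == "field":
        return pct.to_numpy(dtype=float)
    if unit == "replicate":
        return pct.groupby(counts["replicate"]).mean().to_numpy(dtype=float)
    raise ValidationError(f"unknown unit {unit!r}; expected 'field' or 'replicate'")


def marker_index(counts: pd.DataFrame, unit: str = "field") -> tuple[float, float, int]:
    """Mean percent-positive index with SEM.

    ``unit='field'`` (default) treats every field as an independent
    observation; ``unit='replicate'`` first averages fields within each
    replicate. Returns (mean %, SEM %, n observations).
    """
    vals = _percent_indices(counts, unit)
    n = len(vals)
    sem = float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return float(np.mean(vals)), sem, n


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0


def student_t_two_tailed(
    group_a, group_b, equal_var: bool = True
) -> TTestResult:
    """Two-tailed two-sample t-test on per-field percentages.

    Pooled-variance Student's test by default; ``equal_var=False`` gives
    Welch's variant. Degenerate zero-variance inputs follow the
    conventions: equal means -> t = 0, p = 1; unequal means with zero
    variance in both groups -> p = 0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs >= 2 observations")
    df = (
        len(a) + len(b) - 2
        if equal_var
        else _welch_df(a, b)
    )
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            t, p = 0.0, 1.0
        else:
            t = float(np.inf) if np.mean(b) < np.mean(a) else float(-np.inf)
            p = 0.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        t, p = float(t), float(p)
        if np.mean(a) == np.mean(b):
            t, p = 0.0, 1.0  # guard against -0.0 / rounding on identical means
    return TTestResult(
        t_stat=t,
        df=float(df),
        p_two_tailed=p,
        mean_a=float(np.mean(a)),
        mean_b=float(np.mean(b)),
        sem_a=_sem(a),
        sem_b=_sem(b),
    )


def _welch_df(a: np.ndarray, b: np.ndarray) -> float:
    va, vb = np.var(a, ddof=1) / len(a), np.var(b, ddof=1) / len(b)
    if va + vb == 0:
        return float(len(a) + len(b) - 2)
    return float(
        (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    )


def timecourse_tests(
    curve_a: pd.DataFrame,
    curve_b: pd.DataFrame,
    alpha: float = 0.05,
    equal_var: bool = True,
    unit: str = "field",
    correction: str | None = None,
) -> pd.DataFrame:
    """Per-timepoint two-sample t-tests between two labeling curves.

    Both curves must share their time grid. By default no multiple-testing
    correction is applied; ``correction='fdr_bh'`` switches the significance
    flag to Benjamini–Hochberg adjusted p-values.
    """
    times_a = set(curve_a["time_h"].unique())
    times_b = set(curve_b["time_h"].unique())
    shared = sorted(times_a & times_b)
    if times_a != times_b or not shared:
        raise ValidationError("curves must share the same time grid")
    rows = []
    for tp in shared:
        ga = curve_a[curve_a["time_h"] == tp]
        gb = curve_b[curve_b["time_h"] == tp]
        res = student_t_two_tailed(
            _percent_indices(ga, unit), _percent_indices(gb, unit), equal_var
        )
        rows.append(
            {
                "time_h": tp,
                "mean_a": res.mean_a,
                "sem_a": res.sem_a,
                "mean_b": res.mean_b,
                "sem_b": res.sem_b,
                "t_stat": res.t_stat,
                "df": res.df,
                "p": res.p_two_tailed,
            }
        )
    out = pd.DataFrame(rows)
    if correction is None:
        out["significant"] = out["p"] < alpha
    else:
        reject, p_adj, _, _ = multipletests(out["p"], alpha=alpha, method=correction)
        out["p_adjusted"] = p_adj
        out["significant"] = reject
    return out
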