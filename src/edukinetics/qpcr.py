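"""Relative qPCR quantification by the 2^-ddCt method.

Technical replicates are collapsed by arithmetic mean of Ct; each biological
replicate's dCt is the target Ct minus the housekeeping Ct; ddCt references
the mean dCt of the control condition, so control replicates scatter around
a fold change of 1. Statistical testing is done on the additive dCt scale
(two-tailed Student's t-test between conditions) while fold changes are
reported multiplicatively.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .indexstats import student_t_two_tailed

__all__ = [
    "FoldChangeResult",
    "collapse_technical",
    "ddct_fold_change",
    "fold_change_report",
    "significance_stars",
]

CT_COLUMNS = ("sample", "condition", "bio_rep", "tech_rep", "gene", "ct")


@dataclass(frozen=True)
class FoldChangeResult:
    """Per-gene, per-condition 2^-ddCt summary."""

    gene: str
    condition: str
    fc_mean: float
    fc_sem: float
    per_rep_fc: tuple[float, ...]
    p_two_tailed: float

    def __post_init__(self) -> None:
        if any(fc <= 0 for fc in self.per_rep_fc):
            raise ValidationError("fold changes must be > 0")


def collapse_technical(
    records: pd.DataFrame,
    housekeeping: str | None = None,
    spread_threshold: float = 0.5,
) -> pd.DataFrame:
    """Mean Ct over technical replicates per (condition, bio_rep, gene).

    Adds a ``spread_flag`` column marking groups whose technical-replicate
    range exceeds ``spread_threshold`` cycles. When ``housekeeping`` is
    given, every (condition, bio_rep) must include it.
    """
    missing = [c for c in CT_COLUMNS if c not in records.columns]
    if missing:
        raise ValidationError(f"Ct table is missing columns {missing}")
    if len(records) == 0:
        raise ValidationError("Ct table is empty")
    if (records["ct"] <= 0).any():
        raise ValidationError("ct values must be > 0")
    collapsed = (
        records.groupby(["condition", "bio_rep", "gene"], as_index=False)
        .agg(ct=("ct", "mean"), spread=("ct", lambda s: s.max() - s.min()))
    )
    collapsed["spread_flag"] = collapsed["spread"] > spread_threshold
    if housekeeping is not None:
        have_hk = set(
            map(tuple, collapsed.loc[collapsed["gene"] == housekeeping,
                                     ["condition", "bio_rep"]].to_numpy())
        )
        all_units = set(map(tuple, collapsed[["condition", "bio_rep"]].to_numpy()))
        lacking = sorted(all_units - have_hk)
        if lacking:
            raise ValidationError(
                f"housekeeping gene {housekeeping!r} missing for units {lacking}"
            )
    return collapsed


def ddct_fold_change(
    collapsed: pd.DataFrame,
    target: str,
    housekeeping: str,
    control_condition: str,
) -> dict[str, FoldChangeResult]:
    """2^-ddCt fold changes of ``target`` for every condition.

    dCt = Ct_target - Ct_housekeeping per biological replicate; ddCt
    references the control condition's mean dCt. The p-value per non-control
    condition is a two-tailed Student's t-test of per-replicate dCt against
    the control (NaN for the control itself and when either side has < 2
    replicates).
    """
    if target == housekeeping:
        raise ValidationError("target and housekeeping genes must differ")
    sub = collapsed[collapsed["gene"].isin([target, housekeeping])]
    wide = sub.pivot_table(index=["condition", "bio_rep"], columns="gene",
                           values="ct", aggfunc="mean")
    if target not in wide.columns or housekeeping not in wide.columns:
        raise ValidationError(
            f"both {target!r} and {housekeeping!r} must be present in the table"
        )
    if wide[[target, housekeeping]].isna().any().any():
        bad = wide[wide[[target, housekeeping]].isna().any(axis=1)].index.tolist()
        raise ValidationError(f"missing Ct values for units {bad}")
    dct = wide[target] - wide[housekeeping]
    conditions = dct.index.get_level_values("condition")
    if control_condition not in set(conditions):
        raise ValidationError(
            f"control condition {control_condition!r} not present"
        )
    dct_control = dct[conditions == control_condition].to_numpy()
    ref = float(np.mean(dct_control))
    out: dict[str, FoldChangeResult] = {}
    for cond in dict.fromkeys(conditions):        # preserve order
        d = dct[conditions == cond].to_numpy()
        fc = 2.0 ** -(d - ref)
        if cond == control_condition or len(d) < 2 or len(dct_control) < 2:
            p = float("nan")
        else:
            p = student_t_two_tailed(dct_control, d).p_two_tailed
        sem = float(np.std(fc, ddof=1) / np.sqrt(len(fc))) if len(fc) > 1 else 0.0
        out[cond] = FoldChangeResult(
            gene=target,
            condition=cond,
            fc_mean=float(np.mean(fc)),
            fc_sem=sem,
            per_rep_fc=tuple(float(x) for x in fc),
            p_two_tailed=p,
        )
    return out


def significance_stars(p: float) -> str:
    """Map a p-value to the conventional star categories."""
    if np.isnan(p):
        return "ns"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def fold_change_report(results: list[FoldChangeResult]) -> pd.DataFrame:
    """Tidy per-gene fold-change table with significance stars."""
    if not results:
        raise ValidationError("no fold-change results to report")
    rows = [
        {
            "gene": r.gene,
            "condition": r.condition,
            "fc_mean": r.fc_mean,
            "fc_sem": r.fc_sem,
            "n_reps": len(r.per_rep_fc),
            "p": r.p_two_tailed,
            "stars": significance_stars(r.p_two_tailed),
        }
        for r in results
    ]
    return pd.DataFrame(rows)
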