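"""2^-ddCt fold-change analysis of the cell-cycle gene panel.

Reads results/data/ct_table.csv, collapses technical duplicates, computes
per-gene fold changes (FzM1 vs DMSO) with per-replicate structure and
t-tests on the dCt scale, and writes results/qpcr_foldchanges.csv with
significance stars.
"""

from pathlib import Path

import pandas as pd

from edukinetics import QPCR_TRUE_FOLD_CHANGES, collapse_technical, ddct_fold_change, fold_change_report
from edukinetics.io import read_ct_csv

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    records = read_ct_csv(ROOT / "data" / "ct_table.csv")
    collapsed = collapse_technical(records, housekeeping="GAPDH")
    n_flagged = int(collapsed["spread_flag"].sum())
    print(f"collapsed {len(records)} wells to {len(collapsed)} means; "
          f"{n_flagged} technical-duplicate spreads above 0.5 cycles")
    results = []
    for gene in QPCR_TRUE_FOLD_CHANGES:
        results.extend(
            ddct_fold_change(collapsed, gene, "GAPDH", "DMSO").values())
    report = fold_change_report(results)
    treated = report[report["condition"] == "FzM1"].copy()
    treated["true_fc"] = treated["gene"].map(QPCR_TRUE_FOLD_CHANGES)
    print(treated.to_string(index=False))
    report.to_csv(ROOT / "qpcr_foldchanges.csv", index=False, float_format="%.4g")


if __name__ == "__main__":
    main()
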