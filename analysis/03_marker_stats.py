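"""Marker-index summaries and between-arm t-tests.

Reads results/data/marker_counts.csv and writes results/marker_stats.csv:
mean percent-positive +/- SEM per (marker, arm) and two-tailed Student's
t-tests of every arm pair per marker.
"""

from pathlib import Path

import pandas as pd

from edukinetics import marker_index, student_t_two_tailed
from edukinetics.io import read_marker_csv

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = read_marker_csv(ROOT / "data" / "marker_counts.csv")
    rows, tests = [], []
    for (marker, cond), sub in table.groupby(["marker", "condition"], sort=False):
        mean, sem, n = marker_index(sub)
        print(f"{marker:8s} {cond:10s} {mean:6.2f}% +/- {sem:.2f} (n={n} fields)")
        rows.append({"marker": marker, "condition": cond, "mean_pct": mean,
                     "sem_pct": sem, "n_fields": n})
    for marker, sub in table.groupby("marker", sort=False):
        conds = list(dict.fromkeys(sub["condition"]))
        for i in range(len(conds)):
            for j in range(i + 1, len(conds)):
                a = sub[sub["condition"] == conds[i]]
                b = sub[sub["condition"] == conds[j]]
                res = student_t_two_tailed(
                    (100 * a["n_pos"] / a["n_total"]).to_numpy(),
                    (100 * b["n_pos"] / b["n_total"]).to_numpy(),
                )
                print(f"{marker:8s} {conds[i]} vs {conds[j]}: "
                      f"t={res.t_stat:+.2f}, p={res.p_two_tailed:.4f}")
                tests.append({"marker": marker, "condition_a": conds[i],
                              "condition_b": conds[j], "mean_a": res.mean_a,
                              "sem_a": res.sem_a, "mean_b": res.mean_b,
                              "sem_b": res.sem_b, "t": res.t_stat,
                              "df": res.df, "p": res.p_two_tailed})
    pd.DataFrame(rows).to_csv(ROOT / "marker_indices.csv", index=False,
                              float_format="%.4g")
    pd.DataFrame(tests).to_csv(ROOT / "marker_stats.csv", index=False,
                               float_format="%.4g")


if __name__ == "__main__":
    main()
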