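"""Generate the synthetic study data for all three treatment arms.

Writes, under results/data/:
  labeling_curves.csv  — cumulative EdU labeling counts (11 timepoints,
                         5 fields x 3 replicates) for DMSO, FzM1, FzM1+RARi
  marker_counts.csv    — Ki67 / pH3 / mitotic-figure field counts per arm
  ct_table.csv         — qPCR Ct values (control vs FzM1) for the
                         cell-cycle gene panel, 4 biological x 2 technical
                         replicates
plus a manifest with SHA-256 digests so the run can be replayed.
"""

from pathlib import Path

import pandas as pd

from edukinetics import (
    AGENT_CONDITIONS,
    LAGGED_RISE_CONDITIONS,
    QPCR_TRUE_FOLD_CHANGES,
    LabelingProtocol,
    generate_ct_table,
    generate_lagged_rise_curve,
    generate_marker_counts,
)
from edukinetics.io import (
    write_ct_csv,
    write_labeling_csv,
    write_manifest,
    write_marker_csv,
)

SEED = 20260923
OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    protocol = LabelingProtocol(mode="lagged_rise")

    curves = pd.concat(
        [
            generate_lagged_rise_curve(shape, protocol, SEED + i, name)
            for i, (name, shape) in enumerate(LAGGED_RISE_CONDITIONS.items())
        ],
        ignore_index=True,
    )
    curve_path = write_labeling_csv(curves, OUT / "labeling_curves.csv")
    print(f"labeling curves: {len(curves)} rows "
          f"({curves['condition'].nunique()} conditions x "
          f"{curves['time_h'].nunique()} timepoints x 15 fields) -> {curve_path}")

    markers = pd.concat(
        [
            generate_marker_counts(params, marker, seed=SEED + 10 * i + j,
                                   condition=name)
            for i, (name, params) in enumerate(AGENT_CONDITIONS.items())
            for j, marker in enumerate(("ki67", "ph3", "mitotic"))
        ],
        ignore_index=True,
    )
    marker_path = write_marker_csv(markers, OUT / "marker_counts.csv")
    print(f"marker counts: {len(markers)} rows -> {marker_path}")

    ct = generate_ct_table(
        QPCR_TRUE_FOLD_CHANGES, noise_sd=0.2, n_bio=4, n_tech=2, seed=SEED + 99,
        control_condition="DMSO", treated_condition="FzM1",
    )
    ct_path = write_ct_csv(ct, OUT / "ct_table.csv")
    print(f"Ct table: {len(ct)} rows ({len(QPCR_TRUE_FOLD_CHANGES)} target genes "
          f"+ housekeeping) -> {ct_path}")

    write_manifest(OUT / "manifest.json", {"seed": SEED},
                   [curve_path, marker_path, ct_path])


if __name__ == "__main__":
    main()
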