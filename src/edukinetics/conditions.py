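"""Study-condition parameter presets.

The three treatment arms of the SCC25 cumulative-labeling experiment are
represented purely as kinetic parameter sets (no pharmacology is modelled):

* ``DMSO`` — control: Ts = 10 h, Tc = 31 h, short EdU-pulse labeling index
  43.6%;
* ``FzM1`` — Frizzled-4 inhibition: Ts = 16 h, Tc = 42 h, initial index
  43.4%;
* ``FzM1+RARi`` — FzM1 plus a retinoic-acid-receptor antagonist, which
  rescues the control kinetics (Ts = 10 h, Tc = 31 h).

For the lagged-rise shape, ``break1 = Ts`` and ``break2 = Tc − Ts`` (the
exposure time at which every cycling cell has traversed S). The plateau
level — the growth fraction — is not a published number; 0.95 is used for
all arms, consistent with the near-total Ki67 positivity of the culture.
Agent-mode presets use a growth fraction of 0.9; the initial labeling index
they imply (GF·Ts/Tc) is deliberately not forced to match the measured
short-pulse index, which is incompatible with Ts/Tc under any GF ≤ 1.
"""

from __future__ import annotations

from .synthdata import CellCycleParams, LaggedRiseShape

__all__ = [
    "LAGGED_RISE_CONDITIONS",
    "AGENT_CONDITIONS",
    "QPCR_TRUE_FOLD_CHANGES",
]

#: Lagged-rise shapes per condition: (level0, break1=Ts, break2=Tc−Ts, plateau).
LAGGED_RISE_CONDITIONS: dict[str, LaggedRiseShape] = {
    "DMSO": LaggedRiseShape(level0=0.436, break1=10.0, break2=21.0, plateau=0.95),
    "FzM1": LaggedRiseShape(level0=0.434, break1=16.0, break2=26.0, plateau=0.95),
    "FzM1+RARi": LaggedRiseShape(level0=0.436, break1=10.0, break2=21.0, plateau=0.95),
}

#: Agent-based population parameters per condition.
AGENT_CONDITIONS: dict[str, CellCycleParams] = {
    "DMSO": CellCycleParams(tc_mean=31.0, ts=10.0, growth_fraction=0.9),
    "FzM1": CellCycleParams(tc_mean=42.0, ts=16.0, growth_fraction=0.9),
    "FzM1+RARi": CellCycleParams(tc_mean=31.0, ts=10.0, growth_fraction=0.9),
}

#: Measured fold changes of cell-cycle regulators (treated vs control) used
#: as generative truth for the qPCR round-trip analyses.
QPCR_TRUE_FOLD_CHANGES: dict[str, float] = {
    "CDK1": 0.47,
    "CDK2": 0.8936,
    "CCNA1": 0.58,
    "CCNA2": 0.256,
    "CCNE1": 0.8363,
    "CCNE2": 0.5982,
    "CCND2": 0.73,
}
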