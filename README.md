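# edukinetics

Cell-cycle kinetics from cumulative EdU labeling curves.

In a cumulative thymidine-analog (EdU) labeling experiment, an asynchronous
culture is continuously exposed to label and sampled at increasing exposure
times; every cell that traverses S-phase while the label is present becomes
positive. The fraction of labeled nuclei (the labeling index) therefore grows
with exposure time until every actively cycling cell has passed through S,
after which it plateaus at the growth fraction GF. Reading the curve gives the
three headline parameters:

* **GF** — the plateau level (fraction of cells actively cycling),
* **Ts** — S-phase duration: the length of the initial constant phase of the
  curve (a short pulse already labels the cells in S, index ≈ GF·Ts/Tc; the
  index does not change until cells initially just past S re-enter it),
* **Tc** — total cycle length: the saturation time Tsat (where the plateau
  begins) equals Tc − Ts, so **Tc = Ts + Tsat**.

This package provides (1) synthetic-data generators for such experiments — an
agent-based asynchronous population simulator and a phenomenological
flat–linear–flat ("lagged rise") curve generator, plus marker-count (Ki67,
phospho-histone H3, mitotic figures) and qPCR Ct table generators; (2) the
estimators — a three-segment least-squares breakpoint fit and the classical
linear-rise inversion index(t) = GF·min(1, (t+Ts)/Tc) — with field-level
bootstrap confidence intervals and condition contrasts; (3) marker-index
statistics with two-tailed Student's t-tests; and (4) 2^−ΔΔCt relative qPCR
quantification. It reproduces, by simulation and re-estimation, the kinetic
readout of an SCC25 oral-carcinoma study design: control cells at
Ts = 10 h / Tc = 31 h, Frizzled-4 inhibition (FzM1) slowing the cycle to
Ts = 16 h / Tc = 42 h, and a retinoic-acid-receptor antagonist (RARi) rescuing
the control kinetics.

## Worked example

```python
from edukinetics import (LAGGED_RISE_CONDITIONS, LabelingProtocol,
                         generate_lagged_rise_curve, aggregate_curve,
                         fit_segmented, estimate_paper_breakpoint)

shape = LAGGED_RISE_CONDITIONS["DMSO"]          # Ts=10 h, Tc=31 h truth
protocol = LabelingProtocol(mode="lagged_rise") # 11 timepoints, 5 fields x 3 reps
curve = generate_lagged_rise_curve(shape, protocol, seed=1)
fit = fit_segmented(aggregate_curve(curve))
est = estimate_paper_breakpoint(fit)
print(f"Ts={est.ts_hat:.1f} h  Tc={est.tc_hat:.1f} h  GF={est.gf_hat:.3f}")
```

prints

```
Ts=10.0 h  Tc=31.0 h  GF=0.951
```

i.e. the fitted first breakpoint (end of the initial constant phase) gives
Ts = 10.0 h, the saturation breakpoint at 21.0 h gives Tc = 10 + 21 = 31.0 h,
and the plateau estimates a growth fraction of 0.951 (truth 0.95).

The numbered scripts under `analysis/` run the full study: `01_simulate.py`
generates the three arms' labeling curves, marker counts and Ct tables under
`results/data/`; `02_fit_kinetics.py` fits every arm and contrasts them
(FzM1 − DMSO: ΔTs = +6.0 h, ΔTc = +10.7 h, bootstrap p ≈ 0; the rescue arm
reverses both); `03_marker_stats.py` and `04_qpcr.py` produce the marker-index
and fold-change tables; `05_parameter_recovery.py` repeats the
simulate-and-fit loop over 20 seeds per arm (median Ts/Tc: 10.0/31.0,
16.1/42.2, 10.1/31.0 h).

A CLI mirrors these steps: `edukin simulate|fit|recover|markers|qpcr|compare`
(see `edukin --help`). Every artifact-producing command writes a JSON manifest
with config, seeds and SHA-256 digests.

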