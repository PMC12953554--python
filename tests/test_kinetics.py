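"""Kinetic estimators: aggregation, segmented fit, closed-form inversion,
bootstrap, and condition contrasts."""

import numpy as np
import pandas as pd
import pytest

from edukinetics import (
    InsufficientDataError,
    KineticEstimate,
    NoGrowthError,
    NoSaturationError,
    SegmentedFit,
    ValidationError,
    aggregate_curve,
    bootstrap_estimate,
    compare_conditions,
    estimate_linear_rise,
    estimate_paper_breakpoint,
    fit_segmented,
    generate_lagged_rise_curve,
    LabelingProtocol,
    LaggedRiseShape,
    lagged_rise_expectation,
)

from conftest import noiseless_aggregate


def curve_from_fields(fields_by_time):
    rows = []
    for t, fields in fields_by_time.items():
        for i, (pos, tot) in enumerate(fields):
            rows.append(("c", 1, i + 1, float(t), pos, tot))
    return pd.DataFrame(
        rows, columns=["condition", "replicate", "field", "time_h", "n_pos", "n_total"]
    )


class TestAggregate:
    def test_two_field_mean_and_sem(self):
        curve = curve_from_fields({1: [(40, 100), (50, 100)]})
        agg = aggregate_curve(curve)
        assert agg.loc[0, "mean_index"] == pytest.approx(0.45)
        assert agg.loc[0, "sem"] == pytest.approx(0.05)

    def test_single_empty_field(self):
        agg = aggregate_curve(curve_from_fields({1: [(0, 100)]}))
        assert agg.loc[0, "mean_index"] == 0.0
        assert agg.loc[0, "sem"] == 0.0

    def test_zero_total_identified(self):
        curve = curve_from_fields({1: [(0, 100)]})
        curve.loc[0, "n_total"] = 0
        with pytest.raises(ValidationError, match="n_total"):
            aggregate_curve(curve)

    def test_binomial_oracle(self):
        rng = np.random.default_rng(0)
        fields = [(int(rng.binomial(200, 0.436)), 200) for _ in range(15)]
        agg = aggregate_curve(curve_from_fields({1: fields}))
        assert abs(agg.loc[0, "mean_index"] - 0.436) < 3 * max(agg.loc[0, "sem"], 1e-6)


class TestSegmentedFit:
    @pytest.mark.parametrize(
        "shape",
        [
            LaggedRiseShape(0.436, 10.0, 21.0, 0.95),
            LaggedRiseShape(0.434, 16.0, 26.0, 0.95),
        ],
    )
    def test_noiseless_inversion(self, shape):
        agg = noiseless_aggregate(lambda t: lagged_rise_expectation(shape, t))
        fit = fit_segmented(agg, grid_step=0.1)
        assert fit.break1 == pytest.approx(shape.break1, abs=0.1)
        assert fit.break2 == pytest.approx(shape.break2, abs=0.1)
        assert fit.level0 == pytest.approx(shape.level0, abs=1e-9)
        assert fit.plateau == pytest.approx(shape.plateau, abs=1e-9)
        assert fit.rss == pytest.approx(0.0, abs=1e-12)

    def test_flat_curve_degenerate(self):
        agg = noiseless_aggregate(lambda t: np.full_like(t, 0.5))
        with pytest.raises(NoSaturationError):
            fit_segmented(agg)

    def test_still_rising_rejected(self):
        agg = noiseless_aggregate(lambda t: np.clip(t / 80, 0, 1))
        with pytest.raises(NoSaturationError):
            fit_segmented(agg)

    def test_too_few_timepoints(self):
        agg = noiseless_aggregate(lambda t: np.minimum(1, (t + 6) / 24),
                                  times=(1, 4, 8, 10))
        with pytest.raises(InsufficientDataError):
            fit_segmented(agg)

    def test_refine_never_worse(self, dmso_shape, lagged_protocol):
        curve = generate_lagged_rise_curve(dmso_shape, lagged_protocol, seed=21)
        agg = aggregate_curve(curve)
        coarse = fit_segmented(agg, grid_step=0.5)
        refined = fit_segmented(agg, grid_step=0.5, refine=True)
        assert refined.rss <= coarse.rss + 1e-12


def brute_force_segmented(t, y, w, grid_step):
    """Independent exhaustive search: plain loops over every grid pair with
    the same admissibility rules and tie-breaking (smallest b1, then b2)."""
    t0, tmax = t[0], t[-1]
    cand = []
    b = t0
    while b < tmax - grid_step * 0.5 - 1e-12:
        cand.append(round(b, 10))
        b += grid_step
    best = None
    for b1 in cand:
        for b2 in cand:
            if not b1 < b2:
                continue
            left = [k for k in range(len(t)) if t[k] <= b1]
            right = [k for k in range(len(t)) if t[k] >= b2]
            if not left or not right or len(left) == len(t) or len(right) == len(t):
                continue
            level0 = sum(w[k] * y[k] for k in left) / sum(w[k] for k in left)
            plateau = sum(w[k] * y[k] for k in right) / sum(w[k] for k in right)
            if plateau < level0:
                continue
            rss = 0.0
            for k in range(len(t)):
                if k in left:
                    pred = level0
                elif k in right:
                    pred = plateau
                else:
                    pred = level0 + (plateau - level0) * (t[k] - b1) / (b2 - b1)
                rss += w[k] * (y[k] - pred) ** 2
            if best is None or rss < best[0]:
                best = (rss, b1, b2)
    return best


class TestBruteForceEquivalence:
    def test_matches_exhaustive_search(self):
        """Grid fit equals the plain-loop exhaustive oracle on noisy curves."""
        rng = np.random.default_rng(123)
        proto = LabelingProtocol(mode="lagged_rise")
        checked = 0
        for _ in range(10):
            shape = LaggedRiseShape(
                level0=rng.uniform(0.2, 0.5),
                break1=rng.uniform(5, 14),
                break2=rng.uniform(20, 30),
                plateau=rng.uniform(0.75, 0.98),
            )
            curve = generate_lagged_rise_curve(shape, proto,
                                               seed=int(rng.integers(2**31)))
            agg = aggregate_curve(curve)
            try:
                fit = fit_segmented(agg, grid_step=0.5)
            except NoSaturationError:
                continue
            t = agg["time_h"].to_numpy()
            y = agg["mean_index"].to_numpy()
            w = agg["n_fields"].to_numpy(dtype=float)
            rss, b1, b2 = brute_force_segmented(list(t), list(y), list(w), 0.5)
            assert fit.break1 == pytest.approx(b1, abs=1e-9)
            assert fit.break2 == pytest.approx(b2, abs=1e-9)
            assert fit.rss == pytest.approx(rss, rel=1e-9)
            checked += 1
        assert checked >= 8


class TestBreakpointEstimate:
    @pytest.mark.parametrize(
        "b1, b2, ts, tc",
        [(10.0, 21.0, 10.0, 31.0), (16.0, 26.0, 16.0, 42.0),
         (5.0, 5.0001, 5.0, 10.0001)],
    )
    def test_arithmetic(self, b1, b2, ts, tc):
        fit = SegmentedFit(break1=b1, break2=b2, level0=0.4, plateau=0.95,
                           rss=0.0, n_points=11)
        est = estimate_paper_breakpoint(fit)
        assert est.ts_hat == pytest.approx(ts)
        assert est.tc_hat == pytest.approx(tc)
        assert est.tsat_hat == pytest.approx(tc - ts)
        assert est.tc_hat > est.ts_hat > 0

    def test_invariant_enforced(self):
        with pytest.raises(ValidationError):
            KineticEstimate(method="paper_breakpoint", gf_hat=0.9,
                            ts_hat=10, tc_hat=8, tsat_hat=-2)


class TestLinearRise:
    @pytest.mark.parametrize(
        "gf, ts, tc",
        [(1.0, 6.0, 24.0), (0.8, 10.0, 31.0)],
    )
    def test_closed_form_identity(self, gf, ts, tc):
        agg = noiseless_aggregate(lambda t: gf * np.minimum(1, (t + ts) / tc))
        est = estimate_linear_rise(agg)
        assert est.gf_hat == pytest.approx(gf, abs=1e-12)
        assert est.ts_hat == pytest.approx(ts, abs=1e-9)
        assert est.tc_hat == pytest.approx(tc, abs=1e-9)
        assert est.tsat_hat == pytest.approx(tc - ts, abs=1e-9)

    def test_falling_curve_no_growth(self):
        agg = noiseless_aggregate(lambda t: 0.9 - 0.002 * t)
        with pytest.raises((NoGrowthError, NoSaturationError)):
            estimate_linear_rise(agg)

    def test_still_rising_no_plateau(self):
        agg = noiseless_aggregate(lambda t: np.clip(t / 80, 0, 1))
        with pytest.raises(NoSaturationError):
            estimate_linear_rise(agg)

    def test_recovery_on_simulated_agent_curve(self, dmso_agent_params):
        from edukinetics import simulate_cumulative_labeling

        proto = LabelingProtocol(mode="agent")
        params = dmso_agent_params
        ests = []
        for seed in range(5):
            curve = simulate_cumulative_labeling(
                type(params)(tc_mean=31, tc_cv=0, ts=10, growth_fraction=0.9),
                proto, seed=seed)
            est = estimate_linear_rise(aggregate_curve(curve))
            ests.append((est.ts_hat, est.tc_hat))
        med_ts = np.median([e[0] for e in ests])
        med_tc = np.median([e[1] for e in ests])
        assert med_ts == pytest.approx(10, abs=2)
        assert med_tc == pytest.approx(31, abs=2)


class TestBootstrap:
    def test_requires_minimum_replicates(self, dmso_shape, lagged_protocol):
        curve = generate_lagged_rise_curve(dmso_shape, lagged_protocol, seed=1)
        with pytest.raises(ValidationError):
            bootstrap_estimate(curve, n_boot=50)

    def test_point_estimate_ignores_seed(self, dmso_shape, lagged_protocol):
        curve = generate_lagged_rise_curve(dmso_shape, lagged_protocol, seed=2)
        a = bootstrap_estimate(curve, n_boot=100, seed=1)
        b = bootstrap_estimate(curve, n_boot=100, seed=999)
        assert a.ts_hat == b.ts_hat and a.tc_hat == b.tc_hat
        for est in (a, b):
            assert est.ci_ts[0] <= est.ts_hat <= est.ci_ts[1]
            assert est.ci_tc[0] <= est.tc_hat <= est.ci_tc[1]
            assert est.ci_gf[0] <= est.gf_hat <= est.ci_gf[1]

    def test_noiseless_curve_tight_ci(self, dmso_shape):
        """Identical fields carry no resampling variance: CI width <= grid."""
        exp = lagged_rise_expectation(dmso_shape, np.array([1, 4, 8, 10, 12, 14, 16, 20, 24, 38, 60], float))
        rows = []
        for rep in (1, 2, 3):
            for f in range(1, 6):
                for t, p in zip([1, 4, 8, 10, 12, 14, 16, 20, 24, 38, 60], exp):
                    rows.append(("c", rep, f, float(t), int(round(p * 1000)), 1000))
        curve = pd.DataFrame(rows, columns=["condition", "replicate", "field",
                                            "time_h", "n_pos", "n_total"])
        est = bootstrap_estimate(curve, n_boot=100, seed=0, boot_grid_step=0.25)
        assert est.ci_ts[1] - est.ci_ts[0] <= 0.25 + 1e-9


class TestCompare:
    def _est(self, ts, tc, boot=None):
        e = KineticEstimate(method="paper_breakpoint", gf_hat=0.95,
                            ts_hat=ts, tc_hat=tc, tsat_hat=tc - ts)
        e.boot_samples = boot
        return e

    def test_study_arm_deltas(self):
        cmp = compare_conditions(self._est(10, 31), self._est(16, 42))
        assert cmp.delta_ts == pytest.approx(6)
        assert cmp.delta_tc == pytest.approx(11)
        back = compare_conditions(self._est(16, 42), self._est(10, 31))
        assert back.delta_tc == pytest.approx(-11)

    def test_identical_estimates(self):
        cmp = compare_conditions(self._est(10, 31), self._est(10, 31))
        assert cmp.delta_ts == 0 and cmp.delta_tc == 0

    def test_method_mismatch(self):
        lin = KineticEstimate(method="linear_rise", gf_hat=0.9, ts_hat=10,
                              tc_hat=31, tsat_hat=21)
        with pytest.raises(ValidationError):
            compare_conditions(self._est(10, 31), lin)

    def test_exceedance_from_bootstrap(self):
        boot_a = pd.DataFrame({"ts_hat": [10.0] * 10, "tc_hat": [31.0] * 10,
                               "gf_hat": [0.95] * 10})
        boot_b = pd.DataFrame({"ts_hat": [16.0] * 9 + [9.0],
                               "tc_hat": [42.0] * 10, "gf_hat": [0.95] * 10})
        cmp = compare_conditions(self._est(10, 31, boot_a),
                                 self._est(16, 42, boot_b))
        assert cmp.p_ts == pytest.approx(0.1)
        assert cmp.p_tc == pytest.approx(0.0)


class TestRoundTrip:
    def test_generate_fit_recovers_shape(self, dmso_shape, lagged_protocol):
        """Lagged-rise generation -> segmented fit recovers the shape within
        max(grid_step, 1.5 h) at default noise."""
        curve = generate_lagged_rise_curve(dmso_shape, lagged_protocol, seed=17)
        fit = fit_segmented(aggregate_curve(curve))
        est = estimate_paper_breakpoint(fit)
        assert fit.break1 == pytest.approx(dmso_shape.break1, abs=1.5)
        assert fit.break2 == pytest.approx(dmso_shape.break2, abs=1.5)
        assert fit.plateau == pytest.approx(dmso_shape.plateau, abs=0.05)
        assert est.tc_hat == est.ts_hat + est.tsat_hat
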