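"""Trace normalisation, sigmoid descriptors, dose response and global fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fibrilkit import (
    AggregationTrace,
    GlobalRateLawModel,
    ThTDatasetSpec,
    TraceCondition,
    d105n_like_effect,
    dose_response_summary,
    fit_sigmoid,
    integrate_moment_odes,
    normalize_and_average,
    normalize_trace,
    relative_amorphous_aggregation,
    simulate_amorphous,
    simulate_tht_dataset,
    wildtype_like_effect,
)
from fibrilkit.simulate import AmorphousSpec
from fibrilkit.tht import sigmoid

H = 3600.0


def make_sigmoid_trace(F0=100.0, A=400.0, r_max=0.8 / H, tau=10 * H, hours=24, n=400, **cond):
    t = np.linspace(0, hours * H, n)
    return AggregationTrace(t=t, y=sigmoid(t, F0, A, r_max, tau), condition=TraceCondition(**cond))


def group_by_ratio(traces):
    by = {}
    for tr in traces:
        by.setdefault(tr.condition.ratio_percent, []).append(tr)
    return by


class TestNormalization:
    def test_affine_normalization_of_clean_sigmoid(self):
        out = normalize_and_average([make_sigmoid_trace()])
        assert np.mean(out.y[:5]) == pytest.approx(0.0, abs=0.01)
        assert np.mean(out.y[-20:]) == pytest.approx(1.0, abs=0.01)

    def test_averaging_identical_replicates_is_idempotent(self):
        reps = [make_sigmoid_trace(replicate=i) for i in range(3)]
        out = normalize_and_average(reps)
        single = normalize_trace(reps[0])
        assert out.y == pytest.approx(single.y, abs=1e-12)

    def test_mixed_conditions_rejected(self):
        a = make_sigmoid_trace(ratio_percent=0.0)
        b = make_sigmoid_trace(ratio_percent=50.0)
        with pytest.raises(ValueError, match="mixed conditions"):
            normalize_and_average([a, b])

    def test_averaging_reduces_noise(self):
        """The replicate average is closer to truth than any single replicate."""
        spec = ThTDatasetSpec(seed=5, ratios=(0.0,), replicates=4)
        traces = simulate_tht_dataset(spec)
        truth = integrate_moment_odes(spec.baseline, spec.t).normalized_mass
        avg = normalize_and_average(traces)
        sse_avg = np.sum((np.interp(avg.t, spec.t, truth) - avg.y) ** 2)
        for tr in traces:
            single = normalize_trace(tr)
            assert sse_avg < np.sum((truth - single.y) ** 2)

    @given(a=st.floats(0.1, 50.0), b=st.floats(-200.0, 500.0))
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance(self, a, b):
        """y -> a*y + b leaves the normalized trace unchanged."""
        tr = make_sigmoid_trace()
        scaled = AggregationTrace(t=tr.t, y=a * tr.y + b, condition=tr.condition)
        assert normalize_trace(scaled).y == pytest.approx(normalize_trace(tr).y, abs=1e-9)


class TestSigmoidFit:
    def test_exact_recovery_on_noiseless_curve(self):
        fit = fit_sigmoid(make_sigmoid_trace())
        assert fit.tau_half == pytest.approx(10 * H, rel=1e-6)
        assert fit.r_max == pytest.approx(0.8 / H, rel=1e-6)
        assert fit.F0 == pytest.approx(100.0, rel=1e-6)
        assert fit.A == pytest.approx(400.0, rel=1e-6)

    def test_midpoint_identity(self):
        fit = fit_sigmoid(make_sigmoid_trace())
        assert fit.predict(np.array([fit.tau_half]))[0] == pytest.approx(
            fit.F0 + fit.A / 2, rel=1e-12
        )

    def test_flat_trace_rejected(self):
        t = np.linspace(0, 10 * H, 200)
        rng = np.random.default_rng(0)
        tr = AggregationTrace(t=t, y=100 + rng.normal(0, 1.0, len(t)))
        with pytest.raises(ValueError, match="no transition"):
            fit_sigmoid(tr)

    def test_monte_carlo_half_time_recovery(self):
        """Median tau_1/2 error <= 2% over noisy replicates at 2% noise."""
        rng = np.random.default_rng(42)
        t = np.linspace(0, 24 * H, 300)
        truth = sigmoid(t, 100, 400, 0.8 / H, 10 * H)
        errs = []
        for _ in range(100):
            y = truth * (1 + 0.02 * rng.standard_normal(len(t)))
            fit = fit_sigmoid(AggregationTrace(t=t, y=y))
            errs.append(abs(fit.tau_half - 10 * H) / (10 * H))
        assert np.median(errs) <= 0.02

    def test_half_time_matches_rate_law_half_completion(self, baseline_params):
        """The sigmoid's tau_1/2 tracks the kinetic model's half-completion
        time within 3% even though the rate law is not a logistic."""
        t = np.linspace(0, 16 * H, 400)
        traj = integrate_moment_odes(baseline_params, t)
        fit = fit_sigmoid(AggregationTrace(t=t, y=traj.normalized_mass))
        assert fit.tau_half == pytest.approx(traj.half_time(), rel=0.03)


class TestDoseResponse:
    def test_exact_linear_and_exponential_recovery(self):
        ratios = [0.0, 10.0, 30.0, 50.0, 100.0]
        fits = {
            r: type("F", (), {"tau_half": 7200 + 300 * r, "r_max": 5e-4 * np.exp(-r / 40)})()
            for r in ratios
        }
        s = dose_response_summary(fits)
        assert s.tau_slope == pytest.approx(300.0, rel=1e-9)
        assert s.tau_intercept == pytest.approx(7200.0, rel=1e-9)
        assert s.rmax_r0 == pytest.approx(5e-4, rel=1e-6)
        assert s.rmax_c0 == pytest.approx(40.0, rel=1e-6)

    def test_requires_three_ratios_with_zero(self):
        fits = {10.0: None, 50.0: None}
        with pytest.raises(ValueError):
            dose_response_summary(fits)

    def test_simulated_dose_series_directionality(self):
        """k_2 suppression: tau_1/2 rises and r_max falls with dose."""
        spec = ThTDatasetSpec(
            seed=9, effect=wildtype_like_effect(), ratios=(0.0, 30.0, 70.0), replicates=3
        )
        fits = {
            r: fit_sigmoid(normalize_and_average(v))
            for r, v in group_by_ratio(simulate_tht_dataset(spec)).items()
        }
        taus = [fits[r].tau_half for r in sorted(fits)]
        rmaxs = [fits[r].r_max for r in sorted(fits)]
        assert taus == sorted(taus)
        assert rmaxs == sorted(rmaxs, reverse=True)


class TestGlobalFit:
    def test_mechanism_attribution_and_scale_recovery(self):
        """Data generated by pure k_2 suppression: the k_2-free fit wins the
        chi2 comparison and recovers the dose scalings within 10%."""
        spec = ThTDatasetSpec(
            seed=17, effect=wildtype_like_effect(), ratios=(0.0, 30.0, 70.0), replicates=3
        )
        avg = [
            normalize_and_average(v)
            for _, v in sorted(group_by_ratio(simulate_tht_dataset(spec)).items())
        ]
        results = {
            fp: GlobalRateLawModel(avg, free_parameter=fp, normalize=False).fit()
            for fp in ("k_n", "k_2", "k_plus")
        }
        chi2 = {fp: r.chi2 for fp, r in results.items()}
        assert chi2["k_2"] < chi2["k_plus"] and chi2["k_2"] < chi2["k_n"]
        for ratio, scale in results["k_2"].per_condition_scale.items():
            assert scale == pytest.approx(np.exp(-ratio / 60.0), rel=0.10)

    def test_combined_rate_free_parameter_matches_k2(self):
        """sqrt(k_plus k_2) free reproduces the same kappa^2 scaling path."""
        spec = ThTDatasetSpec(
            seed=23, effect=wildtype_like_effect(), ratios=(0.0, 50.0), replicates=3
        )
        avg = [
            normalize_and_average(v)
            for _, v in sorted(group_by_ratio(simulate_tht_dataset(spec)).items())
        ]
        r_k2 = GlobalRateLawModel(avg, free_parameter="k_2", normalize=False).fit()
        r_comb = GlobalRateLawModel(avg, free_parameter="sqrt_k_plus_k_2", normalize=False).fit()
        assert r_comb.per_condition_scale[50.0] ** 2 == pytest.approx(
            r_k2.per_condition_scale[50.0], rel=1e-3
        )
        assert r_comb.chi2 == pytest.approx(r_k2.chi2, rel=1e-6)

    def test_baseline_only_dataset(self):
        spec = ThTDatasetSpec(seed=3, ratios=(0.0,), replicates=3)
        avg = [normalize_and_average(simulate_tht_dataset(spec))]
        res = GlobalRateLawModel(avg, free_parameter="k_2", normalize=False).fit()
        assert res.per_condition_values == {}
        n = len(avg[0].t)
        assert res.chi2 == pytest.approx(res.baseline_sse / (n - 2))

    def test_missing_baseline_condition_rejected(self):
        tr = make_sigmoid_trace(ratio_percent=50.0)
        with pytest.raises(ValueError, match="0%"):
            GlobalRateLawModel([tr])


class TestAmorphousAggregation:
    def test_sample_equals_control(self):
        ctrl = simulate_amorphous(AmorphousSpec(seed=1, suppression=1.0, noise_frac=0))
        assert relative_amorphous_aggregation(ctrl, ctrl) == pytest.approx(100.0)

    def test_flat_sample_is_zero(self):
        ctrl = simulate_amorphous(AmorphousSpec(seed=1, suppression=1.0, noise_frac=0))
        flat = simulate_amorphous(AmorphousSpec(seed=2, suppression=0.0, noise_frac=0))
        assert relative_amorphous_aggregation(flat, ctrl) == pytest.approx(0.0, abs=0.5)

    def test_suppression_factor_recovered(self):
        """40% suppression with 1% noise reads out as 40 +/- 3 percent."""
        ctrl = simulate_amorphous(AmorphousSpec(seed=11, suppression=1.0))
        samp = simulate_amorphous(AmorphousSpec(seed=12, suppression=0.4))
        rel = relative_amorphous_aggregation(samp, ctrl)
        assert rel == pytest.approx(40.0, abs=3.0)

    def test_flat_control_rejected(self):
        flat = simulate_amorphous(AmorphousSpec(seed=3, suppression=0.0))
        ctrl = simulate_amorphous(AmorphousSpec(seed=4, suppression=1.0))
        with pytest.raises(ValueError, match="control"):
            relative_amorphous_aggregation(ctrl, flat)

    def test_non_amorphous_assay_rejected(self):
        tht = make_sigmoid_trace()
        ctrl = simulate_amorphous(AmorphousSpec(seed=5))
        with pytest.raises(ValueError):
            relative_amorphous_aggregation(tht, ctrl)
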