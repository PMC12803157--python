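import numpy as np
import pytest

from denngap import kinetics
from denngap.kinetics import (
    FluorescenceTrace,
    TraceError,
    assess_gef,
    endpoint_activity,
    fit_single_exponential,
    fit_standard_curve,
    gap_rate,
    invert_standard_curve,
    normalize_trace,
)
from denngap.synthetic import CALIBRATION_CONDITIONS, make_trace


def _trace(k=0.01, f0=1.0, f_inf=0.0, n=512, noise=0.0, seed=0):
    return make_trace(k, f0=f0, f_inf=f_inf, n_samples=n, noise_sd=noise, seed=seed)


class TestNormalizeTrace:
    def test_affine_map_to_unit_span(self):
        tr = _trace(k=0.05, f0=2.0, f_inf=1.0)
        norm = normalize_trace(tr)
        assert norm.values[0] == pytest.approx(1.0, abs=0.02)
        assert norm.values[-1] == pytest.approx(0.0, abs=0.02)
        # raw trace untouched
        assert tr.values[0] == pytest.approx(2.0)

    def test_constant_trace_is_degenerate(self):
        with pytest.raises(TraceError, match="need at least 8|span"):
            normalize_trace(
                FluorescenceTrace(times=np.arange(10.0), values=np.full(10, 3.0))
            )

    def test_noisy_tail_lands_near_zero(self):
        tr = _trace(k=0.02, noise=0.02, seed=12)
        norm = normalize_trace(tr)
        tail = norm.values[-51:]
        assert abs(tail.mean()) <= 0.02


class TestFitSingleExponential:
    def test_noise_free_recovery_to_machine_tolerance(self):
        tr = make_trace(0.01, n_samples=512, duration=700.0)
        fit = fit_single_exponential(tr)
        assert fit.converged
        assert fit.k_obs == pytest.approx(0.01, rel=1e-6)
        assert fit.f0 == pytest.approx(1.0, abs=1e-6)
        assert fit.f_inf == pytest.approx(0.0, abs=1e-6)

    def test_published_membrane_condition_round_trips(self):
        cond = CALIBRATION_CONDITIONS["avl9_myr_arf1_rab8"]
        fit = fit_single_exponential(make_trace(cond))
        rate = gap_rate(fit, cond.gap_conc, cond.id)
        assert rate.rate == pytest.approx(480e4, rel=1e-6)

    def test_flat_trace_rejected(self):
        with pytest.raises(TraceError, match="degenerate"):
            fit_single_exponential(
                FluorescenceTrace(times=np.arange(20.0), values=np.full(20, 5.0))
            )

    def test_affine_invariance_of_rate(self):
        tr = _trace(k=0.03, noise=0.01, seed=3)
        k1 = fit_single_exponential(tr).k_obs
        scaled = FluorescenceTrace(
            times=tr.times, values=7.5 * tr.values + 100.0, label="scaled"
        )
        k2 = fit_single_exponential(scaled).k_obs
        assert k2 == pytest.approx(k1, rel=1e-8)

    @pytest.mark.parametrize("k_true", [1e-3, 1e-2, 1e-1])
    def test_noisy_recovery_within_five_percent(self, k_true):
        errs = []
        for seed in range(10):
            tr = make_trace(k_true, noise_sd=0.02, seed=seed)
            errs.append(abs(fit_single_exponential(tr).k_obs - k_true) / k_true)
        assert np.median(errs) < 0.05


class TestGapRate:
    def test_unit_divisor(self):
        fit = fit_single_exponential(_trace(k=0.02))
        assert gap_rate(fit, 1.0).rate == pytest.approx(fit.k_obs)

    def test_micromolar_gap(self):
        fit = fit_single_exponential(_trace(k=1.5e-2))
        rate = gap_rate(fit, 1e-6, "soluble")
        assert rate.rate == pytest.approx(1.5e4, rel=1e-4)
        assert rate.rate_1e4 == pytest.approx(1.5, rel=1e-4)

    def test_nanomolar_gap(self):
        fit = fit_single_exponential(_trace(k=4.8e-3))
        assert gap_rate(fit, 1e-9).rate == pytest.approx(4.8e6, rel=1e-4)

    def test_doubling_concentration_halves_rate(self):
        fit = fit_single_exponential(_trace(k=0.02))
        assert gap_rate(fit, 2e-6).rate == pytest.approx(
            gap_rate(fit, 1e-6).rate / 2
        )

    def test_nonpositive_concentration_rejected(self):
        fit = fit_single_exponential(_trace())
        with pytest.raises(ValueError, match="positive"):
            gap_rate(fit, 0.0)


class TestStandardCurve:
    def test_exact_line_recovered_and_inverted(self):
        concs = np.array([0.0, 2.0, 5.0, 10.0])
        absorb = 0.05 * concs + 0.04
        curve = fit_standard_curve(concs, absorb)
        assert curve.slope == pytest.approx(0.05)
        assert curve.intercept == pytest.approx(0.04)
        assert curve.r_squared == pytest.approx(1.0)
        assert invert_standard_curve(curve, 0.29) == pytest.approx(5.0)

    def test_invert_at_intercept_is_zero(self):
        curve = fit_standard_curve([0, 1, 2], [0.1, 0.2, 0.3])
        assert invert_standard_curve(curve, curve.intercept) == pytest.approx(0.0)

    def test_roundtrip_on_exact_data(self, rng):
        concs = np.array([0.0, 1.0, 2.5, 7.0, 12.0])
        absorb = 0.033 * concs + 0.01
        curve = fit_standard_curve(concs, absorb)
        back = [invert_standard_curve(curve, a) for a in absorb]
        assert np.allclose(back, concs, rtol=1e-10, atol=1e-10)

    def test_noisy_standards_still_fit_well(self):
        rng = np.random.default_rng(5)
        concs = np.array([0.0, 2.0, 5.0, 10.0, 20.0])
        absorb = 0.05 * concs + 0.04 + rng.normal(0, 0.005, concs.size)
        assert fit_standard_curve(concs, absorb).r_squared >= 0.98

    def test_singular_design_rejected(self):
        with pytest.raises(ValueError, match="equal"):
            fit_standard_curve([2.0, 2.0, 2.0], [0.1, 0.2, 0.3])


class TestEndpointActivity:
    def test_equal_phosphate_means_zero_activity(self):
        assert endpoint_activity(1.0, 1.0).activity == 0.0

    def test_five_minute_reaction(self):
        res = endpoint_activity(6.0, 1.0, reaction_time=5.0)
        assert res.activity == pytest.approx(1.0)
        assert not res.negative

    def test_negative_activity_flagged_not_rejected(self):
        res = endpoint_activity(0.5, 1.0, reaction_time=5.0)
        assert res.activity == pytest.approx(-0.1)
        assert res.negative

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            endpoint_activity(1.0, 0.0, reaction_time=0.0)


class TestAssessGef:
    def test_identical_traces_are_not_detectable(self):
        tr = _trace(k=5e-3)
        res = assess_gef(tr, tr)
        assert res.fold == pytest.approx(1.0, rel=1e-6)
        assert not res.detectable

    def test_fivefold_rate_is_detectable(self):
        res = assess_gef(_trace(k=2e-3, n=512), _trace(k=1e-2, n=512))
        assert res.fold == pytest.approx(5.0, rel=1e-3)
        assert res.detectable

    def test_threshold_boundary(self):
        res = assess_gef(_trace(k=1e-3), _trace(k=1.5e-3), detection_fold=2.0)
        assert not res.detectable
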