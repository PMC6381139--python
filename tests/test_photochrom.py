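"""Three-state photochromism model: propagation, simulation, fitting,
scoring and classification."""

import numpy as np
import pytest
import scipy.linalg

from conftest import rk4_states
from fpchar.core import (
    ExposureEvent,
    ExposureSchedule,
    PhotochromParams,
    StateVector,
    ValidationError,
)
from fpchar.photochrom import (
    fit,
    propagate,
    propagation_matrix,
    score,
    simulate,
)
from fpchar.synth import make_schedule


def _full_matrix(params, channel):
    if channel is None:
        alpha, beta = params.s_nd, params.s_dn
    else:
        alpha = params.k_nd.get(channel, 0.0) + params.s_nd
        beta = params.k_dn.get(channel, 0.0) + params.s_dn
    g = params.k_di
    return np.array(
        [[-alpha, beta, 0.0], [alpha, -(beta + g), 0.0], [0.0, g, 0.0]]
    )


class TestPropagate:
    def test_zero_rates_identity(self):
        s = StateVector(0.4, 0.35, 0.25)
        out = propagate(s, "GFP", PhotochromParams(), 5.0)
        assert out == s

    def test_zero_dt_identity(self):
        p = PhotochromParams(k_nd={"GFP": 0.3}, s_nd=0.1, k_di=0.2)
        s = StateVector(0.5, 0.3, 0.2)
        assert propagate(s, "GFP", p, 0.0) == s

    def test_negative_dt_rejected(self):
        with pytest.raises(ValueError):
            propagate(StateVector(1, 0, 0), None, PhotochromParams(), -1.0)

    def test_matches_scipy_expm(self, rate_draws):
        """The analytic matrix exponential equals scipy's on 100 draws."""
        for params in rate_draws:
            for ch in ("GFP", None):
                ours = propagation_matrix(params, ch, 1.7)
                ref = scipy.linalg.expm(_full_matrix(params, ch) * 1.7)
                np.testing.assert_allclose(ours, ref, atol=1e-12)

    def test_matches_rk4_oracle(self, rate_draws):
        """Propagation agrees with a step-1e-4 RK4 integrator."""
        s0 = np.array([0.7, 0.2, 0.1])
        for params in rate_draws[:25]:
            out = propagate(StateVector(*s0), "GFP", params, 1.0)
            ref = rk4_states(params, "GFP", 1.0, s0)
            np.testing.assert_allclose(out.as_array(), ref, atol=1e-8)

    def test_semigroup(self, rate_draws):
        for params in rate_draws[:25]:
            s = StateVector(0.6, 0.3, 0.1)
            once = propagate(s, "RFP", params, 2.5)
            twice = propagate(propagate(s, "RFP", params, 1.0), "RFP", params, 1.5)
            np.testing.assert_allclose(
                once.as_array(), twice.as_array(), atol=1e-10
            )

    def test_conservation_and_nonnegativity(self, rate_draws):
        for params in rate_draws:
            s = StateVector(1.0, 0.0, 0.0)
            for dt, ch in [(0.2, "GFP"), (2.8, None), (0.2, "RFP"), (10.0, None)]:
                s = propagate(s, ch, params, dt)
                arr = s.as_array()
                assert abs(arr.sum() - 1.0) <= 1e-9
                assert np.all(arr >= -1e-12)

    def test_irrdark_monotone(self, rate_draws):
        for params in rate_draws[:25]:
            s = StateVector(1.0, 0.0, 0.0)
            prev = 0.0
            for dt, ch in [(0.2, "GFP"), (2.8, None)] * 10:
                s = propagate(s, ch, params, dt)
                assert s.irrdark >= prev - 1e-12
                prev = s.irrdark


class TestSimulate:
    def test_zero_rates_flat(self):
        tr = simulate(PhotochromParams(), make_schedule("single", "GFP", n_frames=20))
        np.testing.assert_allclose(tr.normalized, 1.0)

    def test_closed_form_exponential_in_cumulative_exposure(self):
        """With only the own-channel bleach rate active, the m-th
        measurement is exp(-k * tau * (m-1)) exactly."""
        k, tau = 0.07, 0.2
        p = PhotochromParams(k_nd={"GFP": k})
        tr = simulate(p, make_schedule("single", "GFP"))
        m = np.arange(tr.n_frames)
        np.testing.assert_allclose(tr.normalized, np.exp(-k * tau * m), atol=1e-10)

    def test_empty_schedule_rejected(self):
        with pytest.raises(ValidationError):
            simulate(PhotochromParams(), ExposureSchedule([]))

    def test_dark_start_photoactivation_rises(self):
        # mostly dark-starting FP pumped back by the second wavelength
        p = PhotochromParams(k_nd={"GFP": 0.01}, k_dn={"CFP": 2.0})
        sched = make_schedule("dual", "GFP", "CFP", n_frames=40)
        tr = simulate(p, sched, initial=StateVector(0.2, 0.8, 0.0))
        assert tr.normalized.max() > 1.0
        assert tr.raw.max() > tr.raw[0]

    def test_one_frame_per_own_event(self):
        sched = make_schedule("dual", "GFP", "RFP", n_frames=10)
        tr = simulate(PhotochromParams(k_nd={"GFP": 0.1}), sched)
        assert tr.n_frames == 5
        np.testing.assert_allclose(tr.frame_times_s, np.arange(5) * 6.0)


IDENTIFIABLE_TRUTH = PhotochromParams(
    k_nd={"CFP": 0.02, "RFP": 0.004}, k_dn={"RFP": 0.06}, k_di=0.002
)


def _truth_traces(truth, initial=None):
    single = make_schedule("single", "CFP")
    dual = make_schedule("dual", "CFP", "RFP")
    return [
        simulate(truth, single, initial=initial),
        simulate(truth, dual, initial=initial),
    ]


class TestFit:
    def test_noiseless_recovery_within_10pct(self):
        res = fit(_truth_traces(IDENTIFIABLE_TRUTH))
        p = res.params
        assert p.k_nd["CFP"] == pytest.approx(0.02, rel=0.1)
        assert p.k_nd["RFP"] == pytest.approx(0.004, rel=0.1)
        assert p.k_dn["RFP"] == pytest.approx(0.06, rel=0.1)
        assert p.k_di == pytest.approx(0.002, rel=0.1)

    def test_non_photochromic_truth_gives_tiny_reversible_rates(self):
        truth = PhotochromParams(k_nd={"CFP": 0.01}, k_di=0.001)
        res = fit(_truth_traces(truth))
        p = res.params
        assert p.s_dn <= 1e-3 and p.s_nd <= 1e-3
        assert p.k_dn.get("RFP", 0.0) <= 1e-3
        assert not res.is_photochromic

    def test_requires_single_wavelength_trace(self):
        dual = make_schedule("dual", "CFP", "RFP")
        tr = simulate(IDENTIFIABLE_TRUTH, dual)
        with pytest.raises(ValueError):
            fit([tr])


class TestScore:
    def test_zero_reversible_rates_score_near_zero(self):
        # no reversible rates and no second-channel bleaching: ablating
        # the second wavelength changes nothing, so the score vanishes
        truth = PhotochromParams(k_nd={"CFP": 0.01}, k_di=0.001)
        res = score(truth, _truth_traces(truth))
        assert res.score == pytest.approx(0.0, abs=1e-9)
        assert not res.is_photochromic

    def test_second_channel_bleaching_alone_gives_small_score(self):
        # light-driven darkening by the second wavelength contributes to
        # the deviation but stays far below the classification cutoff
        truth = PhotochromParams(k_nd={"CFP": 0.01, "RFP": 0.002}, k_di=0.001)
        res = score(truth, _truth_traces(truth))
        assert 0 < res.score <= 50.0
        assert not res.is_photochromic

    def test_photoactivation_scores_above_100(self):
        # dark-starting FP pushed into fluorescence by the second
        # wavelength: fluorescence rises ~4x, deviation >= 1 in
        # start-normalized units
        truth = PhotochromParams(k_nd={"GFP": 0.002}, k_dn={"CFP": 1.5})
        initial = StateVector(0.25, 0.75, 0.0)
        dual = make_schedule("dual", "GFP", "CFP", n_frames=60)
        tr = simulate(truth, dual, initial=initial)
        assert tr.normalized.max() >= 3.0
        res = score(truth, [tr], initial=initial)
        assert res.score >= 100.0
        assert res.is_photochromic

    def test_requires_dual_trace(self):
        single = make_schedule("single", "CFP")
        tr = simulate(IDENTIFIABLE_TRUTH, single)
        with pytest.raises(ValueError):
            score(IDENTIFIABLE_TRUTH, [tr])
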