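"""Decay fitting, BIC selection, photostability and half-times."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fpchar.bleach import (
    DegenerateTraceError,
    bic,
    decay_model,
    fit_and_select,
    fit_decay,
    fit_decay_points,
    half_times,
    normalize_trace,
    photostability,
    select_order,
)
from fpchar.core import BleachTrace, DecayFit


def _trace(values, dt=0.5):
    values = np.asarray(values, dtype=float)
    return BleachTrace("fp", "GFP", np.arange(values.size) * dt, values)


def _model_trace(order, a, r, b=0.0, s=0.0, n=181, dt=0.5):
    t = np.arange(n) * dt
    y = decay_model(t, order, a, r, b, s)
    return BleachTrace("fp", "GFP", t, y, normalized=y / y[0])


def _noisy_points(order, a, r, b=0.0, s=0.0, noise=0.01, seed=0, n=181, dt=0.5):
    t = np.arange(n) * dt
    y = decay_model(t, order, a, r, b, s)
    return t, y + noise * np.random.default_rng(seed).standard_normal(n)


def _select_points(t, y):
    return select_order(fit_decay_points(t, y, 1), fit_decay_points(t, y, 2))


class TestNormalize:
    def test_simple(self):
        tr = normalize_trace(_trace([100.0, 50.0]))
        np.testing.assert_allclose(tr.normalized, [1.0, 0.5])

    def test_constant(self):
        tr = normalize_trace(_trace([7.0] * 4))
        np.testing.assert_allclose(tr.normalized, 1.0)

    def test_idempotent(self):
        tr = normalize_trace(_trace([100.0, 50.0, 25.0]))
        again = normalize_trace(tr)
        np.testing.assert_array_equal(tr.normalized, again.normalized)

    def test_degenerate(self):
        with pytest.raises(DegenerateTraceError):
            normalize_trace(_trace([0.0, 1.0]))


class TestPhotostability:
    def test_constant_trace(self):
        assert photostability(_trace([5.0, 5.0, 5.0])) == pytest.approx(1.0)

    def test_last_over_first(self):
        # ends at 94% of the start: the headline photostability convention
        tr = _trace(np.linspace(1000.0, 940.0, 181))
        assert photostability(tr) == pytest.approx(0.94)

    def test_photoactivation_can_exceed_one(self):
        assert photostability(_trace([1.0, 2.0, 3.0])) == pytest.approx(3.0)


class TestFitDecay:
    def test_noiseless_order1_recovery(self):
        tr = _model_trace(1, a=0.8, r=0.01)
        fit = fit_decay(tr, 1)
        assert fit.a == pytest.approx(0.8, abs=1e-6)
        assert fit.r == pytest.approx(0.01, abs=1e-6)
        assert fit.sse < 1e-12

    def test_noiseless_order2_recovery(self):
        tr = _model_trace(2, a=0.5, r=0.1, b=0.3, s=0.005)
        fit = fit_decay(tr, 2)
        assert fit.a == pytest.approx(0.5, rel=1e-4)
        assert fit.b == pytest.approx(0.3, rel=1e-4)
        assert fit.r == pytest.approx(0.1, rel=1e-4)
        assert fit.s == pytest.approx(0.005, rel=1e-4)

    def test_constant_trace_no_amplitude(self):
        fit = fit_decay(_trace([3.0] * 20), 1)
        assert fit.a == pytest.approx(0.0, abs=0.01)
        assert fit.sse == pytest.approx(0.0, abs=1e-12)
        assert fit.halftime_unreliable  # no bleaching: rate unconstrained

    def test_components_sorted_fast_first(self):
        fit = fit_decay(_model_trace(2, a=0.3, r=0.005, b=0.5, s=0.1), 2)
        assert fit.r >= fit.s


class TestBic:
    def test_unit_mean_square(self):
        assert bic(sse=181.0, n=181, k=2) == pytest.approx(2 * math.log(181))

    def test_penalty_monotone_in_k(self):
        assert bic(10.0, 181, 4) > bic(10.0, 181, 2)

    def test_requires_n_gt_k(self):
        with pytest.raises(ValueError):
            bic(1.0, 2, 2)

    def test_perfect_fit_floored(self):
        assert np.isfinite(bic(0.0, 181, 2))


class TestSelection:
    def test_tie_prefers_order1(self):
        f1 = DecayFit(order=1, a=0.5, r=0.1, sse=1.0, bic=-5.0, half_times_s=[])
        f2 = DecayFit(order=2, a=0.3, b=0.2, r=0.2, s=0.01, sse=1.0, bic=-5.0,
                      half_times_s=[])
        assert select_order(f1, f2).order == 1
        assert select_order(f2, f1).order == 1

    def test_mono_trace_selects_order1(self):
        sel = _select_points(*_noisy_points(1, a=0.8, r=0.02))
        assert sel.order == 1

    def test_biexp_trace_selects_order2(self):
        # rate ratio 20 between components
        sel = _select_points(*_noisy_points(2, a=0.5, r=0.1, b=0.3, s=0.005))
        assert sel.order == 2

    def test_selection_rates_small_monte_carlo(self):
        chosen = [
            _select_points(*_noisy_points(1, a=0.8, r=0.02, seed=seed)).order
            for seed in range(30)
        ]
        assert np.mean(np.array(chosen) == 1) >= 0.9

    def test_noiseless_selection_via_traces(self):
        _, _, sel1 = fit_and_select(_model_trace(1, a=0.8, r=0.02))
        assert sel1.order == 1
        _, _, sel2 = fit_and_select(_model_trace(2, a=0.5, r=0.1, b=0.3, s=0.005))
        assert sel2.order == 2


class TestHalfTimes:
    def test_unit_half_time(self):
        fit = DecayFit(order=1, a=0.5, r=math.log(2), sse=0, bic=0, half_times_s=[])
        assert half_times(fit) == [pytest.approx(1.0)]

    def test_headline_half_time(self):
        # rate ln2/490 gives the 490 s half-time of the cyan reference FP
        fit = DecayFit(order=1, a=0.5, r=math.log(2) / 490, sse=0, bic=0,
                       half_times_s=[])
        assert half_times(fit) == [pytest.approx(490.0)]

    def test_order2_ordering(self):
        fit = fit_decay(_model_trace(2, a=0.5, r=0.1, b=0.3, s=0.005), 2)
        t1, t2 = fit.half_times_s
        assert t1 <= t2


@given(
    a=st.floats(0, 1),
    b=st.floats(0, 1),
    r=st.floats(1e-4, 1.0),
    s=st.floats(1e-4, 1.0),
)
def test_model_is_one_at_time_zero(a, b, r, s):
    b = min(b, 1.0 - a)
    assert decay_model(np.array([0.0]), 2, a, r, b, s)[0] == pytest.approx(1.0)
    assert decay_model(np.array([0.0]), 1, a, r)[0] == pytest.approx(1.0)
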