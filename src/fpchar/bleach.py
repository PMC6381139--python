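"""Photostability and exponential decay fitting of bleaching traces.

A normalized bleaching curve is fitted with a one-phase decay,
``F(t) = (1 - a) + a exp(-t r)``, and a two-phase decay,
``F(t) = (1 - a - b) + a exp(-t r) + b exp(-t s)``, with t in seconds and
rates in s^-1; both evaluate to 1 at t = 0 for any admissible parameters.
The Bayesian information criterion (Gaussian concentrated-likelihood
form) chooses between the two, and half-times T_1/2 = ln 2 / rate are
reported per component.  Photostability itself is model-free: the
normalized fluorescence of the last frame.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
from scipy.optimize import least_squares

from .core import BleachTrace, DecayFit, ValidationError

__all__ = [
    "normalize_trace",
    "photostability",
    "decay_model",
    "fit_decay",
    "fit_decay_points",
    "bic",
    "select_order",
    "half_times",
    "fit_and_select",
    "DegenerateTraceError",
    "FitFailureError",
]

#: fitted fast amplitude below which half-times are flagged unreliable
#: (highly photostable FPs barely bleach, leaving the rate unconstrained)
UNRELIABLE_AMPLITUDE = 0.02


class DegenerateTraceError(ValueError):
    """The trace cannot be normalized (first frame <= 0)."""


class FitFailureError(RuntimeError):
    def __init__(self, message: str, best_sse: float | None = None):
        super().__init__(message)
        self.best_sse = best_sse


def normalize_trace(trace: BleachTrace) -> BleachTrace:
    """Normalize a trace to its first frame (idempotent)."""
    if trace.raw[0] <= 0:
        raise DegenerateTraceError("first frame must be > 0 to normalize")
    return replace(trace, normalized=trace.raw / trace.raw[0])


def photostability(trace: BleachTrace) -> float:
    """Fraction of initial fluorescence left at the last frame.

    Values above 1 are legitimate (photoactivating FPs can end brighter
    than they start)."""
    if trace.n_frames < 2:
        raise ValidationError("photostability needs at least 2 frames")
    tr = trace if trace.normalized is not None else normalize_trace(trace)
    return float(tr.normalized[-1])


def decay_model(t: np.ndarray, order: int, a: float, r: float,
                b: float = 0.0, s: float = 0.0) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if order == 1:
        return (1.0 - a) + a * np.exp(-t * r)
    return (1.0 - a - b) + a * np.exp(-t * r) + b * np.exp(-t * s)


_RATE_STARTS_1 = (1e-4, 1e-3, 1e-2, 1e-1, 1.0)
_RATE_STARTS_2 = ((1e-1, 1e-3), (1e-2, 1e-4), (1.0, 1e-2), (1e-1, 1e-2), (1e-2, 1e-3))


def fit_decay(trace: BleachTrace, order: int) -> DecayFit:
    """Nonlinear least squares of the one- or two-phase decay model on a
    normalized trace (normalizing first if needed)."""
    tr = trace if trace.normalized is not None else normalize_trace(trace)
    return fit_decay_points(tr.frame_times_s, tr.normalized, order)


def fit_decay_points(times_s: np.ndarray, values: np.ndarray, order: int) -> DecayFit:
    """Fit the decay model to (time, normalized fluorescence) points.

    Amplitudes are constrained to a, b >= 0 with a + b <= 1 (via the
    substitution a = u, b = (1-u) v with u, v in [0, 1]); rates are
    positive.  A fixed grid of starts spanning decades of rate makes the
    fit deterministic; components are sorted fast-first (r >= s).
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    y = np.asarray(values, dtype=float)
    times_s = np.asarray(times_s, dtype=float)
    if y.size < 2 * order + 1:
        raise ValidationError(f"order-{order} fit needs >= {2 * order + 1} frames")
    t = times_s - times_s[0]
    n = y.size

    best = None
    if order == 1:
        def resid(v):
            a, r = v
            return decay_model(t, 1, a, r) - y
        for r0 in _RATE_STARTS_1:
            sol = least_squares(
                resid, np.array([0.5, r0]),
                bounds=([0.0, 1e-12], [1.0, np.inf]),
                ftol=1e-15, xtol=1e-15, gtol=1e-15,
            )
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise FitFailureError("all starts failed")
        a, r = best.x
        sse = float(2.0 * best.cost)
        fit = DecayFit(
            order=1, a=float(a), r=float(max(r, 1e-12)), sse=sse,
            bic=bic(sse, n, 2), half_times_s=[],
        )
    else:
        def resid(v):
            u, w, r, s = v
            return decay_model(t, 2, u, r, (1.0 - u) * w, s) - y
        for r0, s0 in _RATE_STARTS_2:
            sol = least_squares(
                resid, np.array([0.5, 0.5, r0, s0]),
                bounds=([0.0, 0.0, 1e-12, 1e-12], [1.0, 1.0, np.inf, np.inf]),
                ftol=1e-15, xtol=1e-15, gtol=1e-15,
            )
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise FitFailureError("all starts failed")
        u, w, r, s = best.x
        a, b = float(u), float((1.0 - u) * w)
        if r < s:  # sort components fast-first
            a, b, r, s = b, a, s, r
        sse = float(2.0 * best.cost)
        fit = DecayFit(
            order=2, a=a, b=b, r=float(max(r, 1e-12)), s=float(max(s, 1e-12)),
            sse=sse, bic=bic(sse, n, 4), half_times_s=[],
        )
    fit.half_times_s = half_times(fit)
    fit.halftime_unreliable = fit.a < UNRELIABLE_AMPLITUDE
    return fit


def bic(sse: float, n: int, k: int) -> float:
    """Gaussian concentrated-likelihood BIC: n ln(sse/n) + k ln n.

    k counts shape parameters only (2 for one-phase, 4 for two-phase);
    sse is floored to avoid log(0) on perfect fits."""
    if not n > k or k < 1:
        raise ValueError("need n > k >= 1")
    if sse < 0:
        raise ValueError("sse must be >= 0")
    sse = max(sse, 1e-300)
    return float(n * math.log(sse / n) + k * math.log(n))


def select_order(fit1: DecayFit, fit2: DecayFit) -> DecayFit:
    """Pick the fit with the lower BIC; ties go to the one-phase model."""
    if abs(fit1.bic - fit2.bic) < 1e-9:
        return fit1 if fit1.order == 1 else fit2
    return fit1 if fit1.bic < fit2.bic else fit2


def half_times(fit: DecayFit) -> list[float]:
    """T_1/2 = ln 2 / rate per component, fast component first."""
    rates = [fit.r] if fit.order == 1 else [fit.r, fit.s]
    if any(r <= 0 for r in rates):
        raise ValidationError("half-time undefined for non-positive rate")
    return [math.log(2.0) / r for r in rates]


def fit_and_select(trace: BleachTrace) -> tuple[DecayFit, DecayFit, DecayFit]:
    """Fit both orders and return (fit1, fit2, selected)."""
    f1 = fit_decay(trace, 1)
    f2 = fit_decay(trace, 2)
    return f1, f2, select_order(f1, f2)
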