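"""Three-state photochromism kinetics: simulate, fit, score, classify.

The chromophore is modelled with three states: natural (fluorescent, N),
reversible dark (D) and irreversible dark (I).  Light drives N<->D at
channel-specific rates (k_nd, k_dn) while the channel illuminates;
spontaneous N<->D transitions (s_nd, s_dn) and the irreversible drain
D -> I (k_di) act at all times:

    dN/dt = -(k_nd + s_nd) N + (k_dn + s_dn) D
    dD/dt = +(k_nd + s_nd) N - (k_dn + s_dn + k_di) D
    dI/dt = k_di D

with k_nd = k_dn = 0 in the dark.  Over any interval of constant
illumination the system is linear, so propagation is the matrix
exponential of the 3x3 rate matrix; because I is absorbing this
exponential has a closed form built from the 2x2 (N, D) block, which is
evaluated analytically (exact, not a discretisation).

Fluorescence is the N fraction sampled at the start of each own-channel
exposure; traces are normalized to their first measurement.  The
photochromism score is 100x the largest deviation, over a dual-wavelength
schedule, between the full model prediction and the prediction with the
second wavelength's light-driven rates ablated; an FP is called
photochromic when the score exceeds 50.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
from scipy.optimize import least_squares

from .core import (
    BleachTrace,
    ExposureSchedule,
    PhotochromParams,
    PhotochromResult,
    StateVector,
    ValidationError,
    chan_name,
)

__all__ = [
    "propagate",
    "propagation_matrix",
    "simulate",
    "fit",
    "score",
    "FitFailureError",
]

_GROUND = StateVector(1.0, 0.0, 0.0)

class FitFailureError(RuntimeError):
    """No optimisation start converged; carries the best candidate found."""

    def __init__(self, message: str, best=None):
        super().__init__(message)
        self.best = best


def _effective_rates(params: PhotochromParams, channel: str | None):
    """(alpha, beta, gamma): N->D, D->N and D->I rates over an interval."""
    if channel is None:
        return params.s_nd, params.s_dn, params.k_di
    ch = chan_name(channel)
    return (
        params.k_nd.get(ch, 0.0) + params.s_nd,
        params.k_dn.get(ch, 0.0) + params.s_dn,
        params.k_di,
    )


def _expm2(alpha: float, beta: float, gamma: float, dt: float):
    """Closed-form exp(M*dt) for M = [[-alpha, beta], [alpha, -(beta+gamma)]].

    The discriminant (alpha - beta - gamma)^2 + 4*alpha*beta is always
    >= 0, so the eigenvalues are real; the defective case is handled by
    the confluent limit.  Returns the four entries (m11, m12, m21, m22).
    """
    delta = beta + gamma
    tr = -(alpha + delta)
    disc = (alpha - delta) ** 2 + 4.0 * alpha * beta
    srt = math.sqrt(disc) if disc > 0 else 0.0
    l1 = 0.5 * (tr + srt)
    l2 = 0.5 * (tr - srt)
    if srt > 1e-14 * max(1.0, abs(tr)):
        e1 = math.exp(l1 * dt)
        e2 = math.exp(l2 * dt)
        # exp(Mt) = [e1 (M - l2 I) - e2 (M - l1 I)] / (l1 - l2)
        inv = 1.0 / srt
        m11 = (e1 * (-alpha - l2) - e2 * (-alpha - l1)) * inv
        m12 = (e1 - e2) * beta * inv
        m21 = (e1 - e2) * alpha * inv
        m22 = (e1 * (-delta - l2) - e2 * (-delta - l1)) * inv
    else:
        # degenerate eigenvalue: exp(Mt) = e^{l t} (I + (M - l I) t)
        el = math.exp(l1 * dt)
        m11 = el * (1.0 + (-alpha - l1) * dt)
        m12 = el * (beta * dt)
        m21 = el * (alpha * dt)
        m22 = el * (1.0 + (-delta - l1) * dt)
    return m11, m12, m21, m22


def propagation_matrix(
    params: PhotochromParams, channel: str | None, dt: float
) -> np.ndarray:
    """The full 3x3 matrix exponential over an interval of duration dt."""
    alpha, beta, gamma = _effective_rates(params, channel)
    m11, m12, m21, m22 = _expm2(alpha, beta, gamma, dt)
    # I is absorbing; its row follows from conservation of each column.
    return np.array(
        [
            [m11, m12, 0.0],
            [m21, m22, 0.0],
            [1.0 - m11 - m21, 1.0 - m12 - m22, 1.0],
        ]
    )


def propagate(
    state: StateVector,
    channel: str | None,
    params: PhotochromParams,
    dt: float,
) -> StateVector:
    """Propagate a state vector over dt seconds of constant illumination
    (``channel``) or darkness (``channel=None``).  Exact linear solution."""
    if dt < 0:
        raise ValueError("dt must be >= 0")
    if dt == 0:
        return state
    alpha, beta, gamma = _effective_rates(params, channel)
    m11, m12, m21, m22 = _expm2(alpha, beta, gamma, dt)
    n = m11 * state.nat + m12 * state.dark
    d = m21 * state.nat + m22 * state.dark
    i = state.irrdark + (state.nat + state.dark) - (n + d)
    # clip away sub-epsilon negatives from floating cancellation
    n, d, i = (max(v, 0.0) for v in (n, d, i))
    s = n + d + i
    return StateVector(n / s, d / s, i / s)


def _measurements(
    params: PhotochromParams,
    schedule: ExposureSchedule,
    initial: StateVector,
    own: str,
):
    """N fraction at the start of each own-channel event, with times."""
    times: list[float] = []
    values: list[float] = []
    n = initial.nat
    d = initial.dark
    cache: dict[tuple[str | None, float], tuple[float, float, float, float]] = {}
    now = 0.0
    for ev in schedule.events:
        gap = ev.start_s - now
        if gap > 0:
            key = (None, gap)
            m = cache.get(key)
            if m is None:
                a, b, g = _effective_rates(params, None)
                m = cache[key] = _expm2(a, b, g, gap)
            n, d = m[0] * n + m[1] * d, m[2] * n + m[3] * d
        if ev.channel == own:
            times.append(ev.start_s)
            values.append(n)
        key = (ev.channel, ev.duration_s)
        m = cache.get(key)
        if m is None:
            a, b, g = _effective_rates(params, ev.channel)
            m = cache[key] = _expm2(a, b, g, ev.duration_s)
        n, d = m[0] * n + m[1] * d, m[2] * n + m[3] * d
        now = ev.start_s + ev.duration_s
    return np.array(times), np.array(values)


def simulate(
    params: PhotochromParams,
    schedule: ExposureSchedule,
    initial: StateVector | None = None,
    fp_name: str = "",
) -> BleachTrace:
    """Forward-simulate a bleaching trace over an exposure schedule.

    The FP's own channel is the channel of the first event (the protocol
    starts with the FP's own wavelength).  Fluorescence is the natural
    fraction at the start of each own-channel exposure, normalized to the
    first measurement (left unnormalized if that measurement is zero,
    e.g. a fully dark-starting FP).
    """
    if len(schedule) == 0:
        raise ValidationError("schedule must contain at least one event")
    initial = initial or _GROUND
    own = schedule.own_channel()
    times, values = _measurements(params, schedule, initial, own)
    if times.size == 0:
        raise ValidationError("schedule has no own-channel (measurement) events")
    norm = values / values[0] if values[0] > 1e-12 else None
    return BleachTrace(
        fp_name=fp_name,
        own_channel=own,
        frame_times_s=times,
        raw=values,
        schedule=schedule,
        normalized=norm,
    )


def _as_pairs(traces) -> list[tuple[BleachTrace, ExposureSchedule]]:
    pairs = []
    for item in traces:
        if isinstance(item, BleachTrace):
            if item.schedule is None:
                raise ValueError("trace carries no schedule; pass (trace, schedule)")
            pairs.append((item, item.schedule))
        else:
            tr, sched = item
            pairs.append((tr, sched))
    return pairs


def _is_dual(trace: BleachTrace, schedule: ExposureSchedule) -> bool:
    return len(schedule.channels() - {trace.own_channel}) > 0


def _pack(params: PhotochromParams, channels: list[str]) -> np.ndarray:
    v = [params.s_nd, params.s_dn, params.k_di]
    for ch in channels:
        v.extend([params.k_nd.get(ch, 0.0), params.k_dn.get(ch, 0.0)])
    return np.array(v)


def _unpack(v: np.ndarray, channels: list[str]) -> PhotochromParams:
    k_nd = {ch: v[3 + 2 * i] for i, ch in enumerate(channels)}
    k_dn = {ch: v[4 + 2 * i] for i, ch in enumerate(channels)}
    return PhotochromParams(k_nd=k_nd, k_dn=k_dn, s_nd=v[0], s_dn=v[1], k_di=v[2])


def fit(
    traces,
    free_channels: set[str] | None = None,
    initial: StateVector | None = None,
    n_starts: int = 8,
    seed: int = 20210,
) -> PhotochromResult:
    """Joint weighted least squares of the three-state model to a set of
    bleaching traces sharing one FP (and one parameter set).

    ``traces`` is a list of BleachTrace (carrying schedules) or of
    (trace, schedule) pairs; at least one single-wavelength trace is
    required.  Rates are bounded >= 0; a fixed grid of log-spaced
    multi-starts makes the optimisation deterministic.  The returned
    result includes the photochromism score when a dual-wavelength trace
    is present (0 otherwise: no second-wavelength deviation to measure).
    """
    pairs = _as_pairs(traces)
    if not pairs:
        raise ValueError("need at least one trace")
    if not any(not _is_dual(tr, sc) for tr, sc in pairs):
        raise ValueError("need at least one single-wavelength trace")
    initial = initial or _GROUND
    channels = sorted({ch for _, sc in pairs for ch in sc.channels()})
    targets = []
    for tr, sc in pairs:
        y = tr.normalized
        if y is None:
            y = tr.raw / tr.raw[0]
        targets.append(np.asarray(y))

    def data_residuals(v: np.ndarray) -> np.ndarray:
        p = _unpack(v, channels)
        out = []
        for (tr, sc), y in zip(pairs, targets):
            _, vals = _measurements(p, sc, initial, tr.own_channel)
            pred = vals / vals[0] if vals[0] > 1e-12 else vals
            out.append(pred - y)
        return np.concatenate(out)

    residuals = data_residuals

    n_par = 3 + 2 * len(channels)
    rng = np.random.default_rng(seed)
    starts = [np.full(n_par, 0.01)]
    while len(starts) < n_starts:
        starts.append(10.0 ** rng.uniform(-4, -0.5, size=n_par))
    best = None
    for x0 in starts:
        try:
            sol = least_squares(
                residuals, x0, bounds=(0.0, 50.0), ftol=1e-14, xtol=1e-14, gtol=1e-14
            )
        except Exception:
            continue
        if sol.success or sol.cost < np.inf:
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None:
        raise FitFailureError("no optimisation start converged")
    x = best.x.copy()
    sse = float(np.sum(data_residuals(x) ** 2))
    # ablation pruning: a rate the traces do not constrain (e.g.
    # dark-state recovery when the dark pool never populates) can end up
    # anywhere along an exactly-flat direction; zero each rate whose
    # removal leaves the fit unchanged, for a parsimonious estimate
    changed = True
    while changed:
        changed = False
        for j in range(x.size):
            if x[j] == 0.0:
                continue
            trial = x.copy()
            trial[j] = 0.0
            trial_sse = float(np.sum(data_residuals(trial) ** 2))
            if trial_sse <= sse + 1e-9 + 1e-6 * sse:
                x = trial
                sse = trial_sse
                changed = True
    params = _unpack(x, channels)
    duals = [(tr, sc) for tr, sc in pairs if _is_dual(tr, sc)]
    if duals:
        res = score(params, duals, initial=initial)
        return PhotochromResult(
            params=params, score=res.score,
            is_photochromic=res.is_photochromic, fit_sse=sse,
        )
    return PhotochromResult(params=params, score=0.0, is_photochromic=False, fit_sse=sse)


def score(
    params: PhotochromParams,
    traces,
    initial: StateVector | None = None,
) -> PhotochromResult:
    """Photochromism score: 100x the largest deviation, over the frames of
    each dual-wavelength schedule, between the full model prediction and
    the prediction with the second wavelength's light-driven rates set to
    zero.  ``is_photochromic`` is True strictly above 50."""
    pairs = _as_pairs(traces)
    duals = [(tr, sc) for tr, sc in pairs if _is_dual(tr, sc)]
    if not duals:
        raise ValueError("scoring requires at least one dual-wavelength trace")
    initial = initial or _GROUND
    worst = 0.0
    for tr, sc in duals:
        others = sc.channels() - {tr.own_channel}
        ablated = replace(
            params,
            k_nd={ch: (0.0 if ch in others else v) for ch, v in params.k_nd.items()},
            k_dn={ch: (0.0 if ch in others else v) for ch, v in params.k_dn.items()},
        )
        _, full = _measurements(params, sc, initial, tr.own_channel)
        _, refv = _measurements(ablated, sc, initial, tr.own_channel)
        full_n = full / full[0] if full[0] > 1e-12 else full
        ref_n = refv / refv[0] if refv[0] > 1e-12 else refv
        worst = max(worst, float(np.max(np.abs(full_n - ref_n))))
    val = 100.0 * worst
    return PhotochromResult(
        params=params, score=val, is_photochromic=val > 50.0, fit_sse=math.nan
    )
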