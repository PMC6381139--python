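import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fpchar.core import (
    BleachTrace,
    CellRecord,
    ExposureEvent,
    ExposureSchedule,
    PhotochromParams,
)

settings.register_profile(
    "fixed",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fixed")


@pytest.fixture
def simple_cells() -> list[CellRecord]:
    """Three cells with hand-picked intensities (own GFP, control RFP)."""
    return [
        CellRecord("c1", "testFP", 1, {"GFP": 200.0, "RFP": 100.0},
                   {"GFP": 100.0, "RFP": 100.0}),
        CellRecord("c2", "testFP", 1, {"GFP": 400.0, "RFP": 200.0},
                   {"GFP": 100.0, "RFP": 100.0}),
        CellRecord("c3", "testFP", 2, {"GFP": 100.0, "RFP": 50.0},
                   {"GFP": 100.0, "RFP": 100.0}),
    ]


@pytest.fixture
def flat_trace() -> BleachTrace:
    sched = ExposureSchedule(
        [ExposureEvent(i * 0.5, "GFP", 0.2) for i in range(5)]
    )
    return BleachTrace(
        fp_name="testFP", own_channel="GFP",
        frame_times_s=np.arange(5) * 0.5, raw=np.full(5, 100.0),
        schedule=sched,
    )


@pytest.fixture
def rate_draws() -> list[PhotochromParams]:
    """100 random but reproducible parameter sets spanning rate decades."""
    rng = np.random.default_rng(1234)
    draws = []
    for _ in range(100):
        r = 10.0 ** rng.uniform(-3, 0, size=7)
        draws.append(
            PhotochromParams(
                k_nd={"GFP": r[0], "RFP": r[1]},
                k_dn={"GFP": r[2], "RFP": r[3]},
                s_nd=r[4], s_dn=r[5], k_di=r[6],
            )
        )
    return draws


def rk4_states(params, channel, dt, y0, step=1e-4):
    """Fine-step RK4 integration of the full 3x3 linear system; the
    independent oracle for the matrix-exponential propagation."""
    if channel is None:
        alpha, beta = params.s_nd, params.s_dn
    else:
        alpha = params.k_nd.get(channel, 0.0) + params.s_nd
        beta = params.k_dn.get(channel, 0.0) + params.s_dn
    gamma = params.k_di
    A = np.array(
        [
            [-alpha, beta, 0.0],
            [alpha, -(beta + gamma), 0.0],
            [0.0, gamma, 0.0],
        ]
    )
    n_steps = max(1, int(round(dt / step)))
    h = dt / n_steps
    y = np.asarray(y0, dtype=float).copy()
    for _ in range(n_steps):
        k1 = A @ y
        k2 = A @ (y + 0.5 * h * k1)
        k3 = A @ (y + 0.5 * h * k2)
        k4 = A @ (y + h * k3)
        y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    return y
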