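"""Synthetic-data generation for every pipeline input.

The generators reproduce the statistical structure the analysis assumes:
lognormal cell-to-cell intensity variation with a multiplicative per-day
effect on the brightness ratio, bleaching traces from the three-state
photochromism model under the single-wavelength (0.5 s interval, 0.2 s
exposure, 181 frames) and dual-wavelength alternating (3 s interval)
protocols, offset-Hill titration curves over pH 3-8 in triplicate,
zero-inflated-Poisson whorl counts, and disk-phantom two-channel images.
Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    BleachTrace,
    CellRecord,
    ChannelId,
    ExposureEvent,
    ExposureSchedule,
    HillFit,
    OserRecord,
    PhotochromParams,
    StateVector,
    TitrationSeries,
    chan_name,
)
from .imaging import LabelMap
from .ph import hill_eval
from .photochrom import simulate

__all__ = [
    "CellSimConfig",
    "make_schedule",
    "gen_cells",
    "gen_bleach",
    "gen_titration",
    "gen_oser",
    "gen_images",
    "CapacityError",
    "SINGLE_INTERVAL_S",
    "SINGLE_EXPOSURE_S",
    "SINGLE_N_FRAMES",
    "DUAL_INTERVAL_S",
    "DUAL_N_EVENTS",
]

# Default acquisition protocols: a frame every 500 ms with 200 ms exposure
# for 181 frames (single wavelength); alternating wavelengths every 3 s,
# own wavelength first (dual).  The dual protocol's length is a package
# default (61 own-channel measurements over ~6 min).
SINGLE_INTERVAL_S = 0.5
SINGLE_EXPOSURE_S = 0.2
SINGLE_N_FRAMES = 181
DUAL_INTERVAL_S = 3.0
DUAL_N_EVENTS = 121

#: arbitrary-units control-channel signal rate (a.u. per ms exposure)
_CONTROL_RATE = 10.0


class CapacityError(RuntimeError):
    """Could not place the requested cells without overlap."""


def _rng(stream: int, seed: int) -> np.random.Generator:
    # fixed per-stream offsets expand one root seed into independent streams
    return np.random.default_rng([stream, seed])


@dataclass
class CellSimConfig:
    """Per-cell intensity simulation: ``n_cells`` cells on each of
    ``n_days`` days, lognormal cell-to-cell spread (``cell_cv``), a
    shared per-day lognormal multiplier on the brightness ratio
    (``day_effect_sd``), camera background and additive Gaussian noise."""

    true_ratio: float = 1.0
    n_cells: int = 100
    n_days: int = 3
    day_effect_sd: float = 0.1
    cell_cv: float = 0.3
    background: float = 100.0
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.n_days < 1:
            raise ValueError("n_cells and n_days must be >= 1")
        if self.day_effect_sd < 0 or self.cell_cv < 0 or self.noise_sd < 0:
            raise ValueError("spread parameters must be >= 0")
        if not self.true_ratio > 0:
            raise ValueError("true_ratio must be > 0")


def make_schedule(
    kind: str,
    own: "ChannelId | str",
    second: "ChannelId | str | None" = None,
    n_frames: int | None = None,
    interval_s: float | None = None,
    exposure_s: float | None = None,
) -> ExposureSchedule:
    """Build a single- or dual-wavelength exposure schedule.

    ``single``: n_frames own-channel events at the stated interval
    (defaults 181 frames, 0.5 s, 0.2 s).  ``dual``: events alternating
    own/second starting with the FP's own wavelength (defaults 121
    events, 3 s, 0.2 s)."""
    own = chan_name(own)
    if kind == "single":
        n = SINGLE_N_FRAMES if n_frames is None else int(n_frames)
        dt = SINGLE_INTERVAL_S if interval_s is None else float(interval_s)
        exp = SINGLE_EXPOSURE_S if exposure_s is None else float(exposure_s)
        events = [ExposureEvent(i * dt, own, exp) for i in range(n)]
        return ExposureSchedule(events)
    if kind == "dual":
        if second is None:
            raise ValueError("dual schedule needs a second channel")
        second = chan_name(second)
        if second == own:
            raise ValueError("second channel must differ from the own channel")
        n = DUAL_N_EVENTS if n_frames is None else int(n_frames)
        dt = DUAL_INTERVAL_S if interval_s is None else float(interval_s)
        exp = SINGLE_EXPOSURE_S if exposure_s is None else float(exposure_s)
        events = [
            ExposureEvent(i * dt, own if i % 2 == 0 else second, exp) for i in range(n)
        ]
        return ExposureSchedule(events)
    raise ValueError("kind must be 'single' or 'dual'")


def gen_cells(
    cfg: CellSimConfig,
    fp_name: str,
    control_channel: "ChannelId | str",
    own_channel: "ChannelId | str",
    own_exposure_ms: float = 100.0,
    control_exposure_ms: float = 200.0,
) -> list[CellRecord]:
    """Simulate a two-channel per-cell intensity table.

    The control channel carries a lognormal expression level per cell;
    the own channel is control x true_ratio x per-day multiplier x
    independent lognormal cell noise.  Background is added with Gaussian
    camera noise and subtracted again, as a real pipeline would."""
    own = chan_name(own_channel)
    control = chan_name(control_channel)
    if own == control:
        raise ValueError("own and control channels must differ")
    rng = _rng(1, cfg.seed)
    sigma = np.sqrt(np.log1p(cfg.cell_cv**2))
    day_mult = np.exp(cfg.day_effect_sd * rng.standard_normal(cfg.n_days))
    records: list[CellRecord] = []
    for day in range(cfg.n_days):
        expr = _CONTROL_RATE * np.exp(sigma * rng.standard_normal(cfg.n_cells))
        cell_noise = np.exp(sigma * rng.standard_normal(cfg.n_cells))
        ctrl_rate = expr
        own_rate = expr * cfg.true_ratio * day_mult[day] * cell_noise
        for i in range(cfg.n_cells):
            meas = {}
            for ch, rate, exp_ms in (
                (own, own_rate[i], own_exposure_ms),
                (control, ctrl_rate[i], control_exposure_ms),
            ):
                raw = rate * exp_ms + cfg.background + cfg.noise_sd * rng.standard_normal()
                meas[ch] = raw - cfg.background
            records.append(
                CellRecord(
                    cell_id=f"d{day + 1}c{i + 1}",
                    fp_name=fp_name,
                    day=day + 1,
                    intensity=meas,
                    exposure_ms={own: own_exposure_ms, control: control_exposure_ms},
                )
            )
    return records


def gen_bleach(
    truth: PhotochromParams,
    schedule: ExposureSchedule,
    noise_sd: float = 0.0,
    seed: int = 0,
    fp_name: str = "",
    initial: StateVector | None = None,
) -> BleachTrace:
    """Forward-simulate the three-state model over a schedule, add i.i.d.
    Gaussian noise, and renormalize to the first frame."""
    clean = simulate(truth, schedule, initial=initial, fp_name=fp_name)
    if noise_sd == 0:
        return clean
    rng = _rng(2, seed)
    noisy = clean.raw + noise_sd * rng.standard_normal(clean.raw.size)
    norm = noisy / noisy[0] if noisy[0] > 1e-12 else None
    return BleachTrace(
        fp_name=fp_name,
        own_channel=clean.own_channel,
        frame_times_s=clean.frame_times_s,
        raw=noisy,
        schedule=schedule,
        normalized=norm,
    )


def gen_titration(
    truth: "HillFit | tuple[float, float, float]",
    pH_grid: np.ndarray | None = None,
    reps: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
    fp_name: str = "",
) -> TitrationSeries:
    """Offset-Hill curve sampled on a pH grid with replicate noise.

    Defaults follow the plate protocol: pH 3-8 in 0.5 steps, 3
    replicates.  Noiseless output is on the normalized model scale and
    flagged as such; noisy output must be normalized by the caller."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    pH = np.arange(3.0, 8.01, 0.5) if pH_grid is None else np.asarray(pH_grid, float)
    clean = hill_eval(truth, pH)
    rng = _rng(3, seed)
    values = np.tile(clean, (reps, 1))
    if noise_sd > 0:
        values = values + noise_sd * rng.standard_normal(values.shape)
    return TitrationSeries(
        fp_name=fp_name, pH=pH, fluorescence=values, normalized=(noise_sd == 0)
    )


def gen_oser(
    p_whorl: float,
    mean_count_given_whorl: float,
    n_cells: int,
    seed: int = 0,
    fp_name: str = "",
) -> list[OserRecord]:
    """Zero-inflated Poisson whorl counts: 0 with probability 1 - p_whorl,
    else 1 + Poisson(mean_count_given_whorl - 1)."""
    if not 0 <= p_whorl <= 1:
        raise ValueError("p_whorl must lie in [0, 1]")
    if mean_count_given_whorl < 1:
        raise ValueError("mean_count_given_whorl must be >= 1")
    rng = _rng(4, seed)
    has = rng.random(n_cells) < p_whorl
    counts = np.where(has, 1 + rng.poisson(mean_count_given_whorl - 1.0, n_cells), 0)
    return [
        OserRecord(cell_id=f"c{i + 1}", fp_name=fp_name, whorl_count=int(c))
        for i, c in enumerate(counts)
    ]


def gen_images(
    n_cells: int,
    radius_px: tuple[int, int] = (6, 12),
    intensities: dict[str, float] | None = None,
    background: float = 100.0,
    noise_sd: float = 0.0,
    size_px: tuple[int, int] = (256, 256),
    seed: int = 0,
    max_tries_per_cell: int = 500,
) -> tuple[dict[str, np.ndarray], LabelMap]:
    """Disk-phantom two-channel images with a ground-truth label map.

    Disks of per-channel constant intensity sit on a constant background
    with optional Gaussian noise; placement is rejection sampling until
    disks neither overlap nor touch the frame edge."""
    intensities = intensities or {"GFP": 300.0, "RFP": 200.0}
    intensities = {chan_name(k): float(v) for k, v in intensities.items()}
    h, w = size_px
    rng = _rng(5, seed)
    placed: list[tuple[int, int, int]] = []  # (cy, cx, r)
    for _ in range(n_cells):
        for _attempt in range(max_tries_per_cell):
            r = int(rng.integers(radius_px[0], radius_px[1] + 1))
            cy = int(rng.integers(r + 1, h - r - 1))
            cx = int(rng.integers(r + 1, w - r - 1))
            if all(
                (cy - py) ** 2 + (cx - px) ** 2 > (r + pr + 2) ** 2
                for py, px, pr in placed
            ):
                placed.append((cy, cx, r))
                break
        else:
            raise CapacityError(
                f"could not place {n_cells} non-overlapping cells in {size_px}"
            )
    # label in raster order of disk bounding-box top edge for readability
    placed.sort(key=lambda t: (t[0] - t[2], t[1] - t[2]))
    labels = np.zeros((h, w), dtype=np.int32)
    yy, xx = np.mgrid[0:h, 0:w]
    for k, (cy, cx, r) in enumerate(placed, start=1):
        labels[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = k
    images: dict[str, np.ndarray] = {}
    for ch, amp in sorted(intensities.items()):
        img = np.full((h, w), background, dtype=float)
        img[labels > 0] += amp
        if noise_sd > 0:
            img = img + noise_sd * rng.standard_normal((h, w))
        images[ch] = img
    return images, LabelMap(labels=labels, n_cells=len(placed))
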