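"""Domain types shared by every stage of the characterisation pipeline.

All types validate their invariants at construction time: an instance that
exists is an instance that is internally consistent.  Time is expressed in
seconds everywhere (rates in s^-1), intensities in arbitrary units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ValidationError",
    "ChannelId",
    "CHANNEL_NAMES",
    "default_channels",
    "channel_by_name",
    "chan_name",
    "CellRecord",
    "ExposureEvent",
    "ExposureSchedule",
    "BleachTrace",
    "DecayFit",
    "StateVector",
    "PhotochromParams",
    "PhotochromResult",
    "TitrationSeries",
    "HillFit",
    "OserRecord",
    "FlimMeasurement",
]


class ValidationError(ValueError):
    """An object's declared invariants do not hold."""


#: Spectral classes, ordered by excitation-filter centre wavelength.
CHANNEL_NAMES = ("CFP", "GFP", "YFP", "RFP")


@dataclass(frozen=True)
class ChannelId:
    """An excitation channel, identified by its bandpass filter.

    ``exc_center_nm``/``exc_bandwidth_nm`` follow the usual centre/width
    filter notation (e.g. CFP 438/24 nm).
    """

    name: str
    exc_center_nm: float
    exc_bandwidth_nm: float

    def __post_init__(self) -> None:
        if self.name not in CHANNEL_NAMES:
            raise ValidationError(f"unknown channel name {self.name!r}")
        if not (self.exc_center_nm > 0 and self.exc_bandwidth_nm > 0):
            raise ValidationError("filter centre and bandwidth must be positive")


_DEFAULTS = (
    ChannelId("CFP", 438.0, 24.0),
    ChannelId("GFP", 480.0, 40.0),
    ChannelId("YFP", 500.0, 24.0),
    ChannelId("RFP", 560.0, 20.0),
)


def default_channels() -> list[ChannelId]:
    """The four widefield excitation presets (CFP 438/24, GFP 480/40,
    YFP 500/24, RFP 560/20)."""
    return list(_DEFAULTS)


def channel_by_name(name: str) -> ChannelId:
    for ch in _DEFAULTS:
        if ch.name == name:
            return ch
    raise ValidationError(f"unknown channel name {name!r}")


def chan_name(channel: "ChannelId | str") -> str:
    """Accept either a ChannelId or a bare channel name and return the name."""
    name = channel.name if isinstance(channel, ChannelId) else str(channel)
    if name not in CHANNEL_NAMES:
        raise ValidationError(f"unknown channel name {name!r}")
    return name


def _finite(x: float) -> bool:
    return isinstance(x, (int, float, np.integer, np.floating)) and math.isfinite(x)


@dataclass
class CellRecord:
    """One segmented cell: background-corrected mean intensity per channel."""

    cell_id: str
    fp_name: str
    day: int
    intensity: dict[str, float]
    exposure_ms: dict[str, float]

    def __post_init__(self) -> None:
        if int(self.day) != self.day or self.day < 1:
            raise ValidationError("day must be an integer >= 1")
        self.day = int(self.day)
        if len(self.intensity) < 2:
            raise ValidationError(
                "a cell needs at least its own channel and one control channel"
            )
        self.intensity = {chan_name(k): float(v) for k, v in self.intensity.items()}
        self.exposure_ms = {chan_name(k): float(v) for k, v in self.exposure_ms.items()}
        for ch, v in self.intensity.items():
            if not _finite(v):
                raise ValidationError(f"non-finite intensity in channel {ch}")
            if ch not in self.exposure_ms:
                raise ValidationError(f"missing exposure time for channel {ch}")
        for ch, v in self.exposure_ms.items():
            if not (_finite(v) and v > 0):
                raise ValidationError(f"exposure_ms must be > 0 (channel {ch})")


@dataclass(frozen=True)
class ExposureEvent:
    start_s: float
    channel: str
    duration_s: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "channel", chan_name(self.channel))
        if not (_finite(self.start_s) and self.start_s >= 0):
            raise ValidationError("event start time must be finite and >= 0")
        if not (_finite(self.duration_s) and self.duration_s > 0):
            raise ValidationError("event duration must be > 0")


@dataclass
class ExposureSchedule:
    """An ordered, non-overlapping list of illumination events."""

    events: list[ExposureEvent]

    def __post_init__(self) -> None:
        evs = [e if isinstance(e, ExposureEvent) else ExposureEvent(*e) for e in self.events]
        for prev, nxt in zip(evs, evs[1:]):
            if not nxt.start_s > prev.start_s:
                raise ValidationError("event start times must be strictly increasing")
            if prev.start_s + prev.duration_s > nxt.start_s + 1e-12:
                raise ValidationError("illumination events must not overlap")
        self.events = evs

    def __len__(self) -> int:
        return len(self.events)

    def channels(self) -> set[str]:
        return {e.channel for e in self.events}

    def own_channel(self) -> str:
        """The FP's own channel: by protocol the first event's channel
        (dual-wavelength bleaching starts with the FP's own wavelength)."""
        if not self.events:
            raise ValidationError("empty schedule has no own channel")
        return self.events[0].channel


@dataclass
class BleachTrace:
    """A bleaching time series: one measured frame per own-channel event."""

    fp_name: str
    own_channel: str
    frame_times_s: np.ndarray
    raw: np.ndarray
    schedule: ExposureSchedule | None = None
    normalized: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.own_channel = chan_name(self.own_channel)
        self.frame_times_s = np.asarray(self.frame_times_s, dtype=float)
        self.raw = np.asarray(self.raw, dtype=float)
        if self.frame_times_s.ndim != 1 or self.raw.shape != self.frame_times_s.shape:
            raise ValidationError("frame times and values must be 1-D and congruent")
        if self.frame_times_s.size == 0:
            raise ValidationError("a trace needs at least one frame")
        if np.any(np.diff(self.frame_times_s) <= 0):
            raise ValidationError("frame times must be strictly increasing")
        if not np.all(np.isfinite(self.raw)):
            raise ValidationError("trace values must be finite")
        if self.normalized is not None:
            self.normalized = np.asarray(self.normalized, dtype=float)
            if self.normalized.shape != self.raw.shape:
                raise ValidationError("normalized trace shape mismatch")
            if abs(self.normalized[0] - 1.0) > 1e-9:
                raise ValidationError("normalized trace must start at 1")
        if self.schedule is not None:
            own_events = [e for e in self.schedule.events if e.channel == self.own_channel]
            if len(own_events) != self.raw.size:
                raise ValidationError(
                    "expected one measured frame per own-channel exposure event"
                )

    @property
    def n_frames(self) -> int:
        return int(self.raw.size)


@dataclass
class DecayFit:
    """One- or two-phase exponential decay fit of a normalized bleach trace.

    Order 1: F(t) = (1-a) + a*exp(-t*r);
    order 2: F(t) = (1-a-b) + a*exp(-t*r) + b*exp(-t*s), with the fast
    component (rate r) listed first.  Rates are s^-1, t in seconds.
    """

    order: int
    a: float
    r: float
    sse: float
    bic: float
    half_times_s: list[float]
    b: float | None = None
    s: float | None = None
    halftime_unreliable: bool = False

    def __post_init__(self) -> None:
        if self.order not in (1, 2):
            raise ValidationError("decay order must be 1 or 2")
        if not (self.a >= 0):
            raise ValidationError("amplitude a must be >= 0")
        if not (self.r > 0):
            raise ValidationError("rate r must be > 0")
        if self.order == 2:
            if self.b is None or self.s is None:
                raise ValidationError("order-2 fit needs b and s")
            if not (self.b >= 0 and self.a + self.b <= 1 + 1e-9):
                raise ValidationError("amplitudes must satisfy 0 <= b, a + b <= 1")
            if not (self.s > 0):
                raise ValidationError("rate s must be > 0")
            if not (self.r >= self.s):
                raise ValidationError("components must be ordered fast first (r >= s)")
        else:
            if self.b is not None or self.s is not None:
                raise ValidationError("order-1 fit carries no b or s")
            if self.a > 1 + 1e-9:
                raise ValidationError("amplitude a must be <= 1")
        if self.sse < 0:
            raise ValidationError("sse must be >= 0")


@dataclass(frozen=True)
class StateVector:
    """Occupancy of the three chromophore states: natural (fluorescent),
    reversible dark, irreversible dark.  Fractions sum to one."""

    nat: float
    dark: float
    irrdark: float

    def __post_init__(self) -> None:
        for v in (self.nat, self.dark, self.irrdark):
            if not (-1e-9 <= v <= 1 + 1e-9):
                raise ValidationError("state fractions must lie in [0, 1]")
        if abs(self.nat + self.dark + self.irrdark - 1.0) > 1e-9:
            raise ValidationError("state fractions must sum to 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.nat, self.dark, self.irrdark], dtype=float)


@dataclass
class PhotochromParams:
    """Rate constants of the three-state photochromism model.

    ``k_nd``/``k_dn`` are light-driven natural<->dark rates, active only
    while the keyed channel illuminates; ``s_nd``/``s_dn`` are the
    spontaneous counterparts, always active; ``k_di`` drains the dark
    state into the irreversible dark state.  All rates in s^-1.
    """

    k_nd: dict[str, float] = field(default_factory=dict)
    k_dn: dict[str, float] = field(default_factory=dict)
    s_nd: float = 0.0
    s_dn: float = 0.0
    k_di: float = 0.0

    def __post_init__(self) -> None:
        self.k_nd = {chan_name(k): float(v) for k, v in self.k_nd.items()}
        self.k_dn = {chan_name(k): float(v) for k, v in self.k_dn.items()}
        for name, val in [("s_nd", self.s_nd), ("s_dn", self.s_dn), ("k_di", self.k_di)]:
            if not (_finite(val) and val >= 0):
                raise ValidationError(f"rate {name} must be finite and >= 0")
        for d in (self.k_nd, self.k_dn):
            for ch, v in d.items():
                if not (_finite(v) and v >= 0):
                    raise ValidationError(f"light-driven rate for {ch} must be >= 0")

@dataclass
class PhotochromResult:
    params: PhotochromParams
    score: float
    is_photochromic: bool
    fit_sse: float

    def __post_init__(self) -> None:
        if not (self.score >= 0):
            raise ValidationError("photochromism score must be >= 0")
        if self.is_photochromic != (self.score > 50.0):
            raise ValidationError("classification must equal (score > 50)")


@dataclass
class TitrationSeries:
    """Replicate fluorescence measurements over a pH grid."""

    fp_name: str
    pH: np.ndarray
    fluorescence: np.ndarray  # shape (n_replicates, n_pH)
    normalized: bool = False

    def __post_init__(self) -> None:
        self.pH = np.asarray(self.pH, dtype=float)
        self.fluorescence = np.atleast_2d(np.asarray(self.fluorescence, dtype=float))
        if self.pH.ndim != 1 or self.pH.size < 3:
            raise ValidationError("need at least 3 pH points")
        if np.any(self.pH < 0) or np.any(self.pH > 14):
            raise ValidationError("pH values must lie in [0, 14]")
        if np.any(np.diff(self.pH) <= 0):
            raise ValidationError("pH values must be strictly increasing")
        if self.fluorescence.shape[1] != self.pH.size:
            raise ValidationError("fluorescence matrix must be replicate x pH")
        if not np.all(np.isfinite(self.fluorescence)):
            raise ValidationError("fluorescence values must be finite")
        if self.normalized:
            # normalized scale: the peak replicate mean is 1 after explicit
            # normalisation, or slightly below for model-scale curves that
            # approach 1 only asymptotically
            peak = self.replicate_means().max()
            if not (0 < peak <= 1 + 1e-9):
                raise ValidationError("normalized series must have peak mean in (0, 1]")

    @property
    def n_replicates(self) -> int:
        return int(self.fluorescence.shape[0])

    def replicate_means(self) -> np.ndarray:
        return self.fluorescence.mean(axis=0)


@dataclass
class HillFit:
    """Offset-Hill description of pH quenching:
    F(pH) = offset + (1-offset) / (1 + 10^((pKa - pH) * hill))."""

    pKa: float
    hill: float
    offset: float
    ph50: float | None = None
    rss: float = 0.0

    def __post_init__(self) -> None:
        if not (self.hill > 0):
            raise ValidationError("Hill coefficient must be > 0")
        if not (0 <= self.offset < 1):
            raise ValidationError("offset must lie in [0, 1)")
        if (self.ph50 is not None) != (self.offset < 0.5):
            raise ValidationError("ph50 is defined exactly when offset < 0.5")


@dataclass
class OserRecord:
    cell_id: str
    fp_name: str
    whorl_count: int

    def __post_init__(self) -> None:
        if int(self.whorl_count) != self.whorl_count or self.whorl_count < 0:
            raise ValidationError("whorl_count must be an integer >= 0")
        self.whorl_count = int(self.whorl_count)


@dataclass
class FlimMeasurement:
    """Frequency-domain phase lifetime: tau_phi = tan(phase) / (2 pi f)."""

    phase_rad: float
    mod_freq_hz: float
    lifetime_ns: float

    def __post_init__(self) -> None:
        if not (0 <= self.phase_rad < math.pi / 2):
            raise ValidationError("phase must lie in [0, pi/2)")
        if not (self.mod_freq_hz > 0):
            raise ValidationError("modulation frequency must be > 0")
        if not (self.lifetime_ns >= 0):
            raise ValidationError("lifetime must be >= 0")
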