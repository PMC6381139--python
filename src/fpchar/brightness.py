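"""Ratiometric (practical) brightness and day-to-day variation.

An FP of interest is co-expressed stoichiometrically with a control FP
(T2A linkage), so the per-cell ratio of exposure-normalized intensities
measures the FP's practical brightness independent of expression level.
The headline summary is the median with quartiles; day-to-day variation
is the coefficient of variation of the daily mean ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import CellRecord, ChannelId, chan_name

__all__ = ["BrightnessSummary", "practical_brightness", "day_to_day_cv",
           "EmptyInputError", "InsufficientReplicationError"]

log = logging.getLogger(__name__)


class EmptyInputError(ValueError):
    pass


class InsufficientReplicationError(ValueError):
    pass


@dataclass
class BrightnessSummary:
    fp_name: str
    per_cell_ratio: np.ndarray
    median: float
    q1: float
    q3: float
    n_cells: int
    control_channel: str
    n_excluded: int = 0

    def __post_init__(self) -> None:
        self.per_cell_ratio = np.asarray(self.per_cell_ratio, dtype=float)
        if not (self.q1 <= self.median <= self.q3):
            raise ValueError("quartiles must bracket the median")
        if self.n_cells != self.per_cell_ratio.size:
            raise ValueError("n_cells must equal the number of ratios")


def _ratios(
    cells: list[CellRecord], own: str, control: str
) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-cell exposure-normalized intensity ratios, with day labels.

    Cells whose control signal is non-positive are excluded (counted)."""
    ratios, days, excluded = [], [], 0
    for c in cells:
        if own not in c.intensity or control not in c.intensity:
            raise KeyError(f"cell {c.cell_id} lacks channel {own} or {control}")
        ctrl = c.intensity[control] / c.exposure_ms[control]
        if ctrl <= 0:
            excluded += 1
            continue
        ownv = c.intensity[own] / c.exposure_ms[own]
        ratios.append(ownv / ctrl)
        days.append(c.day)
    if excluded:
        log.info("excluded %d cells with non-positive control signal", excluded)
    return np.array(ratios), np.array(days), excluded


def practical_brightness(
    cells: list[CellRecord],
    own_channel: "ChannelId | str",
    control_channel: "ChannelId | str",
) -> BrightnessSummary:
    """Practical brightness: per-cell (own / exposure) / (control / exposure),
    summarised as median with quartiles."""
    own = chan_name(own_channel)
    control = chan_name(control_channel)
    ratios, _, excluded = _ratios(cells, own, control)
    if ratios.size == 0:
        raise EmptyInputError("no cells with positive control signal")
    q1, med, q3 = np.percentile(ratios, [25, 50, 75])
    return BrightnessSummary(
        fp_name=cells[0].fp_name,
        per_cell_ratio=ratios,
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        n_cells=int(ratios.size),
        control_channel=control,
        n_excluded=excluded,
    )


def day_to_day_cv(
    cells: list[CellRecord],
    own_channel: "ChannelId | str",
    control_channel: "ChannelId | str",
) -> float:
    """Coefficient of variation of the daily mean brightness ratio
    (sample standard deviation, n-1 denominator)."""
    own = chan_name(own_channel)
    control = chan_name(control_channel)
    ratios, days, _ = _ratios(cells, own, control)
    if ratios.size == 0:
        raise EmptyInputError("no cells with positive control signal")
    uniq = np.unique(days)
    if uniq.size < 2:
        raise InsufficientReplicationError("need cells from at least 2 days")
    daily_means = np.array([ratios[days == d].mean() for d in uniq])
    return float(daily_means.std(ddof=1) / daily_means.mean())
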