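"""Secondary quantifications: OSER monomerism statistics, Tukey HSD,
flow-histogram overlap, FSC gating and frequency-domain phase lifetime."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import studentized_range

from .core import FlimMeasurement, OserRecord

__all__ = [
    "OserSummary",
    "oser_summary",
    "tukey_hsd",
    "overlap_percent",
    "phase_lifetime",
    "lifetime_to_phase",
    "fsc_gate",
]

log = logging.getLogger(__name__)


@dataclass
class OserSummary:
    """Monomerism summary of an OSER assay: mean whorls per cell and the
    fraction of cells with at least one whorl, with bootstrap 95% CIs."""

    fp_name: str
    mean_whorls_per_cell: float
    frac_cells_with_whorl: float
    ci95_mean: tuple[float, float]
    ci95_frac: tuple[float, float]
    n_cells: int

    def __post_init__(self) -> None:
        if not 0 <= self.frac_cells_with_whorl <= 1:
            raise ValueError("fraction must lie in [0, 1]")
        for lo, hi, point in (
            (*self.ci95_mean, self.mean_whorls_per_cell),
            (*self.ci95_frac, self.frac_cells_with_whorl),
        ):
            if not (lo <= point <= hi):
                raise ValueError("CI must bracket the point estimate")


def oser_summary(
    records: list[OserRecord], n_boot: int = 2000, seed: int = 42
) -> OserSummary:
    """Mean whorls/cell and fraction of cells with a whorl, with 95%
    nonparametric bootstrap CIs (percentile method, fixed seed)."""
    if not records:
        raise ValueError("empty OSER record collection")
    counts = np.array([r.whorl_count for r in records], dtype=float)
    n = counts.size
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot = counts[idx]
    boot_mean = boot.mean(axis=1)
    boot_frac = (boot >= 1).mean(axis=1)
    lo_m, hi_m = np.percentile(boot_mean, [2.5, 97.5])
    lo_f, hi_f = np.percentile(boot_frac, [2.5, 97.5])
    return OserSummary(
        fp_name=records[0].fp_name,
        mean_whorls_per_cell=float(counts.mean()),
        frac_cells_with_whorl=float((counts >= 1).mean()),
        ci95_mean=(float(lo_m), float(hi_m)),
        ci95_frac=(float(lo_f), float(hi_f)),
        n_cells=int(n),
    )


def tukey_hsd(groups: dict[str, np.ndarray], alpha: float = 0.01) -> pd.DataFrame:
    """All-pairs Tukey HSD on group means with pooled within-group
    variance and the Tukey-Kramer unequal-n correction.

    q_ij = |mean_i - mean_j| / sqrt(MSW/2 * (1/n_i + 1/n_j)), compared to
    the studentized-range critical value at the given alpha.  Returns a
    table with columns group1, group2, difference, q, q_crit,
    significant."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    names = list(groups)
    data = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    for g, v in data.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} needs at least 2 values")
    k = len(names)
    ns = {g: v.size for g, v in data.items()}
    means = {g: v.mean() for g, v in data.items()}
    big_n = sum(ns.values())
    df = big_n - k
    msw = sum(((v - means[g]) ** 2).sum() for g, v in data.items()) / df
    q_crit = float(studentized_range.ppf(1.0 - alpha, k, df))
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = names[i], names[j]
            diff = means[b] - means[a]
            se = math.sqrt(msw / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
            if se == 0:
                q = math.inf if diff != 0 else 0.0
            else:
                q = abs(diff) / se
            rows.append(
                {
                    "group1": a,
                    "group2": b,
                    "difference": diff,
                    "q": q,
                    "q_crit": q_crit,
                    "significant": bool(q > q_crit),
                }
            )
    return pd.DataFrame(rows)


def overlap_percent(sample_a, sample_b, n_bins: int = 64) -> float:
    """Overlap coefficient (OVL) of two fluorescence distributions, in
    percent: 100 x sum over shared bins of min(p_b, q_b) of the two
    probability-normalized histograms on log10-transformed values.

    Falls back to linear binning (with a logged notice) when either
    sample contains non-positive values."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if (a <= 0).any() or (b <= 0).any():
        log.info("non-positive values present; using linear binning")
    else:
        a, b = np.log10(a), np.log10(b)
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if lo == hi:  # all values identical across the pool
        return 100.0
    edges = np.linspace(lo, hi, n_bins + 1)
    p = np.histogram(a, bins=edges)[0] / a.size
    q = np.histogram(b, bins=edges)[0] / b.size
    return float(100.0 * np.minimum(p, q).sum())


def phase_lifetime(phase_rad: float, mod_freq_hz: float) -> FlimMeasurement:
    """Frequency-domain phase lifetime tau_phi = tan(phase) / (2 pi f),
    reported in nanoseconds."""
    if not 0 <= phase_rad < math.pi / 2:
        raise ValueError("phase must lie in [0, pi/2)")
    if not mod_freq_hz > 0:
        raise ValueError("modulation frequency must be > 0")
    tau_s = math.tan(phase_rad) / (2.0 * math.pi * mod_freq_hz)
    return FlimMeasurement(
        phase_rad=phase_rad, mod_freq_hz=mod_freq_hz, lifetime_ns=tau_s * 1e9
    )


def lifetime_to_phase(lifetime_ns: float, mod_freq_hz: float) -> float:
    """Inverse of phase_lifetime: phase = atan(2 pi f tau)."""
    return math.atan(2.0 * math.pi * mod_freq_hz * lifetime_ns * 1e-9)


def fsc_gate(events, threshold: float = 80000.0) -> list[float]:
    """Keep the fluorescence of events with FSC-H at or above threshold
    (forward-scatter size gate)."""
    return [fl for fsc_h, fl in events if fsc_h >= threshold]
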