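"""pH-quenching analysis: normalisation, offset-Hill fitting, pKa/pH50.

Fluorescence versus pH is described by an offset sigmoid,

    F(pH) = offset + (1 - offset) / (1 + 10^((pKa - pH) * hill)),

rising from the low-pH plateau (the offset) to 1 at high pH.  The pKa is
the midpoint of that transition; pH50 is the pH giving an *absolute* 50%
drop from maximal fluorescence, which differs from the pKa whenever the
curve has an offset and is undefined when the offset is >= 0.5 (the
curve never falls to half-maximum).
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
from scipy.optimize import least_squares

from .core import HillFit, TitrationSeries, ValidationError

__all__ = [
    "normalize_titration",
    "hill_eval",
    "fit_hill",
    "ph50",
    "DegenerateSeriesError",
    "FitFailureError",
]


class DegenerateSeriesError(ValueError):
    pass


class FitFailureError(RuntimeError):
    pass


def normalize_titration(series: TitrationSeries) -> TitrationSeries:
    """Divide all values by the maximal replicate-mean fluorescence
    (the pH giving the highest fluorescence); idempotent."""
    means = series.replicate_means()
    peak = means.max()
    if peak <= 0:
        raise DegenerateSeriesError("all fluorescence values <= 0")
    return replace(series, fluorescence=series.fluorescence / peak, normalized=True)


def hill_eval(fit, pH) -> "float | np.ndarray":
    """Evaluate the offset-Hill curve; accepts a HillFit or a
    (pKa, hill, offset) triple, scalar or array pH."""
    if isinstance(fit, HillFit):
        pKa, hill, offset = fit.pKa, fit.hill, fit.offset
    else:
        pKa, hill, offset = fit
    pH = np.asarray(pH, dtype=float)
    val = offset + (1.0 - offset) / (1.0 + 10.0 ** ((pKa - pH) * hill))
    return float(val) if val.ndim == 0 else val


_PKA_STARTS = (4.0, 5.5, 7.0)


def fit_hill(series: TitrationSeries) -> HillFit:
    """Least-squares offset-Hill fit of the replicate-mean curve.

    Bounds: pKa in [2, 9], hill in (0, 5], offset in [0, 0.95]; three
    pKa starts.  The series must be normalized and span >= 4 distinct pH
    values.  A flat series is rejected as unidentifiable."""
    if not series.normalized:
        raise ValidationError("fit_hill expects a normalized series")
    if series.pH.size < 4:
        raise ValidationError("need at least 4 distinct pH values")
    y = series.replicate_means()
    if y.max() - y.min() < 0.05:
        raise FitFailureError(
            "series is flat: offset indistinguishable from 1, fit unidentifiable"
        )
    pH = series.pH

    def resid(v):
        return hill_eval((v[0], v[1], v[2]), pH) - y

    best = None
    for p0 in _PKA_STARTS:
        sol = least_squares(
            resid, np.array([p0, 1.0, 0.05]),
            bounds=([2.0, 1e-6, 0.0], [9.0, 5.0, 0.95]),
            ftol=1e-15, xtol=1e-15, gtol=1e-15,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitFailureError("no start converged")
    pKa, hill, offset = (float(x) for x in best.x)
    rss = float(2.0 * best.cost)
    p50 = (
        pKa - (1.0 / hill) * math.log10(0.5 / (0.5 - offset)) if offset < 0.5 else None
    )
    return HillFit(pKa=pKa, hill=hill, offset=offset, ph50=p50, rss=rss)


def ph50(fit: HillFit) -> float | None:
    """pH of an absolute 50% drop from maximal fluorescence.

    Closed form pH50 = pKa - (1/hill) log10(0.5 / (0.5 - offset)) when
    offset < 0.5; None otherwise (fluorescence never falls to 0.5).
    Always <= pKa, with equality iff offset = 0."""
    if fit.offset >= 0.5:
        return None
    return fit.pKa - (1.0 / fit.hill) * math.log10(0.5 / (0.5 - fit.offset))
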