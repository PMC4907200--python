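"""Absolute quantification from qPCR standard curves.

A 10-fold plasmid dilution series gives a straight line of Cq on
log10(copies); amplification efficiency follows from the slope as
E = -1 + 10^(-1/slope), so a slope of -3.3219 (= -1/log10(2)) is perfect
doubling (E = 1). Unknowns are interpolated through the curve inverse,
copies = 10^((Cq - intercept)/slope), and converted to gene copies per
cubic meter of air by undoing the template/elution/filter-fraction/air-
volume bookkeeping of the sampling protocol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import ValidationError

__all__ = [
    "StandardCurve",
    "fit_standard_curve",
    "quantify_cq",
    "copies_per_m3",
    "fold_effect",
    "average_replicates",
]


@dataclass
class StandardCurve:
    slope: float          # Cq per log10(copies); negative for a valid assay
    intercept: float      # Cq at 1 copy
    r_squared: float
    n_points: int

    @property
    def efficiency(self) -> float:
        """Amplification efficiency E = -1 + 10^(-1/slope)."""
        return -1.0 + 10.0 ** (-1.0 / self.slope)

    @property
    def is_valid(self) -> bool:
        return self.slope < 0


def fit_standard_curve(log10_copies, cq) -> StandardCurve:
    """Least-squares line of Cq on log10 copies from a dilution series."""
    x = np.asarray(log10_copies, dtype=float)
    y = np.asarray(cq, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need at least 3 (log10_copies, Cq) points")
    if np.unique(x).size < 2:
        raise ValidationError("standard concentrations must be distinct")
    fit = stats.linregress(x, y)
    return StandardCurve(float(fit.slope), float(fit.intercept),
                         float(fit.rvalue ** 2), int(x.size))


def quantify_cq(curve: StandardCurve, cq: float) -> float:
    """Copies per reaction from a Cq value via the curve inverse."""
    if not curve.is_valid:
        raise ValidationError("standard curve has a non-negative slope")
    return float(10.0 ** ((cq - curve.intercept) / curve.slope))


def copies_per_m3(
    copies_per_reaction: float,
    template_volume: float,
    elution_volume: float,
    fraction_of_filter: float = 1.0,
    air_volume: float = 1.0,
) -> float:
    """Scale a per-reaction copy number up to gene copies per m^3 of air.

    Volumes in microliters, air volume in cubic meters; fraction_of_filter
    is the share of the collection filter that went into the extraction
    (e.g. 0.5 when half a filter is processed).
    """
    if min(template_volume, elution_volume, air_volume) <= 0:
        raise ValidationError("volumes must be positive")
    if not (0 < fraction_of_filter <= 1):
        raise ValidationError("fraction_of_filter must lie in (0, 1]")
    return (copies_per_reaction * (elution_volume / template_volume)
            / fraction_of_filter / air_volume)


def fold_effect(downwind: float, upwind: float) -> float:
    """Downwind:upwind abundance ratio; NaN (missing) when upwind is zero."""
    if upwind == 0:
        return float("nan")
    return downwind / upwind


def average_replicates(copies, geometric: bool = False) -> float:
    """Collapse duplicate reactions on the copy scale (arithmetic mean by
    default, geometric behind the flag)."""
    x = np.asarray(copies, dtype=float)
    if x.size == 0:
        raise ValidationError("no replicate values")
    if geometric:
        return float(np.exp(np.mean(np.log(x))))
    return float(x.mean())
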