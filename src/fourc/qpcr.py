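"""qPCR quantitation arithmetic: standard curves, ChIP percent input,
3C interaction frequencies and reference-gene-normalised expression.

The standard-curve method fits ``Ct = intercept + slope * log10(q)`` to
a dilution series of known quantities (slope near -3.32 for a perfectly
efficient reaction) and inverts it to quantify unknowns.  On top of the
recovered quantities:

* ChIP enrichment is expressed as percent input after subtracting the
  no-antibody background, with the input signal scaled up by the
  fraction of chromatin it represents;
* 3C interaction frequencies divide the chromatin-library junction
  signal by a positive-control signal taken from the linear range of a
  control titration;
* RT-qPCR fold changes normalise a target to a reference transcript
  (e.g. GAPDH, or beta-2-microglobulin when GAPDH itself responds to
  the stimulus) and then to a calibrator sample's normalised ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "StandardCurve",
    "fit_standard_curve",
    "quantify",
    "percent_input",
    "interaction_frequency",
    "rt_fold_change",
    "select_linear_control",
]


@dataclass(frozen=True)
class StandardCurve:
    slope: float  # Ct per log10(quantity); < 0 for a valid curve
    intercept: float  # Ct at quantity 1
    r_squared: float


def fit_standard_curve(standards: Sequence[tuple[float, float]]) -> StandardCurve:
    """Least-squares ``Ct = intercept + slope * log10(quantity)``.

    Needs at least three standards with at least two distinct positive
    quantities.
    """
    if len(standards) < 3:
        raise ValueError("need at least 3 standards")
    quantities = np.array([q for q, _ in standards], dtype=float)
    cts = np.array([ct for _, ct in standards], dtype=float)
    if np.any(quantities <= 0):
        raise ValueError("standard quantities must be > 0")
    if np.unique(quantities).size < 2:
        raise ValueError("standards need at least two distinct quantities")
    result = stats.linregress(np.log10(quantities), cts)
    return StandardCurve(
        slope=float(result.slope),
        intercept=float(result.intercept),
        r_squared=float(result.rvalue**2),
    )


def quantify(curve: StandardCurve, ct: float) -> float:
    """Invert the curve: ``quantity = 10 ** ((ct - intercept) / slope)``."""
    if curve.slope == 0:
        raise ValueError("cannot invert a flat standard curve")
    return float(10.0 ** ((ct - curve.intercept) / curve.slope))


def percent_input(
    ip_quantity: float,
    no_antibody_quantity: float,
    input_quantity: float,
    input_fraction: float,
) -> float:
    """Background-subtracted ChIP signal as percent of total input.

    ``100 * (ip - no_antibody) / (input / input_fraction)`` where
    ``input_fraction`` is the fraction of chromatin the input sample
    represents (0.1 for a 10% input).  Negative background-subtracted
    signals are floored at 0 with a warning.
    """
    if input_quantity <= 0:
        raise ValueError("input quantity must be > 0")
    if not 0 < input_fraction <= 1:
        raise ValueError("input_fraction must lie in (0, 1]")
    enrichment = ip_quantity - no_antibody_quantity
    if enrichment < 0:
        warnings.warn(
            "no-antibody control exceeds IP signal; flooring percent input at 0",
            stacklevel=2,
        )
        enrichment = 0.0
    return 100.0 * enrichment / (input_quantity / input_fraction)


def interaction_frequency(library_quantity: float, positive_control_quantity: float) -> float:
    """3C junction signal relative to the linear-range positive control."""
    if positive_control_quantity <= 0:
        raise ValueError("positive-control quantity must be > 0")
    return library_quantity / positive_control_quantity


def rt_fold_change(
    target_quantity: float, reference_quantity: float, calibrator_ratio: float = 1.0
) -> float:
    """Reference-normalised expression relative to a calibrator sample.

    ``(target / reference) / calibrator_ratio``; pass ``calibrator_ratio=1``
    to express a sample relative to itself.
    """
    if reference_quantity <= 0:
        raise ValueError("reference quantity must be > 0")
    if calibrator_ratio <= 0:
        raise ValueError("calibrator ratio must be > 0")
    return (target_quantity / reference_quantity) / calibrator_ratio


def select_linear_control(
    titration: Sequence[tuple[float, float]], max_slope_deviation: float = 0.15
) -> int:
    """Pick the titration point to use as the 3C positive control.

    Operationalises "within the linear range": among (quantity, Ct)
    points sorted by quantity, returns the index of the first point
    whose Ct lies strictly between the titration's extremes and whose
    local slope (centred difference on log10 quantity) deviates from
    the fitted overall slope by less than ``max_slope_deviation``
    (fractional).
    """
    if len(titration) < 3:
        raise ValueError("need at least 3 titration points")
    order = np.argsort([q for q, _ in titration])
    quantities = np.array([titration[i][0] for i in order], dtype=float)
    cts = np.array([titration[i][1] for i in order], dtype=float)
    curve = fit_standard_curve(list(zip(quantities, cts)))
    lo, hi = cts.min(), cts.max()
    logq = np.log10(quantities)
    for j in range(1, len(cts) - 1):
        if not lo < cts[j] < hi:
            continue
        local_slope = (cts[j + 1] - cts[j - 1]) / (logq[j + 1] - logq[j - 1])
        if abs(local_slope - curve.slope) < max_slope_deviation * abs(curve.slope):
            return int(order[j])
    raise ValueError("no titration point satisfies the linear-range rule")
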