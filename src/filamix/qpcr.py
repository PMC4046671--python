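"""RT-qPCR standard-curve quantification and cell-specificity estimation.

Quantities are interpolated from a dilution-series standard curve (Ct
regressed on log10 cDNA input), not from the ddCt shortcut.  A perfect
doubling assay has slope -1/log10(2) = -3.32 cycles per decade and 100%
amplification efficiency.  Transcript levels are normalized to the
constitutively expressed RNase P RNA gene (rnpB) quantified from the same
sample.

Cell specificity of an RNA preparation is estimated from a marker gene
expressed in only one cell type (rbcL for vegetative cells, nifK for
heterocysts): the marker's relative signal in the *opposite* preparation,
as a percent of its signal in its home preparation, is the cross-signal;
specificity is 100 minus that cross-signal percent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


class AssayError(ValueError):
    """The qPCR data violate the assay model (e.g. non-negative slope)."""


@dataclass
class StandardCurve:
    """Linear dilution-series calibration: Ct = slope*log10(amount) + intercept.

    ``slope`` is in Ct per log10(amount) and must be negative for a valid
    assay; ``amplification_efficiency`` = 10^(-1/slope) - 1 (1.0 means the
    amplicon doubles every cycle).
    """

    slope: float
    intercept: float
    r2: float

    def __post_init__(self):
        if self.slope >= 0:
            raise AssayError(
                f"standard-curve slope must be negative, got {self.slope}")
        if not (0.0 <= self.r2 <= 1.0 + 1e-12):
            raise AssayError(f"r2 out of [0, 1]: {self.r2}")

    @property
    def amplification_efficiency(self) -> float:
        return 10.0 ** (-1.0 / self.slope) - 1.0


@dataclass
class SpecificityEstimate:
    """Cell specificity of one RNA preparation judged by one marker gene."""

    target_cell_type: str
    marker_gene: str
    cross_signal_percent: float
    specificity_percent: float

    def __post_init__(self):
        for x in (self.cross_signal_percent, self.specificity_percent):
            if not (0.0 <= x <= 100.0):
                raise AssayError(
                    f"percentage out of [0, 100]: {x} (assay failure)")


def fit_standard_curve(amounts, cts) -> StandardCurve:
    """Least-squares line of Ct on log10(cDNA amount).

    Requires at least three dilution points with strictly positive
    amounts.  A non-negative slope is rejected as an invalid assay.
    """
    amounts = np.asarray(amounts, dtype=float)
    cts = np.asarray(cts, dtype=float)
    if amounts.size != cts.size:
        raise ValueError("amounts and Cts differ in length")
    if amounts.size < 3:
        raise ValueError("need at least 3 dilution points")
    if (amounts <= 0).any():
        raise ValueError("cDNA amounts must be positive")
    res = stats.linregress(np.log10(amounts), cts)
    return StandardCurve(slope=float(res.slope),
                         intercept=float(res.intercept),
                         r2=float(res.rvalue ** 2))


def quantify_relative(ct: float, curve: StandardCurve,
                      reference_quantity: float = 1.0) -> float:
    """Interpolate a quantity from the standard curve and normalize it.

    quantity = 10^((intercept - ct)/|slope|); the relative level divides by
    ``reference_quantity`` (typically the rnpB quantity interpolated from
    the same sample).
    """
    if reference_quantity <= 0:
        raise ValueError("reference quantity must be positive")
    quantity = 10.0 ** ((curve.intercept - ct) / abs(curve.slope))
    return quantity / reference_quantity


def estimate_specificity(marker_home_signal: float,
                         marker_cross_signal: float,
                         target_cell_type: str = "",
                         marker_gene: str = "") -> SpecificityEstimate:
    """Cell specificity from a marker's home vs cross preparation signals.

    Signals must already be reference-normalized (rnpB).  A cross signal
    exceeding the home signal contradicts marker specificity and is
    rejected as an assay failure.
    """
    if marker_home_signal <= 0:
        raise ValueError("home signal must be positive")
    if marker_cross_signal < 0:
        raise ValueError("cross signal must be non-negative")
    if marker_cross_signal > marker_home_signal:
        raise AssayError(
            "cross signal exceeds home signal; marker not specific or "
            "assay failed")
    cross_pct = 100.0 * marker_cross_signal / marker_home_signal
    return SpecificityEstimate(
        target_cell_type=target_cell_type,
        marker_gene=marker_gene,
        cross_signal_percent=cross_pct,
        specificity_percent=100.0 - cross_pct,
    )


def check_reference_stability(reference_cts, tolerance: float = 0.05) -> bool:
    """Warn when the reference gene's Ct varies by more than ``tolerance``.

    The constitutive-expression assumption for rnpB holds when its Ct
    varies by no more than ~5% across preparations; violation is warned
    on, not enforced.
    """
    cts = np.asarray(reference_cts, dtype=float)
    if cts.size < 2:
        return True
    spread = (cts.max() - cts.min()) / cts.mean()
    if spread > tolerance:
        warnings.warn(
            f"reference-gene Ct varies by {100 * spread:.1f}% "
            f"(> {100 * tolerance:.0f}%); constitutive-expression "
            "assumption questionable")
        return False
    return True
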