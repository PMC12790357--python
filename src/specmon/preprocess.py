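"""Conditioning of spectra ahead of similarity analysis.

EPR spectrometers record the first derivative of the absorption line (lock-in
detection); :func:`integrate_derivative` recovers absorption mode, anchoring
both endpoints to zero so the linear drift that cumulative integration of a
noisy derivative produces cannot dominate the union area of the Jaccard
metric.  :func:`estimate_error` supplies the instrument-error scale sigma
that conditions the Jaccard min/max comparison; all three estimators are
robust (MAD-based) because spectra carry sparse large peaks that would
inflate a plain standard deviation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .datatypes import Mode, Spectrum, SpectrumSeries
from .errors import NegativeIntensityError, ValidationError

logger = logging.getLogger("specmon")

# 1/Phi^{-1}(3/4): scales the median absolute deviation to a Gaussian sigma
_MAD_TO_SIGMA = 1.4826


class ErrorMethod(str, Enum):
    REPLICATE_DIFF = "replicate_diff"
    NOISE_REGION = "noise_region"
    ADJACENT_DIFF = "adjacent_diff"


@dataclass
class ErrorEstimate:
    """Point-noise standard deviation on the intensity scale."""

    sigma: float
    method: ErrorMethod
    n_points: int

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValidationError("sigma must be >= 0")
        self.method = ErrorMethod(self.method)


def integrate_derivative(s: Spectrum) -> Spectrum:
    """Cumulative trapezoidal integration of a derivative-mode spectrum.

    Returns an absorption-mode spectrum whose first and last points are
    anchored to zero by subtracting a straight line (anchored detrend); this
    removes the ramp a constant offset in the derivative would integrate to.
    """
    if s.mode != Mode.DERIVATIVE:
        raise ValidationError("integrate_derivative requires a derivative-mode spectrum")
    d = np.diff(s.axis)
    step = d.mean()
    if np.max(np.abs(d - step)) > 1e-6 * abs(step):
        raise ValidationError("integrate_derivative requires a uniformly spaced axis")
    y = cumulative_trapezoid(s.intensity, s.axis, initial=0.0)
    ramp = y[0] + (y[-1] - y[0]) * (s.axis - s.axis[0]) / (s.axis[-1] - s.axis[0])
    return s.with_intensity(y - ramp, mode=Mode.ABSORPTION)


def baseline_correct(s: Spectrum, quantile: float = 0.05) -> Spectrum:
    """Subtract the given intensity quantile from all points."""
    if not 0 <= quantile <= 0.5:
        raise ValidationError("quantile must be in [0, 0.5]")
    return s.with_intensity(s.intensity - np.quantile(s.intensity, quantile))


def block_average(series: SpectrumSeries, k: int) -> SpectrumSeries:
    """Average consecutive non-overlapping blocks of ``k`` spectra.

    Block time is the mean of member times.  A trailing partial block is
    kept and averaged (endpoint detection should see the latest data).
    """
    if k < 1:
        raise ValidationError("block size k must be >= 1")
    if k > len(series):
        raise ValidationError(f"block size {k} exceeds series length {len(series)}")
    if k == 1:
        return series
    out = []
    n = len(series)
    if n % k:
        logger.info("block_average: trailing partial block of %d spectra kept", n % k)
    for start in range(0, n, k):
        block = series.spectra[start : start + k]
        mean_int = np.mean([s.intensity for s in block], axis=0)
        mean_t = float(np.mean([s.time for s in block]))
        out.append(block[0].with_intensity(mean_int, time=mean_t))
    return SpectrumSeries(spectra=out)


def _mad_sigma(x: np.ndarray) -> float:
    return _MAD_TO_SIGMA * float(np.median(np.abs(x - np.median(x))))


def estimate_error(
    series: SpectrumSeries,
    method: ErrorMethod | str = ErrorMethod.REPLICATE_DIFF,
    noise_region: tuple[float, float] | None = None,
) -> ErrorEstimate:
    """Estimate the instrument error sigma on the intensity scale.

    ``replicate_diff``: robust sigma of the pointwise difference of the first
    two spectra, divided by sqrt(2) (the difference of two equal-noise
    acquisitions carries twice the variance).  ``noise_region``: sample s.d.
    inside a signal-free axis interval of the first spectrum after linear
    detrend.  ``adjacent_diff``: robust sigma of successive-point differences
    of the first spectrum, divided by sqrt(2).
    """
    method = ErrorMethod(method)
    first = series[0]
    if method == ErrorMethod.REPLICATE_DIFF:
        if len(series) < 2:
            raise ValidationError("replicate_diff needs at least 2 spectra")
        d = series[1].intensity - first.intensity
        return ErrorEstimate(_mad_sigma(d) / np.sqrt(2), method, d.size)
    if method == ErrorMethod.NOISE_REGION:
        if noise_region is None:
            raise ValidationError("noise_region method requires a noise_region interval")
        lo, hi = sorted(noise_region)
        mask = (first.axis >= lo) & (first.axis <= hi)
        if mask.sum() < 3:
            raise ValidationError("noise region contains fewer than 3 points")
        x, y = first.axis[mask], first.intensity[mask]
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        return ErrorEstimate(float(np.std(resid, ddof=2)), method, int(mask.sum()))
    # adjacent_diff
    dy = np.diff(first.intensity)
    if dy.size < 2:
        raise ValidationError("adjacent_diff needs at least 3 points")
    return ErrorEstimate(_MAD_TO_SIGMA * float(np.median(np.abs(dy))) / np.sqrt(2), method, dy.size)


def enforce_nonnegative(s: Spectrum, epsilon: float = 0.0) -> Spectrum:
    """Clip tiny negatives to zero; fail if any value is below ``-epsilon``.

    Genuinely negative intensities would cancel areas in the Jaccard metric;
    the raised error carries the offending fraction so callers can fall back
    to cross-correlation similarity.
    """
    if epsilon < 0:
        raise ValidationError("epsilon must be >= 0")
    below = s.intensity < -epsilon
    if np.any(below):
        frac = float(below.mean())
        raise NegativeIntensityError(
            f"{below.sum()} of {s.intensity.size} intensities below -epsilon "
            f"({frac:.1%}); use cross-correlation similarity instead",
            fraction=frac,
        )
    if np.any(s.intensity < 0):
        return s.with_intensity(np.maximum(s.intensity, 0.0))
    return s
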