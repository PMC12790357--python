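"""The two spectral similarity measures at the heart of the package.

Geometric Jaccard index
    J(A,B) = |A ∩ B| / |A ∪ B|, where the intersection is the area under the
    pointwise minimum of the two spectra and the union the area under the
    pointwise maximum, both by the trapezoidal rule.  The pointwise min/max
    on near-identical noisy spectra is ill-conditioned — it amplifies
    instrument error the way catastrophic cancellation does in floating-point
    subtraction — so wherever two intensities differ by less than the
    instrument error ``epsilon`` they are treated as equal (both curves get
    their mean, keeping the metric symmetric).

Normalized cross-correlation
    S(f,g) = max_{tau >= 0} Re[(f ⋆ g)(tau)] / sqrt(sum|f|^2 · sum|g|^2),
    with (f ⋆ g)(tau) = sum_t conj(f(t)) · g(t+tau) — linear, not circular.
    Bounded by 1 (Cauchy–Schwarz), invariant to positive scaling and to pure
    delays, and applicable to raw complex FIDs and to spectra whose negative
    excursions make the geometric Jaccard inappropriate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

from .datatypes import ComplexSeries, Spectrum, SpectrumSeries, SimilarityTrace
from .errors import ValidationError

logger = logging.getLogger("specmon")

__all__ = ["JaccardResult", "XcorrResult", "jaccard", "xcorr_similarity", "similarity_trace"]


@dataclass
class JaccardResult:
    value: float
    intersection_area: float
    union_area: float
    window: tuple[float, float] | None
    epsilon: float


@dataclass
class XcorrResult:
    value: float
    best_lag: int
    lag_range: tuple[int, int]


def _window_mask(axis: np.ndarray, window: tuple[float, float] | None) -> np.ndarray:
    if window is None:
        return np.ones(axis.size, dtype=bool)
    lo, hi = sorted(window)
    mask = (axis >= lo) & (axis <= hi)
    if mask.sum() < 2:
        raise ValidationError(f"window {window} overlaps fewer than 2 axis points")
    return mask


def jaccard(
    a: Spectrum,
    b: Spectrum,
    epsilon: float = 0.0,
    window: tuple[float, float] | None = None,
) -> JaccardResult:
    """Error-conditioned geometric Jaccard index of two spectra.

    Both spectra must share an identical axis grid and be nonnegative.
    Points whose intensities differ by at most ``epsilon`` contribute their
    mean to both the lower and the upper envelope.  If both spectra are
    identically zero under ``epsilon`` the value is 1 by convention (two
    silent spectra are maximally similar); blank runs are screened upstream
    by the Spearman gate.
    """
    if epsilon < 0:
        raise ValidationError("epsilon must be >= 0")
    if a.axis.size != b.axis.size or not np.array_equal(a.axis, b.axis):
        raise ValidationError("spectra must share an identical axis grid (resample first)")
    if np.any(a.intensity < 0) or np.any(b.intensity < 0):
        raise ValidationError(
            "negative intensities: apply enforce_nonnegative, or use xcorr_similarity"
        )
    mask = _window_mask(a.axis, window)
    x = a.axis[mask]
    ya, yb = a.intensity[mask], b.intensity[mask]

    lower = np.minimum(ya, yb)
    upper = np.maximum(ya, yb)
    equal = np.abs(ya - yb) <= epsilon
    mean = 0.5 * (ya + yb)
    lower = np.where(equal, mean, lower)
    upper = np.where(equal, mean, upper)

    inter = float(np.trapezoid(lower, x))
    union = float(np.trapezoid(upper, x))
    if union == 0.0:
        logger.info("jaccard: both spectra identically zero under epsilon; value=1 by convention")
        value = 1.0
    else:
        value = inter / union
    return JaccardResult(value=value, intersection_area=inter, union_area=union,
                         window=window, epsilon=epsilon)


def _as_samples(x: Union[ComplexSeries, Spectrum, Sequence]) -> np.ndarray:
    if isinstance(x, ComplexSeries):
        return x.samples
    if isinstance(x, Spectrum):
        return x.intensity.astype(complex)
    return np.asarray(x, dtype=complex)


def xcorr_similarity(
    f: Union[ComplexSeries, Spectrum, Sequence],
    g: Union[ComplexSeries, Spectrum, Sequence],
    max_lag: int | None = None,
    use_modulus: bool = False,
    two_sided: bool = False,
) -> XcorrResult:
    """Normalized maximum cross-correlation of two real or complex series.

    The lag search covers tau in [0, max_lag] by default (max_lag defaults to
    length-1); ``two_sided`` extends it to negative lags for drifting
    references.  The real part of the complex correlation is maximized unless
    ``use_modulus`` is set — the modulus would score a sign-flipped signal as
    identical.  Unequal lengths are zero-padded (all acquired signal energy
    stays in the denominator).  Ties in the argmax go to the smallest tau.
    """
    fs, gs = _as_samples(f), _as_samples(g)
    if fs.size != gs.size:
        logger.info("xcorr: zero-padding shorter series (%d vs %d)", fs.size, gs.size)
        n = max(fs.size, gs.size)
        fs = np.pad(fs, (0, n - fs.size))
        gs = np.pad(gs, (0, n - gs.size))
    n = fs.size
    ef = float(np.sum(np.abs(fs) ** 2))
    eg = float(np.sum(np.abs(gs) ** 2))
    if ef == 0.0 or eg == 0.0:
        raise ValidationError("all-zero input: cross-correlation normalization undefined")
    if max_lag is None:
        max_lag = n - 1
    max_lag = int(min(max_lag, n - 1))
    if max_lag < 0:
        raise ValidationError("max_lag must be >= 0")

    # full linear correlation; index k corresponds to lag k-(n-1) with
    # c(lag) = sum_t conj(f[t]) g[t+lag]
    full = np.correlate(gs, fs, mode="full")
    lags = np.arange(-(n - 1), n)
    lo = -max_lag if two_sided else 0
    sel = (lags >= lo) & (lags <= max_lag)
    c = full[sel]
    lag_vals = lags[sel]
    score = np.abs(c) if use_modulus else c.real
    # ties toward smallest tau: argmax returns first index, and lag_vals is
    # ascending, so prefer smallest |negative| handled below for two_sided
    best = int(np.argmax(score))
    if two_sided:
        # deterministic: among exact ties prefer the smallest absolute lag
        top = np.flatnonzero(score == score[best])
        best = int(top[np.argmin(np.abs(lag_vals[top]))])
    value = float(score[best] / np.sqrt(ef * eg))
    return XcorrResult(value=value, best_lag=int(lag_vals[best]),
                       lag_range=(int(lo), int(max_lag)))


def similarity_trace(
    series: Union[SpectrumSeries, Sequence[ComplexSeries]],
    metric: str = "jaccard",
    reference: Union[str, int] = "first",
    epsilon: float = 0.0,
    window: tuple[float, float] | None = None,
) -> SimilarityTrace:
    """Similarity of every acquisition against a fixed reference acquisition.

    ``reference`` is "first", "last", or an integer index.  The Jaccard
    metric requires nonnegative spectra on a common grid; the xcorr metric
    accepts spectra or raw FIDs.
    """
    if isinstance(series, SpectrumSeries):
        items: Sequence = series.spectra
        times = series.times
    else:
        items = list(series)
        times = np.array([c.time for c in items], dtype=float)
    if len(items) < 2:
        raise ValidationError("similarity trace needs at least 2 acquisitions")
    if reference == "first":
        ref_idx = 0
    elif reference == "last":
        ref_idx = len(items) - 1
    else:
        ref_idx = int(reference)
        if not -len(items) <= ref_idx < len(items):
            raise ValidationError(f"reference index {ref_idx} out of range")
    ref = items[ref_idx]

    values = np.empty(len(items))
    for i, item in enumerate(items):
        try:
            if metric == "jaccard":
                values[i] = jaccard(ref, item, epsilon=epsilon, window=window).value
            elif metric == "xcorr":
                values[i] = xcorr_similarity(ref, item).value
            else:
                raise ValidationError(f"unknown metric {metric!r}")
        except ValidationError as exc:
            raise ValidationError(f"acquisition {i}: {exc}") from exc
    return SimilarityTrace(
        times=times,
        values=values,
        metric=metric,
        reference=str(reference),
        epsilon=epsilon,
        window=window,
    )
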