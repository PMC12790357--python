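"""Kinetic profiling of similarity traces.

Three profiles cover the reaction classes the monitoring method resolves:

* apparent first-order kinetics — the trace follows ``a·exp(-(t-t_first)/tau) + c``
  and the time constant ``tau``, collected across reaction temperatures,
  supports Arrhenius-style analysis;
* autocatalysis — the trace follows a logistic (sigmoidal) step
  ``c + a / (1 + exp((t - t0)/w))``;
* chemical oscillation — the dominant non-DC Fourier component of the
  detrended trace gives the oscillation period.

All fits are deterministic numerical least squares with fixed, documented
initialization; no randomness is involved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import optimize, stats

from .datatypes import SimilarityTrace
from .errors import ValidationError

logger = logging.getLogger("specmon")

__all__ = [
    "KineticFit",
    "ArrheniusResult",
    "OscillationResult",
    "fit_exponential",
    "fit_sigmoid",
    "arrhenius",
    "detect_oscillation",
]


class KineticModel(str, Enum):
    EXPONENTIAL = "exponential"
    SIGMOID = "sigmoid"


@dataclass
class KineticFit:
    model: KineticModel
    params: dict[str, float]
    stderr: dict[str, float]
    rss: float
    aicc: float
    converged: bool

    @property
    def degenerate(self) -> dict[str, bool]:
        """Parameters whose standard error exceeds their value (unidentifiable)."""
        return {
            k: bool(not np.isfinite(self.stderr[k]) or self.stderr[k] > abs(v))
            for k, v in self.params.items()
        }


@dataclass
class ArrheniusResult:
    pairs: list[tuple[float, float]]
    slope_arrhenius: float      # of ln(1/tau) vs 1/T
    intercept_arrhenius: float
    r_squared_arrhenius: float
    slope_linear: float         # of tau vs T
    intercept_linear: float
    r_squared_linear: float


@dataclass
class OscillationResult:
    period: float | None
    frequency: float | None
    power_fraction: float
    spectrum: np.ndarray = field(repr=False)  # (n_bins, 2): frequency, power
    detrend: str = "linear"
    dominant_bin: int = 0
    is_local_max: bool = False


def _aicc(rss: float, n: int, k: int) -> float:
    """Small-sample-corrected Akaike criterion n·ln(rss/n) + 2k + 2k(k+1)/(n-k-1)."""
    rss = max(rss, np.finfo(float).tiny)
    if n - k - 1 <= 0:
        return np.inf
    return n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def _finish_fit(model, func, t, y, p0, names, bounds) -> KineticFit:
    try:
        popt, pcov = optimize.curve_fit(
            func, t, y, p0=p0, bounds=bounds, maxfev=10000,
            xtol=1e-12, ftol=1e-12, gtol=1e-12,
        )
        converged = True
    except (RuntimeError, optimize.OptimizeWarning, ValueError):
        popt = np.asarray(p0, dtype=float)
        pcov = np.full((len(p0), len(p0)), np.inf)
        converged = False
    resid = y - func(t, *popt)
    rss = float(np.dot(resid, resid))
    with np.errstate(invalid="ignore"):
        perr = np.sqrt(np.diag(pcov))
    # a perfect fit (rss = 0) collapses the scaled covariance to zero even
    # for parameters the model is insensitive to; flag those through the
    # Jacobian column norm instead
    scale = max(1.0, float(np.linalg.norm(y)))
    for j, p in enumerate(popt):
        step = 1e-7 * max(1.0, abs(p))
        up = np.array(popt, dtype=float)
        dn = np.array(popt, dtype=float)
        up[j] += step
        dn[j] -= step
        col = (func(t, *up) - func(t, *dn)) / (2 * step)
        if np.linalg.norm(col) <= 1e-10 * scale:
            perr[j] = np.inf
    return KineticFit(
        model=model,
        params=dict(zip(names, (float(v) for v in popt))),
        stderr=dict(zip(names, (float(v) for v in perr))),
        rss=rss,
        aicc=_aicc(rss, len(y), len(p0)),
        converged=converged,
    )


def fit_exponential(trace: SimilarityTrace) -> KineticFit:
    """Fit ``a·exp(-(t - t_first)/tau) + c`` to a similarity trace.

    Time is referenced to the first sample so the amplitude ``a`` is the
    initial departure from the plateau ``c`` and is unaffected by shifting
    the run clock.  Initialization: ``c0`` is the mean of the last three
    values, ``a0`` the first value minus ``c0``, and ``tau0`` the time at
    which the trace first decays to ``c0 + a0/e`` (falling back to one third
    of the span).  A failed optimization returns ``converged=False`` rather
    than raising; a constant trace converges with ``a ~ 0`` and tau flagged
    unidentifiable through its standard error.
    """
    if len(trace) < 5:
        raise ValidationError("exponential fit needs at least 5 points")
    if not np.all(np.isfinite(trace.values)):
        raise ValidationError("trace values must be finite")
    t = trace.times - trace.times[0]
    y = trace.values
    span = t[-1] if t[-1] > 0 else 1.0
    c0 = float(np.mean(y[-3:]))
    a0 = float(y[0] - c0)
    tau0 = span / 3
    if a0 != 0:
        ratio = (y - c0) / a0  # ~1 at t=0, decaying toward 0
        crossed = np.flatnonzero(ratio <= 1 / np.e)
        if crossed.size and t[crossed[0]] > 0:
            tau0 = float(t[crossed[0]])

    def model(tt, a, tau, c):
        return a * np.exp(-tt / tau) + c

    bounds = ([-np.inf, 1e-12 * span, -np.inf], [np.inf, np.inf, np.inf])
    return _finish_fit(KineticModel.EXPONENTIAL, model, t, y,
                       [a0, tau0, c0], ("a", "tau", "c"), bounds)


def fit_sigmoid(trace: SimilarityTrace) -> KineticFit:
    """Fit the logistic step ``c + a / (1 + exp((t - t0)/w))``.

    Initialization: ``t0`` at the steepest finite-difference slope, width
    one tenth of the span, amplitude first minus last value, offset the last
    value.  Same convergence contract as :func:`fit_exponential`.
    """
    if len(trace) < 7:
        raise ValidationError("sigmoid fit needs at least 7 points")
    if not np.all(np.isfinite(trace.values)):
        raise ValidationError("trace values must be finite")
    t = trace.times.astype(float)
    y = trace.values
    span = t[-1] - t[0] if t[-1] > t[0] else 1.0
    dy = np.abs(np.diff(y) / np.diff(t))
    t0_0 = float(0.5 * (t[np.argmax(dy)] + t[np.argmax(dy) + 1]))
    w0 = span / 10
    a0 = float(y[0] - y[-1])
    c0 = float(y[-1])

    def model(tt, a, t0, w, c):
        z = np.clip((tt - t0) / w, -500, 500)
        return c + a / (1 + np.exp(z))

    bounds = ([-np.inf, -np.inf, 1e-12 * span, -np.inf],
              [np.inf, np.inf, np.inf, np.inf])
    return _finish_fit(KineticModel.SIGMOID, model, t, y,
                       [a0, t0_0, w0, c0], ("a", "t0", "w", "c"), bounds)


def arrhenius(fits: list[tuple[float, KineticFit]]) -> ArrheniusResult:
    """Temperature dependence of exponential time constants, both ways.

    Reports ordinary least squares of ln(1/tau) on 1/T (the standard
    Arrhenius form, slope = -Ea/R) and of tau on T (the directly plotted
    form), each with r².  Neither is privileged.
    """
    if len(fits) < 3:
        raise ValidationError("Arrhenius analysis needs at least 3 temperatures")
    temps = np.array([T for T, _ in fits], dtype=float)
    if np.unique(temps).size != temps.size:
        raise ValidationError("temperatures must be distinct")
    for T, f in fits:
        if f.model != KineticModel.EXPONENTIAL or not f.converged:
            raise ValidationError(f"fit at T={T} K is not a converged exponential fit")
    taus = np.array([f.params["tau"] for _, f in fits], dtype=float)
    if np.any(taus <= 0):
        raise ValidationError("time constants must be positive")

    arr = stats.linregress(1.0 / temps, np.log(1.0 / taus))
    lin = stats.linregress(temps, taus)
    return ArrheniusResult(
        pairs=[(float(T), float(tau)) for T, tau in zip(temps, taus)],
        slope_arrhenius=float(arr.slope),
        intercept_arrhenius=float(arr.intercept),
        r_squared_arrhenius=float(arr.rvalue**2),
        slope_linear=float(lin.slope),
        intercept_linear=float(lin.intercept),
        r_squared_linear=float(lin.rvalue**2),
    )


def detect_oscillation(
    trace: SimilarityTrace, detrend: str = "linear"
) -> OscillationResult:
    """Oscillation period by Fourier transformation of the trace.

    The trace is detrended (OLS line by default, or a moving-mean baseline),
    Hann-windowed and real-FFT'd; the dominant bin is the non-DC power
    maximum, and the frequency is refined by parabolic interpolation over
    the dominant bin and its neighbors (exact for a sinusoid completing an
    integer number of cycles, leakage-suppressed otherwise).  The power
    fraction is reported on the unrefined spectrum.  A constant trace
    reports no period and a power fraction of zero.
    """
    n = len(trace)
    if n < 16:
        raise ValidationError("oscillation detection needs at least 16 points")
    dts = np.diff(trace.times)
    dt = float(dts.mean())
    if np.max(np.abs(dts - dt)) > 1e-6 * dt:
        raise ValidationError(
            "non-uniform sampling: resample the trace to a uniform time grid first"
        )
    y = trace.values.astype(float)
    if detrend == "linear":
        slope, intercept = np.polyfit(trace.times, y, 1)
        resid = y - (slope * trace.times + intercept)
    elif detrend == "moving_mean":
        k = max(3, n // 8) | 1  # odd window
        pad = k // 2
        padded = np.pad(y, pad, mode="edge")
        baseline = np.convolve(padded, np.ones(k) / k, mode="valid")
        resid = y - baseline
    else:
        raise ValidationError(f"unknown detrend method {detrend!r}")

    windowed = resid * np.hanning(n)
    spec = np.fft.rfft(windowed)
    power = np.abs(spec) ** 2
    freqs = np.fft.rfftfreq(n, d=dt)
    spectrum = np.column_stack([freqs, power])

    nondc = power[1:]
    total = float(nondc.sum())
    # effectively-constant trace: residual at floating-point rounding level
    resid_rms = float(np.sqrt(np.mean(resid**2)))
    if total <= 0 or resid_rms <= 1e-10 * max(1.0, float(np.max(np.abs(y)))):
        return OscillationResult(period=None, frequency=None, power_fraction=0.0,
                                 spectrum=spectrum, detrend=detrend)
    k = 1 + int(np.argmax(nondc))
    power_fraction = float(power[k] / total)
    is_local_max = bool(
        0 < k < power.size - 1 and power[k] > power[k - 1] and power[k] > power[k + 1]
    )

    # parabolic refinement on log-magnitude over (k-1, k, k+1)
    delta = 0.0
    if 0 < k < power.size - 1 and power[k - 1] > 0 and power[k + 1] > 0:
        la, lb, lc = (0.5 * np.log(power[k - 1]), 0.5 * np.log(power[k]),
                      0.5 * np.log(power[k + 1]))
        denom = la - 2 * lb + lc
        if denom < 0:
            delta = float(np.clip(0.5 * (la - lc) / denom, -0.5, 0.5))
    frequency = (k + delta) / (n * dt)
    return OscillationResult(
        period=1.0 / frequency,
        frequency=frequency,
        power_fraction=power_fraction,
        spectrum=spectrum,
        detrend=detrend,
        dominant_bin=k,
        is_local_max=is_local_max,
    )
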