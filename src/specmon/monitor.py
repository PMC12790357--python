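"""Decisions from a similarity trace: noise gating, endpoint, profile class.

A blank (unreactive) run produces a similarity trace that fluctuates randomly
and makes windowed plateau detection erratic, so runs are first screened by
the Spearman rank correlation of similarity versus time: a genuine reaction
drifts monotonically and scores |rho| near 1, noise does not.  The endpoint
itself is declared when the slope of an ordinary least-squares line through
a sliding window of consecutive trace points falls below a threshold
(window 5 points, threshold 1e-3 per sample by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import stats

from . import config, kinetics
from .datatypes import SimilarityTrace
from .errors import ValidationError

logger = logging.getLogger("specmon")

__all__ = ["GateResult", "PlateauResult", "ProfileClass", "spearman_gate",
           "detect_plateau", "classify_profile"]


@dataclass
class GateResult:
    active: bool
    rho: float
    p_value: float
    n_perm: int
    seed: int


@dataclass
class PlateauResult:
    detected: bool
    onset_index: int | None
    onset_time: float | None
    window: int
    slope_threshold: float
    slopes: np.ndarray = field(repr=False)


class ProfileClass(str, Enum):
    INACTIVE = "inactive"
    FIRST_ORDER = "first_order"
    SIGMOIDAL = "sigmoidal"
    OSCILLATORY = "oscillatory"
    UNDETERMINED = "undetermined"


def _centered_ranks(x: np.ndarray) -> np.ndarray:
    r = stats.rankdata(x)  # average ranks on ties
    return r - r.mean()


def spearman_gate(
    trace: SimilarityTrace,
    rho_min: float = config.GATE_RHO_MIN,
    n_perm: int = config.GATE_N_PERM,
    seed: int = 0,
) -> GateResult:
    """Screen out noise-dominated runs by rank correlation with time.

    rho is the Spearman correlation (average ranks on ties) between the
    similarity values and the acquisition times; its two-sided p-value comes
    from seeded permutations of the values with the add-one correction
    p = (1 + #{|rho_perm| >= |rho|}) / (1 + n_perm).  The run is active when
    |rho| >= rho_min and p <= 0.05.
    """
    if len(trace) < 5:
        raise ValidationError("spearman gate needs at least 5 points")
    if not 0 <= rho_min <= 1:
        raise ValidationError("rho_min must be in [0, 1]")
    # Spearman rho is the Pearson correlation of rank vectors; permuting the
    # values permutes their ranks, so each permutation costs one dot product.
    rt = _centered_ranks(trace.times)
    rv = _centered_ranks(trace.values)
    denom = np.sqrt(np.dot(rt, rt) * np.dot(rv, rv))
    rho = float(np.dot(rt, rv) / denom) if denom > 0 else 0.0
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm_rho = np.dot(rt, rng.permutation(rv)) / denom if denom > 0 else 0.0
        if abs(perm_rho) >= abs(rho):
            count += 1
    p = (1 + count) / (1 + n_perm)
    active = bool(abs(rho) >= rho_min and p <= config.GATE_P_MAX)
    return GateResult(active=active, rho=rho, p_value=p, n_perm=n_perm, seed=seed)


def detect_plateau(
    trace: SimilarityTrace,
    window: int = config.PLATEAU_WINDOW,
    slope_threshold: float = config.PLATEAU_SLOPE_THRESHOLD,
    per_second: bool = False,
) -> PlateauResult:
    """Find the first window of consecutive points whose OLS slope is flat.

    For every index i >= window-1 the ordinary least-squares slope of the
    trace values against sample index (or against seconds with
    ``per_second``) over the window ending at i is computed; the plateau
    onset is the first i with |slope| < slope_threshold.  The absolute value
    makes the criterion symmetric so rising traces (reference=last) plateau
    too.
    """
    if window < 2:
        raise ValidationError("window must be >= 2")
    if slope_threshold <= 0:
        raise ValidationError("slope_threshold must be > 0")
    n = len(trace)
    if n < window:
        raise ValidationError(f"trace length {n} shorter than window {window}")
    x_all = trace.times if per_second else np.arange(n, dtype=float)
    slopes = np.full(n, np.nan)
    onset: int | None = None
    for i in range(window - 1, n):
        x = x_all[i - window + 1 : i + 1]
        y = trace.values[i - window + 1 : i + 1]
        xc = x - x.mean()
        slopes[i] = float(np.dot(xc, y) / np.dot(xc, xc))
        if onset is None and abs(slopes[i]) < slope_threshold:
            onset = i
    return PlateauResult(
        detected=onset is not None,
        onset_index=onset,
        onset_time=float(trace.times[onset]) if onset is not None else None,
        window=window,
        slope_threshold=slope_threshold,
        slopes=slopes,
    )


def _oscillation_significant(
    trace: SimilarityTrace,
    power_fraction_min: float,
    seed: int,
    n_perm: int = 199,
) -> bool:
    """Evidence for a genuine oscillation in the trace.

    Requires the dominant non-DC bin to carry >= ``power_fraction_min`` of
    the non-DC power, to sit at an interior local maximum at bin >= 2, and
    to beat the max-power-fraction null obtained from seeded shuffles of the
    trace values (add-one permutation p <= 0.05) — white noise occasionally
    concentrates power by chance, a shuffle null does not care.
    """
    osc = kinetics.detect_oscillation(trace)
    if (
        osc.period is None
        or osc.power_fraction < power_fraction_min
        or osc.dominant_bin < 2
        or not osc.is_local_max
    ):
        return False
    # step- and decay-shaped residuals leak into the lowest bins; a real
    # oscillation carries almost no power below its fundamental
    power = osc.spectrum[:, 1]
    nondc_total = power[1:].sum()
    low_frac = power[1 : osc.dominant_bin].sum() / nondc_total
    if low_frac > config.OSC_LOWFREQ_FRACTION_MAX:
        return False
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        shuffled = SimilarityTrace(
            times=trace.times, values=rng.permutation(trace.values),
            metric=trace.metric, reference=trace.reference, epsilon=trace.epsilon,
        )
        if kinetics.detect_oscillation(shuffled).power_fraction >= osc.power_fraction:
            exceed += 1
    return (1 + exceed) / (1 + n_perm) <= config.GATE_P_MAX


def classify_profile(
    trace: SimilarityTrace,
    rho_min: float = config.GATE_RHO_MIN,
    n_perm: int = config.GATE_N_PERM,
    seed: int = 0,
    power_fraction_min: float = config.OSC_POWER_FRACTION_MIN,
    aicc_margin: float = config.AICC_MARGIN,
) -> ProfileClass:
    """Classify the kinetic profile underlying a similarity trace.

    Order of tests: (1) a dominant non-DC spectral peak carrying at least
    ``power_fraction_min`` of the detrended non-DC power, sitting at an
    interior local maximum at bin >= 2 (at least two full cycles in the
    record) and beating a seeded permutation null, marks *oscillatory* —
    this runs before the Spearman gate because a clean oscillation has rank
    correlation near zero with time and would otherwise be discarded as
    noise; the bin/local-max condition keeps monotone decays, whose residual
    power piles up in the first bin, out of this branch; (2) runs failing
    the Spearman gate are *inactive*; (3) otherwise the exponential and the
    logistic model are both fitted and the lower small-sample-corrected AIC
    wins when the margin exceeds ``aicc_margin``, else *undetermined*.
    """
    if len(trace) < 10:
        raise ValidationError("classification needs at least 10 points")
    if len(trace) >= 16 and _oscillation_significant(
        trace, power_fraction_min=power_fraction_min, seed=seed
    ):
        return ProfileClass.OSCILLATORY

    gate = spearman_gate(trace, rho_min=rho_min, n_perm=n_perm, seed=seed)
    if not gate.active:
        return ProfileClass.INACTIVE

    exp_fit = kinetics.fit_exponential(trace)
    sig_fit = kinetics.fit_sigmoid(trace)
    if not exp_fit.converged and not sig_fit.converged:
        return ProfileClass.UNDETERMINED
    if exp_fit.converged and (not sig_fit.converged or exp_fit.aicc + aicc_margin < sig_fit.aicc):
        return ProfileClass.FIRST_ORDER
    if sig_fit.converged and (not exp_fit.converged or sig_fit.aicc + aicc_margin < exp_fit.aicc):
        return ProfileClass.SIGMOIDAL
    return ProfileClass.UNDETERMINED
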