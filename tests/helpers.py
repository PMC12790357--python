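"""Shared test utilities: canonical synthetic inputs and pipeline shortcuts."""

from __future__ import annotations

import numpy as np

from specmon.datatypes import Spectrum, SpectrumSeries
from specmon.preprocess import enforce_nonnegative, estimate_error
from specmon.similarity import similarity_trace
from specmon.synthgen import RunSpec, simulate_reaction


def gaussian_spectrum(centers=(3.0, 7.0), widths=(0.3, 0.5), amps=(1.0, 0.6),
                      n=200, lo=0.0, hi=10.0, time=0.0):
    x = np.linspace(lo, hi, n)
    y = np.zeros(n)
    for c, w, a in zip(centers, widths, amps):
        y += a * np.exp(-((x - c) ** 2) / (2 * w**2))
    return Spectrum(axis=x, intensity=y, time=time)


def preset_trace(spec: RunSpec, epsilon=None, reference="first", window=None):
    """simulate -> clip -> similarity trace, the standard Jaccard pipeline."""
    series = simulate_reaction(spec)
    if epsilon is None:
        epsilon = estimate_error(series).sigma if spec.noise_sigma > 0 else 0.0
    clipped = SpectrumSeries(
        spectra=[enforce_nonnegative(s, epsilon=1.0) for s in series]
    )
    return similarity_trace(clipped, metric="jaccard", reference=reference,
                            epsilon=epsilon, window=window)
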