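"""Detect a reaction endpoint from the Jaccard similarity trace.

Simulates a first-order reaction monitored by NMR-like spectra (1% noise),
computes the similarity of every spectrum to the first one, and declares the
endpoint when the slope of five consecutive trace points stays below 1e-3.
"""

import numpy as np

from specmon import detect_plateau, estimate_error, fit_exponential, similarity_trace
from specmon.datatypes import SpectrumSeries
from specmon.preprocess import enforce_nonnegative
from specmon.synthgen import first_order_preset, simulate_reaction

series = simulate_reaction(first_order_preset(seed=0))
sigma = estimate_error(series).sigma
series = SpectrumSeries(spectra=[enforce_nonnegative(s, epsilon=1.0) for s in series])

trace = similarity_trace(series, metric="jaccard", reference="first", epsilon=sigma)
plateau = detect_plateau(trace, window=5, slope_threshold=1e-3)
fit = fit_exponential(trace)

print(f"instrument noise sigma (estimated): {sigma:.4f}")
print(f"trace starts at {trace.values[0]:.3f} and ends at {trace.values[-1]:.3f}")
print(f"plateau detected: {plateau.detected} at t = {plateau.onset_time:.0f} s "
      f"(sample {plateau.onset_index})")
print(f"apparent first-order time constant tau = {fit.params['tau']:.1f} s "
      f"(generator: 120 s)")
print()
print("The trace decays from 1 (self-comparison) as the mixture composition")
print("moves away from the initial spectrum; the flat-slope window marks the")
print("point where the spectra stop changing, i.e. the reaction endpoint.")
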