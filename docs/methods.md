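# Methods

This note documents the models, numerical choices and limitations behind
`specmon`, in the spirit of a package manual rather than a tutorial.

## Similarity metrics

### Geometric Jaccard index

Two spectra on a bitwise-identical axis grid are compared by forming the
pointwise lower envelope `min(aᵢ, bᵢ)` and upper envelope `max(aᵢ, bᵢ)` and
integrating both by the trapezoidal rule; the index is the ratio
intersection/union.  Trapezoidal integration is exact for the piecewise
linear interpolant that the regridding step (`spectra_io.resample_series`)
already assumes, so no second discretization model is introduced.  Inputs
must be nonnegative: negative excursions would cancel area between the two
envelopes and make the geometric reading meaningless
(`preprocess.enforce_nonnegative` clips rounding-level negatives and
rejects genuinely negative data, directing the caller to the
cross-correlation metric).

**Error conditioning.**  The min/max operation is ill-conditioned on
near-identical noisy inputs: for two acquisitions of an unchanged sample,
`E[min(a+n₁, b+n₂)]` sits below the true common curve by ~σ/√π wherever the
signals agree to within the noise, so the index of an unchanged sample sits
measurably below 1 and fluctuates.  The mitigation: wherever
`|aᵢ − bᵢ| ≤ ε`, both envelopes receive the mean `(aᵢ + bᵢ)/2`.  The mean
(rather than either input) keeps the metric symmetric.  Consequences,
all enforced by tests:

* the index is monotonically non-decreasing in ε (the lower envelope can
  only rise, the upper only fall);
* symmetry, bounds [0, 1] and joint scale invariance (scale both spectra
  and ε by c > 0) are preserved;
* two identically-zero spectra (union area 0) score 1 by convention — two
  silent runs are maximally similar; blank runs are screened upstream by
  the Spearman gate, not by the metric.

ε defaults to 1 × the estimated instrument sigma (`estimate_error`); the
multiplier is configurable.  Windowed comparison (e.g. a diagnostic ppm
region) restricts both integrals to an axis interval.

### Normalized maximum cross-correlation

For real or complex series (raw FIDs, dispersive spectra), similarity is
the maximum over non-negative lags of the real part of the linear
(non-circular) cross-correlation `Σ conj(f(t))·g(t+τ)`, normalized by the
geometric mean of the two signal energies.  Choices:

* **Real part, not modulus**: the modulus would score a sign-flipped signal
  as identical.  A `use_modulus` flag exists for phase-insensitive use.
* **Non-negative lags by default**, `two_sided` extends the search to
  negative lags (drifting references); ties in the argmax break toward the
  smallest lag (smallest |lag| in two-sided mode) for determinism.
* **Zero-padding** (never truncation) of unequal lengths, so all acquired
  energy stays in the denominator.
* Underflowing energies (all-zero input) are a validation error — the
  normalization is undefined, and silently returning 0 would be wrong in
  both directions.

Both metrics are verified against independent explicit-loop oracles on
~2000 random small instances to 1e-12.

## Instrument-error estimation

Three estimators, all returning a point-noise sigma on the intensity scale:

* `replicate_diff` (default): robust sigma of the pointwise difference of
  the first two acquisitions, divided by √2.  Closest to "instrument
  error"; needs no user input, valid when the sample changes little between
  the first two frames.
* `noise_region`: sample s.d. of a declared signal-free axis interval after
  linear detrend.
* `adjacent_diff`: robust sigma of successive-point differences of one
  spectrum, divided by √2; fallback when only one acquisition exists.
  Assumes the signal varies slowly relative to the grid.

Robust (MAD × 1.4826) estimators are used instead of plain standard
deviations because spectra carry sparse large peaks that would dominate a
moment-based estimate.

## Preprocessing

* **EPR derivative integration**: cumulative trapezoid, then subtraction of
  the straight line through the first and last points (anchored detrend).
  Plain cumulative integration of a noisy derivative drifts linearly and
  the drift would dominate the Jaccard union; anchoring both endpoints to
  zero removes exactly the ramp that a constant offset in the derivative
  integrates to.  Requires a uniform axis (1e-6 relative).
* **Block averaging**: non-overlapping blocks of k spectra averaged
  pointwise (noise shrinks as 1/√k), block time = mean of member times; a
  trailing partial block is kept so endpoint detection always sees the most
  recent data.
* **Baseline correction**: subtraction of a low intensity quantile
  (default 0.05); adequate for flat baselines, not a polynomial baseline
  model (out of scope).

## Decision layer

### Spearman noise gate

A blank run's similarity trace is exchangeable noise; a genuine reaction
drifts monotonically.  The gate computes Spearman's ρ between trace values
and time (average ranks on ties; a constant trace is defined as ρ = 0) and
a two-sided permutation p-value with the add-one correction
`p = (1 + #{|ρ_perm| ≥ |ρ|})/(1 + n_perm)`, seeded and with `n_perm = 999`
by default.  Active requires `|ρ| ≥ 0.5` and `p ≤ 0.05`.  Because ρ depends
only on ranks, the gate is invariant under any strictly monotone transform
of the values.  Permutations are evaluated as dot products of centered rank
vectors (ranks are computed once; permuting values permutes their ranks),
which keeps 200-run Monte-Carlo checks cheap.

### Plateau (endpoint) detection

For each index i, the OLS slope of the trace values over the `window = 5`
samples ending at i; the endpoint is the first i with `|slope| < 1e-3`.
The absolute value makes the rule symmetric so rising traces
(reference = last) plateau too.  The slope is computed against sample index
by default — the threshold is then per-point and matches regular sampling —
with a `per_second` option for irregular clocks.  The first-hit rule makes
the onset stable under appending data.

### Profile classification

Order of evidence, all thresholds declared in `specmon.config`:

1. **Oscillatory** — the dominant non-DC bin of the detrended,
   Hann-windowed FFT must (a) carry ≥ 0.2 of the non-DC power, (b) sit at
   an interior local maximum at bin ≥ 2 (at least two full cycles in the
   record), (c) leave ≤ 0.2 of the non-DC power in the bins below it, and
   (d) beat a seeded shuffle null (199 permutations, p ≤ 0.05).  This test
   runs *before* the noise gate because a clean oscillation has rank
   correlation ≈ 0 with time and would otherwise be discarded as noise.
   Conditions (b)–(c) exist because monotone and step-shaped traces leak
   detrended power into the lowest bins (a sigmoid step concentrates ~0.5
   of its power at bin 2) and would otherwise masquerade as oscillations;
   condition (d) stops white noise from concentrating power by chance.
2. **Inactive** — fails the Spearman gate.
3. **First-order vs sigmoidal** — both models are fitted; the smaller
   small-sample-corrected AIC wins if the margin exceeds 2, else
   *undetermined*.  `AICc = n·ln(rss/n) + 2k + 2k(k+1)/(n−k−1)`.

## Kinetic fits

* Exponential `a·exp(−(t−t_first)/τ) + c`: initialization c₀ = mean of the
  last 3 values, a₀ = first − c₀, τ₀ = first crossing of c₀ + a₀/e (else
  span/3).  Time is referenced to the first sample so `a` is clock-shift
  invariant.
* Logistic `c + a/(1 + exp((t−t0)/w))`: t0₀ at the steepest finite
  difference, w₀ = span/10, a₀ = first − last, c₀ = last.
* Both use trust-region least squares (positivity bounds on τ, w;
  tolerances 1e-12, deterministic — no randomness anywhere in fitting).
  Optimization failure returns `converged=False` instead of raising.
  Degenerate parameters (e.g. τ of a constant trace) are flagged when the
  standard error exceeds the value; since a perfect fit collapses the
  scaled covariance, insensitive directions are additionally detected
  through vanishing Jacobian column norms.
* Arrhenius analysis reports both OLS of ln(1/τ) on 1/T (standard form,
  slope −Ea/R) and OLS of τ on T (the form sometimes plotted directly),
  each with r²; neither is privileged.

## Oscillation period

Linear (or moving-mean) detrend, Hann window, real FFT; the dominant non-DC
bin's frequency is refined by parabolic interpolation on log-magnitude over
the bin and its neighbors.  For a sinusoid completing an integer number of
cycles the Hann leakage is symmetric and the refinement is exact; for
incommensurate periods it lands well inside the bin width (≲0.1%
relative in tests at ~37 cycles).  The power fraction is reported on the
unrefined spectrum.  A trace whose detrended residual is at rounding level
reports no period and power fraction 0.  Non-uniform sampling is rejected
with a pointer to resampling rather than silently NFFT-ing.

## Synthetic data generator

`synthgen` emulates the monitoring scenarios the method targets, with one
seeded RNG stream per run (one integer reproduces a dataset bit-for-bit):

* spectra = `c_R(t)·(reactant peaks) + (1−c_R(t))·(product peaks)` + i.i.d.
  Gaussian point noise; Gaussian peaks parameterized by sigma, Lorentzians
  by HWHM;
* kinetic laws: first-order `c_R = e^{−kt}`; autocatalytic logistic
  `c_R = 1/(1+e^{(t−t0)/w})`; oscillation `c_R = (1+cos(2πt/P))/2`, which
  starts from pure reactant so the trace against the first spectrum
  oscillates at the chemical period P (a quadrature phase would start the
  run at the composition midpoint and fold the trace to period P/2);
  blank = noise only;
* EPR runs: analytic derivative lineshapes scaled by `1 − e^{−t/τ_growth}`;
* FIDs: sums of `A·e^{iφ}·e^{2πiνt − t/T₂}` plus complex Gaussian noise.

Preset conditions: first-order k = 1/120 s⁻¹ sampled every 10 s for 600 s
at 1% noise; sigmoid t0 = 300 s, w = 30 s, 2 s sampling, 2% noise; BZ-like
preset P = 7.25 s, dt = 0.25 s, 1160 frames (exactly 40 cycles, so the FFT
check is leakage-free), 1% noise.  The first-order and sigmoid presets use
a spectroscopically silent product (common when the product has no
absorption in the diagnostic window); the noiseless Jaccard trace then
equals `c_R(t)` exactly, making ground-truth recovery a sharp test.  With
an absorbing product the trace is a monotone rational transform of `c_R`
— still monotone and still first-order-like, but not exactly exponential.

**What the generator does not emulate** — and what passing tests therefore
do not establish about real instruments: correlated baseline drift,
lineshape changes (shimming, temperature), phase errors, solvent signals,
intensity-dependent noise.  The noise model is i.i.d. Gaussian per point.

## Known limitations

* **Noise bias of the min/max comparison.**  At 1% spectral noise the
  apparent exponential time constant from a Jaccard trace of spectra with a
  silent product sits ~4% below the generating value even with ε = 1σ
  conditioning (~7% unconditioned); the bias shrinks with larger ε and with
  signal averaging.  It is measured and asserted in the test suite.  Time
  constants recovered from traces are precise (sd < 1%) but, at low SNR,
  not exact.
* The plateau rule's threshold (1e-3 per point) presumes roughly regular
  sampling; use `per_second=True` otherwise and rescale the threshold.
* JCAMP-DX support covers uncompressed AFFN `(X++(Y..Y))` and `XYPOINTS`
  tables only; compressed encodings (SQZ/DIF/DUP) are rejected explicitly.
* Regridding never extrapolates: spectra are compared on the intersection
  of their axis ranges only.
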