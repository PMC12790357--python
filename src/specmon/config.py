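"""Declared default constants for monitoring decisions.

Every threshold the pipeline applies is a named constant here (and echoed in
CLI/JSON output), never a hidden literal.
"""

# Plateau rule: OLS slope over this many consecutive trace points must stay
# below this per-sample bound for the endpoint to be declared.
PLATEAU_WINDOW = 5
PLATEAU_SLOPE_THRESHOLD = 1e-3

# Spearman noise gate: minimum |rho| plus permutation-test significance.
GATE_RHO_MIN = 0.5
GATE_N_PERM = 999
GATE_P_MAX = 0.05

# Profile classification: dominant non-DC FFT peak must carry at least this
# fraction of non-DC power; model selection requires this AICc margin.
OSC_POWER_FRACTION_MIN = 0.2
AICC_MARGIN = 2.0

# Oscillation evidence: bins below the dominant one may carry at most this
# fraction of non-DC power (monotone or step-like traces leak heavily into
# the lowest bins; a genuine oscillation does not).
OSC_LOWFREQ_FRACTION_MAX = 0.2

# Epsilon policy: multiplier applied to the estimated instrument sigma when
# the caller asks for an automatic equality tolerance.
EPSILON_SIGMA_MULTIPLIER = 1.0
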