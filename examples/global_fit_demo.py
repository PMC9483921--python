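"""Global photocycle fit of six synthetic fractional-radical curves.

Regenerates the six-power experiment from the canonical constants, fits
the four free rate constants (electron transfer, deprotonation, back-ET,
cation decay) with the photophysical constants fixed, and reports the
identifiability diagnostics alongside the estimates.
"""

from trpkin import global_fit
from trpkin.fitting import p_deprot_estimate, problem_from_traces
from trpkin.synthetic import RadicalTraceSpec, gen_radical_traces

traces, truth = gen_radical_traces(RadicalTraceSpec(seed=7))
problem = problem_from_traces(traces, truth)
result = global_fit(problem)

print(result.summary())
p, se = p_deprot_estimate(problem, result)
print(f"\np_deprot (identifiable combination) = {p:.4f} +/- {se:.4f} (truth 0.1000)")
print(f"per-trace residual RMS: "
      + ", ".join(f"{k}={v:.2e}" for k, v in result.per_trace_rms.items()))

print(
    "\nThe curves constrain only the branching probabilities of the cation\n"
    "radical, not the absolute cation rates, and p_ET is saturated at 1 for\n"
    "any plausible k_ET -- so those parameters are flagged as flat\n"
    "directions while the branching fraction p_deprot is recovered sharply."
)
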