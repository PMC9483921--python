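"""Recover the triplet lifetime and radical dark-decay rate from synthetic
absorbance traces with realistic instrument noise and baseline drift."""

import numpy as np

from trpkin import correct_drift, fit_monoexponential
from trpkin.synthetic import (
    RadicalTraceSpec,
    TripletTraceSpec,
    gen_radical_traces,
    gen_triplet_trace,
)

# 450 nm triplet decays, five replicates
taus = []
for seed in range(1, 6):
    trace, truth = gen_triplet_trace(TripletTraceSpec(seed=seed))
    fit = fit_monoexponential(trace, window=(truth["light_off_s"], trace.time_s[-1]))
    taus.append(fit.tau_s)
print(
    f"triplet lifetime tau_T: {1e3 * np.mean(taus):.0f} +/- "
    f"{1e3 * np.std(taus):.0f} ms (truth {1e3 * truth['tau_T_s']:.0f} ms)"
)

# 514 nm radical dark decays at six excitation powers
traces, truth = gen_radical_traces(RadicalTraceSpec(seed=1))
rates = []
for trace in traces:
    corrected = correct_drift(trace, (0.0, truth["light_on_s"] - 0.2))
    fit = fit_monoexponential(
        corrected, window=(truth["light_off_s"] + 0.1, trace.time_s[-1])
    )
    rates.append(fit.rate)
print(
    f"radical dark decay k_decay: {np.mean(rates):.4f} +/- {np.std(rates):.4f} 1/s "
    f"(truth {truth['rates']['k_decay']})"
)
print(
    "\nBoth constants are fixed inputs of the global photocycle fit; the\n"
    "spread across traces reflects the 2e-4 AU instrument noise."
)
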