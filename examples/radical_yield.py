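"""Radical quantum yield from initial rates across excitation powers.

Builds the yield regression the way the bench analysis does: initial
absorbance slope -> radicals per second, absorbed photons -> excited states
per second, then the through-origin slope across the six powers. Compares
with the analytic one-pass branching yield Phi_isc * p_ET * p_deprot.
"""

import numpy as np

from trpkin import azurin_rates, correct_drift, initial_rate, one_pass_radical_yield, radical_quantum_yield
from trpkin.pipeline import excited_formation_rate, radical_formation_rate
from trpkin.synthetic import RadicalTraceSpec, gen_radical_traces

traces, truth = gen_radical_traces(RadicalTraceSpec(seed=1))
volume_L = truth["beam_area_cm2"] * 0.2 * 1e-3  # beam area x excitation path

excited, radical = [], []
for trace in traces:
    corrected = correct_drift(trace, (0.0, truth["light_on_s"] - 0.2))
    slope, _ = initial_rate(
        corrected, (truth["light_on_s"], truth["light_on_s"] + 30.0)
    )
    excited.append(
        excited_formation_rate(trace.beam, truth["epsilon_excitation"],
                               truth["conc_w48_M"], 0.2)
    )
    radical.append(
        radical_formation_rate(slope, truth["epsilon_probe"],
                               truth["probe_path_cm"], volume_L)
    )

reg = radical_quantum_yield(np.array(excited), np.array(radical))
analytic = one_pass_radical_yield(azurin_rates(0.044))
print(f"Phi_rad (regression):  {reg.slope:.4f} +/- {reg.slope_stderr:.4f}")
print(f"Phi_rad (analytic):    {analytic:.4f}")
print(
    "\nThe regression slope is events per absorbed photon. It runs a few\n"
    "percent below the analytic branching yield because even an early-time\n"
    "rate estimate sees some radical turnover within its window."
)
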