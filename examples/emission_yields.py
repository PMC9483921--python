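"""Relative fluorescence and phosphorescence quantum yields.

Generates a two-band protein emission spectrum (fluorescence near 308 nm,
vibronic phosphorescence at 400-535 nm) plus a reference-fluorophore
spectrum of known yield 0.13, then runs the normalise-and-integrate
procedure to recover the constructed yields.
"""

from trpkin import relative_quantum_yields
from trpkin.synthetic import EmissionSpec, gen_emission_spectra

sample, reference, truth = gen_emission_spectra(EmissionSpec())
phi_fluo, phi_phos = relative_quantum_yields(sample, reference, truth["phi_ref"])
print(f"Phi_fluo = {phi_fluo:.3f} (constructed truth {truth['phi_fluo']})")
print(f"Phi_phos = {phi_phos:.4f} (constructed truth {truth['phi_phos']})")

# triplet-quenched analogue: the phosphorescence band vanishes
sample_q, reference_q, _ = gen_emission_spectra(EmissionSpec(phi_phos_true=0.0))
_, phi_phos_q = relative_quantum_yields(sample_q, reference_q)
print(f"Phi_phos with the triplet quenched: {phi_phos_q:.2g}")

print(
    "\nEmission is normalised by the fraction of excitation light absorbed\n"
    "(1 - 10^-A) and by the emitter's share of that absorption, then scaled\n"
    "against the reference band integral. Quenching of the phosphorescence\n"
    "band by an electron acceptor is the signature of triplet-state ET."
)
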