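"""Per-residue Calpha RMSF profiles and their difference between two systems.

Generates two toy trajectories that differ only in the flexibility of one
loop (residues 36-47 doubled), superposes every frame onto the first, and
reports where the signed RMSF difference localises.
"""

import numpy as np

from trpkin import delta_rmsf, rmsf
from trpkin.synthetic import TrajectorySpec, gen_trajectory

loop = tuple(range(36, 48))
flexible, truth = gen_trajectory(
    TrajectorySpec(n_residues=128, n_frames=600, loop_residues=loop,
                   loop_amp_A=1.5, seed=1)
)
rigid, _ = gen_trajectory(TrajectorySpec(n_residues=128, n_frames=600, seed=2))

prof_a = rmsf(flexible)
prof_b = rmsf(rigid)
diff = delta_rmsf(prof_a, prof_b)

in_loop = np.isin(diff.residue_ids, loop)
print(f"mean RMSF, flexible system: {prof_a.rmsf_A.mean():.2f} A")
print(f"mean dRMSF inside the loop:  {diff.rmsf_A[in_loop].mean():+.2f} A")
print(f"mean dRMSF outside the loop: {diff.rmsf_A[~in_loop].mean():+.2f} A")

print(
    "\nThe signed difference isolates the extra loop mobility (~+1 A) while\n"
    "the rest of the chain cancels to ~0, the same analysis used to compare\n"
    "apo- and metal-loaded protein dynamics."
)
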