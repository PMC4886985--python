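"""Superpose a displaced bead model back onto its reference.

Builds a chiral four-lobe bead envelope, displaces it by a random rigid
transform (rotation uniform over SO(3), shift up to 30 Å), and recovers the
original pose by maximizing the reciprocal-space correlation (NCC).
"""

import numpy as np

from harmalign import (ShapeSpec, apply_transform, generate_beads,
                       random_transform, superpose)

reference = generate_beads(ShapeSpec(kind="multilobe", size=(12.0,),
                                     spacing=5.0))
moved = apply_transform(reference, random_transform(seed=7, max_shift=30.0))

result = superpose(reference, moved)
recovered = apply_transform(moved, result.transform)
rmsd = np.sqrt(((recovered.coords - reference.coords) ** 2)
               .sum(axis=1).mean())

print(f"beads: {reference.n_points}, D_max: {result.d_max[0]:.1f} A")
print(f"NCC  = {result.ncc:.6f}   (1 = ideal overlap)")
print(f"NSD  = {result.nsd:.4f}    (~0 identical, <~1 good similarity)")
print(f"RMSD = {rmsd:.4f} A  between recovered and original coordinates")
print(f"winning start: {result.start_index}, mirror: "
      f"{result.transform.mirror}")
# NCC ~ 1 and sub-Angstrom RMSD mean the arbitrary displacement was fully
# undone by the inertia-axes starts plus 1/NCC refinement.
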