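"""Mirror images: why enantiomorph starts matter.

Small-angle scattering cannot distinguish a shape from its mirror image, so
the superposition sweep optionally includes mirrored starting poses.  A
chiral fixture (five points, all pairwise distances distinct) shows the
effect: its mirror image can only be matched when mirror starts are on.
"""

from harmalign import (MIRROR_OPERATOR, ShapeSpec, apply_transform,
                       generate_beads, random_transform, superpose)

tetra = generate_beads(ShapeSpec(kind="chiral-tetra", size=(10.0,)))
mirrored = tetra.replace_coords(tetra.coords @ MIRROR_OPERATOR.T)
moved = apply_transform(mirrored, random_transform(seed=11, max_shift=20.0))

with_mirror = superpose(tetra, moved, enantiomorphs=True)
without = superpose(tetra, moved, enantiomorphs=False)

print(f"enantiomorphs on : NCC = {with_mirror.ncc:.6f}, "
      f"mirror flag = {with_mirror.transform.mirror}")
print(f"enantiomorphs off: NCC = {without.ncc:.6f}")
# With mirror starts the chiral model is matched exactly (NCC ~ 1, mirror
# flag set); without them the best achievable overlap is clearly worse.
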