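# Methods

## Model representation

Every supported input is normalized to a weighted point set: the scattering
density ρ(r) is carried as points r_j with weights w_j.  Atomic PDB input
weights each atom by its element's integer electron count (H, C, N, O, P, S
table, periodic-table fallback); weights are treated as independent of
momentum transfer.  This deliberately omits s-dependent atomic form
factors, excluded-volume and hydration-shell corrections: the method
operates at resolutions (truncation order L = 5, s ≤ 7π/D_max) far below
where those details matter, and the NCC objective is normalization
invariant.  Bead (dummy-atom) models get unit weights; multi-phase bead
models are re-weighted by a user-supplied relative scattering density per
phase.  The phase of a bead is taken from the chain identifier of its PDB
record (first chain seen → phase 1, and so on) — a package convention, as
no standard encoding exists.  Density maps contribute one point per voxel
above a threshold, at the voxel center, weighted by the raw voxel density;
cubic voxels only.  When no threshold is given, the pipeline picks the
value enclosing 99% of the total positive density.

## Amplitudes and intensities

Partial amplitudes of a point model are

    A_lm(s) = √(2/π) Σ_j w_j j_l(s r_j) Y*_lm(θ_j, φ_j),

with complex orthonormal spherical harmonics (Condon–Shortley phase) and
spherical Bessel functions j_l.  The orientationally averaged intensity and
the cross-term of two models in a common frame are

    I(s) = 2π² Σ_lm |A_lm(s)|²,
    I_AB(s) = 2π² Σ_lm Re[A_lm(s) B*_lm(s)].

The prefactor pair is pinned by the forward-scattering identity
I(0) = (Σ_j w_j)², which a unit test asserts; the Debye formula
I(s) = Σ_jk w_j w_k sinc(s·r_jk) serves as the independent oracle for the
full curve.  A per-order phase i^l, present in some amplitude conventions,
is omitted from the stored coefficients: every quantity computed from them
(self- and cross-intensities, hence NCC) is invariant to it, and without it
a real density obeys the clean symmetry A_{l,−m} = (−1)^m A*_{l,m}, which
is enforced as an invariant.

Spherical Bessel values dominate the cost of every objective evaluation and
are computed by vectorized range-split recursions (ascending series below
x = 1, upward recursion above, Miller's downward recursion in the
transition region for L > 5), matching `scipy.special.spherical_jn` to
better than 1e-8 relative everywhere tested.

Rotations of an amplitude set are applied coefficient-side with Wigner
finite-rotation matrices D^l (z-y-z Euler factorization, explicit small-d
sum with exact factorials — stable for the L ≤ 15 supported here).  The
index and sign conventions are validated against recomputation from rotated
coordinates, not against a second analytic formula.  Translations (and
mirrors) recompute the amplitudes from transformed coordinates instead of
using the translation addition theorem: at L = 5 with desk-scale models a
full recomputation costs milliseconds, which keeps the code simple at the
price of giving up the constant-cost-per-pose property for the moved model.
The fixed model's amplitudes are computed exactly once.

## The NCC objective

    NCC = ∫₀^{s_m} I_AB ds / [∫₀^{s_m} I_A ds · ∫₀^{s_m} I_B ds]^{1/2}

integrated by the trapezoidal rule on a shared grid of s = 0 plus 10·L
uniform points up to s_m (≥ 2 points per Shannon channel at defaults; the
quadrature error is far below the 1% accuracy budget of the truncated
expansion).  The geometric-mean normalization is the unique symmetric
choice that yields exactly 1 for identical amplitude sets at any truncation
and is bounded by 1 via Cauchy–Schwarz.  s_m defaults to N_sh·π/D_max with
N_sh = 7, using the larger D_max of the two models (the conservative
resolution choice).  NCC values ≥ 0.7 indicate good similarity at the
default resolution; this threshold is advisory and never gates anything.

## Superposition algorithm

1. Both models are reduced to points; D_max values (exact maximum pairwise
   distance; convex-hull accelerated above 2000 points) fix s_m.
2. The pipeline shifts to a template-centered frame, so the multipole
   expansions are taken about the template's center of mass and truncation
   error stays minimal.
3. Principal axes come from the covariance (gyration) tensor
   Σ w (r−c)(r−c)ᵀ/Σ w, eigen-sorted ASCENDING, so the X axis carries the
   smallest second moment (an elongated particle's long axis lands on Z).
   The physical inertia tensor has the same eigenvectors, so the alignment
   is unaffected by using the covariance form.  If the eigenvector matrix
   is improper its last column is negated; the sign sweep covers the
   alternative.  Near-degenerate eigenvalues (symmetric particles) warn but
   do not fail — the sign sweep plus refinement absorb the ambiguity.
4. Starting poses map the matched model into the template's axis frame
   through each of the 4 proper axis sign flips diag(±1,±1,±1), det +1;
   with enantiomorphs enabled (the default — scattering cannot distinguish
   a shape from its mirror) each flip is also tried with the mirror
   operator P = diag(1,1,−1) applied to the matched model, for 8 starts.
   The mirror is carried as an explicit flag; rotation matrices are always
   proper.  Mirror convention is observationally arbitrary: any single-axis
   flip differs from P by a proper flip already in the sweep.
5. Every start is refined fully (no early pruning — cheap at L = 5) over 6
   parameters: incremental z-y-z Euler deltas composed onto the start
   rotation, pivoting at the template's center of mass, plus a translation
   delta.  The derivative-free Nelder–Mead simplex minimizes 1/NCC with an
   explicit initial simplex (0.15 rad / 2 Å — the basin scale of the
   inertia pre-alignment), terminating at 1e-8 objective change, 1e-6
   parameter spread, or 500 evaluations.  The best final NCC wins; ties
   within 1e-9 go to the lowest start index, so results are fully
   deterministic — there is no randomness anywhere in the pipeline.
6. The winning transform is conjugated back to the original input frame and
   reported together with NCC, the NSD of the superposed point sets, the
   winning start, and convergence diagnostics.

## Real-space metrics

NSD accumulates, for each point of either model, the squared distance to
the nearest point of the other model (exact KD-tree search — NSD values
are a published comparison surface, so no approximate neighbours), each
side normalized by that model's mean nearest-neighbour spacing; ~0 means
identical, values around 1 still indicate good similarity.  NOV voxelizes
both models on a shared cubic grid (a voxel is occupied by ≥ 1 point) and
reports |A∩B|/√(|A|·|B|); the geometric-mean normalization mirrors the NCC
choice (a min-count normalization would be the natural alternative).  The
library default voxel is D_max/32; the CLI additionally floors the voxel at
twice the models' mean point spacing, since voxelizing a discrete point set
finer than its own spacing deflates the overlap spuriously.  Both are
reporting metrics only; NOV in particular is too insensitive to fine detail
to drive optimization.

## Synthetic fixtures

The generator produces parametric shapes as beads on a cubic lattice
(deterministic, with exact brute-force count oracles), binary density maps
sampled at voxel centers on the same lattice convention, two-phase
core/shell models, and seeded random rigid transforms (rotation uniform
over SO(3) via normalized quaternions, translation uniform in a cube).
Two shapes exist specifically because the enantiomorph code path is
untestable on achiral fixtures: a five-point "chiral-tetra" with all
pairwise distances distinct, and a four-lobe "multilobe" envelope (distinct
radii, non-coplanar centers) that is chiral and fully asymmetric — the
pose-recovery workhorse, since for axially or mirror-symmetric shapes
coordinate-level recovery is ill-posed under the mirror sweep.  The
"L-shape" is a 3D corner piece with three unequal arms; a flat planar L
would be achiral in 3D.  The fixtures emulate the geometry of ab initio
envelopes but not experimental artifacts (noise, missing density,
resolution anisotropy); passing tests demonstrate correctness of the
method's mathematics and pose recovery under its own assumptions, not
robustness to experimental map pathology.

## Problem sizes and numerical choices

Standard test conditions: bead envelopes of ~100–500 beads with D_max
60–100 Å, displaced by uniform random rotations and shifts up to 50 Å, and
superposed back at L = 5, N_sh = 7 — recovery RMSD is then well below the
~1 Å scale expected at this resolution.  The acceptance script runs 50 such
trials and the identity check on a ~200-bead ellipsoid.  Degenerate inputs:
a point exactly at the origin contributes only to (l,m) = (0,0) since
j_l(0) = δ_l0; single-point models have D_max = 0 and no defined NSD
(reported as NaN); an all-negative map has no auto-threshold and errors.

## Known limitations

No mmCIF; no CRYSOL-grade form factors (hence computed intensities are not
fit-quality SAXS curves — they exist to be compared with each other); no
exhaustive 6D search, so the method refines locally from inertia starts and
is not a substitute for FFT-based EM docking; no flexible or
symmetry-constrained alignment; orders above L ≈ 15 are unsupported (no
high-order-stable recursions); maps with anisotropic voxels are rejected.
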