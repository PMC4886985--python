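"""Deterministic synthetic fixtures: parametric shapes, bead envelopes,
density maps, multi-phase models and seeded random rigid transforms.

Every generator is a pure function of its arguments (lattice placement, not
random sprinkling), so bead counts have exact brute-force oracles and tests
need no external data.  Shapes:

* ``ellipsoid`` — triaxial ellipsoid, semi-axes (a, b, c);
* ``dumbbell`` — two spheres of radii (r1, r2) separated along z;
* ``lshape`` — 3D corner piece: three axis-aligned arms of distinct lengths
  meeting at one corner (chiral when the lengths differ);
* ``helix`` — tube around a helical curve (radius, pitch, turns, tube radius);
* ``multilobe`` — four spheres of distinct radii at non-coplanar centers;
  chiral and fully asymmetric, the workhorse pose-recovery fixture;
* ``chiral-tetra`` — five explicit points with distinct pairwise distances
  and nonzero chirality (ignores the lattice), for enantiomorph tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import RigidTransform
from .models import DensityMap, PhaseDensityTable, PointModel

__all__ = ["ShapeSpec", "generate_beads", "generate_map",
           "generate_two_phase", "random_transform"]

_KINDS = ("ellipsoid", "dumbbell", "lshape", "helix", "multilobe",
          "chiral-tetra")


@dataclass
class ShapeSpec:
    """Parametric shape description.

    ``size`` semantics per kind: ellipsoid (a, b, c) semi-axes; dumbbell
    (r1, r2, separation); lshape (arm1, arm2, arm3, width); helix (radius,
    pitch, turns, tube_radius); multilobe (scale,); chiral-tetra (scale,).
    All lengths in Å.
    """

    kind: str = "ellipsoid"
    size: tuple = (20.0, 15.0, 10.0)
    spacing: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown shape kind {self.kind!r}; "
                             f"choose from {_KINDS}")
        if not self.spacing > 0:
            raise ValueError("spacing must be positive")
        if any(s <= 0 for s in np.atleast_1d(self.size)):
            raise ValueError("all size parameters must be positive")


def _multilobe_centers(scale: float) -> tuple[np.ndarray, np.ndarray]:
    """Four sphere centers (non-coplanar) and radii, distinct by design."""
    centers = scale * np.array([
        [0.0, 0.0, 0.0],
        [1.6, 0.2, 0.1],
        [0.3, 1.4, 0.2],
        [0.5, 0.6, 1.3],
    ])
    radii = scale * np.array([1.0, 0.75, 0.6, 0.5])
    return centers, radii


def _chiral_tetra_points(scale: float) -> np.ndarray:
    # five points, all pairwise distances distinct, nonzero chirality
    return scale * np.array([
        [0.0, 0.0, 0.0],
        [1.0, 0.0, 0.0],
        [0.2, 1.3, 0.0],
        [0.4, 0.5, 1.7],
        [1.1, 1.0, 0.6],
    ])


def _inside(spec: ShapeSpec, pts: np.ndarray) -> np.ndarray:
    """Boolean mask: which points fall inside the analytic shape."""
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    if spec.kind == "ellipsoid":
        a, b, c = spec.size[:3]
        return (x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2 <= 1.0
    if spec.kind == "dumbbell":
        r1, r2, sep = spec.size[:3]
        d1 = x ** 2 + y ** 2 + (z + sep / 2) ** 2
        d2 = x ** 2 + y ** 2 + (z - sep / 2) ** 2
        return (d1 <= r1 ** 2) | (d2 <= r2 ** 2)
    if spec.kind == "lshape":
        a1, a2, a3, w = spec.size[:4]
        in1 = (0 <= x) & (x <= a1) & (np.abs(y) <= w / 2) \
            & (np.abs(z) <= w / 2)
        in2 = (np.abs(x) <= w / 2) & (0 <= y) & (y <= a2) \
            & (np.abs(z) <= w / 2)
        in3 = (np.abs(x) <= w / 2) & (np.abs(y) <= w / 2) \
            & (0 <= z) & (z <= a3)
        return in1 | in2 | in3
    if spec.kind == "helix":
        radius, pitch, turns, tube = spec.size[:4]
        t = np.linspace(0, 2 * np.pi * turns, max(int(40 * turns), 40))
        curve = np.column_stack([radius * np.cos(t), radius * np.sin(t),
                                 pitch * t / (2 * np.pi)])
        curve -= curve.mean(axis=0)
        d2 = ((pts[:, None, :] - curve[None, :, :]) ** 2).sum(axis=2)
        return d2.min(axis=1) <= tube ** 2
    if spec.kind == "multilobe":
        centers, radii = _multilobe_centers(spec.size[0])
        d2 = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        return (d2 <= radii[None, :] ** 2).any(axis=1)
    raise ValueError(f"{spec.kind} has no lattice representation")


def _bounding_radius(spec: ShapeSpec) -> float:
    if spec.kind == "ellipsoid":
        return max(spec.size[:3])
    if spec.kind == "dumbbell":
        r1, r2, sep = spec.size[:3]
        return sep / 2 + max(r1, r2)
    if spec.kind == "lshape":
        return max(spec.size[:3]) + spec.size[3]
    if spec.kind == "helix":
        radius, pitch, turns, tube = spec.size[:4]
        return max(radius + tube, pitch * turns / 2 + tube)
    if spec.kind == "multilobe":
        centers, radii = _multilobe_centers(spec.size[0])
        return float(np.linalg.norm(centers, axis=1).max() + radii.max())
    return 2.0 * spec.size[0]


def _lattice(spec: ShapeSpec) -> np.ndarray:
    r = _bounding_radius(spec)
    n = int(np.ceil(r / spec.spacing))
    axis = spec.spacing * np.arange(-n, n + 1)
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])


def generate_beads(spec: ShapeSpec) -> PointModel:
    """Unit-weight beads on a cubic lattice inside the analytic shape."""
    if spec.kind == "chiral-tetra":
        return PointModel(_chiral_tetra_points(spec.size[0]),
                          np.ones(5), label="chiral-tetra")
    pts = _lattice(spec)
    mask = _inside(spec, pts)
    if not mask.any():
        raise ValueError(
            f"shape too small to contain any lattice point at spacing "
            f"{spec.spacing}")
    coords = pts[mask]
    return PointModel(coords, np.ones(len(coords)),
                      label=f"{spec.kind} beads")


def generate_map(spec: ShapeSpec, voxel: float) -> DensityMap:
    """Binary density map of the shape: 1 inside, 0 outside, at voxel centers."""
    if not voxel > 0:
        raise ValueError("voxel must be positive")
    if spec.kind == "chiral-tetra":
        raise ValueError("chiral-tetra is a point fixture, not a volume")
    r = _bounding_radius(spec) + voxel
    # odd voxel count with the grid centered on the origin puts voxel
    # centers on integer multiples of the voxel size, i.e. on the same
    # lattice generate_beads uses when voxel == spacing
    n = 2 * int(np.ceil(r / voxel)) + 1
    origin = np.full(3, -n * voxel / 2.0)
    axis = origin[0] + (np.arange(n) + 0.5) * voxel
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    grid = _inside(spec, pts).astype(float).reshape(n, n, n)
    return DensityMap(grid=grid, voxel_size=voxel, origin=origin)


def generate_two_phase(spec_core: ShapeSpec, spec_shell: ShapeSpec,
                       densities: dict | None = None):
    """Two-phase bead model: phase 1 = core, phase 2 = shell minus core.

    Emulates multi-phase bead models of inhomogeneous particles (e.g. the
    protein and RNA moieties of a ribonucleoprotein).  Returns the labelled
    model and a :class:`PhaseDensityTable` (default {1: 1.0, 2: 2.0}).
    """
    core = generate_beads(spec_core)
    shell_all = generate_beads(spec_shell)
    in_core = _inside(spec_core, shell_all.coords)
    shell_coords = shell_all.coords[~in_core]
    if len(shell_coords) == 0:
        raise ValueError("shell phase is empty (core covers the shell)")
    coords = np.vstack([core.coords, shell_coords])
    labels = np.concatenate([np.ones(core.n_points, dtype=int),
                             np.full(len(shell_coords), 2, dtype=int)])
    model = PointModel(coords, np.ones(len(coords)), phase_labels=labels,
                       label="two-phase model")
    table = PhaseDensityTable(densities or {1: 1.0, 2: 2.0})
    return model, table


def random_transform(seed: int, max_shift: float = 50.0) -> RigidTransform:
    """Seeded random rigid transform: uniform SO(3) rotation (quaternion
    method) and translation uniform in the cube [-max_shift, max_shift]^3."""
    if max_shift < 0:
        raise ValueError("max_shift must be non-negative")
    rng = np.random.default_rng(seed)
    quat = rng.normal(size=4)
    quat /= np.linalg.norm(quat)
    w, x, y, z = quat
    rotation = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])
    translation = rng.uniform(-max_shift, max_shift, size=3)
    return RigidTransform(rotation=rotation, translation=translation)
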