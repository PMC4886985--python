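"""Rigid-body machinery: mass centers, inertia axes, canonical poses,
sign-combination starts, transforms and maximum diameter.

Conventions
-----------
The "inertia tensor" used throughout is the covariance (gyration) form
``sum_j w_j (r_j - c)(r_j - c)^T / sum_j w_j`` whose eigenvectors coincide
with those of the physical inertia tensor.  Principal axes are taken in
ASCENDING order of these second central moments, so after
:func:`canonical_pose` the X axis carries the smallest second moment (the
long axis of an elongated particle therefore ends up on Z, not X).

Mirroring (enantiomorph generation) is carried by an explicit flag on
:class:`RigidTransform` and realized as the fixed operator P = diag(1,1,-1)
applied before the rotation; the rotation matrix itself is always proper.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist

from .models import PointModel

__all__ = [
    "RigidTransform",
    "MIRROR_OPERATOR",
    "center_of_mass",
    "inertia_tensor",
    "canonical_pose",
    "sign_combinations",
    "apply_transform",
    "max_diameter",
]

MIRROR_OPERATOR = np.diag([1.0, 1.0, -1.0])


@dataclass
class RigidTransform:
    """Proper rotation + translation, with an optional mirror flag.

    Application order: mirror (if set), then rotation, then translation:
    ``x' = R (P x) + t``.  The rotation is always proper (det = +1); an
    improper overall operation is expressed through the mirror flag.
    """

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    mirror: bool = False

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(
            self.translation, dtype=float).reshape(3)
        err = np.abs(self.rotation.T @ self.rotation - np.eye(3)).max()
        if err > 1e-8:
            raise ValueError(f"rotation not orthogonal (error {err:.2e})")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError(
                "improper rotation; use the mirror flag for enantiomorphs")

    @property
    def effective_matrix(self) -> np.ndarray:
        """The full linear part, mirror included (may have det -1)."""
        return self.rotation @ MIRROR_OPERATOR if self.mirror \
            else self.rotation

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.effective_matrix.T + self.translation

    def compose(self, first: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``first`` then ``self``.

        At most one of the two may carry a mirror flag (a double mirror is a
        proper rotation but never arises in the alignment pipeline).
        """
        if self.mirror and first.mirror:
            raise ValueError("composition of two mirrored transforms")
        m_self, m_first = self.effective_matrix, first.effective_matrix
        linear = m_self @ m_first
        mirror = self.mirror or first.mirror
        rotation = linear @ MIRROR_OPERATOR if mirror else linear
        return RigidTransform(
            rotation=rotation,
            translation=m_self @ first.translation + self.translation,
            mirror=mirror,
        )

    def inverse(self) -> "RigidTransform":
        m = self.effective_matrix
        inv_linear = m.T
        rotation = inv_linear @ MIRROR_OPERATOR if self.mirror else inv_linear
        return RigidTransform(
            rotation=rotation,
            translation=-(inv_linear @ self.translation),
            mirror=self.mirror,
        )


def center_of_mass(model: PointModel) -> np.ndarray:
    """Weight-averaged coordinate of the model, Å."""
    total = model.total_weight
    if total <= 0:
        raise ValueError("total weight must be positive")
    return model.weights @ model.coords / total


def inertia_tensor(model: PointModel) -> np.ndarray:
    """Second-central-moment (covariance) tensor about the center of mass."""
    c = center_of_mass(model)
    d = model.coords - c
    t = (model.weights[:, None] * d).T @ d / model.total_weight
    return 0.5 * (t + t.T)  # enforce exact symmetry


def canonical_pose(model: PointModel,
                   degeneracy_rtol: float = 1e-9) -> RigidTransform:
    """Transform that origin-centers the model and aligns its principal axes
    (ascending second-moment order) with X, Y, Z.

    Nearly degenerate eigenvalues (symmetric particles) produce a warning,
    not an error: the sign-combination sweep plus local refinement absorb
    the resulting axis ambiguity.
    """
    tensor = inertia_tensor(model)
    evals, evecs = np.linalg.eigh(tensor)  # ascending
    gaps = np.diff(evals)
    scale = max(evals[-1], np.finfo(float).tiny)
    if np.any(gaps < degeneracy_rtol * scale):
        warnings.warn(
            "near-degenerate inertia eigenvalues: principal axes are "
            "underdetermined; relying on sign-combination starts",
            stacklevel=2,
        )
    if np.linalg.det(evecs) < 0:
        evecs = evecs.copy()
        evecs[:, -1] *= -1  # proper-rotation repair
    c = center_of_mass(model)
    return RigidTransform(rotation=evecs.T, translation=-(evecs.T @ c))


def sign_combinations(enantiomorphs: bool) -> list[RigidTransform]:
    """Axis sign-flip starting transforms for the superposition sweep.

    Returns the 4 proper diagonal sign flips diag(±1, ±1, ±1) with det +1;
    with ``enantiomorphs`` each one is duplicated with the mirror flag set,
    for 8 starts total.
    """
    flips = [np.diag(s) for s in product((1.0, -1.0), repeat=3)
             if np.prod(s) > 0]
    flips.sort(key=lambda f: -np.trace(f))  # identity first, deterministic
    starts = [RigidTransform(rotation=f) for f in flips]
    if enantiomorphs:
        starts += [RigidTransform(rotation=f, mirror=True) for f in flips]
    return starts


def apply_transform(model: PointModel, t: RigidTransform) -> PointModel:
    """Apply a rigid transform to the coordinates; weights/phases unchanged."""
    return model.replace_coords(t.apply(model.coords))


def max_diameter(model: PointModel) -> float:
    """Maximum pairwise distance D_max in Å (0 for a single point).

    Exact: small models by direct O(N^2) scan, larger ones via the convex
    hull (the diameter is attained between hull vertices).
    """
    pts = model.coords
    if len(pts) < 2:
        return 0.0
    if len(pts) > 2000:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except Exception:
            pass  # degenerate (flat/collinear) clouds: fall through to exact
    return float(pdist(pts).max())
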