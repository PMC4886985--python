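"""Rigid-body superposition by NCC maximization in reciprocal space.

Algorithm (template model A is held fixed, matched model B is moved):

(i)   centers of mass and inertia-axis frames are computed for both models;
(ii)  B is brought into A's canonical frame for each of the 4 proper
      axis sign combinations (8 when enantiomorphs are allowed: each flip
      with and without a mirror applied to B);
(iii) the multipole scattering amplitudes of A are computed once; B's are
      evaluated for each trial pose;
(iv)  from every start, the 6 pose parameters (3 rotations, 3 translations)
      are refined by derivative-free local minimization of 1/NCC, and the
      pose with the highest final NCC wins.

Defaults: truncation order L = 5 and integration range s_m = 7 pi / D_max
(seven Shannon channels of the larger model) — sufficient for reliable
positioning while keeping every NCC evaluation cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .geometry import (MIRROR_OPERATOR, RigidTransform, apply_transform,
                       canonical_pose, center_of_mass, max_diameter,
                       sign_combinations)
from .harmonics import (PartialAmplitudeSet, default_s_grid,
                        partial_amplitudes, shannon_smax)
from .models import DensityMap, PointModel
from .models_io import map_to_points
from .proximity import ncc, nsd

__all__ = ["AlignmentResult", "superpose", "refine_pose", "align_ensemble",
           "auto_threshold"]

#: Starts whose final NCC is within this of the best are resolved by index.
_TIE_TOLERANCE = 1e-9


@dataclass
class AlignmentResult:
    """Outcome of one superposition (transform applies to the matched model).

    Attributes
    ----------
    transform : RigidTransform
        Maps matched-model coordinates onto the template frame.
    ncc : float
        Final normalized correlation coefficient.
    nsd : float
        Normalized spatial discrepancy of the superposed point models
        (NaN when either model has fewer than two points).
    start_index : int
        Which sign-combination start produced the winning pose.
    n_evaluations : int
        Total objective evaluations across all starts.
    converged : bool
        True if the winning start's minimizer reported convergence.
    d_max : tuple
        (D_max of template, D_max of matched) in Å.
    s_max : float
        Integration cutoff actually used, Å^-1.
    L : int
        Truncation order used.
    """

    transform: RigidTransform
    ncc: float
    nsd: float
    start_index: int
    n_evaluations: int
    converged: bool
    d_max: tuple = (0.0, 0.0)
    s_max: float = 0.0
    L: int = 5


def auto_threshold(dmap: DensityMap, fraction: float = 0.99) -> float:
    """Density threshold enclosing ``fraction`` of the total positive density."""
    positive = np.sort(dmap.grid[dmap.grid > 0].ravel())[::-1]
    if positive.size == 0:
        raise ValueError("map has no positive density")
    cum = np.cumsum(positive)
    k = int(np.searchsorted(cum, fraction * cum[-1]))
    k = min(k, positive.size - 1)
    return float(positive[k]) * (1.0 - 1e-9)


def _as_points(obj, threshold: float | None) -> PointModel:
    if isinstance(obj, DensityMap):
        thr = auto_threshold(obj) if threshold is None else threshold
        return map_to_points(obj, thr)
    if isinstance(obj, PointModel):
        return obj
    raise TypeError(f"expected PointModel or DensityMap, got {type(obj)!r}")


def _objective_factory(amps_a: PartialAmplitudeSet, model_b: PointModel,
                       start: RigidTransform):
    """Build the 6-parameter 1/NCC objective around a start transform.

    Parameters are incremental z-y-z Euler deltas (rad) composed onto the
    start rotation, pivoting at the work-frame origin (the template's center
    of mass), plus a translation delta (Å).
    """
    L, s_grid = amps_a.L, amps_a.s_grid
    counter = {"n": 0}

    def transform_at(p: np.ndarray) -> RigidTransform:
        r_delta = Rotation.from_euler("zyz", p[:3]).as_matrix()
        return RigidTransform(
            rotation=r_delta @ start.rotation,
            translation=r_delta @ start.translation + p[3:],
            mirror=start.mirror,
        )

    def objective(p: np.ndarray) -> float:
        counter["n"] += 1
        t = transform_at(p)
        amps_b = partial_amplitudes(apply_transform(model_b, t), L, s_grid)
        value = ncc(amps_a, amps_b)
        if value <= 1e-8:
            return 1e8 * (1.0 - value)  # repel from the degenerate region
        return 1.0 / value

    return objective, transform_at, counter


def refine_pose(amps_a: PartialAmplitudeSet, model_b: PointModel,
                start: RigidTransform, max_evaluations: int = 500):
    """Local 6-DOF refinement of 1/NCC from a starting transform.

    Returns ``(transform, ncc_value, diagnostics)`` where diagnostics is a
    dict with the evaluation count and convergence flag.  Termination: the
    simplex collapses below 1e-6 (rad / Å) in parameters or 1e-8 in the
    objective, or the evaluation budget is exhausted.
    """
    objective, transform_at, counter = _objective_factory(
        amps_a, model_b, start)
    p0 = np.zeros(6)
    f0 = objective(p0)
    if not np.isfinite(f0):
        raise ValueError("non-finite objective at the starting pose")
    # explicit initial simplex: NM's default one around the origin is too
    # small to escape the start; 0.15 rad / 2 A reflects the basin size of
    # the inertia-axes pre-alignment
    steps = np.array([0.15, 0.15, 0.15, 2.0, 2.0, 2.0])
    simplex = np.vstack([p0, p0 + np.diag(steps)])
    res = minimize(
        objective, p0, method="Nelder-Mead",
        options={
            "initial_simplex": simplex,
            "xatol": 1e-6, "fatol": 1e-8,
            "maxfev": max_evaluations, "disp": False,
        },
    )
    best_p = res.x if res.fun <= f0 else p0
    best_f = min(res.fun, f0)
    transform = transform_at(best_p)
    value = 1.0 / best_f if best_f > 0 else np.nan
    diagnostics = {"n_evaluations": counter["n"],
                   "converged": bool(res.success)}
    return transform, float(value), diagnostics


def _start_transforms(model_a: PointModel, model_b: PointModel,
                      enantiomorphs: bool) -> list[RigidTransform]:
    """Inertia-axes pre-alignment starts: B -> A frame, per sign combination."""
    pose_a = canonical_pose(model_a)
    v_a = pose_a.rotation.T  # columns: A's principal axes, proper
    c_a = center_of_mass(model_a)
    starts = []
    for flip in sign_combinations(enantiomorphs):
        if flip.mirror:
            mirrored = model_b.replace_coords(model_b.coords
                                              @ MIRROR_OPERATOR.T)
            pose_b = canonical_pose(mirrored)
            c_b_eff = MIRROR_OPERATOR @ center_of_mass(model_b)
        else:
            pose_b = canonical_pose(model_b)
            c_b_eff = center_of_mass(model_b)
        v_b = pose_b.rotation.T
        rotation = v_a @ flip.rotation @ v_b.T
        starts.append(RigidTransform(
            rotation=rotation,
            translation=c_a - rotation @ c_b_eff,
            mirror=flip.mirror,
        ))
    return starts


def superpose(model_a, model_b, L: int = 5, n_sh: int = 7,
              enantiomorphs: bool = True, s_max: float | None = None,
              threshold_a: float | None = None,
              threshold_b: float | None = None,
              max_evaluations: int = 500) -> AlignmentResult:
    """Superpose ``model_b`` onto the fixed template ``model_a``.

    Parameters
    ----------
    model_a, model_b : PointModel or DensityMap
        Template (held fixed) and matched model.  Maps are converted to
        weighted point models via a density threshold (auto-chosen to
        enclose 99% of the positive density when not given).
    L : int
        Spherical-harmonics truncation order (default 5).
    n_sh : int
        Number of Shannon channels; sets s_m = n_sh * pi / max(D_max).
    enantiomorphs : bool
        Also try mirror-image starts (SAS data cannot distinguish a shape
        from its mirror).
    s_max : float, optional
        Explicit integration cutoff in Å^-1, overriding ``n_sh``.
    max_evaluations : int
        Objective-evaluation budget per start.

    Returns
    -------
    AlignmentResult
        Winning transform (in the original input frame), final NCC, the NSD
        of the superposed models, and diagnostics.  Deterministic: identical
        inputs always give identical results.
    """
    a = _as_points(model_a, threshold_a)
    b = _as_points(model_b, threshold_b)
    d_max_a, d_max_b = max_diameter(a), max_diameter(b)
    if s_max is None:
        s_max = shannon_smax(max(d_max_a, d_max_b, 1e-6), n_sh)
    s_grid = default_s_grid(s_max, L)

    # work in a template-centered frame so truncation error is minimal
    c_a = center_of_mass(a)
    a_w = a.replace_coords(a.coords - c_a)
    b_w = b.replace_coords(b.coords - c_a)

    amps_a = partial_amplitudes(a_w, L, s_grid)
    starts = _start_transforms(a_w, b_w, enantiomorphs)

    best = None
    total_evals = 0
    failures = []
    for index, start in enumerate(starts):
        try:
            transform, value, diag = refine_pose(
                amps_a, b_w, start, max_evaluations=max_evaluations)
        except (ValueError, FloatingPointError) as exc:
            failures.append((index, exc))
            continue
        total_evals += diag["n_evaluations"]
        if best is None or value > best[1] + _TIE_TOLERANCE:
            best = (index, value, transform, diag)
    if best is None:
        raise RuntimeError(
            f"all {len(starts)} refinement starts failed: {failures}")
    index, value, transform_w, diag = best

    # conjugate the work-frame transform back to the original frame:
    # x' = Rw (P (x - c_a)) + tw + c_a
    p_eff = MIRROR_OPERATOR if transform_w.mirror else np.eye(3)
    rotation = transform_w.rotation
    translation = (transform_w.translation + c_a
                   - rotation @ (p_eff @ c_a))
    transform = RigidTransform(rotation=rotation, translation=translation,
                               mirror=transform_w.mirror)

    b_aligned = apply_transform(b, transform)
    nsd_value = np.nan
    if a.n_points >= 2 and b.n_points >= 2:
        nsd_value = nsd(a, b_aligned)
    return AlignmentResult(
        transform=transform, ncc=value, nsd=nsd_value,
        start_index=index, n_evaluations=total_evals,
        converged=diag["converged"],
        d_max=(d_max_a, d_max_b), s_max=float(s_max), L=L,
    )


def align_ensemble(reference: PointModel, others: list[PointModel],
                   **options) -> list:
    """Superpose each model of ``others`` independently onto ``reference``.

    Returns a list parallel to ``others``; an entry is the raised exception
    object if that particular model failed, leaving the rest unaffected.
    """
    results = []
    for model in others:
        try:
            results.append(superpose(reference, model, **options))
        except (ValueError, RuntimeError, TypeError) as exc:
            results.append(exc)
    return results
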