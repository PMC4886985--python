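"""Proximity measures between 3D models.

Three measures are provided:

* **NCC** — normalized correlation coefficient in reciprocal space, built
  from the integrated cross-term of two multipole amplitude sets.  This is
  the quantity the superposition pipeline maximizes; 1 means ideal overlap.
* **NSD** — normalized spatial discrepancy, the classic real-space point-set
  measure (mutual nearest-neighbour distances normalized by each model's
  internal nearest-neighbour spacing); ~0 identical, values around 1 still
  indicate good similarity.
* **NOV** — normalized overlapped volume of the two models voxelized on a
  shared cubic grid; a fast, coarse overlap fraction in [0, 1].

NSD and NOV are validation/reporting metrics only; neither is used as an
optimization objective here.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .harmonics import PartialAmplitudeSet, cross_intensity, intensity
from .models import PointModel

__all__ = ["ncc", "nsd", "nov", "similarity_verdict",
           "NCC_GOOD_THRESHOLD", "NSD_GOOD_THRESHOLD"]

#: Rule-of-thumb lower limit for a good overlap at the default resolution.
NCC_GOOD_THRESHOLD = 0.7
#: Rule-of-thumb upper limit of NSD for good similarity.
NSD_GOOD_THRESHOLD = 1.0


def ncc(a: PartialAmplitudeSet, b: PartialAmplitudeSet) -> float:
    """Normalized correlation coefficient of two amplitude sets.

    NCC = int I_AB ds / sqrt(int I_A ds * int I_B ds), integrated by the
    trapezoidal rule over the common s-grid (s = 0 included).  The geometric
    -mean normalization makes NCC exactly 1 for identical amplitude sets at
    any truncation, and |NCC| <= 1 by the Cauchy-Schwarz inequality.
    """
    if not a.compatible_with(b):
        raise ValueError("amplitude sets have different L or s-grid")
    s = a.s_grid
    int_ab = np.trapezoid(cross_intensity(a, b).values, s)
    int_a = np.trapezoid(intensity(a).values, s)
    int_b = np.trapezoid(intensity(b).values, s)
    if int_a <= 0 or int_b <= 0:
        raise ValueError("zero self-intensity; cannot normalize")
    return float(int_ab / np.sqrt(int_a * int_b))


def _mean_nn_distance(coords: np.ndarray, tree: cKDTree) -> float:
    d, _ = tree.query(coords, k=2)
    return float(d[:, 1].mean())


def nsd(a: PointModel, b: PointModel) -> float:
    """Normalized spatial discrepancy between two point models.

    For every point of each model the squared distance to the nearest point
    of the other model is accumulated and normalized by that model's mean
    nearest-neighbour spacing:

        NSD^2 = 1/2 [ (1 / (N_B d_A^2)) sum_{b in B} min_a |a-b|^2
                    + (1 / (N_A d_B^2)) sum_{a in A} min_b |a-b|^2 ].

    Symmetric; 0 iff the point sets coincide.  Nearest-neighbour searches
    are exact (KD-tree).
    """
    if a.n_points < 2 or b.n_points < 2:
        raise ValueError("NSD needs at least 2 points per model")
    tree_a = cKDTree(a.coords)
    tree_b = cKDTree(b.coords)
    d_a = _mean_nn_distance(a.coords, tree_a)
    d_b = _mean_nn_distance(b.coords, tree_b)
    if d_a == 0 or d_b == 0:
        raise ValueError("duplicate points make the NSD normalization zero")
    b_to_a, _ = tree_a.query(b.coords)
    a_to_b, _ = tree_b.query(a.coords)
    value = 0.5 * ((b_to_a ** 2).sum() / (b.n_points * d_a ** 2)
                   + (a_to_b ** 2).sum() / (a.n_points * d_b ** 2))
    return float(np.sqrt(value))


def _occupied_voxels(coords: np.ndarray, origin: np.ndarray,
                     voxel: float) -> set:
    idx = np.floor((coords - origin) / voxel).astype(np.int64)
    return set(map(tuple, idx))


def nov(a: PointModel, b: PointModel, voxel: float | None = None) -> float:
    """Normalized overlapped volume of the two models on a shared grid.

    Each model occupies the voxels containing at least one of its points;
    NOV = |A and B| / sqrt(|A| * |B|).  The default voxel size is D_max/32
    of the larger model.
    """
    if voxel is None:
        from .geometry import max_diameter
        voxel = max(max_diameter(a), max_diameter(b)) / 32.0
    if not voxel > 0:
        raise ValueError("voxel size must be positive")
    origin = np.minimum(a.coords.min(axis=0), b.coords.min(axis=0))
    occ_a = _occupied_voxels(a.coords, origin, voxel)
    occ_b = _occupied_voxels(b.coords, origin, voxel)
    return len(occ_a & occ_b) / np.sqrt(len(occ_a) * len(occ_b))


def similarity_verdict(ncc_value: float, nsd_value: float) -> str:
    """Advisory classification of an alignment (never used for gating).

    Good similarity is flagged when NCC >= 0.7 or NSD <= 1.0 (inclusive),
    the rule-of-thumb limits for models at the default resolution.
    """
    if not (np.isfinite(ncc_value) and np.isfinite(nsd_value)):
        raise ValueError("non-finite inputs")
    ncc_good = ncc_value >= NCC_GOOD_THRESHOLD
    nsd_good = nsd_value <= NSD_GOOD_THRESHOLD
    verdict = "good" if (ncc_good or nsd_good) else "poor"
    return (f"{verdict} similarity: NCC = {ncc_value:.4f} "
            f"({'good' if ncc_good else 'poor'}, threshold "
            f"{NCC_GOOD_THRESHOLD}), NSD = {nsd_value:.4f} "
            f"({'good' if nsd_good else 'poor'}, threshold "
            f"{NSD_GOOD_THRESHOLD})")
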