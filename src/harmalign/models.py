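"""Core data containers: weighted point models, density maps, phase tables.

A :class:`PointModel` is the universal real-space carrier: atoms (weighted by
electron count), dummy-atom beads (unit weight), or map voxels above a density
threshold (weighted by the voxel value).  All downstream scattering-amplitude
machinery consumes this one representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PointModel", "DensityMap", "PhaseDensityTable"]


@dataclass
class PointModel:
    """Weighted 3D point set in Å, optionally with integer phase labels.

    Parameters
    ----------
    coords : (N, 3) float array
        Cartesian coordinates in Å.
    weights : (N,) float array
        Per-point scattering weight (relative density x volume); treated as
        independent of momentum transfer.
    phase_labels : (N,) int array, optional
        Per-point phase id for multi-phase (e.g. protein/RNA) bead models.
    atom_records : list, optional
        Per-point (name, resname, chain, resseq, element) tuples preserved
        from an input PDB file for faithful round-trip writing.
    label : str
        Free-text description.
    """

    coords: np.ndarray
    weights: np.ndarray
    phase_labels: np.ndarray | None = None
    atom_records: list | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        self.weights = np.atleast_1d(np.asarray(self.weights, dtype=float))
        if self.coords.shape != (len(self.weights), 3):
            raise ValueError(
                f"coords shape {self.coords.shape} inconsistent with "
                f"{len(self.weights)} weights"
            )
        if len(self.weights) < 1:
            raise ValueError("a point model needs at least one point")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("non-finite weights")
        if self.phase_labels is not None:
            self.phase_labels = np.atleast_1d(
                np.asarray(self.phase_labels, dtype=int)
            )
            if len(self.phase_labels) != len(self.weights):
                raise ValueError("phase_labels length mismatch")

    @property
    def n_points(self) -> int:
        return len(self.weights)

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())

    def replace_coords(self, coords: np.ndarray) -> "PointModel":
        """Copy of the model with new coordinates, metadata preserved."""
        return PointModel(
            coords=np.asarray(coords, dtype=float),
            weights=self.weights.copy(),
            phase_labels=None if self.phase_labels is None
            else self.phase_labels.copy(),
            atom_records=self.atom_records,
            label=self.label,
        )


@dataclass
class DensityMap:
    """Regular cubic-voxel 3D density grid.

    ``grid[ix, iy, iz]`` holds the density of the voxel whose center sits at
    ``origin + (ix + 0.5, iy + 0.5, iz + 0.5) * voxel_size``.
    """

    grid: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 3 or min(self.grid.shape) < 1:
            raise ValueError("grid must be a non-empty 3D array")
        self.voxel_size = float(self.voxel_size)
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be positive")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid.shape))


class PhaseDensityTable(dict):
    """Mapping phase id -> relative scattering density (dimensionless).

    Used to re-weight multi-phase bead models (e.g. protein vs. nucleic acid
    phases of a ribosome envelope) before amplitude calculation.
    """

    def __init__(self, mapping=None):
        super().__init__()
        if mapping:
            for k, v in dict(mapping).items():
                self[int(k)] = float(v)

    def density_for(self, phase: int) -> float:
        try:
            return self[int(phase)]
        except KeyError:
            raise KeyError(
                f"no scattering density given for phase {phase}"
            ) from None
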