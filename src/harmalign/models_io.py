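"""Reading and writing of model representations.

Supported formats:

* fixed-column PDB (``ATOM``/``HETATM`` records), including dummy-atom bead
  models as written by ab initio shape programs (DAMMIN/DAMMIF/GASBOR/MONSA);
* CCP4/MRC 2014 electron-density maps (cubic voxels only);
* plain-text phase-density tables (``phase_id density`` pairs, ``#`` comments).

Multi-phase bead models encode the phase in the chain identifier: chains in
order of first appearance map to phases 1, 2, 3, ...
"""

from __future__ import annotations

import os

import gemmi
import numpy as np

from .models import DensityMap, PhaseDensityTable, PointModel

__all__ = [
    "ParseError",
    "read_pdb",
    "write_pdb",
    "read_density_map",
    "write_density_map",
    "map_to_points",
    "apply_phase_densities",
    "read_phase_table",
]


class ParseError(ValueError):
    """Raised for unparseable or empty input files."""


# Electron counts for the elements that dominate biomolecules; anything else
# falls back to gemmi's periodic table (matched by the element field or the
# first letter of the atom name).
_ELECTRONS = {"H": 1, "C": 6, "N": 7, "O": 8, "P": 15, "S": 16}


def _electron_count(atom: gemmi.Atom) -> float:
    el = atom.element
    name = el.name.upper()
    if name in _ELECTRONS:
        return float(_ELECTRONS[name])
    if el.atomic_number > 0:
        return float(el.atomic_number)
    fallback = gemmi.Element(atom.name.strip()[:1])
    return float(max(fallback.atomic_number, 1))


def _validate_atom_lines(path: str) -> int:
    """Check coordinate columns of every ATOM/HETATM record.

    gemmi tolerates garbage in the coordinate fields, so the fixed-column
    floats (columns 31-54) are verified here to report the offending line.
    Returns the number of atom records seen.
    """
    n = 0
    with open(path, "r", errors="replace") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            n += 1
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                fieldtxt = line[lo:hi].strip()
                try:
                    float(fieldtxt)
                except ValueError:
                    raise ParseError(
                        f"{path}: malformed coordinate field "
                        f"{fieldtxt!r} on line {lineno}"
                    ) from None
    return n


def read_pdb(path: str | os.PathLike, bead_mode: bool = False) -> PointModel:
    """Read a PDB file into a :class:`PointModel`.

    Parameters
    ----------
    path : path-like
        Fixed-column PDB file with at least one ATOM/HETATM record.
    bead_mode : bool
        If True every point gets unit weight (dummy-atom bead convention);
        otherwise the weight is the element's electron count.

    Returns
    -------
    PointModel
        One point per atom record, in file order.  Chain identifiers are
        translated to integer phase labels (first chain seen -> 1).
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such file: {path}")
    if _validate_atom_lines(path) == 0:
        raise ParseError(f"{path}: no atom records")
    try:
        st = gemmi.read_pdb(path, split_chain_on_ter=False)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc

    coords, weights, phases, records = [], [], [], []
    chain_phase: dict[str, int] = {}
    for model in st:
        for chain in model:
            phase = chain_phase.setdefault(chain.name, len(chain_phase) + 1)
            for res in chain:
                for atom in res:
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    weights.append(1.0 if bead_mode else _electron_count(atom))
                    phases.append(phase)
                    records.append(
                        (atom.name, res.name, chain.name, res.seqid.num,
                         atom.element.name)
                    )
        break  # single-model semantics; NMR ensembles are split by the caller
    if not coords:
        raise ParseError(f"{path}: no atom records")
    return PointModel(
        coords=np.array(coords),
        weights=np.array(weights),
        phase_labels=np.array(phases) if len(chain_phase) > 1 else None,
        atom_records=records,
        label=os.path.basename(path),
    )


def read_pdb_ensemble(path: str | os.PathLike,
                      bead_mode: bool = False) -> list[PointModel]:
    """Read every MODEL of a multi-model (e.g. NMR ensemble) PDB file."""
    path = os.fspath(path)
    if _validate_atom_lines(path) == 0:
        raise ParseError(f"{path}: no atom records")
    st = gemmi.read_pdb(path, split_chain_on_ter=False)
    out = []
    for model in st:
        coords, weights = [], []
        for chain in model:
            for res in chain:
                for atom in res:
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    weights.append(1.0 if bead_mode else _electron_count(atom))
        if coords:
            out.append(PointModel(np.array(coords), np.array(weights),
                                  label=f"{os.path.basename(path)}#{model.num}"))
    if not out:
        raise ParseError(f"{path}: no atom records")
    return out


_PHASE_CHAINS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789"


def write_pdb(model: PointModel, path: str | os.PathLike) -> None:
    """Write a :class:`PointModel` as fixed-column PDB.

    Coordinates are written with three decimals (PDB precision).  Serial
    numbers above 99999 wrap modulo 100000; nothing downstream relies on
    serials.  Metadata preserved by :func:`read_pdb` is re-emitted; synthetic
    models are written as dummy-atom beads (one per phase chain).
    """
    path = os.fspath(path)
    lines = []
    for i in range(model.n_points):
        x, y, z = model.coords[i]
        if model.atom_records is not None:
            name, resname, chain, resseq, element = model.atom_records[i]
        else:
            phase = (1 if model.phase_labels is None
                     else int(model.phase_labels[i]))
            name, resname, element = "CA", "DUM", "C"
            chain = _PHASE_CHAINS[(phase - 1) % len(_PHASE_CHAINS)]
            resseq = (i % 9999) + 1
        serial = (i % 99999) + 1
        atom_name = name if len(name) >= 4 else f" {name:<3s}"
        lines.append(
            f"ATOM  {serial:5d} {atom_name:<4.4s} {resname:<3.3s} "
            f"{str(chain)[:1]:1s}{int(resseq) % 10000:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          "
            f"{element:>2.2s}\n"
        )
    lines.append("END\n")
    with open(path, "w") as fh:
        fh.writelines(lines)


def read_density_map(path: str | os.PathLike) -> DensityMap:
    """Read a CCP4/MRC map into a :class:`DensityMap`.

    The grid is reordered to the internal X/Y/Z axis convention irrespective
    of the header's axis permutation.  Only cubic voxels are supported.  The
    origin comes from the MRC2014 ORIGIN header words; when those are all
    zero it is computed from the start indices times the voxel size.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such file: {path}")
    try:
        m = gemmi.read_ccp4_map(path)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{path}: not a valid CCP4/MRC map ({exc})") from exc
    # start indices are per column/row/section in file order; map them to
    # crystal axes through MAPC/MAPR/MAPS before gemmi reorders the grid
    starts_file = [m.header_i32(w) for w in (5, 6, 7)]
    axis_of = [m.header_i32(w) - 1 for w in (17, 18, 19)]
    starts_xyz = [0, 0, 0]
    for file_axis, xyz_axis in enumerate(axis_of):
        starts_xyz[xyz_axis] = starts_file[file_axis]
    origin = np.array([m.header_float(w) for w in (50, 51, 52)])

    m.setup(0.0, gemmi.MapSetup.ReorderOnly)
    spacing = np.array(m.grid.spacing)
    if spacing.min() <= 0 or np.ptp(spacing) > 1e-3 * spacing.mean():
        raise ParseError(
            f"{path}: non-cubic voxels unsupported "
            f"(spacing {tuple(np.round(spacing, 4))})"
        )
    voxel = float(spacing.mean())
    if np.allclose(origin, 0.0):
        origin = np.asarray(starts_xyz, dtype=float) * voxel
    grid = np.array(m.grid, copy=True, dtype=float)
    return DensityMap(grid=grid, voxel_size=voxel, origin=origin)


def write_density_map(dmap: DensityMap, path: str | os.PathLike) -> None:
    """Write a :class:`DensityMap` as a CCP4/MRC 2014 file (P1, cubic)."""
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(dmap.grid, dtype=np.float32))
    nx, ny, nz = dmap.grid.shape
    v = dmap.voxel_size
    m.grid.unit_cell = gemmi.UnitCell(nx * v, ny * v, nz * v, 90, 90, 90)
    m.grid.spacegroup = gemmi.find_spacegroup_by_name("P1")
    m.update_ccp4_header()
    for word, value in zip((50, 51, 52), dmap.origin):
        m.set_header_float(word, float(value))
    m.write_ccp4_map(os.fspath(path))


def map_to_points(dmap: DensityMap, threshold: float) -> PointModel:
    """Convert a density map to a weighted point model.

    Every voxel with density strictly above ``threshold`` becomes one point
    at the voxel center, carrying the raw voxel density as its weight.
    Points are emitted in raster (C) order, so the conversion is
    deterministic.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    mask = dmap.grid > threshold
    if not mask.any():
        raise ValueError(f"empty model at threshold {threshold}")
    idx = np.argwhere(mask)  # raster order
    coords = dmap.origin + (idx + 0.5) * dmap.voxel_size
    return PointModel(coords=coords, weights=dmap.grid[mask],
                      label="map-derived model")


def apply_phase_densities(model: PointModel,
                          table: PhaseDensityTable) -> PointModel:
    """Scale each point's weight by its phase's relative scattering density."""
    if model.phase_labels is None:
        raise ValueError("model has no phase labels")
    factors = np.empty(model.n_points)
    for phase in np.unique(model.phase_labels):
        factors[model.phase_labels == phase] = table.density_for(int(phase))
    out = model.replace_coords(model.coords)
    out.weights = model.weights * factors
    return out


def read_phase_table(path: str | os.PathLike) -> PhaseDensityTable:
    """Read a two-column ``phase_id density`` text table ('#' comments)."""
    table = PhaseDensityTable()
    with open(os.fspath(path)) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ParseError(
                    f"{path}: expected 'phase_id density' on line {lineno}"
                )
            table[int(parts[0])] = float(parts[1])
    if not table:
        raise ParseError(f"{path}: empty phase-density table")
    return table
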