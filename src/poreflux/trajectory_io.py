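"""Structure/trajectory ingestion, atom selection and unit conventions.

Canonical units are Å for lengths and ns for times; every reader converts
on ingest (nm-based formats such as XTC are scaled by 10). The pore axis
convention is a z-vector pointing from the extracellular side toward the
cytosol, so site order along +z is vestibule < Sa < S3 < Sb < Sc < cavity.

Three trajectory dialects are supported:

* multi-model PDB (topology and trajectory),
* a plain columnar TSV (``time_ns  atom_index  x  y  z``) used as the
  language-portable fixture format,
* XTC through :mod:`mdtraj` when that package is installed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "AtomTable",
    "TrajectoryBundle",
    "Selector",
    "read_topology",
    "write_topology",
    "read_trajectory",
    "write_trajectory_tsv",
    "select_atoms",
]

#: residue names treated as water when a selector asks for solvent
WATER_RESIDUES = frozenset({"HOH", "SOL", "WAT", "TIP3", "TIP", "SPC"})

#: ns timestep-uniformity tolerance
DT_TOLERANCE = 1e-9


@dataclass
class AtomTable:
    """Per-atom metadata: chain, residue id/name, atom name, element.

    The table is indexed by a contiguous 0-based ``atom_index``; residue
    numbers follow the source file (author numbering, e.g. C479).
    """

    df: pd.DataFrame

    REQUIRED = ("chain_id", "residue_number", "residue_name", "atom_name", "element")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"AtomTable missing columns: {missing}")
        n = len(self.df)
        if not np.array_equal(self.df.index.to_numpy(), np.arange(n)):
            self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def chain_ids(self) -> np.ndarray:
        return self.df["chain_id"].to_numpy()

    @property
    def residue_numbers(self) -> np.ndarray:
        return self.df["residue_number"].to_numpy()

    @property
    def residue_names(self) -> np.ndarray:
        return self.df["residue_name"].to_numpy()

    @property
    def atom_names(self) -> np.ndarray:
        return self.df["atom_name"].to_numpy()

    @property
    def elements(self) -> np.ndarray:
        return self.df["element"].to_numpy()

    def is_water(self) -> np.ndarray:
        """Boolean mask of solvent atoms by residue name."""
        return np.isin(self.residue_names, list(WATER_RESIDUES))

    def to_biotite(self, coords: np.ndarray) -> struc.AtomArray:
        """Build a biotite AtomArray from this table plus one coordinate set."""
        n = len(self)
        arr = struc.AtomArray(n)
        arr.chain_id = self.chain_ids.astype("U4")
        arr.res_id = self.residue_numbers.astype(int)
        arr.res_name = self.residue_names.astype("U5")
        arr.atom_name = self.atom_names.astype("U6")
        arr.element = self.elements.astype("U2")
        arr.hetero = np.isin(
            self.residue_names, list(WATER_RESIDUES) + ["LI", "NA", "K", "RB", "CS", "CL"]
        )
        arr.coord = np.asarray(coords, dtype=np.float64)
        return arr


@dataclass
class TrajectoryBundle:
    """Frames × atoms coordinates (Å) with uniformly spaced times (ns).

    ``coords`` has shape ``(n_frames, n_atoms, 3)``; ``box`` is an optional
    per-frame Å triplet.
    """

    times: np.ndarray
    coords: np.ndarray
    atoms: AtomTable
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[0] != self.times.shape[0]:
            raise ValueError("times and coords disagree on frame count")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError(
                f"coordinate frames have {self.coords.shape[1]} atoms but the "
                f"topology has {len(self.atoms)}"
            )
        if self.times.size and self.times[0] < 0:
            raise ValueError("times must start at t >= 0")
        if self.times.size > 1:
            diffs = np.diff(self.times)
            if np.any(diffs <= 0):
                raise ValueError("times must be strictly increasing")
            if np.max(np.abs(diffs - diffs[0])) > DT_TOLERANCE:
                raise ValueError("non-uniform timestep beyond tolerance")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def dt(self) -> float:
        """Frame spacing in ns (0.0 for a single-frame bundle)."""
        if self.times.size < 2:
            return 0.0
        return float(self.times[1] - self.times[0])


@dataclass(frozen=True)
class Selector:
    """Predicate combination over the AtomTable columns.

    Every non-None field must match; list-valued fields match any element.
    ``water`` selects (or excludes) solvent residues by residue name.
    """

    chain_id: str | Sequence[str] | None = None
    residue_number: int | Iterable[int] | None = None
    residue_name: str | Sequence[str] | None = None
    atom_name: str | Sequence[str] | None = None
    element: str | Sequence[str] | None = None
    water: bool | None = None


def _match(values: np.ndarray, wanted) -> np.ndarray:
    if np.isscalar(wanted) or isinstance(wanted, str):
        return values == wanted
    return np.isin(values, list(wanted))


def select_atoms(
    atoms: AtomTable, selector: Selector, allow_empty: bool = False
) -> np.ndarray:
    """Resolve a selector to a sorted array of 0-based atom indices.

    Raises ``ValueError`` on an empty result unless ``allow_empty``.
    """
    mask = np.ones(len(atoms), dtype=bool)
    for column, wanted in (
        ("chain_id", selector.chain_id),
        ("residue_number", selector.residue_number),
        ("residue_name", selector.residue_name),
        ("atom_name", selector.atom_name),
        ("element", selector.element),
    ):
        if wanted is not None:
            mask &= _match(atoms.df[column].to_numpy(), wanted)
    if selector.water is not None:
        mask &= atoms.is_water() == selector.water
    indices = np.flatnonzero(mask)
    if indices.size == 0 and not allow_empty:
        raise ValueError(f"selector matched no atoms: {selector}")
    return indices


# ---------------------------------------------------------------------------
# PDB topology
# ---------------------------------------------------------------------------

def _atoms_from_biotite(arr: struc.AtomArray) -> AtomTable:
    df = pd.DataFrame(
        {
            "chain_id": arr.chain_id,
            "residue_number": arr.res_id.astype(int),
            "residue_name": arr.res_name,
            "atom_name": arr.atom_name,
            "element": arr.element,
        }
    )
    return AtomTable(df)


def read_topology(path: str | os.PathLike) -> tuple[AtomTable, np.ndarray]:
    """Read a PDB file into an AtomTable plus first-model coordinates (Å).

    ATOM and HETATM records are both kept, so ions and waters are present
    with their element field populated. Duplicate atom serial numbers are
    rejected with the offending serial named.
    """
    pdb = PDBFile.read(os.fspath(path))
    model = pdb.get_structure(model=1, extra_fields=["atom_id"])
    if model.array_length() == 0:
        raise ValueError(f"{path}: no ATOM/HETATM records")
    serials = model.atom_id
    if len(np.unique(serials)) != len(serials):
        vals, counts = np.unique(serials, return_counts=True)
        dup = int(vals[counts > 1][0])
        raise ValueError(f"{path}: duplicate atom serial {dup}")
    return _atoms_from_biotite(model), np.asarray(model.coord, dtype=np.float64)


def write_topology(
    path: str | os.PathLike, atoms: AtomTable, coords: np.ndarray
) -> None:
    """Write a single-model PDB preserving chain/residue/atom fields."""
    pdb = PDBFile()
    pdb.set_structure(atoms.to_biotite(coords))
    pdb.write(os.fspath(path))


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

def read_trajectory(
    path: str | os.PathLike,
    atoms: AtomTable,
    dt_override: float | None = None,
) -> TrajectoryBundle:
    """Read a trajectory (PDB multi-model, TSV fixture, or XTC) in Å/ns.

    ``dt_override`` (ns) replaces/declares the frame spacing for formats
    that do not carry times (multi-model PDB) or whose times should be
    overridden. The frame atom count must match ``atoms``.
    """
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tsv", ".txt", ".dat"):
        return _read_trajectory_tsv(path, atoms, dt_override)
    if ext == ".pdb":
        return _read_trajectory_pdb(path, atoms, dt_override)
    if ext == ".xtc":
        return _read_trajectory_xtc(path, atoms, dt_override)
    raise ValueError(f"unrecognised trajectory format: {path}")


def _check_atom_count(n_file: int, atoms: AtomTable, path: str) -> None:
    if n_file != len(atoms):
        raise ValueError(
            f"{path}: trajectory has {n_file} atoms per frame but the "
            f"topology has {len(atoms)}"
        )


def _read_trajectory_pdb(
    path: str, atoms: AtomTable, dt_override: float | None
) -> TrajectoryBundle:
    pdb = PDBFile.read(path)
    stack = pdb.get_structure()
    coords = np.asarray(stack.coord, dtype=np.float64)
    if coords.ndim == 2:  # single model
        coords = coords[None]
    _check_atom_count(coords.shape[1], atoms, path)
    dt = 1.0 if dt_override is None else float(dt_override)
    times = np.arange(coords.shape[0]) * dt
    return TrajectoryBundle(times=times, coords=coords, atoms=atoms)


def _read_trajectory_tsv(
    path: str, atoms: AtomTable, dt_override: float | None
) -> TrajectoryBundle:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"time_ns", "atom_index", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: TSV trajectory needs columns {sorted(required)}")
    times = np.unique(df["time_ns"].to_numpy())
    n_per_frame = len(df) // len(times)
    _check_atom_count(n_per_frame, atoms, path)
    df = df.sort_values(["time_ns", "atom_index"], kind="stable")
    coords = df[["x", "y", "z"]].to_numpy(dtype=np.float64).reshape(
        len(times), n_per_frame, 3
    )
    if dt_override is not None and len(times) > 1:
        times = times[0] + np.arange(len(times)) * float(dt_override)
    return TrajectoryBundle(times=times, coords=coords, atoms=atoms)


def _read_trajectory_xtc(
    path: str, atoms: AtomTable, dt_override: float | None
) -> TrajectoryBundle:
    try:
        from mdtraj.formats import XTCTrajectoryFile
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "XTC support requires mdtraj (install the 'xtc' extra)"
        ) from exc
    with XTCTrajectoryFile(path) as fh:
        xyz, times_ps, _, box = fh.read()
    coords = np.asarray(xyz, dtype=np.float64) * 10.0  # nm -> Å
    _check_atom_count(coords.shape[1], atoms, path)
    if dt_override is not None:
        times = np.arange(coords.shape[0]) * float(dt_override)
    else:
        times = np.asarray(times_ps, dtype=np.float64) / 1000.0  # ps -> ns
    box_ang = None
    if box is not None:
        box_ang = np.einsum("fii->fi", np.asarray(box, dtype=np.float64)) * 10.0
    return TrajectoryBundle(times=times, coords=coords, atoms=atoms, box=box_ang)


def write_trajectory_tsv(path: str | os.PathLike, bundle: TrajectoryBundle) -> None:
    """Write the columnar fixture format (time_ns, atom_index, x, y, z)."""
    n_frames, n_atoms = bundle.n_frames, bundle.n_atoms
    times = np.repeat(bundle.times, n_atoms)
    idx = np.tile(np.arange(n_atoms), n_frames)
    flat = bundle.coords.reshape(-1, 3)
    df = pd.DataFrame(
        {
            "time_ns": times,
            "atom_index": idx,
            "x": flat[:, 0],
            "y": flat[:, 1],
            "z": flat[:, 2],
        }
    )
    df.to_csv(os.fspath(path), sep="\t", index=False, float_format="%.6f")
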