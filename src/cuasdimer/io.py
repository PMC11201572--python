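"""Structures, trajectories and tabular output.

The in-memory model is deliberately small: a :class:`Structure` is a flat,
ordered atom table (numpy-backed) with chain / residue / element labels, and
a :class:`Trajectory` couples one topology with a stack of coordinate
frames.  Reading of PDB / DCD / XYZ goes through MDAnalysis coordinate
readers; PDB and XYZ writing emit the fixed-width records directly so chain
identifiers and element columns survive round trips exactly.

Residue numbering is 1-based throughout, matching the AS(1-140) convention;
the two monomers of a dimer are chains "A" and "B".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

WATER_RESNAMES = frozenset({"HOH", "TIP3", "WAT", "SOL"})


class PDBParseError(ValueError):
    """A structure file could not be parsed."""


class ShapeError(ValueError):
    """Trajectory frame does not match its topology."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a structure (coordinates in angstroms)."""

    atom_id: int
    name: str
    element: str
    residue_index: int
    residue_name: str
    chain_id: str
    coords: tuple[float, float, float]


class Structure:
    """Ordered atom table for one conformation.

    Parameters are parallel arrays over atoms.  ``coords`` is (n_atoms, 3)
    in angstroms.
    """

    def __init__(self, names, elements, residue_indices, residue_names,
                 chain_ids, coords, atom_ids=None, box=None):
        self.names = np.asarray(names, dtype=object)
        self.elements = np.asarray(elements, dtype=object)
        self.residue_indices = np.asarray(residue_indices, dtype=int)
        self.residue_names = np.asarray(residue_names, dtype=object)
        self.chain_ids = np.asarray(chain_ids, dtype=object)
        self.coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        n = len(self.names)
        if not (len(self.elements) == len(self.residue_indices)
                == len(self.residue_names) == len(self.chain_ids)
                == self.coords.shape[0] == n):
            raise ValueError("atom attribute arrays differ in length")
        if n == 0:
            raise PDBParseError("structure contains no atoms")
        if atom_ids is None:
            atom_ids = np.arange(1, n + 1)
        self.atom_ids = np.asarray(atom_ids, dtype=int)
        if len(np.unique(self.atom_ids)) != n:
            raise ValueError("atom_ids must be unique")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        for el in self.elements:
            if not el:
                raise ValueError("empty element symbol")
        self.box = None if box is None else np.asarray(box, dtype=float)

    # -- basic introspection -------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chain_ids:
            seen.setdefault(c)
        return list(seen)

    @property
    def atoms(self) -> list[AtomRecord]:
        return [AtomRecord(int(self.atom_ids[i]), self.names[i],
                           self.elements[i], int(self.residue_indices[i]),
                           self.residue_names[i], self.chain_ids[i],
                           tuple(self.coords[i]))
                for i in range(self.n_atoms)]

    def is_water(self) -> np.ndarray:
        """Boolean mask of solvent atoms (by residue name)."""
        return np.array([rn in WATER_RESNAMES for rn in self.residue_names])

    @property
    def protein_chains(self) -> list[str]:
        wat = self.is_water()
        cu = self.elements == "CU"
        return sorted({c for c, w, m in zip(self.chain_ids, wat, cu)
                       if not w and not m})

    # -- selection -----------------------------------------------------------

    def select(self, chain=None, residue_index=None, name=None, element=None):
        """Indices of atoms matching all given criteria.

        Each criterion may be a scalar or an iterable of allowed values;
        selection order is immaterial (criteria are conjunctive).
        """
        mask = np.ones(self.n_atoms, dtype=bool)

        def _match(values, crit):
            if isinstance(crit, (str, int, np.integer)):
                crit = [crit]
            allowed = set(crit)
            return np.array([v in allowed for v in values])

        if chain is not None:
            mask &= _match(self.chain_ids, chain)
        if residue_index is not None:
            mask &= _match(self.residue_indices, residue_index)
        if name is not None:
            mask &= _match(self.names, name)
        if element is not None:
            mask &= _match(self.elements, element)
        return np.flatnonzero(mask)

    def subset(self, indices) -> "Structure":
        idx = np.asarray(indices, dtype=int)
        return Structure(self.names[idx], self.elements[idx],
                         self.residue_indices[idx], self.residue_names[idx],
                         self.chain_ids[idx], self.coords[idx],
                         atom_ids=self.atom_ids[idx], box=self.box)

    def with_coords(self, coords) -> "Structure":
        return Structure(self.names, self.elements, self.residue_indices,
                         self.residue_names, self.chain_ids, coords,
                         atom_ids=self.atom_ids, box=self.box)

    def residues(self, chain=None):
        """Ordered unique (chain_id, residue_index, residue_name) triples."""
        out = []
        seen = set()
        for i in range(self.n_atoms):
            if chain is not None and self.chain_ids[i] != chain:
                continue
            key = (self.chain_ids[i], int(self.residue_indices[i]))
            if key not in seen:
                seen.add(key)
                out.append(key + (self.residue_names[i],))
        return out


@dataclass
class Trajectory:
    """A topology plus an ordered stack of coordinate frames (angstroms)."""

    topology: Structure
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    save_interval_ps: float | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ShapeError("frames must be (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ShapeError(
                f"frame atom count {self.frames.shape[1]} does not match "
                f"topology ({self.topology.n_atoms} atoms)")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration_ns(self) -> float | None:
        """(n_frames - 1) x save interval, in ns."""
        if self.save_interval_ps is None:
            return None
        return (self.n_frames - 1) * self.save_interval_ps / 1000.0

    def frame_structure(self, i: int) -> Structure:
        return self.topology.with_coords(self.frames[i])


def frames_in_final_window(total_duration_ns: float, save_interval_ps: float,
                           window_ns: float) -> int:
    """Number of saved conformations in the last `window_ns` of a run.

    With structures saved every `save_interval_ps`, a 5 ns window of a
    200 ns / 10 ps run holds 500 conformations.
    """
    if save_interval_ps <= 0:
        raise ValueError("save_interval must be positive")
    if window_ns < 0 or window_ns > total_duration_ns:
        raise ValueError("window must lie within the total duration")
    return int(math.floor(window_ns * 1000.0 / save_interval_ps))


# ---------------------------------------------------------------------------
# readers


def _element_from_name(name: str) -> str:
    stripped = "".join(ch for ch in name if ch.isalpha())
    if not stripped:
        return "X"
    two = stripped[:2].upper()
    if two in {"CU", "NA", "CL", "MG", "ZN", "FE", "MN", "CA"} and len(stripped) <= 2:
        return two
    return stripped[0].upper()


def load_structure(path) -> Structure:
    """Read a PDB file (first MODEL) into a :class:`Structure`."""
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        u = mda.Universe(str(path))
    except Exception as exc:  # pragma: no cover - depends on reader internals
        raise PDBParseError(f"{path}: {exc}") from exc
    ag = u.atoms
    if len(ag) == 0:
        raise PDBParseError(f"{path}: no atoms")
    try:
        chain_ids = [c if c.strip() else "A" for c in ag.chainIDs]
    except Exception:
        chain_ids = ["A"] * len(ag)
    try:
        elements = [e.upper() if e.strip() else _element_from_name(n)
                    for e, n in zip(ag.elements, ag.names)]
    except Exception:
        elements = [_element_from_name(n) for n in ag.names]
    return Structure(
        names=list(ag.names), elements=elements,
        residue_indices=[int(r) for r in ag.resids],
        residue_names=[rn.strip() for rn in ag.resnames],
        chain_ids=chain_ids, coords=ag.positions.astype(float),
        atom_ids=[int(i) for i in ag.ids],
    )


def load_trajectory(topology: Structure, path,
                    save_interval_ps: float | None = None) -> Trajectory:
    """Read frames from a multi-model PDB, DCD or XYZ file.

    DCD and XYZ carry no topology; atom order must match `topology`.
    """
    from MDAnalysis.coordinates.DCD import DCDReader
    from MDAnalysis.coordinates.PDB import PDBReader
    from MDAnalysis.coordinates.XYZ import XYZReader

    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".dcd":
        reader = DCDReader(str(path))
    elif suffix == ".xyz":
        reader = XYZReader(str(path))
    else:
        reader = PDBReader(str(path))
    frames = []
    with reader:
        for i, ts in enumerate(reader):
            if ts.positions.shape[0] != topology.n_atoms:
                raise ShapeError(
                    f"frame {i}: {ts.positions.shape[0]} atoms, topology has "
                    f"{topology.n_atoms}")
            frames.append(ts.positions.astype(float).copy())
    if not frames:
        raise PDBParseError(f"{path}: no frames")
    return Trajectory(topology, np.stack(frames), save_interval_ps)


# ---------------------------------------------------------------------------
# writers


_PDB_FMT = ("{rec:<6s}{serial:>5d} {name:<4s}{resname:>4s} {chain:1s}"
            "{resid:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
            "          {element:>2s}\n")


def _pdb_atom_line(st: Structure, i: int, coords: np.ndarray,
                   serial: int) -> str:
    hetatm = st.elements[i] == "CU" or st.residue_names[i] in WATER_RESNAMES
    name = st.names[i]
    if len(name) < 4:
        name = " " + name  # right-justify short names into columns 14-16
    return _PDB_FMT.format(
        rec="HETATM" if hetatm else "ATOM", serial=serial % 100000,
        name=name[:4], resname=st.residue_names[i][:4],
        chain=str(st.chain_ids[i])[:1], resid=int(st.residue_indices[i]) % 10000,
        x=coords[i, 0], y=coords[i, 1], z=coords[i, 2], occ=1.0, b=0.0,
        element=st.elements[i][:2])


def write_structure(structure: Structure, path) -> None:
    """Write a single-model PDB file."""
    with open(path, "w") as fh:
        for i in range(structure.n_atoms):
            fh.write(_pdb_atom_line(structure, i, structure.coords,
                                    int(structure.atom_ids[i])))
        fh.write("END\n")


def write_trajectory(traj: Trajectory, path) -> None:
    """Write frames as multi-model PDB, DCD or XYZ (chosen by suffix)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".dcd":
        _write_dcd(traj, path)
    elif suffix == ".xyz":
        _write_xyz(traj, path)
    else:
        _write_multimodel_pdb(traj, path)


def _write_multimodel_pdb(traj: Trajectory, path) -> None:
    st = traj.topology
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"MODEL     {f + 1:>4d}\n")
            for i in range(st.n_atoms):
                fh.write(_pdb_atom_line(st, i, traj.frames[f],
                                        int(st.atom_ids[i])))
            fh.write("ENDMDL\n")
        fh.write("END\n")


def _write_dcd(traj: Trajectory, path) -> None:
    import MDAnalysis as mda

    n_atoms = traj.topology.n_atoms
    u = mda.Universe.empty(n_atoms, trajectory=True)
    with mda.coordinates.DCD.DCDWriter(str(path), n_atoms) as w:
        for f in range(traj.n_frames):
            u.atoms.positions = traj.frames[f]
            w.write(u.atoms)


def _write_xyz(traj: Trajectory, path) -> None:
    st = traj.topology
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{st.n_atoms}\nframe {f}\n")
            for i in range(st.n_atoms):
                x, y, z = traj.frames[f, i]
                fh.write(f"{st.elements[i]:<3s} {x:12.6f} {y:12.6f} {z:12.6f}\n")


def write_tsv(df: pd.DataFrame, path) -> None:
    """Write a results table as TSV with a header row."""
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
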