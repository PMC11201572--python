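"""Cu(2+) binding occupancy and coordination-number accounting.

A residue is "bound" in a frame when any Cu ion lies within a distance
cutoff of any of the residue's ligand (donor) atoms: carboxylate O for
Asp/Glu, imidazole N for His, amide O for Asn, thioether S for Met, the
backbone amine N of residue 1 and the terminal carboxylate O atoms of the
last residue.  Occupancy is the percentage of frames bound; sites with
occupancy >= 70% are classified as strongly bound, below 70% weakly.

The distance criterion is not a bond-order statement: typical Cu(2+)-O/N
coordination bonds are 1.9-2.3 A and the 3.0 A default absorbs thermal
fluctuation.  Coordination numbers count protein donor atoms (O, N, S)
plus water oxygens within the cutoff; waters complete the metal's
coordination shell to four or six.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Structure, Trajectory

STRONG_BINDING_THRESHOLD = 70.0  # percent
DEFAULT_BINDING_CUTOFF = 3.0  # A

#: side-chain donor atoms by residue type
LIGAND_ATOM_NAMES = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "ASN": ("OD1",),
    "HIS": ("NE2", "ND1"),
    "MET": ("SD",),
}

#: elements counted as protein electron donors in coordination shells
DONOR_ELEMENTS = ("O", "N", "S")


@dataclass(frozen=True)
class BindingSiteDefinition:
    """A named binding site: its residues and their donor atoms."""

    site: str
    residues: tuple  # ((residue_index, residue_name), ...)

    def ligand_names(self, residue_name: str) -> tuple:
        return LIGAND_ATOM_NAMES.get(residue_name, ())


def site_definition(site, n_residues: int = 140) -> BindingSiteDefinition:
    """Binding-site definition with positions remapped for short chains."""
    from .synthetic import SITE_RESIDUES, SPECIAL_RESIDUES, BindingSite, binding_site_map

    site = BindingSite(site)
    amap = binding_site_map(n_residues)
    residues = tuple((amap[p], SPECIAL_RESIDUES[p]) for p in SITE_RESIDUES[site])
    return BindingSiteDefinition(site.value, residues)


def ligand_atom_indices(st: Structure) -> dict:
    """(chain_id, residue_index) -> atom indices of that residue's donor
    atoms, for every protein residue that has any.

    Includes the backbone amine N of residue 1 and the terminal
    carboxylate oxygens (O, OXT) of each chain's last residue.
    """
    out: dict[tuple[str, int], list[int]] = {}
    waters = st.is_water()
    chain_last: dict[str, int] = {}
    for i in range(st.n_atoms):
        if waters[i] or st.elements[i] == "CU":
            continue
        ch = st.chain_ids[i]
        chain_last[ch] = max(chain_last.get(ch, 0), int(st.residue_indices[i]))
    for i in range(st.n_atoms):
        if waters[i] or st.elements[i] == "CU":
            continue
        ch, r = st.chain_ids[i], int(st.residue_indices[i])
        names = LIGAND_ATOM_NAMES.get(st.residue_names[i], ())
        hit = st.names[i] in names
        if r == 1 and st.names[i] == "N":
            hit = True
        if r == chain_last.get(ch) and st.names[i] in ("O", "OXT"):
            hit = True
        if hit:
            out.setdefault((ch, r), []).append(i)
    return {k: np.array(v) for k, v in out.items()}


@dataclass
class OccupancyProfile:
    """Per-residue Cu-binding occupancy percentages."""

    table: pd.DataFrame  # monomer, residue_index, residue_name,
    # occupancy_percent, classification
    n_frames: int
    cutoff: float

    def percent(self, monomer: str, residue_index: int) -> float:
        t = self.table
        row = t[(t.monomer == monomer) & (t.residue_index == residue_index)]
        if row.empty:
            raise KeyError((monomer, residue_index))
        return float(row.occupancy_percent.iloc[0])


def classify_binding(occupancy_percent: float) -> str:
    """"strong" when occupancy >= 70%, else "weak"."""
    if not 0.0 <= occupancy_percent <= 100.0:
        raise ValueError(f"occupancy must be in [0, 100], "
                         f"got {occupancy_percent}")
    return ("strong" if occupancy_percent >= STRONG_BINDING_THRESHOLD
            else "weak")


def compute_occupancy(traj: Trajectory, sites: BindingSiteDefinition | None = None,
                      cutoff: float = DEFAULT_BINDING_CUTOFF) -> OccupancyProfile:
    """Occupancy percentage per (monomer, residue) over a trajectory.

    With ``sites`` given, only that site's residues are reported;
    otherwise every residue with donor atoms is scanned (which surfaces
    binding at residues outside the constructed site, e.g. Glu46, Glu61,
    Asp135 or the C-terminal carboxylate).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    st = traj.topology
    cu_idx = st.select(element="CU")
    if len(cu_idx) == 0:
        raise ValueError("trajectory contains no Cu atoms")
    ligands = ligand_atom_indices(st)
    if sites is not None:
        wanted = {r for r, _ in sites.residues}
        ligands = {k: v for k, v in ligands.items() if k[1] in wanted}
    resnames = {(st.chain_ids[i], int(st.residue_indices[i])): st.residue_names[i]
                for i in range(st.n_atoms)}
    rows = []
    for (ch, r), idx in sorted(ligands.items()):
        lig = traj.frames[:, idx, :]  # (F, L, 3)
        cu = traj.frames[:, cu_idx, :]  # (F, M, 3)
        d = np.linalg.norm(lig[:, :, None, :] - cu[:, None, :, :], axis=3)
        bound = (d <= cutoff).any(axis=(1, 2))
        pct = 100.0 * float(bound.mean())
        rows.append((ch, r, resnames[(ch, r)], pct, classify_binding(pct)))
    table = pd.DataFrame(rows, columns=["monomer", "residue_index",
                                        "residue_name", "occupancy_percent",
                                        "classification"])
    return OccupancyProfile(table, traj.n_frames, cutoff)


@dataclass(frozen=True)
class CoordinationRecord:
    """Ligands of one Cu ion in one frame."""

    frame: int
    cu_id: int
    ligands: tuple  # ((atom_id, distance, category), ...)

    @property
    def coordination_number(self) -> int:
        return len(self.ligands)


def coordination_numbers(traj: Trajectory,
                         cutoff: float = DEFAULT_BINDING_CUTOFF) -> list:
    """Per frame and per Cu ion, the coordinating atoms within `cutoff`.

    Protein donors are O/N/S atoms of protein residues; water oxygens
    count toward the coordination number with category "water".
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    st = traj.topology
    cu_idx = st.select(element="CU")
    if len(cu_idx) == 0:
        raise ValueError("trajectory contains no Cu atoms")
    waters = st.is_water()
    protein_donors = np.array([
        i for i in range(st.n_atoms)
        if not waters[i] and st.elements[i] in DONOR_ELEMENTS], dtype=int)
    water_o = np.array([i for i in range(st.n_atoms)
                        if waters[i] and st.elements[i] == "O"], dtype=int)
    records = []
    for f in range(traj.n_frames):
        for cu in cu_idx:
            ligs = []
            for pool, category in ((protein_donors, "protein"),
                                   (water_o, "water")):
                if len(pool) == 0:
                    continue
                d = np.linalg.norm(traj.frames[f][pool] - traj.frames[f][cu],
                                   axis=1)
                for j in np.flatnonzero(d <= cutoff):
                    ligs.append((int(st.atom_ids[pool[j]]), float(d[j]),
                                 category))
            records.append(CoordinationRecord(f, int(st.atom_ids[cu]),
                                              tuple(sorted(ligs))))
    return records
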