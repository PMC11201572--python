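"""Synthetic two-chain dimer trajectories with planted, known ground truth.

This module stands in for the study's explicit-solvent MD runs: it emits
trajectories of a two-monomer AS-like dimer (chains "A" and "B") in which
every signal the analysis modules measure has been planted with a known
realisation --

* per-frame Cu(2+) binding at chosen residues (Bernoulli per frame; the ion
  sits 2.05 A from the residue's side-chain donor atom when bound and is
  parked >= 8 A away otherwise),
* inter-monomer hydrophobic contacts (chosen C-alpha pairs brought within
  the 10 A criterion in a planned fraction of frames),
* per-residue secondary structure (helical dihedrals, or an inter-chain
  parallel beta-ladder, switched on per frame),
* a decaying number of inter-monomer hydrogen bonds (amide H placed 1.9 A
  from a backbone carbonyl O, count following an exponential decay),
* a water shell (single-O waters; a designated subset held within 3.0 A of
  chosen residues, the rest kept in a far bulk region).

The realised per-frame indicators are re-measured from the emitted
coordinates with the same distance rules the analysis modules use and
recorded in :class:`GroundTruth`, so downstream recovery can be checked
exactly; the drawn plan probabilities are kept alongside for statistical
checks.  Chains shorter than the full 140-residue sequence carry the
binding-site residues at proportionally remapped positions (the map is part
of the ground truth).  No force field is involved and no physical realism
is claimed beyond the planted geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.spatial.distance import cdist

from . import _geometry as geom
from .energetics import (BOLTZMANN_K, DEFAULT_TEMPERATURE, EnergyEnsemble,
                         HYDROPHOBIC_RESIDUES)
from .io import Structure, Trajectory

AS_N_RESIDUES = 140

#: binding-site and coordination-relevant positions of the AS sequence
#: (canonical numbering); everything else is modelled as alanine.
SPECIAL_RESIDUES = {
    1: "MET", 2: "ASP", 5: "MET",
    46: "GLU", 50: "HIS", 61: "GLU",
    119: "ASP", 121: "ASP", 122: "ASN", 123: "GLU",
    135: "ASP",
}

#: side-chain donor-atom name and CA distance (A) per residue type
ANCHOR_ATOMS = {
    "ASP": ("OD1", "O", 2.5),
    "GLU": ("OE1", "O", 3.1),
    "ASN": ("OD1", "O", 2.5),
    "HIS": ("NE2", "N", 3.4),
    "MET": ("SD", "S", 3.0),
}

#: NAC domain of the full-length sequence (residues 61-95)
NAC_REGION = (61, 95)

CU_BOUND_DISTANCE = 2.05  # A, generator's "bound" Cu-donor distance
CU_UNBOUND_MIN = 8.0  # A
CONTACT_BOUND_DISTANCE = 6.0  # A, planted CA-CA contact distance
HBOND_PLANT_DISTANCE = 1.9  # A, planted H...O distance
WATER_SHELL_DISTANCE = 2.5  # A, planted water-O to CA distance

# analysis criteria mirrored by the bookkeeping (same values as the
# analysis modules' defaults)
BINDING_CUTOFF = 3.0
CONTACT_CUTOFF = 10.0
HBOND_CUTOFF = 2.4
WATER_SHELL = 3.0

# calibrated parallel beta-ladder offset: translating a strand built from
# ideal strand dihedrals by this vector (in its build frame) yields a
# Kabsch-Sander parallel bridge ladder with the original, with every
# load-bearing hydrogen bond far enough below the -0.5 kcal/mol threshold
# to survive the generator's coordinate noise
LADDER_OFFSET = np.array([2.6, 3.6, 1.5])


class Polymorph(str, Enum):
    A = "A"
    B = "B"
    C = "C"
    D = "D"


class BindingSite(str, Enum):
    NTERM = "NTERM"
    HIS50 = "HIS50"
    CTERM = "CTERM"


class CuASRatio(str, Enum):
    LOW = "1:2"   # one Cu per dimer
    HIGH = "1:1"  # one Cu per monomer


#: residues (full-sequence numbering) defining each binding site
SITE_RESIDUES = {
    BindingSite.NTERM: (1, 2, 5),
    BindingSite.HIS50: (50,),
    BindingSite.CTERM: (119, 121, 122, 123),
}


@dataclass(frozen=True)
class ModelSpec:
    """One catalog entry: polymorph x binding site x Cu:AS ratio."""

    polymorph: Polymorph
    site: BindingSite
    cu_as_ratio: CuASRatio

    @property
    def model_id(self) -> str:
        number = {BindingSite.NTERM: 1, BindingSite.HIS50: 2,
                  BindingSite.CTERM: 3}[self.site]
        if self.cu_as_ratio is CuASRatio.HIGH:
            number += 3
        return f"{self.polymorph.value}{number}"

    @classmethod
    def from_model_id(cls, model_id: str) -> "ModelSpec":
        poly = Polymorph(model_id[0])
        number = int(model_id[1:])
        if not 1 <= number <= 6:
            raise ValueError(f"bad model id {model_id!r}")
        site = {1: BindingSite.NTERM, 2: BindingSite.HIS50,
                3: BindingSite.CTERM}[(number - 1) % 3 + 1]
        ratio = CuASRatio.LOW if number <= 3 else CuASRatio.HIGH
        return cls(poly, site, ratio)


@dataclass
class SyntheticConfig:
    """Plan of planted signals for one generated trajectory.

    Probabilities are per-frame Bernoulli parameters.  ``ss_plan`` entries
    are contiguous residue segments ``(klass, start, end, fraction)`` with
    klass "H" (intra-chain helix, planted in both monomers) or "E"
    (inter-monomer parallel beta-ladder; at most one E segment).
    ``site_occupancy`` maps (chain_id, residue_index) to a binding
    probability; ``contact_plan`` entries are ``(res_a, res_b, fraction)``
    C-alpha contacts between chain A residue a and chain B residue b;
    ``water_plan`` maps (chain_id, residue_index) to a planted shell count.
    """

    n_residues: int = AS_N_RESIDUES
    n_frames: int = 100
    save_interval_ps: float = 10.0
    noise_sigma: float = 0.05
    site_occupancy: dict = field(default_factory=dict)
    contact_plan: list = field(default_factory=list)
    ss_plan: list = field(default_factory=list)
    hbond_decay: tuple | None = None  # (initial count, decay const, frames)
    hbond_residues: list | None = None
    n_waters: int = 30
    water_plan: dict = field(default_factory=dict)
    chain_separation: float = 30.0
    dihedral_jitter: float = 4.0  # degrees, per residue per frame
    seed: int = 0

    def validate(self):
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for p in self.site_occupancy.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("occupancy probabilities must be in [0, 1]")
        for _, _, p in self.contact_plan:
            if not 0.0 <= p <= 1.0:
                raise ValueError("contact occurrences must be in [0, 1]")
        claimed: dict[int, str] = {}
        n_e = 0
        for klass, start, end, frac in self.ss_plan:
            if klass not in ("H", "E"):
                raise ValueError(f"unknown secondary-structure class {klass!r}")
            if not 0.0 <= frac <= 1.0:
                raise ValueError("ss fractions must be in [0, 1]")
            if not 2 <= start <= end <= self.n_residues - 1:
                raise ValueError("ss segment must lie inside (1, n_residues)")
            if klass == "H" and end - start < 3:
                raise ValueError("helix segments need at least 4 residues")
            if klass == "E" and not 3 <= start <= end <= self.n_residues - 2:
                raise ValueError("E segments need a 2-residue margin inside "
                                 "the chain")
            n_e += klass == "E"
            margin = 2 if klass == "E" else 1
            for r in range(start - margin, end + margin + 1):
                if r in claimed:
                    raise ValueError(
                        f"residue {r} claimed by two secondary-structure "
                        f"segments ({claimed[r]} and {klass})")
                claimed[r] = klass
        if n_e > 1:
            raise ValueError("at most one E segment is supported")
        for _, rb, _ in self.contact_plan:
            if rb in claimed:
                raise ValueError(f"contact-plan residue {rb} (chain B) "
                                 f"overlaps a secondary-structure segment")
        return self


@dataclass
class GroundTruth:
    """Realised per-frame signals of one generated trajectory."""

    site_map: dict  # full-sequence residue index -> emitted index
    occupancy: dict  # (chain, residue) -> bool array (n_frames,)
    occupancy_plan: dict  # (chain, residue) -> planned probability
    contacts: dict  # (res_a, res_b) -> bool array
    contact_plan: dict  # (res_a, res_b) -> planned fraction
    ss_classes: dict  # (chain, residue) -> object array of "H"/"E"/"C"
    hbond_counts: np.ndarray  # planted per-frame count
    hbond_measured: np.ndarray  # re-measured per-frame count
    water_counts: dict  # (chain, residue) -> per-frame int array
    cutoffs: dict

    def occupancy_percent(self, chain, residue) -> float:
        ind = self.occupancy[(chain, residue)]
        return 100.0 * float(np.mean(ind))


#: the experimentally proposed binding-site residues plus the terminus;
#: always present in the emitted sequence
CORE_POSITIONS = (1, 2, 5, 50, 119, 121, 122, 123)


def binding_site_map(n_residues: int) -> dict[int, int]:
    """Proportional, order-preserving remap of the special full-sequence
    positions onto a shorter chain; identity for 140 residues.

    Chains shorter than 24 residues carry only the core binding-site
    positions (the decoy residues Glu46/Glu61/Asp135 need room).
    """
    if n_residues >= AS_N_RESIDUES:
        return {p: p for p in SPECIAL_RESIDUES}
    positions = sorted(SPECIAL_RESIDUES if n_residues >= 24
                       else CORE_POSITIONS)
    # forward pass: proportional target, strictly increasing
    q = []
    for k, pos in enumerate(positions):
        target = max(1, min(n_residues,
                            round(pos * n_residues / AS_N_RESIDUES)))
        q.append(max(target, (q[-1] + 1) if q else 1))
    # backward pass: cap so the tail still fits inside the chain
    for k in range(len(q) - 1, -1, -1):
        limit = n_residues - (len(q) - 1 - k)
        q[k] = min(q[k], limit)
        if k + 1 < len(q):
            q[k] = min(q[k], q[k + 1] - 1)
    return dict(zip(positions, q))


def residue_names(n_residues: int) -> list[str]:
    """Emitted sequence: alanine everywhere except the (remapped)
    binding-site positions."""
    names = ["ALA"] * n_residues
    for full_pos, short_pos in binding_site_map(n_residues).items():
        names[short_pos - 1] = SPECIAL_RESIDUES[full_pos]
    return names


def nac_region(n_residues: int) -> tuple[int, int]:
    """NAC-domain residue range scaled to the emitted chain length."""
    lo = max(2, round(NAC_REGION[0] * n_residues / AS_N_RESIDUES))
    hi = min(n_residues - 1, round(NAC_REGION[1] * n_residues / AS_N_RESIDUES))
    return lo, hi


# ---------------------------------------------------------------------------
# structure construction


def _chain_atoms(names_seq, bb, anchors, chain_id, start_atom_id):
    """Flatten backbone + side-chain atoms of one chain into table rows."""
    rows = []
    aid = start_atom_id
    n = len(names_seq)
    for i in range(n):
        resname = names_seq[i]
        atoms = [("N", "N", bb["N"][i]), ("H", "H", bb["H"][i]),
                 ("CA", "C", bb["CA"][i]), ("C", "C", bb["C"][i]),
                 ("O", "O", bb["O"][i])]
        if resname in ANCHOR_ATOMS:
            nm, el, _ = ANCHOR_ATOMS[resname]
            atoms.append((nm, el, anchors[i]))
        else:
            atoms.append(("CB", "C", anchors[i]))
        if i == n - 1:  # terminal carboxylate
            atoms.append(("OXT", "O", bb["OXT"]))
        for nm, el, xyz in atoms:
            rows.append((aid, nm, el, i + 1, resname, chain_id, xyz))
            aid += 1
    return rows, aid


def _build_chain_coords(phi, psi):
    bb = geom.build_backbone(phi, psi)
    n = len(phi)
    anchors = np.empty((n, 3))
    names = None  # anchor length depends on residue type; fill later
    bb["OXT"] = geom.place_atom(bb["N"][n - 1], bb["CA"][n - 1],
                                bb["C"][n - 1], 1.25, 117.0, psi[n - 1])
    return bb, anchors


def _anchors_for(bb, names_seq):
    n = len(names_seq)
    anchors = np.empty((n, 3))
    for i in range(n):
        length = ANCHOR_ATOMS.get(names_seq[i], ("CB", "C", 1.53))[2]
        anchors[i] = geom.sidechain_anchor(bb["N"][i], bb["CA"][i],
                                           bb["C"][i], length)
    return anchors


def build_dimer(n_residues: int = AS_N_RESIDUES, seed: int = 0) -> Structure:
    """Two-chain dimer with full backbone (N, H, CA, C, O), side-chain
    donor anchors at binding-site residues, CB elsewhere, and a terminal
    OXT; chain B is offset so NAC segments sit within contact range."""
    if n_residues < 10:
        raise ValueError("n_residues must be >= 10")
    rng = np.random.default_rng(seed)
    names_seq = residue_names(n_residues)
    rows = []
    aid = 1
    for k, chain_id in enumerate("AB"):
        phi = np.full(n_residues, geom.PHI_PSI_COIL[0]) + rng.normal(0, 3, n_residues)
        psi = np.full(n_residues, geom.PHI_PSI_COIL[1]) + rng.normal(0, 3, n_residues)
        bb, _ = _build_chain_coords(phi, psi)
        anchors = _anchors_for(bb, names_seq)
        if k == 1:
            for key in bb:
                bb[key] = bb[key] + np.array([0.0, 0.0, 8.0])
            anchors = anchors + np.array([0.0, 0.0, 8.0])
        chain_rows, aid = _chain_atoms(names_seq, bb, anchors, chain_id, aid)
        rows.append(chain_rows)
    rows = rows[0] + rows[1]
    return Structure(
        names=[r[1] for r in rows], elements=[r[2] for r in rows],
        residue_indices=[r[3] for r in rows], residue_names=[r[4] for r in rows],
        chain_ids=[r[5] for r in rows], coords=np.array([r[6] for r in rows]),
        atom_ids=[r[0] for r in rows])


# ---------------------------------------------------------------------------
# trajectory generation


def generate_trajectory(base: Structure,
                        config: SyntheticConfig) -> tuple[Trajectory, GroundTruth]:
    """Emit a trajectory over `base`'s dimer with the planted signals of
    `config`, plus Cu ions and waters, and the realised ground truth."""
    config.validate()
    n_res = config.n_residues
    names_seq = residue_names(n_res)
    for (ch, r) in config.site_occupancy:
        if names_seq[r - 1] not in ANCHOR_ATOMS:
            raise ValueError(f"residue {r} ({names_seq[r - 1]}) has no "
                             f"side-chain donor atom to bind Cu")
    for (ra, rb, _) in config.contact_plan:
        for r in (ra, rb):
            if names_seq[r - 1] not in HYDROPHOBIC_RESIDUES:
                raise ValueError(f"contact-plan residue {r} is not hydrophobic")

    rng = np.random.default_rng(config.seed)
    cu_chains = sorted({ch for ch, _ in config.site_occupancy})

    # ---- topology: protein + Cu + waters -------------------------------
    proto_bb = [_build_chain_coords(np.full(n_res, geom.PHI_PSI_COIL[0]),
                                    np.full(n_res, geom.PHI_PSI_COIL[1]))[0]
                for _ in "AB"]
    rows = []
    aid = 1
    for k, chain_id in enumerate("AB"):
        bb = proto_bb[k]
        anchors = _anchors_for(bb, names_seq)
        chain_rows, aid = _chain_atoms(names_seq, bb, anchors, chain_id, aid)
        rows += chain_rows
    n_protein = len(rows)
    for i, ch in enumerate(cu_chains):
        rows.append((aid, "CU", "CU", i + 1, "CU", "I", np.zeros(3)))
        aid += 1
    for w in range(config.n_waters):
        rows.append((aid, "O", "O", w + 1, "HOH", "W", np.zeros(3)))
        aid += 1
    topology = Structure(
        names=[r[1] for r in rows], elements=[r[2] for r in rows],
        residue_indices=[r[3] for r in rows], residue_names=[r[4] for r in rows],
        chain_ids=[r[5] for r in rows], coords=np.array([r[6] for r in rows]),
        atom_ids=[r[0] for r in rows])

    # per-chain atom layout (atoms per residue fixed by sequence)
    chain_slices = {ch: np.flatnonzero(topology.chain_ids == ch) for ch in "AB"}
    res_atoms = {ch: {r: np.flatnonzero((topology.chain_ids == ch)
                                        & (topology.residue_indices == r))
                      for r in range(1, n_res + 1)} for ch in "AB"}
    cu_idx = np.flatnonzero(topology.chain_ids == "I")
    wat_idx = np.flatnonzero(topology.chain_ids == "W")

    # ---- draw all indicators up front ----------------------------------
    nf = config.n_frames
    ss_draw = {}
    for seg_i, (klass, start, end, frac) in enumerate(config.ss_plan):
        ss_draw[seg_i] = rng.random(nf) < frac
    occ_draw = {key: rng.random(nf) < p
                for key, p in sorted(config.site_occupancy.items())}
    con_draw = {(ra, rb): rng.random(nf) < p
                for ra, rb, p in config.contact_plan}
    if config.hbond_decay is not None:
        n0, tau = config.hbond_decay[:2]
        hb_counts = np.round(n0 * np.exp(-np.arange(nf) / tau)).astype(int)
        hb_residues = config.hbond_residues
        if hb_residues is None:
            step_start = 2
            hb_residues = list(range(step_start, step_start + 2 * n0, 2))
        if max(hb_residues, default=0) > n_res:
            raise ValueError("hbond residues exceed chain length")
        reserved = {r for _, s, e, _ in config.ss_plan for r in range(s - 1, e + 2)}
        reserved |= {r for ra, rb, _ in config.contact_plan for r in (ra, rb)}
        if reserved & set(hb_residues):
            raise ValueError("hbond residues overlap other plans")
    else:
        hb_counts = np.zeros(nf, dtype=int)
        hb_residues = []

    # waters: designated shell waters first, rest bulk
    shell_assign = []  # (water_index, chain, residue, slot)
    w_next = 0
    for (ch, r), count in sorted(config.water_plan.items()):
        for slot in range(count):
            if w_next >= config.n_waters:
                raise ValueError("water_plan exceeds n_waters")
            shell_assign.append((w_next, ch, r, slot))
            w_next += 1

    e_segments = [(s, e, ss_draw[i])
                  for i, (k, s, e, _) in enumerate(config.ss_plan) if k == "E"]
    h_segments = [(s, e, ss_draw[i])
                  for i, (k, s, e, _) in enumerate(config.ss_plan) if k == "H"]

    frames = np.empty((nf, topology.n_atoms, 3))
    truth_occ = {key: np.zeros(nf, dtype=bool) for key in occ_draw}
    truth_con = {key: np.zeros(nf, dtype=bool) for key in con_draw}
    truth_ss = {}
    for i, (klass, start, end, frac) in enumerate(config.ss_plan):
        for r in range(start, end + 1):
            for ch in "AB":
                truth_ss[(ch, r)] = np.where(ss_draw[i], klass, "C").astype(object)
    truth_hb = np.zeros(nf, dtype=int)
    truth_wat = {key: np.zeros(nf, dtype=int)
                 for key in sorted({(c, r) for c, r in config.water_plan})}

    from .coordination import ligand_atom_indices

    lig_idx = {key: v for key, v in ligand_atom_indices(topology).items()
               if key in truth_occ}

    ladder_template = None
    if e_segments:
        s, e, _ = e_segments[0]
        m = e - s + 5  # two margin residues each side
        tphi = np.full(m, geom.PHI_PSI_STRAND[0])
        tpsi = np.full(m, geom.PHI_PSI_STRAND[1])
        ladder_template = geom.build_backbone(tphi, tpsi)

    from .metrics import kabsch_superpose

    for f in range(nf):
        # -- dihedrals, shared by the two chains so the congruent monomers
        # keep their exact separation (inter-chain geometry is planted,
        # not emergent)
        coords = np.empty((topology.n_atoms, 3))
        jit = config.dihedral_jitter
        phi = np.full(n_res, geom.PHI_PSI_COIL[0]) + rng.normal(0, jit, n_res)
        psi = np.full(n_res, geom.PHI_PSI_COIL[1]) + rng.normal(0, jit, n_res)
        for s, e, draw in h_segments:
            if draw[f]:
                phi[s - 2:e] = geom.PHI_PSI_HELIX[0]
                psi[s - 2:e] = geom.PHI_PSI_HELIX[1]
        for s, e, draw in e_segments:
            phi[s - 3:e + 2] = geom.PHI_PSI_STRAND[0]
            psi[s - 3:e + 2] = geom.PHI_PSI_STRAND[1]
        bb0, _ = _build_chain_coords(phi, psi)
        chain_bb = {"A": bb0, "B": {k: v.copy() for k, v in bb0.items()}}

        # -- chain placement: B is the congruent copy of A translated
        # along A's least-extent principal axis by (extent + separation),
        # which guarantees a minimum inter-chain distance of exactly
        # `chain_separation`.  In E frames only the B ladder segment
        # (with margins) is re-placed against A; the rest of chain B
        # stays far away so no stray inter-chain hydrogen bonds or
        # bridges arise.
        ca = chain_bb["A"]["CA"]
        _, _, vt = np.linalg.svd(ca - ca.mean(axis=0), full_matrices=False)
        u = vt[2]
        if u[np.argmax(np.abs(u))] < 0:
            u = -u
        proj = ca @ u
        # 8 A slack covers non-CA atoms (H, O, side-chain anchors)
        shift = (proj.max() - proj.min() + 8.0 + config.chain_separation) * u
        for key in chain_bb["B"]:
            chain_bb["B"][key] = chain_bb["B"][key] + shift
        ladder_move: tuple | None = None  # (residue set, rot, tr)
        if e_segments and e_segments[0][2][f]:
            s, e, _ = e_segments[0]
            sl = slice(s - 3, e + 2)
            tmpl = ladder_template

            def seg_points(bb, sl):
                return np.concatenate([bb["N"][sl], bb["CA"][sl], bb["C"][sl]])

            tpts = np.concatenate([tmpl["N"], tmpl["CA"], tmpl["C"]])
            rot_a, tr_a, _ = kabsch_superpose(seg_points(chain_bb["A"], sl), tpts)
            target = (tpts + LADDER_OFFSET) @ rot_a.T + tr_a
            rot_b, tr_b, _ = kabsch_superpose(target, seg_points(chain_bb["B"], sl))
            ladder_move = (set(range(s - 2, e + 3)), rot_b, tr_b)

        anchors = {ch: _anchors_for(chain_bb[ch], names_seq) for ch in "AB"}

        # -- planted contacts: translate chain-B residues toward chain A
        contact_shift: dict[int, np.ndarray] = {}
        cent_a = chain_bb["A"]["CA"].mean(axis=0)
        for (ra, rb), draw in con_draw.items():
            ca_a = chain_bb["A"]["CA"][ra - 1]
            out_dir = ca_a - cent_a
            nrm = np.linalg.norm(out_dir)
            out_dir = out_dir / nrm if nrm > 1e-9 else np.array([0.0, 0.0, 1.0])
            if draw[f]:
                target_ca = ca_a + CONTACT_BOUND_DISTANCE * out_dir
            else:
                target_ca = ca_a + (CONTACT_CUTOFF + 4.0) * out_dir
            contact_shift[rb] = target_ca - chain_bb["B"]["CA"][rb - 1]

        # -- write protein coordinates
        for ch in "AB":
            bb = chain_bb[ch]
            anc = anchors[ch]
            for r in range(1, n_res + 1):
                idx = res_atoms[ch][r]
                pos = [bb["N"][r - 1], bb["H"][r - 1], bb["CA"][r - 1],
                       bb["C"][r - 1], bb["O"][r - 1], anc[r - 1]]
                if r == n_res:
                    pos.append(bb["OXT"])
                pos = np.array(pos)
                if ch == "B" and ladder_move is not None and r in ladder_move[0]:
                    pos = pos @ ladder_move[1].T + ladder_move[2]
                if ch == "B" and r in contact_shift:
                    pos = pos + contact_shift[r]
                coords[idx] = pos

        # -- planted inter-chain H-bonds: move amide H of chain B residues
        n_bonds = int(hb_counts[f])
        for b in range(min(n_bonds, len(hb_residues))):
            r = hb_residues[b]
            o_pos = coords[res_atoms["A"][r][4]]  # O of chain A residue r
            c_pos = coords[res_atoms["A"][r][3]]
            direction = o_pos - c_pos
            direction /= np.linalg.norm(direction)
            coords[res_atoms["B"][r][1]] = o_pos + HBOND_PLANT_DISTANCE * direction

        # -- Cu placement
        for i, ch in enumerate(cu_chains):
            bound = [(chh, r) for (chh, r) in occ_draw
                     if chh == ch and occ_draw[(chh, r)][f]]
            if bound:
                targets = []
                for chh, r in bound:
                    anchor = coords[res_atoms[chh][r][5]]
                    ca = coords[res_atoms[chh][r][2]]
                    u = anchor - ca
                    u /= np.linalg.norm(u)
                    targets.append(anchor + CU_BOUND_DISTANCE * u)
                coords[cu_idx[i]] = np.mean(targets, axis=0)
            else:
                coords[cu_idx[i]] = np.array([0.0, 0.0, -60.0 - 15.0 * i])

        # -- waters
        bulk = np.array([0.0, 0.0, -120.0])
        for w in range(config.n_waters):
            g = w % 25
            coords[wat_idx[w]] = bulk + np.array([4.0 * (g % 5),
                                                  4.0 * (g // 5),
                                                  -5.0 * (w // 25)])
        for w, ch, r, slot in shell_assign:
            ca = coords[res_atoms[ch][r][2]]
            bb = chain_bb[ch]
            u1 = bb["N"][r - 1] - bb["CA"][r - 1]
            u2 = bb["C"][r - 1] - bb["CA"][r - 1]
            out = np.cross(u2, u1)
            out /= np.linalg.norm(out)
            side = bb["CA"][r - 1] - 1.0 * (u1 + u2) / np.linalg.norm(u1 + u2)
            axis = (side - bb["CA"][r - 1])
            axis /= np.linalg.norm(axis)
            tilt = np.deg2rad(25.0 * slot)
            direction = -out * np.cos(tilt) + axis * np.sin(tilt)
            coords[wat_idx[w]] = ca + WATER_SHELL_DISTANCE * direction

        # -- noise, then bookkeeping from the final coordinates
        if config.noise_sigma > 0:
            coords = coords + rng.normal(0.0, config.noise_sigma, coords.shape)
        frames[f] = coords

        for (chh, r) in truth_occ:
            lig = coords[lig_idx[(chh, r)]]
            d = cdist(coords[cu_idx], lig)
            truth_occ[(chh, r)][f] = bool(d.size and d.min() <= BINDING_CUTOFF)
        for (ra, rb) in truth_con:
            d = np.linalg.norm(coords[res_atoms["A"][ra][2]]
                               - coords[res_atoms["B"][rb][2]])
            truth_con[(ra, rb)][f] = d <= CONTACT_CUTOFF
        truth_hb[f] = _count_interchain_hbonds(topology, coords,
                                               chain_slices["A"], chain_slices["B"])
        if truth_wat:
            wcoords = coords[wat_idx]
            for (chh, r) in truth_wat:
                ratoms = coords[res_atoms[chh][r]]
                d = cdist(wcoords, ratoms)
                truth_wat[(chh, r)][f] = int(np.sum(d.min(axis=1) <= WATER_SHELL))

    traj = Trajectory(topology, frames, config.save_interval_ps)
    truth = GroundTruth(
        site_map=binding_site_map(n_res),
        occupancy=truth_occ,
        occupancy_plan=dict(config.site_occupancy),
        contacts=truth_con,
        contact_plan={(ra, rb): p for ra, rb, p in config.contact_plan},
        ss_classes=truth_ss,
        hbond_counts=hb_counts,
        hbond_measured=truth_hb,
        water_counts=truth_wat,
        cutoffs={"binding": BINDING_CUTOFF, "contact": CONTACT_CUTOFF,
                 "hbond": HBOND_CUTOFF, "water_shell": WATER_SHELL},
    )
    return traj, truth


def _count_interchain_hbonds(topology: Structure, coords: np.ndarray,
                             idx_a: np.ndarray, idx_b: np.ndarray) -> int:
    """Donor-H to acceptor O/N pairs across the two chains within the
    2.4 A criterion (same rule as the contacts module)."""
    count = 0
    for don_idx, acc_idx in ((idx_a, idx_b), (idx_b, idx_a)):
        h = don_idx[np.array([topology.elements[i] == "H" for i in don_idx])]
        acc = acc_idx[np.array([topology.elements[i] in ("O", "N")
                                for i in acc_idx])]
        if len(h) and len(acc):
            d = cdist(coords[h], coords[acc])
            count += int(np.sum(d <= HBOND_CUTOFF))
    return count


# ---------------------------------------------------------------------------
# energy ensembles


def generate_energy_ensembles(n_conformers: int, n_per_conformer: int,
                              energy_offsets, spread: float, seed: int = 0,
                              temperature: float = DEFAULT_TEMPERATURE):
    """Grouped Gaussian energy ensembles with exact reference populations.

    Conformer k's energies are offset_k + N(0, spread); the returned truth
    is the exact stationary population of the Metropolis chain (mean
    Boltzmann weight per conformer), computed by direct enumeration.
    """
    offsets = np.asarray(energy_offsets, dtype=float)
    if offsets.shape != (n_conformers,):
        raise ValueError("need one energy offset per conformer")
    if not np.all(np.isfinite(offsets)):
        raise ValueError("offsets must be finite")
    if n_per_conformer < 1:
        raise ValueError("n_per_conformer must be >= 1")
    rng = np.random.default_rng(seed)
    ensembles = []
    for k in range(n_conformers):
        e = offsets[k] + rng.normal(0.0, spread, n_per_conformer)
        ensembles.append(EnergyEnsemble(f"S{k + 1}", e))
    kt = BOLTZMANN_K * temperature
    emin = min(float(e.energies.min()) for e in ensembles)
    weights = np.array([np.mean(np.exp(-(e.energies - emin) / kt))
                        for e in ensembles])
    exact = weights / weights.sum()
    return ensembles, exact
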