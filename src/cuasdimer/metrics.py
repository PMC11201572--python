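"""Structural metrics: Kabsch RMSD, per-residue RMSF, secondary structure.

RMSD and RMSF operate on C-alpha atoms of one monomer at a time and remove
global rigid-body motion by optimal (Kabsch) superposition, so that only
internal conformational change is measured.

Secondary structure uses a minimal Kabsch-Sander assignment: backbone
hydrogen bonds are detected with the electrostatic energy

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)   [kcal/mol]

(a bond when E < -0.5 kcal/mol); alpha-helix (H) is assigned on runs of at
least two consecutive i -> i+4 turns and strand (E) on parallel or
antiparallel bridge ladders.  Everything else, including 3-10/pi helices
and turns, is reported as coil (C).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .io import Structure, Trajectory

KS_COUPLING = 0.084 * 332.0  # kcal/mol * angstrom
KS_CUTOFF = -0.5  # kcal/mol


class DegenerateInputError(ValueError):
    """Point set too small or collinear for a unique superposition."""


# ---------------------------------------------------------------------------
# Kabsch superposition


def kabsch_superpose(reference: np.ndarray, mobile: np.ndarray):
    """Optimal rigid superposition of `mobile` onto `reference`.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits `reference` in the
    least-squares sense, with a proper rotation (det = +1).
    """
    ref = np.asarray(reference, dtype=float).reshape(-1, 3)
    mob = np.asarray(mobile, dtype=float).reshape(-1, 3)
    if ref.shape != mob.shape:
        raise ValueError("point sets must have equal shape")
    if ref.shape[0] < 3:
        raise DegenerateInputError("need at least 3 points")
    cr = ref.mean(axis=0)
    cm = mob.mean(axis=0)
    h = (mob - cm).T @ (ref - cr)
    u, s, vt = np.linalg.svd(h)
    if s[1] <= 1e-10 * max(s[0], 1.0):
        raise DegenerateInputError("collinear point set")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = cr - rotation @ cm
    fitted = (mob @ rotation.T) + translation
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1))))
    return rotation, translation, rmsd


@dataclass
class RMSDSeries:
    """Per-frame RMSD (angstroms) against a reference frame."""

    values: np.ndarray
    chain: str
    reference_frame: int
    selection: str = "CA"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frame": np.arange(len(self.values)),
                             "rmsd": self.values})


def _ca_indices(st: Structure, chain: str) -> np.ndarray:
    idx = st.select(chain=chain, name="CA")
    if len(idx) == 0:
        raise ValueError(f"chain {chain!r} has no CA atoms")
    return idx


def rmsd_series(traj: Trajectory, chain: str,
                reference_frame: int = 0) -> RMSDSeries:
    """Kabsch-fit C-alpha RMSD of one monomer versus a reference frame."""
    idx = _ca_indices(traj.topology, chain)
    ref = traj.frames[reference_frame][idx]
    values = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        _, _, values[f] = kabsch_superpose(ref, traj.frames[f][idx])
    return RMSDSeries(values, chain, reference_frame)


def detect_convergence(series: RMSDSeries, window: int = 25,
                       tol: float = 0.5):
    """First frame after which the sliding-window mean stays within `tol`.

    Returns the frame index, or ``None`` if the series never settles.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    v = np.asarray(series.values, dtype=float)
    if len(v) < window:
        raise ValueError("series shorter than window")
    means = np.convolve(v, np.ones(window) / window, mode="valid")
    # candidate i converged iff all later window means stay within tol of
    # means[i]; the tail must span at least one full window so the last
    # positions cannot qualify trivially
    for i in range(len(means)):
        tail = means[i:]
        if len(tail) < window:
            break
        if np.all(np.abs(tail - means[i]) < tol):
            return i
    return None


def rmsf(traj: Trajectory, chains=None) -> pd.DataFrame:
    """Per-residue C-alpha RMSF per monomer (angstroms).

    Each frame is superposed onto the running mean structure (one
    refinement pass) before measuring fluctuations about the mean.
    Columns: monomer, residue_index, residue_name, rmsf.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    st = traj.topology
    if chains is None:
        chains = st.protein_chains
    rows = []
    for chain in chains:
        idx = _ca_indices(st, chain)
        fitted = np.empty((traj.n_frames, len(idx), 3))
        ref = traj.frames[0][idx]
        for f in range(traj.n_frames):
            r, t, _ = kabsch_superpose(ref, traj.frames[f][idx])
            fitted[f] = traj.frames[f][idx] @ r.T + t
        mean = fitted.mean(axis=0)
        for f in range(traj.n_frames):  # refine once against the mean
            r, t, _ = kabsch_superpose(mean, fitted[f])
            fitted[f] = fitted[f] @ r.T + t
        mean = fitted.mean(axis=0)
        fluct = np.sqrt(np.mean(np.sum((fitted - mean) ** 2, axis=2), axis=0))
        resids = st.residue_indices[idx]
        resnames = st.residue_names[idx]
        for k in range(len(idx)):
            rows.append((chain, int(resids[k]), resnames[k], float(fluct[k])))
    return pd.DataFrame(rows, columns=["monomer", "residue_index",
                                       "residue_name", "rmsf"])


# ---------------------------------------------------------------------------
# Kabsch-Sander secondary structure


def _backbone_tables(st: Structure):
    """Per protein residue: chain, resid and backbone atom indices."""
    keys = ["N", "H", "CA", "C", "O"]
    table: dict[tuple[str, int], dict[str, int]] = {}
    order: list[tuple[str, int]] = []
    waters = st.is_water()
    for i in range(st.n_atoms):
        if waters[i] or st.elements[i] == "CU":
            continue
        key = (st.chain_ids[i], int(st.residue_indices[i]))
        if key not in table:
            table[key] = {}
            order.append(key)
        if st.names[i] in keys and st.names[i] not in table[key]:
            table[key][st.names[i]] = i
    return order, table


def ks_hbond_matrix(st: Structure, warn_missing: bool = True):
    """Backbone H-bond indicator: bonds[d, a] is True when the amide of
    residue `d` donates to the carbonyl of residue `a` (E < -0.5)."""
    order, table = _backbone_tables(st)
    n = len(order)
    pos = {k: {} for k in order}
    missing = []
    for k in order:
        atoms = table[k]
        for nm in ("N", "H", "CA", "C", "O"):
            if nm in atoms:
                pos[k][nm] = st.coords[atoms[nm]]
        if not {"N", "CA", "C", "O"} <= set(atoms):
            missing.append(k)
    if missing and warn_missing:
        warnings.warn(f"residues missing backbone atoms treated as coil: "
                      f"{missing[:5]}{'...' if len(missing) > 5 else ''}")

    can_donate = np.array([{"N", "H"} <= set(pos[k]) for k in order])
    can_accept = np.array([{"C", "O"} <= set(pos[k]) for k in order])
    big = 1e6
    N = np.array([pos[k].get("N", (big, big, big)) for k in order])
    H = np.array([pos[k].get("H", (big, big, big)) for k in order])
    C = np.array([pos[k].get("C", (big, big, big)) for k in order])
    O = np.array([pos[k].get("O", (big, big, big)) for k in order])

    bonds = np.zeros((n, n), dtype=bool)
    if n == 0:
        return order, bonds
    # prescreen on N(d)-O(a) distance; real backbone H-bonds sit well below 5.2 A
    don = np.flatnonzero(can_donate)
    acc = np.flatnonzero(can_accept)
    if len(don) and len(acc):
        d_no = cdist(N[don], O[acc])
        for di, d in enumerate(don):
            for ai, a in enumerate(acc):
                if d_no[di, ai] > 5.2:
                    continue
                cd, rd = order[d]
                ca_, ra = order[a]
                if cd == ca_ and abs(rd - ra) <= 1:
                    continue
                r_on = np.linalg.norm(O[a] - N[d])
                r_ch = np.linalg.norm(C[a] - H[d])
                r_oh = np.linalg.norm(O[a] - H[d])
                r_cn = np.linalg.norm(C[a] - N[d])
                if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                    continue  # clashing geometry, not a hydrogen bond
                e = KS_COUPLING * (1.0 / r_on + 1.0 / r_ch
                                   - 1.0 / r_oh - 1.0 / r_cn)
                if e < KS_CUTOFF:
                    bonds[d, a] = True
    return order, bonds


def assign_secondary_structure(st: Structure, warn_missing: bool = True) -> dict:
    """Per-residue class H / E / C for one conformation.

    Returns a mapping ``(chain_id, residue_index) -> class``.
    """
    order, bonds = ks_hbond_matrix(st, warn_missing=warn_missing)
    n = len(order)
    index = {k: i for i, k in enumerate(order)}

    def successor(i, step=1):
        c, r = order[i]
        return index.get((c, r + step))

    # i -> i+4 turns: carbonyl of i accepts from amide of i+4
    turn4 = np.zeros(n, dtype=bool)
    for i in range(n):
        j = successor(i, 4)
        if j is not None and bonds[j, i]:
            turn4[i] = True

    cls = np.full(n, "C", dtype=object)
    for i in range(1, n):
        prev = index.get((order[i][0], order[i][1] - 1))
        if prev is not None and turn4[prev] and turn4[i]:
            for step in (1, 2, 3, 4):
                j = successor(i, step)
                if j is not None:
                    cls[j] = "H"

    def hb(i, j):  # carbonyl of i accepts from amide of j
        return i is not None and j is not None and bonds[j, i]

    for i in range(n):
        for j in range(n):
            ci, ri = order[i]
            cj, rj = order[j]
            if ci == cj and abs(ri - rj) < 3:
                continue
            im1, ip1 = index.get((ci, ri - 1)), index.get((ci, ri + 1))
            jm1, jp1 = index.get((cj, rj - 1)), index.get((cj, rj + 1))
            parallel = (hb(im1, j) and hb(j, ip1)) or (hb(jm1, i) and hb(i, jp1))
            antiparallel = (hb(i, j) and hb(j, i)) or (hb(im1, jp1) and hb(jm1, ip1))
            if parallel or antiparallel:
                if cls[i] != "H":
                    cls[i] = "E"
                if cls[j] != "H":
                    cls[j] = "E"
    return {order[i]: cls[i] for i in range(n)}


def ss_percentages(traj: Trajectory) -> pd.DataFrame:
    """Percentage of frames each residue spends in H, E and C.

    Columns: monomer, residue_index, H, E, C; the three percentages sum
    to 100 for every residue.
    """
    counts: dict[tuple[str, int], dict[str, int]] = {}
    for f in range(traj.n_frames):
        assign = assign_secondary_structure(traj.frame_structure(f),
                                            warn_missing=(f == 0))
        for key, c in assign.items():
            counts.setdefault(key, {"H": 0, "E": 0, "C": 0})[c] += 1
    rows = []
    for (chain, resid), c in sorted(counts.items()):
        total = c["H"] + c["E"] + c["C"]
        rows.append((chain, resid, 100.0 * c["H"] / total,
                     100.0 * c["E"] / total, 100.0 * c["C"] / total))
    return pd.DataFrame(rows, columns=["monomer", "residue_index",
                                       "H", "E", "C"])
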