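"""Conformational-energy ensembles and Monte Carlo conformer populations.

A *conformer* is one dimer model (e.g. "A3"); its *ensemble* is the set of
per-conformation energies (kcal/mol) evaluated on the conformations saved
from the final stretch of its trajectory (500 conformations from the last
5 ns under the 200 ns / 10 ps bookkeeping).

Populations are estimated with a Metropolis Monte Carlo walk over the union
of all conformations: from the current conformation (of conformer i) a
proposal is drawn by picking a conformer j uniformly and then one of its
conformations uniformly; the move is accepted when the Boltzmann factor
exp(-(Ej - Ei)/kT) exceeds a uniform random number.  Every step credits the
current conformer with one visit, and P_n = N_n / N_total.

Because the proposal picks conformers uniformly regardless of their
ensemble sizes, the chain's stationary distribution weights conformation c
of conformer n by exp(-E_c/kT) / |ensemble_n|; :func:`boltzmann_oracle`
evaluates that stationary distribution exactly by enumeration and is the
reference the sampler is validated against.

The energy provider is pluggable: externally computed tables (e.g. from an
implicit-solvent model) are read with :func:`load_energy_table`, and
:func:`surrogate_energy` offers a simple built-in score (hydrophobic SASA
term at 0.00592 kcal/mol/A^2 plus screened Coulomb with a
distance-dependent dielectric) for self-contained runs.  The surrogate is a
stand-in scoring function, not a Generalized Born model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .io import Structure

BOLTZMANN_K = 0.0019872  # kcal / (mol K)
DEFAULT_TEMPERATURE = 298.0  # K
SASA_FACTOR = 0.00592  # kcal / (mol A^2)
COULOMB_CONSTANT = 332.0  # kcal A / (mol e^2)

#: residues treated as hydrophobic throughout the package
HYDROPHOBIC_RESIDUES = frozenset(
    {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO"})

#: formal charges by residue name (side chain) and for the copper ion
FORMAL_CHARGES = {"ASP": -1.0, "GLU": -1.0, "LYS": +1.0, "ARG": +1.0}

VDW_RADII = {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
             "CU": 1.40, "P": 1.80}


@dataclass
class EnergyEnsemble:
    """Per-conformation energies (kcal/mol) of one conformer."""

    conformer_id: str
    energies: np.ndarray

    def __post_init__(self):
        self.energies = np.atleast_1d(np.asarray(self.energies, dtype=float))
        if self.energies.size < 1:
            raise ValueError("ensemble needs at least one energy")
        if not np.all(np.isfinite(self.energies)):
            raise ValueError(f"{self.conformer_id}: non-finite energy")

    @property
    def n_conformations(self) -> int:
        return int(self.energies.size)


@dataclass
class MCConfig:
    """Monte Carlo settings (298 K, 1e6 steps by default)."""

    temperature: float = DEFAULT_TEMPERATURE
    n_steps: int = 1_000_000
    seed: int = 0
    boltzmann_k: float = BOLTZMANN_K

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")

    @property
    def kT(self) -> float:
        return self.boltzmann_k * self.temperature


@dataclass
class PopulationEstimate:
    """Visit counts and populations per conformer, P_n = N_n / N_total.

    When the sampler tracked visit batches, ``standard_errors`` gives a
    batch-means Monte Carlo standard error per conformer (batch means are
    far less autocorrelated than single steps).
    """

    conformer_ids: list[str]
    visits: np.ndarray
    n_total: int
    batch_populations: np.ndarray | None = None

    @property
    def populations(self) -> np.ndarray:
        return self.visits / self.n_total

    @property
    def standard_errors(self) -> np.ndarray | None:
        if self.batch_populations is None:
            return None
        b = self.batch_populations.shape[0]
        return self.batch_populations.std(axis=0, ddof=1) / math.sqrt(b)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"conformer_id": self.conformer_ids,
                             "visits": self.visits.astype(int),
                             "population": self.populations})


# ---------------------------------------------------------------------------
# SASA and the surrogate energy


def _sphere_points(n: int) -> np.ndarray:
    """Near-uniform points on the unit sphere (golden-spiral lattice)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + math.sqrt(5.0)) * k
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def shrake_rupley_sasa(structure: Structure, probe: float = 1.4,
                       n_points: int = 960) -> tuple[np.ndarray, float]:
    """Shrake-Rupley solvent-accessible surface area.

    Each atom's solvent sphere (vdW radius + probe) is sampled with
    `n_points` test points; points inside any neighbour's solvent sphere
    are occluded.  Returns (per-atom areas, total area) in A^2.
    """
    st = structure
    radii = np.empty(st.n_atoms)
    for i, el in enumerate(st.elements):
        try:
            radii[i] = VDW_RADII[el.upper()]
        except KeyError:
            raise ValueError(f"no van der Waals radius for element "
                             f"{el!r} (atom id {st.atom_ids[i]})") from None
    radii = radii + probe
    pts = _sphere_points(n_points)
    coords = st.coords
    d = cdist(coords, coords)
    areas = np.empty(st.n_atoms)
    eps = 1e-9
    for i in range(st.n_atoms):
        neigh = np.flatnonzero((d[i] < radii[i] + radii) & (np.arange(st.n_atoms) != i))
        test = coords[i] + radii[i] * pts
        exposed = np.ones(n_points, dtype=bool)
        for j in neigh:
            d2 = np.sum((test - coords[j]) ** 2, axis=1)
            occluded = d2 < radii[j] ** 2 - eps
            if j < i:  # shared boundary surface belongs to the earlier atom
                occluded |= np.abs(d2 - radii[j] ** 2) <= eps
            exposed &= ~occluded
            if not exposed.any():
                break
        areas[i] = 4.0 * np.pi * radii[i] ** 2 * exposed.mean()
    return areas, float(areas.sum())


def hydrophobic_sasa(structure: Structure, probe: float = 1.4,
                     n_points: int = 960) -> float:
    """SASA summed over atoms of hydrophobic residues (A^2)."""
    areas, _ = shrake_rupley_sasa(structure, probe=probe, n_points=n_points)
    mask = np.array([rn in HYDROPHOBIC_RESIDUES
                     for rn in structure.residue_names])
    return float(areas[mask].sum())


def _formal_charges(st: Structure) -> np.ndarray:
    """Integer formal charges placed on one representative atom per
    charged residue (the side-chain anchor, else the CA), +2 on Cu."""
    q = np.zeros(st.n_atoms)
    for i in range(st.n_atoms):
        if st.elements[i] == "CU":
            q[i] = 2.0
    seen: set[tuple[str, int]] = set()
    for i in range(st.n_atoms):
        rn = st.residue_names[i]
        if rn not in FORMAL_CHARGES:
            continue
        key = (st.chain_ids[i], int(st.residue_indices[i]))
        if key in seen:
            continue
        if st.names[i].startswith(("OD", "OE", "NZ", "NH")) or st.names[i] == "CA":
            q[i] = FORMAL_CHARGES[rn]
            seen.add(key)
    return q


def surrogate_energy(structure: Structure,
                     sasa_factor: float = SASA_FACTOR,
                     n_points: int = 960) -> float:
    """Simple conformational score: hydrophobic-SASA term plus screened
    Coulomb energy with distance-dependent dielectric eps(r) = 4r.

    E = sasa_factor * SASA_hydrophobic + sum_ij 332 q_i q_j / (4 r_ij^2)

    A lightweight stand-in scoring function for self-contained pipeline
    runs; external energy tables are the first-class input.
    """
    e = sasa_factor * hydrophobic_sasa(structure, n_points=n_points)
    q = _formal_charges(structure)
    charged = np.flatnonzero(q)
    if len(charged) > 1:
        sub = structure.coords[charged]
        d = cdist(sub, sub)
        qq = np.outer(q[charged], q[charged])
        iu = np.triu_indices(len(charged), k=1)
        e += float(np.sum(COULOMB_CONSTANT * qq[iu] / (4.0 * d[iu] ** 2)))
    return e


# ---------------------------------------------------------------------------
# energy tables


def load_energy_table(path) -> list[EnergyEnsemble]:
    """Read a TSV with columns (conformer_id, energy) into ensembles,
    grouped in order of first appearance."""
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        return []
    cols = {c.lower(): c for c in df.columns}
    try:
        id_col = cols["conformer_id"]
        e_col = next(cols[c] for c in cols if c.startswith("energy"))
    except (KeyError, StopIteration):
        raise ValueError(f"{path}: expected columns conformer_id, energy") from None
    energies = pd.to_numeric(df[e_col], errors="coerce")
    bad = np.flatnonzero(energies.isna().to_numpy())
    if len(bad):
        raise ValueError(f"{path}: non-numeric energy on data line {bad[0] + 1}")
    out = []
    for cid in df[id_col].drop_duplicates():
        out.append(EnergyEnsemble(str(cid),
                                  energies[df[id_col] == cid].to_numpy()))
    return out


def write_energy_table(ensembles: list[EnergyEnsemble], path) -> None:
    rows = [(e.conformer_id, x) for e in ensembles for x in e.energies]
    pd.DataFrame(rows, columns=["conformer_id", "energy_kcal_mol"]).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# populations


def mc_populations(ensembles: list[EnergyEnsemble],
                   config: MCConfig | None = None,
                   n_batches: int = 50) -> PopulationEstimate:
    """Metropolis Monte Carlo population estimate over conformers.

    State is the current conformation; proposals draw a conformer
    uniformly, then one of its conformations uniformly, and are accepted
    when exp(-(Ej - Ei)/kT) > u with u ~ U(0, 1).  Each step credits the
    current conformer with one visit.  Visits are additionally tallied in
    `n_batches` contiguous batches for the batch-means standard error.
    """
    if config is None:
        config = MCConfig()
    if len(ensembles) == 0:
        raise ValueError("no ensembles")
    if len(ensembles) == 1:
        warnings.warn("single ensemble: population is trivially 1")
        return PopulationEstimate([ensembles[0].conformer_id],
                                  np.array([config.n_steps], dtype=float),
                                  config.n_steps)
    kt = config.kT
    rng = np.random.default_rng(config.seed)
    k = len(ensembles)
    energies = [e.energies for e in ensembles]
    sizes = np.array([e.n_conformations for e in ensembles])

    cur_conf = int(rng.integers(k))
    cur_e = energies[cur_conf][int(rng.integers(sizes[cur_conf]))]
    visits = np.zeros(k, dtype=float)

    n_batches = max(1, min(n_batches, config.n_steps))
    batch_visits = np.zeros((n_batches, k), dtype=float)
    edges = np.linspace(0, config.n_steps, n_batches + 1).astype(int)

    for b in range(n_batches):
        m = edges[b + 1] - edges[b]
        if m == 0:
            continue
        prop_conf = rng.integers(k, size=m)
        prop_u = rng.random(size=m)  # conformation pick within conformer
        accept_u = rng.random(size=m)
        for s in range(m):
            j = int(prop_conf[s])
            ej = energies[j][int(prop_u[s] * sizes[j])]
            if math.exp(min(50.0, -(ej - cur_e) / kt)) > accept_u[s]:
                cur_conf, cur_e = j, ej
            batch_visits[b, cur_conf] += 1.0
        visits += batch_visits[b]
    batch_pop = batch_visits / np.diff(edges)[:, None]
    return PopulationEstimate([e.conformer_id for e in ensembles],
                              visits, config.n_steps, batch_pop)


def boltzmann_oracle(ensembles: list[EnergyEnsemble],
                     temperature: float = DEFAULT_TEMPERATURE,
                     boltzmann_k: float = BOLTZMANN_K) -> np.ndarray:
    """Exact stationary populations of the sampler's Markov chain.

    With uniform-over-conformer proposals, detailed balance gives
    pi(c) proportional to exp(-E_c/kT) / |ensemble of c|, hence

        P_n  proportional to  (1/|n|) * sum_{c in n} exp(-E_c / kT)

    normalised to sum to 1.  Energies are shifted by their minimum first,
    so the result is overflow-safe and shift-invariant.
    """
    if len(ensembles) == 0:
        raise ValueError("no ensembles")
    kt = boltzmann_k * temperature
    all_min = min(float(e.energies.min()) for e in ensembles)
    w = np.array([np.sum(np.exp(-(e.energies - all_min) / kt))
                  / e.n_conformations for e in ensembles])
    return w / w.sum()


def relative_conformational_energy(
        ensembles: list[EnergyEnsemble]) -> pd.DataFrame:
    """Per-conformer mean energy +- standard error, shifted so the lowest
    mean is zero (kcal/mol).  Columns: conformer_id, mean, se, relative."""
    if len(ensembles) == 0:
        raise ValueError("no ensembles")
    means = np.array([float(e.energies.mean()) for e in ensembles])
    ses = np.array([float(e.energies.std(ddof=1) / math.sqrt(e.n_conformations))
                    if e.n_conformations > 1 else 0.0 for e in ensembles])
    return pd.DataFrame({"conformer_id": [e.conformer_id for e in ensembles],
                         "mean": means, "se": ses,
                         "relative": means - means.min()})
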