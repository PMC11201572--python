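"""Inter-monomer hydrophobic contact maps and hydrogen-bond series.

A hydrophobic contact between monomer residues exists in a frame when the
two C-alpha atoms are within 10 A (inclusive); the contact map reports the
fraction of frames each hydrophobic residue pair spends in contact.  The
map diagonal (equal residue indices across the two monomers) corresponds
to in-register, fibril-like pairing.

Hydrogen bonds are counted with a pure distance criterion of 2.4 A taken
between the donor hydrogen and the acceptor heavy atom (O or N) -- 2.4 A
would be implausibly short for a donor-acceptor distance, so the criterion
is applied H-to-acceptor; no angle term is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .energetics import HYDROPHOBIC_RESIDUES
from .io import Structure, Trajectory

DEFAULT_CONTACT_CUTOFF = 10.0  # A, CA-CA
DEFAULT_HBOND_CUTOFF = 2.4  # A, H...acceptor


@dataclass
class ContactMap:
    """Occurrence fractions of inter-monomer hydrophobic contacts."""

    rows: np.ndarray  # monomer-1 residue indices
    cols: np.ndarray  # monomer-2 residue indices
    values: np.ndarray  # (len(rows), len(cols)) in [0, 1]
    cutoff: float
    residue_filter: frozenset
    chains: tuple

    def value(self, res_row: int, res_col: int) -> float:
        i = int(np.flatnonzero(self.rows == res_row)[0])
        j = int(np.flatnonzero(self.cols == res_col)[0])
        return float(self.values[i, j])

    @property
    def diagonal(self) -> pd.DataFrame:
        """In-register (same residue index) contact occurrences."""
        common = np.intersect1d(self.rows, self.cols)
        vals = [self.value(r, r) for r in common]
        return pd.DataFrame({"residue_index": common, "occurrence": vals})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.rows, columns=self.cols)


def hydrophobic_contact_map(traj: Trajectory, chain1: str = "A",
                            chain2: str = "B",
                            cutoff: float = DEFAULT_CONTACT_CUTOFF,
                            region: tuple | None = None,
                            hydrophobic=HYDROPHOBIC_RESIDUES) -> ContactMap:
    """Fraction of frames each hydrophobic CA pair spends within `cutoff`.

    `region` restricts both axes to a 1-based inclusive residue range
    (e.g. the NAC domain); by default the full sequences are mapped.
    """
    st = traj.topology

    def ca_selection(chain):
        idx = st.select(chain=chain, name="CA")
        if len(idx) == 0:
            raise ValueError(f"chain {chain!r} has no CA atoms")
        keep = [i for i in idx if st.residue_names[i] in hydrophobic]
        if region is not None:
            keep = [i for i in keep
                    if region[0] <= st.residue_indices[i] <= region[1]]
        return np.array(keep, dtype=int)

    idx1, idx2 = ca_selection(chain1), ca_selection(chain2)
    counts = np.zeros((len(idx1), len(idx2)))
    for f in range(traj.n_frames):
        d = cdist(traj.frames[f][idx1], traj.frames[f][idx2])
        counts += d <= cutoff
    return ContactMap(rows=st.residue_indices[idx1].astype(int),
                      cols=st.residue_indices[idx2].astype(int),
                      values=counts / traj.n_frames, cutoff=cutoff,
                      residue_filter=frozenset(hydrophobic),
                      chains=(chain1, chain2))


@dataclass
class HBondSeries:
    """Per-frame inter-monomer hydrogen-bond counts."""

    counts: np.ndarray
    cutoff: float
    chains: tuple

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frame": np.arange(len(self.counts)),
                             "count": self.counts})


def hbond_count_series(traj: Trajectory, chain1: str = "A", chain2: str = "B",
                       cutoff: float = DEFAULT_HBOND_CUTOFF) -> HBondSeries:
    """Count donor-H / acceptor-(O, N) pairs across the two chains with
    an H-to-acceptor distance <= `cutoff`, per frame."""
    st = traj.topology

    def atoms(chain):
        idx = st.select(chain=chain)
        h = np.array([i for i in idx if st.elements[i] == "H"], dtype=int)
        acc = np.array([i for i in idx if st.elements[i] in ("O", "N")],
                       dtype=int)
        return h, acc

    h1, a1 = atoms(chain1)
    h2, a2 = atoms(chain2)
    if len(h1) == 0 and len(h2) == 0:
        raise ValueError(
            "topology has no hydrogens: the 2.4 A hydrogen-bond criterion "
            "is an H-to-acceptor distance and needs explicit polar H atoms")
    counts = np.zeros(traj.n_frames, dtype=int)
    for f in range(traj.n_frames):
        c = 0
        for h, acc in ((h1, a2), (h2, a1)):
            if len(h) and len(acc):
                c += int(np.sum(cdist(traj.frames[f][h],
                                      traj.frames[f][acc]) <= cutoff))
        counts[f] = c
    return HBondSeries(counts, cutoff, (chain1, chain2))


def is_decaying(series: HBondSeries) -> tuple[bool, float]:
    """Least-squares slope of count vs frame; decaying when negative.

    Returns ``(decaying, slope_per_frame)``.
    """
    counts = np.asarray(series.counts, dtype=float)
    if len(counts) < 10:
        raise ValueError("need at least 10 frames")
    slope = float(np.polyfit(np.arange(len(counts)), counts, 1)[0])
    if abs(slope) < 1e-9:  # constant series up to round-off
        slope = 0.0
    return slope < 0.0, slope


def fit_decay_constant(series: HBondSeries) -> float:
    """Exponential decay constant (frames) of a count series.

    Nonlinear least squares of N0 * exp(-t/tau) on the raw counts (a fit
    on log counts would be biased by the integer rounding of low counts);
    the log-linear slope provides the starting point.
    """
    from scipy.optimize import curve_fit

    counts = np.asarray(series.counts, dtype=float)
    frames = np.arange(len(counts), dtype=float)
    mask = counts > 0
    if mask.sum() < 3:
        raise ValueError("too few positive counts to fit a decay")
    slope, intercept = np.polyfit(frames[mask], np.log(counts[mask]), 1)
    if slope >= 0:
        raise ValueError("series does not decay")
    p0 = (float(np.exp(intercept)), float(-1.0 / slope))
    popt, _ = curve_fit(lambda t, n0, tau: n0 * np.exp(-t / tau),
                        frames, counts, p0=p0, maxfev=10_000)
    if popt[1] <= 0:
        raise ValueError("series does not decay")
    return float(popt[1])
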