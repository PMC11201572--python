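"""Per-residue water-shell statistics and cross-model normalisation.

For every protein residue, the number of water molecules whose oxygen lies
within 3.0 A of any atom of the residue is counted per frame and averaged,
separately for each monomer.  Profiles from a batch of models are then
normalised to percentages against the single largest mean count across all
residues of all supplied models, so that exactly one residue cell of the
batch reads 100%.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .io import Trajectory

DEFAULT_SHELL = 3.0  # A


def water_shell_counts(traj: Trajectory, shell: float = DEFAULT_SHELL,
                       model_id: str | None = None) -> pd.DataFrame:
    """Mean number of waters within `shell` of each residue, per monomer.

    Columns: monomer, residue_index, residue_name, mean_waters (plus
    model_id when given).  A water counts toward a residue when its O is
    within `shell` of any atom (heavy or H) of the residue.
    """
    if shell <= 0:
        raise ValueError("shell must be positive")
    st = traj.topology
    waters = st.is_water()
    water_o = np.flatnonzero(waters & (st.elements == "O"))
    if len(water_o) == 0:
        warnings.warn("no waters in topology; solvation profile is zero")
    residues = []
    res_idx = {}
    for i in range(st.n_atoms):
        if waters[i] or st.elements[i] == "CU":
            continue
        key = (st.chain_ids[i], int(st.residue_indices[i]))
        if key not in res_idx:
            res_idx[key] = []
            residues.append((key, st.residue_names[i]))
        res_idx[key].append(i)

    means = {key: 0.0 for key, _ in residues}
    if len(water_o):
        for f in range(traj.n_frames):
            wpos = traj.frames[f][water_o]
            for key, _ in residues:
                d = cdist(wpos, traj.frames[f][res_idx[key]])
                means[key] += float(np.sum(d.min(axis=1) <= shell))
        for key in means:
            means[key] /= traj.n_frames

    rows = [(ch, r, name, means[(ch, r)]) for (ch, r), name in residues]
    df = pd.DataFrame(rows, columns=["monomer", "residue_index",
                                     "residue_name", "mean_waters"])
    if model_id is not None:
        df.insert(0, "model_id", model_id)
    return df


def normalize_profiles(profiles: list[pd.DataFrame]) -> list[pd.DataFrame]:
    """Add a `percent` column: 100 x mean_waters / (global maximum over
    all residues of all supplied profiles)."""
    if not profiles:
        raise ValueError("no profiles to normalize")
    global_max = max(float(p.mean_waters.max()) for p in profiles)
    if global_max <= 0:
        raise ValueError("all water counts are zero; cannot normalize")
    out = []
    for p in profiles:
        q = p.copy()
        q["percent"] = 100.0 * q.mean_waters / global_max
        out.append(q)
    return out
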