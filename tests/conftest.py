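import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cuasdimer import synthetic as syn

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def dimer20():
    return syn.build_dimer(20, seed=1)


@pytest.fixture(scope="session")
def dimer40():
    return syn.build_dimer(40, seed=1)


@pytest.fixture(scope="session")
def planted(dimer40):
    """A 60-frame trajectory with every kind of planted signal."""
    n = 40
    amap = syn.binding_site_map(n)
    cfg = syn.SyntheticConfig(
        n_residues=n, n_frames=60, noise_sigma=0.05,
        site_occupancy={("A", amap[2]): 0.7, ("B", amap[50]): 0.3},
        contact_plan=[(20, 20, 0.6), (22, 21, 0.25)],
        ss_plan=[("H", 5, 10, 0.5), ("E", 25, 30, 0.6)],
        hbond_decay=(6, 25.0),
        hbond_residues=[13, 15, 17, 33, 35, 37],
        n_waters=20,
        water_plan={("A", 12): 3, ("B", 18): 2},
        seed=7,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        traj, truth = syn.generate_trajectory(dimer40, cfg)
    return cfg, traj, truth


@pytest.fixture(scope="session")
def hbond_only(dimer40):
    """A decay-only trajectory: no beta-ladder or contact plants, so the
    measured inter-chain hydrogen-bond series equals the planted one."""
    cfg = syn.SyntheticConfig(
        n_residues=40, n_frames=300, noise_sigma=0.05,
        hbond_decay=(12, 100.0),
        hbond_residues=list(range(3, 27, 2)),
        n_waters=0, seed=3,
    )
    traj, truth = syn.generate_trajectory(dimer40, cfg)
    return cfg, traj, truth


def backbone_structure(backbones, chains, resname="ALA"):
    """Structure from per-chain backbone dicts (N, H, CA, C, O arrays)."""
    from cuasdimer.io import Structure

    names, elements, resid, resnames, chain_ids, coords = [], [], [], [], [], []
    for bb, ch in zip(backbones, chains):
        n = bb["N"].shape[0]
        for i in range(n):
            for nm, el in (("N", "N"), ("H", "H"), ("CA", "C"),
                           ("C", "C"), ("O", "O")):
                names.append(nm)
                elements.append(el)
                resid.append(i + 1)
                resnames.append(resname)
                chain_ids.append(ch)
                coords.append(bb[nm][i])
    return Structure(names, elements, resid, resnames, chain_ids,
                     np.array(coords))


def rigid_frames(coords, n_frames, seed=0):
    """Frames that differ from `coords` by rigid motion only."""
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_frames):
        rot = Rotation.random(random_state=rng).as_matrix()
        out.append(coords @ rot.T + rng.normal(0, 5, 3))
    return np.array(out)
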