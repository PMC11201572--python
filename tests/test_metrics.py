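import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cuasdimer import _geometry as geom
from cuasdimer import io as cio
from cuasdimer import metrics as met
from cuasdimer.synthetic import LADDER_OFFSET

from conftest import backbone_structure, rigid_frames


def _scipy_rmsd(ref, mob):
    """Independent Kabsch RMSD via scipy's Wahba solver."""
    ref_c = ref - ref.mean(axis=0)
    mob_c = mob - mob.mean(axis=0)
    _, rssd = Rotation.align_vectors(ref_c, mob_c)
    return rssd / np.sqrt(len(ref))


class TestKabsch:
    def test_identical_sets(self):
        pts = np.random.default_rng(0).normal(size=(7, 3))
        _, _, rmsd = met.kabsch_superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_removed(self):
        pts = np.random.default_rng(1).normal(size=(5, 3))
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = pts @ rot.T + np.array([3.0, -1.0, 2.0])
        r, t, rmsd = met.kabsch_superpose(pts, moved)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.linalg.det(r) == pytest.approx(1.0)

    def test_matches_independent_solver_on_displaced_point(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            ref = rng.normal(size=(4, 3))
            mob = ref.copy()
            mob[0] += rng.normal(size=3)
            rot = Rotation.random(random_state=rng).as_matrix()
            mob = mob @ rot.T + rng.normal(size=3)
            _, _, rmsd = met.kabsch_superpose(ref, mob)
            assert rmsd == pytest.approx(_scipy_rmsd(ref, mob), abs=1e-3)

    def test_optimal_over_random_rotations(self):
        rng = np.random.default_rng(3)
        ref = rng.normal(size=(4, 3))
        mob = ref + rng.normal(scale=0.5, size=(4, 3))
        _, _, best = met.kabsch_superpose(ref, mob)
        ref_c = ref - ref.mean(axis=0)
        mob_c = mob - mob.mean(axis=0)
        for rot in Rotation.random(2000, random_state=rng):
            trial = np.sqrt(np.mean(np.sum(
                (mob_c @ rot.as_matrix().T - ref_c) ** 2, axis=1)))
            assert best <= trial + 1e-12

    def test_degenerate_inputs(self):
        with pytest.raises(met.DegenerateInputError):
            met.kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(met.DegenerateInputError):
            met.kabsch_superpose(line, line)


class TestRMSDSeries:
    def test_static_trajectory_is_zero(self, dimer20):
        traj = cio.Trajectory(dimer20,
                              np.repeat(dimer20.coords[None], 5, axis=0), 10.0)
        series = met.rmsd_series(traj, "A")
        assert np.allclose(series.values, 0.0, atol=1e-10)

    def test_rigid_motion_is_zero(self, dimer20):
        traj = cio.Trajectory(dimer20, rigid_frames(dimer20.coords, 8), 10.0)
        assert np.allclose(met.rmsd_series(traj, "A").values, 0.0, atol=1e-9)

    def test_matches_direct_per_frame_computation(self, planted):
        _, traj, _ = planted
        series = met.rmsd_series(traj, "A")
        idx = traj.topology.select(chain="A", name="CA")
        ref = traj.frames[0][idx]
        direct = [_scipy_rmsd(ref, traj.frames[f][idx])
                  for f in range(traj.n_frames)]
        assert np.allclose(series.values, direct, atol=1e-6)


class TestConvergence:
    def test_constant_series(self):
        s = met.RMSDSeries(np.ones(100), "A", 0)
        assert met.detect_convergence(s, window=25, tol=0.5) == 0

    def test_linear_series_never_converges(self):
        s = met.RMSDSeries(np.linspace(0, 50, 100), "A", 0)
        assert met.detect_convergence(s, window=25, tol=0.5) is None

    def test_flat_after_rise(self):
        rng = np.random.default_rng(0)
        vals = np.concatenate([np.linspace(0.0, 3.0, 125),
                               3.0 + rng.normal(0, 0.05, 375)])
        s = met.RMSDSeries(vals, "A", 0)
        idx = met.detect_convergence(s, window=25, tol=0.5)
        assert idx is not None and idx <= 150

    def test_window_validation(self):
        s = met.RMSDSeries(np.ones(10), "A", 0)
        with pytest.raises(ValueError):
            met.detect_convergence(s, window=1)
        with pytest.raises(ValueError):
            met.detect_convergence(s, window=25)


class TestRMSF:
    def test_static_and_rigid_are_zero(self, dimer20):
        static = cio.Trajectory(dimer20,
                                np.repeat(dimer20.coords[None], 4, axis=0),
                                10.0)
        assert np.allclose(met.rmsf(static).rmsf, 0.0, atol=1e-10)
        rigid = cio.Trajectory(dimer20, rigid_frames(dimer20.coords, 6), 10.0)
        assert np.allclose(met.rmsf(rigid).rmsf, 0.0, atol=1e-9)

    def test_single_noisy_residue(self):
        # a long chain keeps the rigid-fit leverage of the single noisy
        # residue negligible, so its fluctuation is close to sqrt(3)*sigma
        from cuasdimer.synthetic import build_dimer
        st = build_dimer(80, seed=6)
        sigma = 1.0
        rng = np.random.default_rng(4)
        n_frames = 1000
        frames = np.repeat(st.coords[None], n_frames, axis=0)
        noisy_atom = st.select(chain="A", residue_index=40, name="CA")[0]
        frames[:, noisy_atom, :] += rng.normal(0, sigma, (n_frames, 3))
        traj = cio.Trajectory(st, frames, 10.0)
        prof = met.rmsf(traj, chains=["A"])
        got = prof[prof.residue_index == 40].rmsf.iloc[0]
        assert got == pytest.approx(np.sqrt(3.0) * sigma, rel=0.05)
        assert prof[prof.residue_index != 40].rmsf.max() < 0.3

    def test_matches_brute_force_recomputation(self, planted):
        _, traj, _ = planted
        prof = met.rmsf(traj, chains=["A"])
        idx = traj.topology.select(chain="A", name="CA")
        # direct recomputation with the independent solver
        fitted = np.empty((traj.n_frames, len(idx), 3))
        ref = traj.frames[0][idx]
        for f in range(traj.n_frames):
            mob = traj.frames[f][idx]
            rot, _ = Rotation.align_vectors(ref - ref.mean(axis=0),
                                            mob - mob.mean(axis=0))
            fitted[f] = (mob - mob.mean(axis=0)) @ rot.as_matrix().T \
                + ref.mean(axis=0)
        mean = fitted.mean(axis=0)
        for f in range(traj.n_frames):
            mob = fitted[f]
            rot, _ = Rotation.align_vectors(mean - mean.mean(axis=0),
                                            mob - mob.mean(axis=0))
            fitted[f] = (mob - mob.mean(axis=0)) @ rot.as_matrix().T \
                + mean.mean(axis=0)
        mean = fitted.mean(axis=0)
        direct = np.sqrt(np.mean(np.sum((fitted - mean) ** 2, axis=2), axis=0))
        assert np.allclose(prof.rmsf.to_numpy(), direct, rtol=0.01)

    def test_single_frame_rejected(self, dimer20):
        traj = cio.Trajectory(dimer20, dimer20.coords[None], 10.0)
        with pytest.raises(ValueError):
            met.rmsf(traj)


def _ideal_helix(n=12):
    return geom.build_backbone(np.full(n, -57.0), np.full(n, -47.0))


def _ladder_pair(n=8):
    bb = geom.build_backbone(np.full(n, -139.0), np.full(n, 135.0))
    other = {k: v + LADDER_OFFSET for k, v in bb.items()}
    return backbone_structure([bb, other], ["A", "B"])


class TestSecondaryStructure:
    def test_ideal_helix_interior_is_h(self):
        st = backbone_structure([_ideal_helix()], ["A"])
        assign = met.assign_secondary_structure(st)
        for r in range(3, 11):
            assert assign[("A", r)] == "H"

    def test_helix_agrees_with_mdtraj_interior(self):
        mdtraj = pytest.importorskip("mdtraj")
        n = 12
        bb = _ideal_helix(n)
        top = mdtraj.Topology()
        ch = top.add_chain()
        xyz = []
        for i in range(n):
            res = top.add_residue("ALA", ch)
            for nm, el in (("N", "N"), ("H", "H"), ("CA", "C"),
                           ("C", "C"), ("O", "O")):
                top.add_atom(nm, mdtraj.element.get_by_symbol(el), res)
                xyz.append(bb[nm][i])
        t = mdtraj.Trajectory(np.asarray(xyz)[None] / 10.0, top)
        theirs = mdtraj.compute_dssp(t, simplified=True)[0]
        st = backbone_structure([bb], ["A"])
        ours = met.assign_secondary_structure(st)
        for r in range(3, n - 1):
            assert ours[("A", r)] == theirs[r - 1] == "H"

    def test_strand_ladder_is_e(self):
        st = _ladder_pair()
        assign = met.assign_secondary_structure(st)
        for ch in "AB":
            assert sum(assign[(ch, r)] == "E" for r in range(2, 8)) >= 5

    def test_isolated_extended_chain_is_coil(self):
        bb = geom.build_backbone(np.full(10, -139.0), np.full(10, 135.0))
        st = backbone_structure([bb], ["A"])
        assign = met.assign_secondary_structure(st)
        assert all(v == "C" for v in assign.values())

    def test_assignment_is_rigid_motion_invariant(self):
        st = _ladder_pair()
        rot = Rotation.random(random_state=7).as_matrix()
        moved = st.with_coords(st.coords @ rot.T + np.array([4.0, 5.0, 6.0]))
        assert (met.assign_secondary_structure(st)
                == met.assign_secondary_structure(moved))

    def test_missing_backbone_atom_warns_and_coils(self):
        st = backbone_structure([_ideal_helix()], ["A"])
        keep = [i for i in range(st.n_atoms)
                if not (st.residue_indices[i] == 6 and st.names[i] == "O")]
        broken = st.subset(keep)
        with pytest.warns(UserWarning, match="missing backbone"):
            assign = met.assign_secondary_structure(broken)
        assert assign[("A", 6)] in {"C", "H"}  # never E, and no crash


class TestSSPercentages:
    def test_closure_sums_to_100(self, planted):
        _, traj, _ = planted
        sp = met.ss_percentages(traj)
        assert np.allclose(sp.H + sp.E + sp.C, 100.0, atol=1e-9)

    def test_planted_fractions_recovered_exactly(self, planted):
        _, traj, truth = planted
        sp = met.ss_percentages(traj)
        for (ch, r), classes in truth.ss_classes.items():
            row = sp[(sp.monomer == ch) & (sp.residue_index == r)].iloc[0]
            assert row.H == pytest.approx(100.0 * np.mean(classes == "H"),
                                          abs=1e-9)
            assert row.E == pytest.approx(100.0 * np.mean(classes == "E"),
                                          abs=1e-9)

    def test_all_frames_helix(self):
        bb = _ideal_helix()
        st = backbone_structure([bb], ["A"])
        traj = cio.Trajectory(st, np.repeat(st.coords[None], 3, axis=0), 10.0)
        sp = met.ss_percentages(traj)
        interior = sp[(sp.residue_index >= 3) & (sp.residue_index <= 10)]
        assert (interior.H == 100.0).all()
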