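import numpy as np
import pytest
from hypothesis import given, strategies as st

from cuasdimer import energetics as en
from cuasdimer import io as cio
from cuasdimer import synthetic as syn


def _atoms(entries):
    return cio.Structure(
        names=[e[0] for e in entries], elements=[e[1] for e in entries],
        residue_indices=[e[2] for e in entries],
        residue_names=[e[3] for e in entries],
        chain_ids=[e[4] for e in entries],
        coords=np.array([e[5] for e in entries]))


class TestSASA:
    def test_single_atom_analytic_sphere(self):
        st_ = _atoms([("C1", "C", 1, "ALA", "A", (0.0, 0.0, 0.0))])
        _, total = en.shrake_rupley_sasa(st_)
        assert total == pytest.approx(4 * np.pi * (1.7 + 1.4) ** 2, rel=0.01)

    def test_coincident_atoms_add_nothing(self):
        st_ = _atoms([("C1", "C", 1, "ALA", "A", (0.0, 0.0, 0.0)),
                      ("C2", "C", 1, "ALA", "A", (0.0, 0.0, 0.0))])
        _, total = en.shrake_rupley_sasa(st_)
        assert total == pytest.approx(4 * np.pi * 3.1 ** 2, rel=0.02)

    def test_buried_atom_in_cage(self):
        # central C enclosed by a dense shell of C atoms at 3 A
        entries = [("C0", "C", 1, "ALA", "A", (0.0, 0.0, 0.0))]
        pts = en._sphere_points(200) * 3.0
        for k, p in enumerate(pts):
            entries.append((f"C{k+1}", "C", 2, "ALA", "A", tuple(p)))
        areas, _ = en.shrake_rupley_sasa(_atoms(entries))
        assert areas[0] == pytest.approx(0.0, abs=1.0)

    def test_agrees_with_mdtraj(self, dimer20):
        mdtraj = pytest.importorskip("mdtraj")
        sub = dimer20.subset(dimer20.select(chain="A", name="CA"))
        areas, total = en.shrake_rupley_sasa(sub, n_points=960)
        top = mdtraj.Topology()
        ch = top.add_chain()
        for i in range(sub.n_atoms):
            res = top.add_residue("ALA", ch)
            top.add_atom("CA", mdtraj.element.carbon, res)
        t = mdtraj.Trajectory(sub.coords[None] / 10.0, top)
        theirs = mdtraj.shrake_rupley(t, probe_radius=0.14, n_sphere_points=960,
                                      mode="atom")[0].sum() * 100.0
        assert total == pytest.approx(theirs, rel=0.02)

    def test_unknown_element(self):
        st_ = _atoms([("X1", "XX", 1, "ALA", "A", (0.0, 0.0, 0.0))])
        with pytest.raises(ValueError, match="van der Waals"):
            en.shrake_rupley_sasa(st_)


class TestSurrogateEnergy:
    def test_no_hydrophobic_sasa_no_charges_is_zero(self):
        st_ = _atoms([("CA", "C", 1, "SER", "A", (0.0, 0.0, 0.0))])
        assert en.surrogate_energy(st_) == 0.0

    def test_sasa_term_scales_with_factor(self):
        st_ = _atoms([("CA", "C", 1, "ALA", "A", (0.0, 0.0, 0.0))])
        sasa = en.hydrophobic_sasa(st_)
        assert en.surrogate_energy(st_) == pytest.approx(0.00592 * sasa)
        # the study's printed factor: 1000 A^2 of hydrophobic surface
        # contributes 5.92 kcal/mol
        assert 0.00592 * 1000.0 == pytest.approx(5.92)

    def test_screened_coulomb_pair(self):
        st_ = _atoms([("OD1", "O", 1, "ASP", "A", (0.0, 0.0, 0.0)),
                      ("NZ", "N", 2, "LYS", "A", (10.0, 0.0, 0.0))])
        # eps(r) = 4r: E = 332 * (-1)(+1) / (4 * 10 * 10)
        assert en.surrogate_energy(st_) == pytest.approx(-0.83)


class TestEnergyTable:
    def test_roundtrip_grouping(self, tmp_path):
        ens, _ = syn.generate_energy_ensembles(4, 50, [0, 1, 2, 3], 0.5, 9)
        path = tmp_path / "e.tsv"
        en.write_energy_table(ens, path)
        back = en.load_energy_table(path)
        assert [e.conformer_id for e in back] == [e.conformer_id for e in ens]
        for a, b in zip(ens, back):
            assert np.allclose(a.energies, b.energies)

    def test_shuffled_rows_same_ensembles(self, tmp_path):
        import pandas as pd
        ens, _ = syn.generate_energy_ensembles(3, 20, [0, 1, 2], 0.3, 5)
        path = tmp_path / "e.tsv"
        en.write_energy_table(ens, path)
        df = pd.read_csv(path, sep="\t")
        shuffled = df.sample(frac=1.0, random_state=0)
        shuffled.to_csv(tmp_path / "s.tsv", sep="\t", index=False)
        back = en.load_energy_table(tmp_path / "s.tsv")
        assert {e.conformer_id for e in back} == {e.conformer_id for e in ens}
        for a in ens:
            b = next(x for x in back if x.conformer_id == a.conformer_id)
            assert np.allclose(np.sort(a.energies), np.sort(b.energies))

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("conformer_id\tenergy_kcal_mol\n")
        assert en.load_energy_table(path) == []

    def test_non_numeric_energy_named_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("conformer_id\tenergy\nA1\t1.0\nA1\toops\n")
        with pytest.raises(ValueError, match="line 2"):
            en.load_energy_table(path)


class TestMCPopulations:
    def test_symmetric_pair_half(self):
        ens, _ = syn.generate_energy_ensembles(2, 1, [0.0, 0.0], 0.0, 1)
        est = en.mc_populations(ens, en.MCConfig(seed=2))
        assert est.populations[0] == pytest.approx(0.5, abs=0.006)
        assert est.visits.sum() == est.n_total == 1_000_000

    def test_boltzmann_ratio_three(self):
        kt = en.BOLTZMANN_K * 298.0
        ens, _ = syn.generate_energy_ensembles(
            2, 1, [0.0, kt * np.log(3.0)], 0.0, 1)
        est = en.mc_populations(ens, en.MCConfig(seed=3))
        se = est.standard_errors
        assert abs(est.populations[0] - 0.75) <= 3 * se[0] + 1e-4

    def test_matches_oracle_on_generated_ensembles(self):
        ens, exact = syn.generate_energy_ensembles(
            4, 20, [0.0, 0.5, 1.5, 3.0], 0.4, 6)
        oracle = en.boltzmann_oracle(ens)
        assert np.allclose(oracle, exact, atol=1e-12)
        est = en.mc_populations(ens, en.MCConfig(seed=8, n_steps=400_000))
        z = np.abs(est.populations - oracle) / est.standard_errors
        assert z.max() <= 3.0

    def test_reproducible_under_seed(self):
        ens, _ = syn.generate_energy_ensembles(3, 10, [0, 1, 2], 0.2, 4)
        a = en.mc_populations(ens, en.MCConfig(seed=5, n_steps=50_000))
        b = en.mc_populations(ens, en.MCConfig(seed=5, n_steps=50_000))
        assert np.array_equal(a.visits, b.visits)

    def test_single_ensemble_warns(self):
        ens, _ = syn.generate_energy_ensembles(1, 5, [0.0], 0.1, 2)
        with pytest.warns(UserWarning, match="single"):
            est = en.mc_populations(ens, en.MCConfig(n_steps=10))
        assert est.populations.tolist() == [1.0]

    def test_non_finite_energy_rejected(self):
        with pytest.raises(ValueError):
            en.EnergyEnsemble("X", [np.nan, 1.0])


class TestBoltzmannOracle:
    def test_uniform_for_equal_energy_equal_size(self):
        ens = [en.EnergyEnsemble(f"C{k}", np.zeros(7)) for k in range(4)]
        assert np.allclose(en.boltzmann_oracle(ens), 0.25)

    def test_softmax_for_single_conformations(self):
        energies = [0.0, 0.7, 1.9]
        ens = [en.EnergyEnsemble(f"C{k}", [e]) for k, e in enumerate(energies)]
        kt = en.BOLTZMANN_K * 298.0
        w = np.exp(-np.array(energies) / kt)
        assert np.allclose(en.boltzmann_oracle(ens), w / w.sum())

    @given(shift=st.floats(-500.0, 500.0))
    def test_shift_invariance(self, shift):
        ens, _ = syn.generate_energy_ensembles(3, 8, [0, 1, 4], 0.5, 7)
        base = en.boltzmann_oracle(ens)
        shifted = [en.EnergyEnsemble(e.conformer_id, e.energies + shift)
                   for e in ens]
        assert np.allclose(en.boltzmann_oracle(shifted), base, atol=1e-10)

    def test_monotone_in_mean_energy_single_conformations(self):
        ens = [en.EnergyEnsemble(f"C{k}", [float(k)]) for k in range(5)]
        pops = en.boltzmann_oracle(ens)
        assert np.all(np.diff(pops) < 0)

    def test_temperature_limits(self):
        ens = [en.EnergyEnsemble("lo", [0.0, 0.1]),
               en.EnergyEnsemble("hi", [5.0, 5.1])]
        cold = en.boltzmann_oracle(ens, temperature=1e-3)
        assert cold[0] == pytest.approx(1.0, abs=1e-9)
        hot = en.boltzmann_oracle(ens, temperature=1e9)
        assert np.allclose(hot, 0.5, atol=1e-3)


class TestRelativeEnergy:
    def test_single_ensemble_is_zero(self):
        ens = [en.EnergyEnsemble("A1", [3.0, 4.0])]
        df = en.relative_conformational_energy(ens)
        assert df.relative.tolist() == [0.0]

    def test_two_ensembles_shifted(self):
        ens = [en.EnergyEnsemble("A1", [10.0]), en.EnergyEnsemble("A2", [12.0])]
        df = en.relative_conformational_energy(ens)
        assert df.relative.tolist() == [0.0, 2.0]

    def test_generated_offsets_recovered(self):
        offsets = [0.0, 1.0, 3.0, 7.0]
        ens, _ = syn.generate_energy_ensembles(4, 500, offsets, 0.1, 12)
        df = en.relative_conformational_energy(ens)
        for rel, off, se_ in zip(df.relative, offsets, df.se):
            assert abs(rel - off) <= 3 * (se_ + df.se.iloc[0]) + 1e-9
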