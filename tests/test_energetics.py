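"""MM/GBSA terms against closed forms and independent numerical oracles."""

import numpy as np
import pandas as pd
import pytest

from conftest import descreening_integral_quadrature, shrake_rupley_sasa
from mdfingerprint import synth
from mdfingerprint.core import Selection, Trajectory, apply_parameters
from mdfingerprint.energetics import (COULOMB_CONSTANT, EnergyDecomposition,
                                      GBSAOptions, HBondCriterion,
                                      born_radii, coulomb_energy,
                                      debye_kappa, delta_occupancy,
                                      gb_energy, hbond_occupancy,
                                      lcpo_sasa, lj_energy,
                                      mmgbsa_ensemble, mmgbsa_snapshot,
                                      pick_frames)


class TestCoulomb:
    def test_unit_charges_reference_distance(self):
        coords = np.array([[0.0, 0, 0], [3.320636, 0, 0]])
        e = coulomb_energy(coords, np.array([1.0, -1.0]))
        assert e == pytest.approx(-100.0, abs=1e-9)

    def test_single_atom_zero(self):
        assert coulomb_energy(np.zeros((1, 3)), np.array([2.0])) == 0.0

    def test_dielectric_scaling(self):
        coords = np.random.default_rng(0).normal(size=(4, 3)) * 5
        q = np.array([1.0, -0.5, 0.3, 0.7])
        e1 = coulomb_energy(coords, q, 1.0)
        e2 = coulomb_energy(coords, q, 2.0)
        assert e2 == pytest.approx(e1 / 2.0)

    def test_coincident_charges_rejected(self):
        coords = np.zeros((2, 3))
        with pytest.raises(ValueError, match="coincident"):
            coulomb_energy(coords, np.array([1.0, 1.0]))


class TestLennardJones:
    def test_minimum_depth(self):
        eps = np.array([0.2, 0.45])
        rh = np.array([1.8, 1.6])
        rmin = rh.sum()
        coords = np.array([[0.0, 0, 0], [rmin, 0, 0]])
        e = lj_energy(coords, eps, rh)
        assert e == pytest.approx(-np.sqrt(eps[0] * eps[1]), abs=1e-12)

    def test_zero_crossing(self):
        eps = np.array([0.1, 0.1])
        rh = np.array([1.7, 1.7])
        r0 = rh.sum() * 2.0 ** (-1.0 / 6.0)
        coords = np.array([[0.0, 0, 0], [r0, 0, 0]])
        assert lj_energy(coords, eps, rh) == pytest.approx(0.0, abs=1e-10)

    def test_matches_independent_pair_loop(self):
        rng = np.random.default_rng(4)
        coords = rng.uniform(0, 8, (4, 3))
        eps = rng.uniform(0.05, 0.3, 4)
        rh = rng.uniform(1.3, 2.0, 4)
        ref = 0.0
        for i in range(4):
            for j in range(i + 1, 4):
                d = np.linalg.norm(coords[i] - coords[j])
                eij = np.sqrt(eps[i] * eps[j])
                rr = (rh[i] + rh[j]) / d
                ref += eij * (rr ** 12 - 2 * rr ** 6)
        assert lj_energy(coords, eps, rh) == pytest.approx(ref, abs=1e-10)


class TestBornRadii:
    def test_isolated_atom_offset(self):
        r = born_radii(np.zeros((1, 3)), np.array([1.5]))
        assert r[0] == pytest.approx(1.41, abs=1e-12)

    def test_burial_increases_radius(self):
        lone = born_radii(np.zeros((1, 3)), np.array([1.5]))[0]
        # surround with an octahedron of neighbors
        shell = 3.0 * np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                                [0, -1, 0], [0, 0, 1], [0, 0, -1]])
        coords = np.vstack([np.zeros(3), shell])
        radii = np.full(7, 1.5)
        buried = born_radii(coords, radii)[0]
        assert buried > lone

    @pytest.mark.parametrize("d", [2.0, 3.5, 6.0])
    def test_two_atom_descreening_matches_quadrature(self, d):
        rho = np.array([1.5, 1.8])
        screen = 0.8
        offset = 0.09
        coords = np.array([[0.0, 0, 0], [d, 0, 0]])
        eff = born_radii(coords, rho, screen)
        # reconstruct atom 0's effective radius from the numerically
        # integrated descreening term
        rho_red = rho - offset
        i_num = descreening_integral_quadrature(d, rho_red[0],
                                                screen * rho_red[1])
        psi = rho_red[0] * i_num
        alpha, beta, gamma = 1.0, 0.8, 4.85
        inv = 1.0 / rho_red[0] - np.tanh(
            alpha * psi - beta * psi ** 2 + gamma * psi ** 3) / rho[0]
        assert eff[0] == pytest.approx(1.0 / inv, abs=1e-8)


class TestGBEnergy:
    @pytest.mark.parametrize("radius", [1.0, 2.0, 3.0, 4.0])
    @pytest.mark.parametrize("charge", [1.0, -1.0, 2.0, -2.0])
    def test_born_ion_limit(self, radius, charge):
        e = gb_energy(np.zeros((1, 3)), np.array([charge]),
                      np.array([radius]), salt_molar=0.0)
        born = -COULOMB_CONSTANT / 2.0 * (1.0 - 1.0 / 80.0) \
            * charge ** 2 / radius
        assert e == pytest.approx(born, abs=0.1)

    def test_zero_charges(self):
        coords = np.random.default_rng(0).normal(size=(5, 3))
        e = gb_energy(coords, np.zeros(5), np.full(5, 1.5))
        assert e == 0.0

    def test_magnitude_monotone_in_salt(self):
        coords = np.array([[0.0, 0, 0], [4.0, 0, 0]])
        q = np.array([1.0, 1.0])
        r = np.array([2.0, 2.0])
        energies = [gb_energy(coords, q, r, salt_molar=c)
                    for c in (0.0, 0.15, 0.4, 1.0, 5.0)]
        mags = [abs(e) for e in energies]
        assert mags == sorted(mags)

    def test_rigid_motion_invariance(self):
        from scipy.spatial.transform import Rotation
        rng = np.random.default_rng(1)
        coords = rng.normal(size=(6, 3)) * 3
        q = rng.normal(size=6)
        reff = rng.uniform(1.2, 2.5, 6)
        e1 = gb_energy(coords, q, reff)
        rot = Rotation.from_euler("zyx", [20, 45, 70],
                                  degrees=True).as_matrix()
        e2 = gb_energy(coords @ rot.T + 11.0, q, reff)
        assert e2 == pytest.approx(e1, abs=1e-9)

    def test_debye_length_matches_textbook(self):
        # 1:1 electrolyte at 25 C in water (eps 78.5):
        # lambda_D ~ 3.04 A / sqrt(I[M])
        kappa = debye_kappa(0.1, eps_out=78.5)
        assert 1.0 / kappa == pytest.approx(3.04 / np.sqrt(0.1), rel=0.005)


class TestLcpoSasa:
    def test_isolated_atom_full_sphere(self):
        per, tot = lcpo_sasa(np.zeros((1, 3)), np.array([1.7]))
        assert tot == pytest.approx(4 * np.pi * (1.7 + 1.4) ** 2, abs=1e-9)

    def test_separated_atoms_additive(self):
        coords = np.array([[0.0, 0, 0], [50.0, 0, 0]])
        radii = np.array([1.5, 2.0])
        per, tot = lcpo_sasa(coords, radii)
        expected = sum(4 * np.pi * (r + 1.4) ** 2 for r in radii)
        assert tot == pytest.approx(expected, abs=1e-9)

    def test_missing_parameter_key_named(self):
        with pytest.raises(KeyError, match="unobtainium"):
            lcpo_sasa(np.zeros((1, 3)), np.array([1.5]), ["unobtainium"])

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_point_sampling_oracle(self, seed):
        coords, radii = synth.make_sphere_cluster(seed)
        _, total = lcpo_sasa(coords, radii)
        ref = shrake_rupley_sasa(coords, radii)
        assert total == pytest.approx(ref, rel=0.05)


def _toy(receptor, ligand):
    top, traj, table = synth.make_toy_complex(receptor, ligand)
    rec = top.select(chain="R")
    lig = top.select(chain="L")
    return top, traj, rec, lig


class TestMmgbsaSnapshot:
    def test_separated_uncharged_all_zero(self):
        top, traj, rec, lig = _toy(
            [((0.0, 0, 0), 0.0, 0.0, 1.7, 1.5),
             ((3.0, 0, 0), 0.0, 0.0, 1.7, 1.5)],
            [((200.0, 0, 0), 0.0, 0.0, 1.7, 1.5)])
        dec = mmgbsa_snapshot(top, traj.coordinates[0], rec, lig)
        for v in dec.components().values():
            assert v == pytest.approx(0.0, abs=1e-9)
        assert dec.g_total == pytest.approx(0.0, abs=1e-9)

    def test_internal_term_identically_zero(self):
        rng = np.random.default_rng(0)
        top, traj, rec, lig = _toy(
            [(tuple(rng.uniform(0, 5, 3)), 0.3, 0.1, 1.8, 1.6)
             for _ in range(3)],
            [(tuple(rng.uniform(6, 9, 3)), -0.4, 0.1, 1.8, 1.6)
             for _ in range(2)])
        dec = mmgbsa_snapshot(top, traj.coordinates[0], rec, lig)
        assert dec.e_internal == 0.0

    def test_two_particle_electrostatics(self):
        top, traj, rec, lig = _toy(
            [((0.0, 0, 0), 1.0, 0.0, 1.0, 1.5)],
            [((3.320636, 0, 0), -1.0, 0.0, 1.0, 1.5)])
        opt = GBSAOptions(salt_molar=0.0, gamma=0.0)
        dec = mmgbsa_snapshot(top, traj.coordinates[0], rec, lig, opt)
        assert dec.e_electrostatic == pytest.approx(-100.0, abs=1e-9)

    def test_decomposition_identity_random_systems(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            top, traj, rec, lig = _toy(
                [(tuple(rng.uniform(0, 6, 3)), rng.normal(), 0.1, 1.8, 1.6)
                 for _ in range(4)],
                [(tuple(rng.uniform(8, 12, 3)), rng.normal(), 0.1, 1.8,
                  1.6) for _ in range(3)])
            dec = mmgbsa_snapshot(top, traj.coordinates[0], rec, lig)
            dec.check_identity(atol=1e-6)

    def test_overlapping_selections_rejected(self):
        top, traj, rec, lig = _toy(
            [((0.0, 0, 0), 0.0, 0.0, 1.7, 1.5)],
            [((5.0, 0, 0), 0.0, 0.0, 1.7, 1.5)])
        both = Selection(np.arange(2))
        with pytest.raises(ValueError, match="overlap"):
            mmgbsa_snapshot(top, traj.coordinates[0], both, lig)


class TestMmgbsaEnsemble:
    def _breathing_system(self, n_frames, offsets):
        top, traj, rec, lig = _toy(
            [((0.0, 0, 0), 1.0, 0.0, 1.0, 1.5)],
            [((3.0, 0, 0), -1.0, 0.0, 1.0, 1.5)])
        coords = np.repeat(traj.coordinates, n_frames, axis=0)
        coords[:, 1, 0] += offsets
        traj = Trajectory(coords, np.full((n_frames, 3), 500.0),
                          np.arange(1.0, n_frames + 1.0))
        return top, traj, rec, lig

    def test_identical_frames_zero_sem(self):
        top, traj, rec, lig = self._breathing_system(10, np.zeros(10))
        dec = mmgbsa_ensemble(top, traj, rec, lig,
                              frame_indices=np.arange(10))
        single = mmgbsa_snapshot(top, traj.coordinates[0], rec, lig)
        assert dec.g_total == pytest.approx(single.g_total, abs=1e-9)
        assert dec.sem == pytest.approx(0.0, abs=1e-12)

    def test_alternating_energies_closed_form(self):
        # distances alternate 3.0 / 4.0 A: electrostatic snapshots are two
        # exactly known values; mean and sem follow from arithmetic
        n = 50
        offs = np.where(np.arange(n) % 2 == 0, 0.0, 1.0)
        top, traj, rec, lig = self._breathing_system(n, offs)
        opt = GBSAOptions(salt_molar=0.0, gamma=0.0)
        dec = mmgbsa_ensemble(top, traj, rec, lig,
                              frame_indices=np.arange(n), options=opt)
        e1 = -COULOMB_CONSTANT / 3.0
        e2 = -COULOMB_CONSTANT / 4.0
        assert dec.e_electrostatic == pytest.approx((e1 + e2) / 2, rel=1e-9)
        vals = np.where(np.arange(n) % 2 == 0, e1, e2)
        sem = vals.std(ddof=1) / np.sqrt(n)
        assert dec.component_sem["e_electrostatic"] == pytest.approx(
            sem, rel=1e-6)

    def test_sem_scales_inverse_sqrt_n(self):
        rng = np.random.default_rng(6)
        offs = rng.normal(0, 0.2, 200)
        top, traj, rec, lig = self._breathing_system(200, offs)
        opt = GBSAOptions(salt_molar=0.0, gamma=0.0)
        d50 = mmgbsa_ensemble(top, traj, rec, lig,
                              frame_indices=np.arange(50), options=opt)
        d200 = mmgbsa_ensemble(top, traj, rec, lig,
                               frame_indices=np.arange(200), options=opt)
        assert d200.sem < d50.sem

    def test_snapshot_picker_yields_fifty(self):
        # 500 ns trajectory at 1 ns/frame, final 100 ns every 2 ns
        times = np.arange(1.0, 501.0)
        idx = pick_frames(times, last_ns=100.0, interval_ns=2.0)
        assert len(idx) == 50

    def test_too_few_snapshots_rejected(self):
        top, traj, rec, lig = self._breathing_system(5, np.zeros(5))
        with pytest.raises(ValueError, match="2 snapshots"):
            mmgbsa_ensemble(top, traj, rec, lig,
                            frame_indices=np.array([0]))


class TestHBondOccupancy:
    def test_planted_full_occupancy(self):
        top, traj, _ = synth.make_hbond_traj(synth.HBondPlantSpec(
            [("N1", "H1", "O1", 1.0)], n_frames=100, seed=0))
        tab = hbond_occupancy(top, traj)
        row = tab[(tab.donor_atom == "N1") & (tab.acceptor_atom == "O1")]
        assert row["occupancy_pct"].iloc[0] == 100.0

    def test_planted_half_occupancy(self):
        top, traj, truth = synth.make_hbond_traj(synth.HBondPlantSpec(
            [("N1", "H1", "O1", 0.5)], n_frames=2000, seed=1))
        tab = hbond_occupancy(top, traj)
        row = tab[(tab.donor_atom == "N1") & (tab.acceptor_atom == "O1")]
        got = row["occupancy_pct"].iloc[0]
        assert got == pytest.approx(100 * truth["realized_occupancy"][0],
                                    abs=1e-9)
        assert abs(got - 50.0) < 3.0

    def test_pair_beyond_distance_cutoff_zero(self):
        top, traj, _ = synth.make_hbond_traj(synth.HBondPlantSpec(
            [("N1", "H1", "O1", 1.0)],
            bonded_geometry=(3.4, 179.0), n_frames=10, seed=0))
        tab = hbond_occupancy(top, traj, HBondCriterion(3.0, 150.0))
        row = tab[(tab.donor_atom == "N1") & (tab.acceptor_atom == "O1")]
        assert row["occupancy_pct"].iloc[0] == 0.0

    def test_explicit_donor_without_hydrogen_warns(self):
        top, traj, _ = synth.make_hbond_traj(synth.HBondPlantSpec(
            [("N1", "H1", "O1", 1.0)], n_frames=5, seed=0))
        acceptor_only = top.select(name="O1", label="acceptor as donor")
        with pytest.warns(UserWarning, match="no attached hydrogen"):
            hbond_occupancy(top, traj, donors=acceptor_only)


class TestDeltaOccupancy:
    def _table(self, occs):
        return pd.DataFrame([
            dict(donor_chain="A", donor_resid=i + 1, donor_atom="N",
                 acceptor_chain="B", acceptor_resid=i + 1,
                 acceptor_atom="O", occupancy_pct=o, n_frames=100)
            for i, o in enumerate(occs)])

    def test_identical_zero_and_example(self):
        t = self._table([40.0, 70.0])
        assert (delta_occupancy(t, t)["delta_pct"] == 0).all()
        d = delta_occupancy(self._table([80.0]), self._table([30.0]))
        assert d["delta_pct"].iloc[0] == pytest.approx(50.0)

    def test_antisymmetry(self):
        a = self._table([80.0, 10.0])
        b = self._table([30.0, 55.0])
        np.testing.assert_allclose(
            delta_occupancy(a, b)["delta_pct"],
            -delta_occupancy(b, a)["delta_pct"])

    def test_pair_mismatch_rejected(self):
        a = self._table([80.0])
        b = self._table([30.0, 55.0])
        with pytest.raises(ValueError, match="pair lists differ"):
            delta_occupancy(a, b)


class TestDecompositionContainer:
    def test_identity_check(self):
        dec = EnergyDecomposition(0.0, -10.0, -5.0, 8.0, -1.0, -8.0)
        dec.check_identity()
        bad = EnergyDecomposition(0.0, -10.0, -5.0, 8.0, -1.0, -9.0)
        with pytest.raises(AssertionError):
            bad.check_identity()
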