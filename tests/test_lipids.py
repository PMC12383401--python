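"""Lipid contacts and acyl-chain order parameters."""

import numpy as np
import pandas as pd
import pytest

from mdfingerprint import synth
from mdfingerprint.core import Selection, Topology, Trajectory
from mdfingerprint.lipids import (delta_occupancy_profile, delta_scd,
                                  lipid_chains, lipid_occupancy,
                                  residue_lipid_min_distance, scd_profile,
                                  ScdProfile)


def _probe_system(lipid_positions_per_frame, ca_pos=(0.0, 0.0, 0.0),
                  box=200.0):
    """One CA residue plus one lipid atom with scripted positions."""
    rows = [
        dict(name="CA", element="C", resid=1, resname="ALA", chain="A",
             segment="protein", mass=12.0, charge=np.nan,
             lj_epsilon=np.nan, lj_rmin_half=np.nan, born_radius=np.nan),
        dict(name="C31", element="C", resid=1, resname="POPC", chain="L",
             segment="lipid", mass=12.0, charge=np.nan,
             lj_epsilon=np.nan, lj_rmin_half=np.nan, born_radius=np.nan),
    ]
    top = Topology(pd.DataFrame(rows))
    n = len(lipid_positions_per_frame)
    coords = np.zeros((n, 2, 3))
    coords[:, 0] = ca_pos
    coords[:, 1] = lipid_positions_per_frame
    traj = Trajectory(coords, np.full((n, 3), box),
                      np.arange(n, dtype=float))
    return top, traj


class TestMinDistance:
    def test_static_seven_angstrom(self):
        top, traj = _probe_system([(7.0, 0, 0)] * 3)
        prof = residue_lipid_min_distance(
            top, traj, top.select(segment="protein"),
            top.select(segment="lipid"))
        assert prof.entries["value"].iloc[0] == pytest.approx(7.0)

    def test_alternating_distances_average(self):
        top, traj = _probe_system([(5.0, 0, 0), (9.0, 0, 0)] * 5)
        prof = residue_lipid_min_distance(
            top, traj, top.select(segment="protein"),
            top.select(segment="lipid"))
        assert prof.entries["value"].iloc[0] == pytest.approx(7.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        top, traj, _ = synth.make_bilayer_traj(synth.BilayerSpec(
            4, 5, ("isotropic",), n_frames=6, seed=1))
        # add a 3-residue protein
        prot_rows = [dict(name="CA", element="C", resid=i + 1,
                          resname="ALA", chain="A", segment="protein",
                          mass=12.0, charge=np.nan, lj_epsilon=np.nan,
                          lj_rmin_half=np.nan, born_radius=np.nan)
                     for i in range(3)]
        prot = Topology(pd.DataFrame(prot_rows))
        pc = rng.uniform(10, 40, (traj.n_frames, 3, 3))
        from mdfingerprint.pipeline import _concat_systems
        ptraj = Trajectory(pc, traj.box, traj.frame_times)
        mtop, mtraj = _concat_systems(top, traj, prot, ptraj)
        prof = residue_lipid_min_distance(
            mtop, mtraj, mtop.select(segment="protein"),
            mtop.select(segment="lipid"))
        # brute force double loop with minimum-image wrapping
        from mdfingerprint.core import min_image_distance
        lip = mtop.select(segment="lipid").atom_indices
        ca = [i for i in mtop.select(segment="protein").atom_indices]
        for r, ca_idx in enumerate(ca):
            per_frame = []
            for f in range(mtraj.n_frames):
                dmin = min(
                    min_image_distance(mtraj.coordinates[f, ca_idx],
                                       mtraj.coordinates[f, j],
                                       mtraj.box[f])
                    for j in lip)
                per_frame.append(dmin)
            assert prof.entries["value"].iloc[r] == pytest.approx(
                np.mean(per_frame), abs=1e-9)


class TestOccupancy:
    def test_always_within_cutoff(self):
        top, traj = _probe_system([(4.0, 0, 0)] * 5)
        prof = lipid_occupancy(top, traj, top.select(segment="protein"),
                               top.select(segment="lipid"), cutoff=5.0)
        assert prof.entries["value"].iloc[0] == 100.0

    def test_never_within_cutoff(self):
        top, traj = _probe_system([(9.0, 0, 0)] * 5)
        prof = lipid_occupancy(top, traj, top.select(segment="protein"),
                               top.select(segment="lipid"), cutoff=5.0)
        assert prof.entries["value"].iloc[0] == 0.0

    def test_planted_thirty_percent_exact(self):
        positions = [(4.0, 0, 0)] * 3 + [(9.0, 0, 0)] * 7
        top, traj = _probe_system(positions)
        prof = lipid_occupancy(top, traj, top.select(segment="protein"),
                               top.select(segment="lipid"), cutoff=5.0)
        assert prof.entries["value"].iloc[0] == pytest.approx(30.0)

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(2)
        positions = rng.uniform(2, 12, (30, 3))
        top, traj = _probe_system(positions)
        prot = top.select(segment="protein")
        lip = top.select(segment="lipid")
        occs = [lipid_occupancy(top, traj, prot, lip, c)
                .entries["value"].iloc[0] for c in (3.0, 5.0, 8.0, 12.0)]
        assert occs == sorted(occs)


class TestDeltaOccupancyProfile:
    def _prof(self, values):
        from mdfingerprint.core import PerResidueProfile
        rows = [dict(chain="A", resid=i + 1, value=v)
                for i, v in enumerate(values)]
        return PerResidueProfile(pd.DataFrame(rows), "occupancy_pct")

    def test_identity_and_example(self):
        a = self._prof([100.0, 40.0])
        np.testing.assert_allclose(
            delta_occupancy_profile(a, a).entries["value"], 0.0)
        d = delta_occupancy_profile(self._prof([100.0]), self._prof([40.0]))
        assert d.entries["value"].iloc[0] == pytest.approx(60.0)

    def test_antisymmetry_and_mismatch(self):
        a = self._prof([80.0, 20.0])
        b = self._prof([50.0, 60.0])
        np.testing.assert_allclose(
            delta_occupancy_profile(a, b).entries["value"].to_numpy(),
            -delta_occupancy_profile(b, a).entries["value"].to_numpy())
        with pytest.raises(ValueError, match="differ"):
            delta_occupancy_profile(a, self._prof([1.0]))


class TestScd:
    @pytest.mark.parametrize("theta,expected", [
        (0.0, 1.0), (30.0, 0.625), (54.7356, 0.0), (90.0, -0.5)])
    def test_fixed_tilt_closed_form(self, theta, expected):
        top, traj, _ = synth.make_bilayer_traj(synth.BilayerSpec(
            4, 8, ("fixed_angle", theta), n_frames=3, seed=0))
        for chain_id in ("sn1", "sn2"):
            prof = scd_profile(top, traj, chain_id)
            np.testing.assert_allclose(prof.entries["s_cd"], expected,
                                       atol=1e-6)

    def test_isotropic_near_zero(self):
        top, traj, _ = synth.make_bilayer_traj(synth.BilayerSpec(
            100, 8, ("isotropic",), n_frames=500, seed=5))
        prof = scd_profile(top, traj, "sn1")
        assert np.all(np.abs(prof.entries["s_cd"]) < 0.01)

    def test_bounds_for_arbitrary_tilt(self):
        for seed in range(3):
            top, traj, _ = synth.make_bilayer_traj(synth.BilayerSpec(
                4, 6, ("wrapped_gaussian", 45.0, 40.0), n_frames=20,
                seed=seed))
            prof = scd_profile(top, traj, "sn2")
            v = prof.entries["s_cd"].to_numpy()
            assert np.all(v >= -0.5 - 1e-9) and np.all(v <= 1.0 + 1e-9)

    def test_chain_axis_mode_agrees_on_rigid_rods(self):
        top, traj, _ = synth.make_bilayer_traj(synth.BilayerSpec(
            4, 8, ("fixed_angle", 25.0), n_frames=2, seed=0))
        per = scd_profile(top, traj, "sn1", mode="per_carbon")
        ax = scd_profile(top, traj, "sn1", mode="chain_axis")
        assert ax.entries["s_cd"].iloc[0] == pytest.approx(
            per.entries["s_cd"].iloc[0], abs=1e-9)

    def test_shell_filter_excludes_remote_lipids(self):
        # ordered bilayer far from the protein probe; with a tight shell
        # no lipid qualifies
        top, traj, _ = synth.make_bilayer_traj(synth.BilayerSpec(
            4, 6, ("fixed_angle", 0.0), n_frames=2, seed=0))
        probe_rows = [dict(name="CA", element="C", resid=1, resname="ALA",
                           chain="A", segment="protein", mass=12.0,
                           charge=np.nan, lj_epsilon=np.nan,
                           lj_rmin_half=np.nan, born_radius=np.nan)]
        probe = Topology(pd.DataFrame(probe_rows))
        pc = np.full((traj.n_frames, 1, 3), 150.0)
        from mdfingerprint.pipeline import _concat_systems
        ptraj = Trajectory(pc, traj.box, traj.frame_times)
        mtop, mtraj = _concat_systems(top, traj, probe, ptraj)
        with pytest.raises(ValueError, match="shell"):
            scd_profile(mtop, mtraj, "sn1",
                        protein_selection=mtop.select(segment="protein"),
                        shell=6.0)

    def test_short_chain_rejected(self):
        top, traj, _ = synth.make_bilayer_traj(synth.BilayerSpec(
            4, 3, ("fixed_angle", 0.0), n_frames=1, seed=0))
        # 3 carbons is the minimum; synthesize a 2-carbon rule instead
        with pytest.raises(ValueError):
            scd_profile(top, traj, "sn3",
                        name_rules={"sn3": r"^NOPE(\d+)$"})


class TestDeltaScd:
    def _prof(self, values, chain="sn1"):
        return ScdProfile(chain, pd.DataFrame(
            {"carbon": np.arange(2, 2 + len(values)), "s_cd": values}))

    def test_identity_and_example(self):
        a = self._prof([0.3, 0.2])
        np.testing.assert_allclose(delta_scd(a, a)["delta_s_cd"], 0.0)
        d = delta_scd(self._prof([0.0]), self._prof([1.0]))
        assert d["delta_s_cd"].iloc[0] == pytest.approx(-1.0)

    def test_antisymmetry_and_mismatch(self):
        a = self._prof([0.5, -0.1])
        b = self._prof([0.2, 0.4])
        np.testing.assert_allclose(
            delta_scd(a, b)["delta_s_cd"].to_numpy(),
            -delta_scd(b, a)["delta_s_cd"].to_numpy())
        with pytest.raises(ValueError, match="carbon"):
            delta_scd(a, self._prof([0.1]))


class TestChainExtraction:
    def test_charmm_prefix_rules(self):
        top, _, _ = synth.make_bilayer_traj(synth.BilayerSpec(
            2, 5, ("fixed_angle", 0.0), n_frames=1, seed=0))
        sn1 = lipid_chains(top, "sn1")
        sn2 = lipid_chains(top, "sn2")
        assert len(sn1) == len(sn2) == 4  # 2 per leaflet
        names = top.atoms["name"].to_numpy()
        assert all(names[c[0]] == "C31" for c in sn1)
        assert all(names[c[0]] == "C21" for c in sn2)
        # carbons ordered along the chain
        for c in sn1:
            nums = [int(names[i][2:]) for i in c]
            assert nums == sorted(nums)
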