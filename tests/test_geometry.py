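"""Superposition and scalar metrics: RMSD, RMSF, Rg, distances, rotamers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from hemodyn.ensemble import Ensemble
from hemodyn.geometry import (DegenerateGeometryError, differential_profile,
                              dihedral, distance_series, FluctuationProfile,
                              gyration_series, kabsch_superpose, rmsd_series,
                              rmsf_profile, rotamer_bin,
                              sidechain_conformation_series)
from hemodyn.topology import Topology
from oracles import grid_rmsd


def point_topology(n, masses=None, names=None):
    return Topology(
        names=np.array(names if names is not None else [f"A{i}" for i in range(n)],
                       dtype=object),
        elements=np.array(["C"] * n, dtype=object),
        resids=np.arange(1, n + 1),
        resnames=np.array(["GLY"] * n, dtype=object),
        chains=np.array(["A"] * n, dtype=object),
        vdw_radii=np.full(n, 1.7),
        masses=np.asarray(masses if masses is not None else np.ones(n), dtype=float),
    )


class TestKabsch:
    def test_identity_and_pure_translation_give_zero_rmsd(self, rng):
        ref = rng.normal(size=(6, 3)) * 4
        _, r0 = kabsch_superpose(ref, ref)
        assert r0 == pytest.approx(0.0, abs=1e-12)
        _, r1 = kabsch_superpose(ref + [5.0, 0.0, 0.0], ref)
        assert r1 == pytest.approx(0.0, abs=1e-10)

    def test_agrees_with_rotation_grid_oracle(self, rng):
        ref = rng.normal(size=(5, 3)) * 3
        R = Rotation.random(random_state=7).as_matrix()
        mobile = ref @ R.T + np.array([1.0, -2.0, 0.5])
        mobile[3] += rng.normal(size=3) * (0.5 / np.sqrt(3))
        _, rmsd = kabsch_superpose(mobile, ref)
        assert rmsd == pytest.approx(grid_rmsd(mobile, ref), abs=1e-3)

    def test_symmetric_and_rigid_invariant(self, rng):
        a = rng.normal(size=(8, 3)) * 2
        b = a + rng.normal(size=(8, 3)) * 0.3
        _, r_ab = kabsch_superpose(a, b)
        _, r_ba = kabsch_superpose(b, a)
        assert r_ab == pytest.approx(r_ba, abs=1e-9)
        R = Rotation.random(random_state=1).as_matrix()
        _, r_rot = kabsch_superpose(a @ R.T + 3.0, b)
        assert r_rot == pytest.approx(r_ab, abs=1e-9)

    def test_degenerate_input_rejected(self):
        line = np.stack([np.arange(4.0), np.zeros(4), np.zeros(4)], axis=1)
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(line, line)
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestRmsdSeries:
    def test_static_ensemble_gives_zeros(self, rng):
        ref = rng.normal(size=(10, 3)) * 3
        ens = Ensemble(topology=point_topology(10),
                       coords=np.repeat(ref[None], 4, axis=0))
        values, mean, sd = rmsd_series(ens, ref)
        np.testing.assert_allclose(values, 0.0, atol=1e-10)
        assert mean == pytest.approx(0.0, abs=1e-10) and sd == pytest.approx(0.0, abs=1e-10)

    def test_single_displaced_atom_bounded_by_naive_rmsd(self, rng):
        n, d = 12, 0.9
        ref = rng.normal(size=(n, 3)) * 5
        frame = ref.copy()
        frame[4, 0] += d
        ens = Ensemble(topology=point_topology(n), coords=frame[None])
        values, _, _ = rmsd_series(ens, ref)
        naive = d / np.sqrt(n)
        assert values[0] <= naive + 1e-12
        assert values[0] == pytest.approx(grid_rmsd(frame, ref), abs=1e-3)


class TestRmsf:
    def test_two_frame_symmetric_displacement(self, rng):
        # many spread-out anchor atoms so the mean-fit barely absorbs the
        # planted ±1 Å displacement of one residue
        n = 40
        base = rng.normal(size=(n, 3)) * 30
        top = point_topology(n, names=["CA"] * n)
        coords = np.stack([base, base])
        coords[0, 2, 0] += 1.0
        coords[1, 2, 0] -= 1.0
        ens = Ensemble(topology=top, coords=coords)
        prof = rmsf_profile(ens, selection=np.arange(n))
        assert prof.rmsf[2] == pytest.approx(1.0, rel=0.05)

    def test_identical_frames_have_zero_rmsf(self, rng):
        base = rng.normal(size=(6, 3)) * 4
        ens = Ensemble(topology=point_topology(6, names=["CA"] * 6),
                       coords=np.repeat(base[None], 3, axis=0))
        prof = rmsf_profile(ens, selection=np.arange(6))
        np.testing.assert_allclose(prof.rmsf, 0.0, atol=1e-9)

    def test_isotropic_gaussian_matches_sqrt3_sigma(self, rng):
        n_res, sigma = 100, 0.5
        base = rng.normal(size=(n_res, 3)) * 20
        coords = base[None] + rng.normal(size=(10000, n_res, 3)) * sigma
        ens = Ensemble(topology=point_topology(n_res, names=["CA"] * n_res),
                       coords=coords)
        prof = rmsf_profile(ens, selection=np.arange(n_res))
        assert prof.rmsf.mean() == pytest.approx(np.sqrt(3) * sigma, abs=0.02)

    def test_self_concatenation_leaves_rmsf_unchanged(self, rng):
        coords = rng.normal(size=(20, 8, 3))
        top = point_topology(8, names=["CA"] * 8)
        one = rmsf_profile(Ensemble(topology=top, coords=coords),
                           selection=np.arange(8))
        two = rmsf_profile(
            Ensemble(topology=top, coords=np.concatenate([coords, coords])),
            selection=np.arange(8))
        np.testing.assert_allclose(one.rmsf, two.rmsf, atol=1e-8)

    def test_single_frame_is_an_error(self, rng):
        ens = Ensemble(topology=point_topology(5), coords=rng.normal(size=(1, 5, 3)))
        with pytest.raises(ValueError):
            rmsf_profile(ens, selection=np.arange(5))


class TestGyration:
    def test_analytic_cases(self):
        two = Ensemble(topology=point_topology(2),
                       coords=np.array([[[-1.0, 0, 0], [1, 0, 0]]]))
        _, mean, _ = gyration_series(two)
        assert mean == pytest.approx(1.0)
        one = Ensemble(topology=point_topology(1), coords=np.zeros((1, 1, 3)))
        assert gyration_series(one)[1] == pytest.approx(0.0)
        cube = np.array([[x, y, z] for x in (-1.0, 1) for y in (-1.0, 1)
                         for z in (-1.0, 1)])
        ens = Ensemble(topology=point_topology(8), coords=cube[None])
        assert gyration_series(ens)[1] == pytest.approx(np.sqrt(3))

    def test_rigid_invariance_and_linear_scaling(self, rng):
        coords = rng.normal(size=(1, 9, 3)) * 4
        top = point_topology(9, masses=rng.uniform(1, 12, 9))
        _, rg, _ = gyration_series(Ensemble(topology=top, coords=coords))
        R = Rotation.random(random_state=2).as_matrix()
        moved = coords @ R.T + np.array([3.0, -1.0, 7.0])
        _, rg_moved, _ = gyration_series(Ensemble(topology=top, coords=moved))
        assert rg_moved == pytest.approx(rg, rel=1e-10)
        _, rg_scaled, _ = gyration_series(Ensemble(topology=top, coords=coords * 2.5))
        assert rg_scaled == pytest.approx(2.5 * rg, rel=1e-10)

    def test_zero_mass_rejected(self):
        ens = Ensemble(topology=point_topology(3, masses=np.zeros(3)),
                       coords=np.zeros((1, 3, 3)))
        with pytest.raises(ValueError):
            gyration_series(ens)


class TestDifferentialProfile:
    def _profile(self, values):
        return FluctuationProfile(resids=np.arange(1, len(values) + 1),
                                  rmsf=np.asarray(values, dtype=float))

    def test_identical_profiles_flag_nothing(self):
        p = self._profile([0.3, 0.8, 1.2])
        flags = differential_profile(p, p, threshold=0.01)
        assert flags.flagged.size == 0

    def test_boundary_value_is_flagged_inclusively(self):
        a = self._profile([1.0, 1.0])
        b = self._profile([0.5, 0.6])
        flags = differential_profile(a, b, threshold=0.5)
        assert flags.flagged.tolist() == [1]

    def test_mismatched_residues_rejected(self):
        a = self._profile([1.0, 1.0])
        b = FluctuationProfile(resids=np.array([2, 3]), rmsf=np.array([1.0, 1.0]))
        with pytest.raises(ValueError):
            differential_profile(a, b, threshold=0.5)


class TestDistances:
    def test_static_pair_mean_and_sd(self):
        coords = np.zeros((5, 2, 3))
        coords[:, 1, 0] = 3.0
        ens = Ensemble(topology=point_topology(2), coords=coords)
        series = distance_series(ens, [(0, 1)])[0]
        assert series.mean == pytest.approx(3.0) and series.sd == pytest.approx(0.0)

    def test_percent_deviation_vs_reference_length(self):
        coords = np.zeros((1, 2, 3))
        coords[0, 1, 0] = 2.252
        ens = Ensemble(topology=point_topology(2), coords=coords)
        series = distance_series(ens, [(0, 1)], reference_lengths=[2.0])[0]
        assert series.pct_deviation == pytest.approx(12.6, abs=0.01)

    def test_jittered_sd_matches_monte_carlo(self, rng):
        base = np.zeros((4000, 2, 3))
        base[:, 1, 0] = 5.0
        jitter = rng.normal(size=base.shape) * 0.05
        ens = Ensemble(topology=point_topology(2), coords=base + jitter)
        series = distance_series(ens, [(0, 1)])[0]
        # independent Monte-Carlo oracle with a different stream
        rng2 = np.random.default_rng(999)
        a = rng2.normal(size=(200000, 3)) * 0.05
        b = rng2.normal(size=(200000, 3)) * 0.05 + [5.0, 0, 0]
        oracle_sd = np.linalg.norm(b - a, axis=1).std()
        assert series.sd == pytest.approx(oracle_sd, rel=0.10)

    def test_identical_atom_pair_rejected(self, rng):
        ens = Ensemble(topology=point_topology(3), coords=rng.normal(size=(2, 3, 3)))
        with pytest.raises(ValueError):
            distance_series(ens, [(1, 1)])


class TestDihedralsAndRotamers:
    def test_planar_trans_chain(self):
        pts = np.array([[0.0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0]])
        assert dihedral(*pts) == pytest.approx(180.0)

    @given(st.floats(min_value=-179.9, max_value=180.0))
    @settings(max_examples=40, deadline=None)
    def test_constructed_dihedral_recovered(self, angle):
        rad = np.radians(angle)
        pts = np.array([
            [1.0, 0.0, -1.0],
            [0.0, 0.0, 0.0],
            [0.0, 0.0, 1.0],
            [np.cos(rad), np.sin(rad), 2.0],
        ])
        assert dihedral(*pts) == pytest.approx(angle, abs=1e-6)

    @pytest.mark.parametrize("chi,expected", [
        (60.0, "gauche+"), (0.0, "gauche+"), (119.9, "gauche+"),
        (180.0, "trans"), (120.0, "trans"), (-120.0, "gauche-"),
        (-60.0, "gauche-"), (-0.1, "gauche-"), (150.0, "trans"),
    ])
    def test_rotamer_sector_binning(self, chi, expected):
        assert rotamer_bin(chi) == expected

    def test_sidechain_series_identical_frames(self, default_spec):
        from hemodyn.synthetic import sample_ensemble
        from conftest import clone_spec
        spec = clone_spec(default_spec, n_frames=4,
                          baseline_amplitude=0.0, tail_amplitude=0.0)
        spec.gate.open_prob = {"oxy": 1.0, "deoxy": 1.0}
        for c in spec.planted_contacts:
            c.prob = {"oxy": 1.0, "deoxy": 1.0}
        spec.rotation.mean_deg = {"oxy": 0.0, "deoxy": 0.0}
        spec.rotation.jitter_deg = 0.0
        for loop in spec.loop_ranges:
            loop.amplitude = {"oxy": 0.0, "deoxy": 0.0}
        ens = sample_ensemble(spec, "oxy", 0)
        series = sidechain_conformation_series(ens, spec.gate.residue)
        np.testing.assert_allclose(series.rmsd, 0.0, atol=1e-9)
        assert len(set(series.rotamers[:, 0])) == 1

    def test_gate_rotamer_flip_detected(self, default_spec):
        # noise-free backbone so the anchor superposition is exact and the
        # two planted rotamers appear as two sharply separated RMSD values
        from hemodyn.synthetic import sample_ensemble
        from conftest import clone_spec
        spec = clone_spec(default_spec, n_frames=60, baseline_amplitude=0.0,
                          tail_amplitude=0.0)
        spec.rotation.jitter_deg = 0.0
        spec.rotation.mean_deg = {"oxy": 0.0, "deoxy": 0.0}
        ens = sample_ensemble(spec, "deoxy", 0)
        series = sidechain_conformation_series(ens, spec.gate.residue,
                                               atom_names=("GB", "GG", "GD"))
        values = set(np.round(series.rmsd, 6))
        assert len(values) == 2
        assert series.rmsd.max() > 3.0
        # and the chi-1 rotamer bin flips together with the conformation
        assert len(set(series.rotamers[:, 0])) == 2

    def test_residue_without_sidechain_rejected(self, default_spec):
        from hemodyn.synthetic import sample_ensemble
        from conftest import clone_spec
        spec = clone_spec(default_spec, n_frames=2)
        ens = sample_ensemble(spec, "oxy", 0)
        with pytest.raises(ValueError):
            # plain Cα-only residue on the protein chain
            sidechain_conformation_series(ens, 100, chain="A")
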