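import numpy as np
import pytest

from _oracles import (brute_contact_count, brute_hbonds, kabsch_aligned_rmsd,
                      random_rigid_transform)
from bpmdkit import (AlignedRmsdCV, ProtocolConfig, ScoreSeries, SyntheticSpec,
                     Trajectory, comp_score, constant, contact_count,
                     contact_score, detect_hbonds, linear_ramp,
                     make_toy_complex, pers_score, pose_score,
                     recenter_trajectory, rmsd_series, score_replica,
                     synth_trajectory)
from conftest import random_perturbed_frame


def _series(times_ps, rmsd=None, contacts=None, initial_contacts=6,
            initial_hbonds=frozenset(), present=None):
    n = len(times_ps)
    return ScoreSeries(
        times=np.asarray(times_ps, float),
        rmsd=np.zeros(n) if rmsd is None else np.asarray(rmsd, float),
        n_hbonds=np.zeros(n, int),
        n_contacts=np.full(n, initial_contacts) if contacts is None
        else np.asarray(contacts, int),
        initial_hbonds=initial_hbonds,
        initial_contacts=initial_contacts,
        n_initial_hbonds_present=None if present is None else np.asarray(present, int),
    )


class TestRecenter:
    def _boxed(self, box_length=60.0):
        spec = SyntheticSpec(seed=3, box_length=box_length)
        fx = make_toy_complex(spec)
        traj = synth_trajectory(fx, spec, duration_ns=0.5)
        return fx, traj

    def test_already_centered_frames_unchanged(self):
        fx, traj = self._boxed()
        out = recenter_trajectory(traj, fx.complex)
        # solute was built around the box center; only a rigid translation
        # to the exact center may be applied, so internal geometry is fixed
        d_before = traj.frames[0][:, None, :] - traj.frames[0][None, :, :]
        d_after = out.frames[0][:, None, :] - out.frames[0][None, :, :]
        np.testing.assert_allclose(d_after, d_before, atol=1e-6)

    def test_ligand_wrapped_by_one_box_vector_is_restored(self):
        fx, traj = self._boxed()
        L = traj.box[:3]
        wrapped = traj.frames.copy()
        lig = fx.complex.ligand_indices
        wrapped[:, lig, 0] += L[0]
        t2 = Trajectory(frames=wrapped, times=traj.times, box=traj.box)
        out = recenter_trajectory(t2, fx.complex)
        ref = recenter_trajectory(traj, fx.complex)
        np.testing.assert_allclose(out.frames, ref.frames, atol=1e-9)

    def test_minimum_image_protein_ligand_distance_preserved(self, rng):
        fx, traj = self._boxed()
        L = traj.box[:3]
        lig = fx.complex.ligand_indices
        prot = fx.complex.protein_indices
        wrapped = traj.frames.copy()
        wrapped[:, lig] += rng.integers(-1, 2, 3) * L
        out = recenter_trajectory(Trajectory(frames=wrapped, times=traj.times,
                                             box=traj.box), fx.complex)
        for f_orig, f_new in zip(traj.frames[:3], out.frames[:3]):
            d0 = np.linalg.norm(f_orig[prot[0]] - f_orig[lig[0]])
            d1 = np.linalg.norm(f_new[prot[0]] - f_new[lig[0]])
            assert d1 == pytest.approx(d0, abs=1e-6)

    def test_missing_box_passes_through_with_warning(self, fixture, spec):
        traj = synth_trajectory(fixture, spec, duration_ns=0.2)
        with pytest.warns(UserWarning, match="box"):
            out = recenter_trajectory(traj, fixture.complex)
        assert not out.recentered
        np.testing.assert_array_equal(out.frames, traj.frames)


class TestRmsdSeries:
    def test_static_trajectory_is_zero(self, fixture, spec, cv):
        traj = synth_trajectory(fixture, spec, duration_ns=0.3)
        np.testing.assert_allclose(rmsd_series(traj, cv), 0.0, atol=1e-9)

    def test_linear_drift_gives_linear_ramp(self, fixture, cv):
        spec = SyntheticSpec(seed=1, rmsd_schedule=linear_ramp(1000.0, 4.0))
        traj = synth_trajectory(fixture, spec, duration_ns=1.0)
        expected = np.linspace(0.0, 4.0, traj.n_frames)
        np.testing.assert_allclose(rmsd_series(traj, cv), expected, atol=1e-9)

    def test_matches_kabsch_oracle_per_frame(self, fixture, cv, rng):
        frames = np.array([random_perturbed_frame(rng, fixture.complex)
                           for _ in range(10)])
        traj = Trajectory(frames=frames, times=np.arange(10.0) + 1)
        got = rmsd_series(traj, cv)
        want = [kabsch_aligned_rmsd(f, cv.reference_coords,
                                    cv.anchor.atom_indices,
                                    cv.ligand_heavy_indices) for f in frames]
        np.testing.assert_allclose(got, want, atol=1e-9)


class TestPoseScore:
    def test_constant_rmsd(self):
        s = _series(np.arange(0, 10001, 100), rmsd=np.full(101, 1.5))
        assert pose_score(s, tail_ns=2.0) == pytest.approx(1.5)

    def test_ramp_tail_mean_matches_explicit_average(self):
        times = np.arange(0, 10001, 100.0)
        rmsd = times / 10000.0 * 4.0
        s = _series(times, rmsd=rmsd)
        expected = rmsd[times > 8000.0].mean()
        assert pose_score(s, tail_ns=2.0) == pytest.approx(expected)

    def test_full_length_tail_is_global_mean(self):
        times = np.arange(0, 1001, 100.0)
        rmsd = np.linspace(0, 2, len(times))
        s = _series(times, rmsd=rmsd)
        assert pose_score(s, tail_ns=1.0) == pytest.approx(rmsd[times > 0].mean())

    def test_too_short_trajectory_rejected(self):
        s = _series(np.arange(0, 501, 100.0))
        with pytest.raises(ValueError, match="tail"):
            pose_score(s, tail_ns=2.0)


class TestDetectHbonds:
    def test_ideal_geometry_found(self, complex_, spec):
        assert len(detect_hbonds(complex_.coords, complex_)) == spec.n_hbonds

    def test_bent_geometry_fails_angle(self, fixture):
        coords = fixture.complex.coords.copy()
        for unit in fixture.contact_units:
            if unit.is_hbond:
                n_idx, h_idx = unit.protein_atoms
                coords[h_idx] = coords[n_idx] + np.array([0.0, 0.0, 1.0])
        assert len(detect_hbonds(coords, fixture.complex)) == 0

    def test_apolar_system_gives_empty_set(self):
        spec = SyntheticSpec(n_hbonds=0, n_contacts=4)
        fx = make_toy_complex(spec)
        assert detect_hbonds(fx.complex.coords, fx.complex) == frozenset()

    def test_matches_brute_force_triple_loop(self, complex_, rng):
        for _ in range(25):
            frame = random_perturbed_frame(rng, complex_, scale=0.4)
            got = detect_hbonds(frame, complex_)
            want = brute_hbonds(frame, complex_.atoms, 3.5, 150.0)
            assert set(got) == want


class TestPersScore:
    def test_all_bonds_persist(self):
        hb = frozenset({(0, 1, 2), (3, 4, 5)})
        s = _series(np.arange(0, 1001, 100.0), initial_hbonds=hb,
                    present=np.full(11, 2))
        frac, defined = pers_score(s, tail_ns=0.5)
        assert frac == 1.0 and defined

    def test_half_of_four_bonds_persist(self):
        hb = frozenset({(0, 1, 2), (3, 4, 5), (6, 7, 8), (9, 10, 11)})
        s = _series(np.arange(0, 1001, 100.0), initial_hbonds=hb,
                    present=np.full(11, 2))
        frac, defined = pers_score(s, tail_ns=0.5)
        assert frac == pytest.approx(0.5) and defined

    def test_no_initial_bonds_flags_undefined(self):
        s = _series(np.arange(0, 1001, 100.0))
        frac, defined = pers_score(s, tail_ns=0.5)
        assert frac == 0.0 and not defined


class TestContactCount:
    def test_boundary_inclusive_at_cutoff(self):
        spec = SyntheticSpec(n_hbonds=0, n_contacts=1, n_ligand_heavy=1)
        fx = make_toy_complex(spec)
        coords = fx.complex.coords.copy()
        unit = fx.contact_units[0]
        cb = unit.protein_atoms[0]
        lig = unit.ligand_atom
        direction = coords[cb] - coords[lig]
        direction /= np.linalg.norm(direction)
        for dist, expected in ((3.4, 1), (3.5, 1), (3.6, 0)):
            coords[cb] = coords[lig] + direction * dist
            assert contact_count(coords, fx.complex) == expected

    def test_far_ligand_has_no_contacts(self, complex_):
        coords = complex_.coords.copy()
        coords[complex_.ligand_indices] += 100.0
        assert contact_count(coords, complex_) == 0

    def test_matches_brute_force_double_loop(self, complex_, rng):
        for _ in range(25):
            frame = random_perturbed_frame(rng, complex_, scale=1.0)
            want = brute_contact_count(frame, complex_.protein_heavy_indices,
                                       complex_.ligand_heavy_indices, 3.5)
            assert contact_count(frame, complex_) == want

    def test_minimum_image_with_box(self, rng):
        spec = SyntheticSpec(seed=5, box_length=40.0)
        fx = make_toy_complex(spec)
        coords = fx.complex.coords.copy()
        coords[fx.complex.ligand_indices] += np.array([40.0, 0, 0])
        assert contact_count(coords, fx.complex) == spec.n_contacts


class TestContactScore:
    def test_constant_contacts_is_one(self):
        s = _series(np.arange(0, 1001, 100.0))
        assert contact_score(s, tail_ns=0.5) == pytest.approx(1.0)

    def test_halved_contacts(self):
        times = np.arange(0, 1001, 100.0)
        contacts = np.where(times > 500, 3, 6)
        s = _series(times, contacts=contacts)
        assert contact_score(s, tail_ns=0.5) == pytest.approx(0.5)

    def test_doubled_contacts_unclipped(self):
        times = np.arange(0, 1001, 100.0)
        s = _series(times, contacts=np.where(times > 500, 12, 6))
        assert contact_score(s, tail_ns=0.5) == pytest.approx(2.0)

    def test_zero_initial_contacts_is_pocket_error(self):
        s = _series(np.arange(0, 1001, 100.0), initial_contacts=0)
        with pytest.raises(ValueError, match="pocket"):
            contact_score(s, tail_ns=0.5)


class TestCompScore:
    @pytest.mark.parametrize("ps,cs,expected", [
        (0.0, 1.0, -5.0),
        (2.0, 0.4, 0.0),
    ])
    def test_substitution(self, ps, cs, expected):
        assert comp_score(ps, cs) == pytest.approx(expected)

    def test_stable_pose_scores_lower(self):
        assert comp_score(1.0, 0.9) < comp_score(4.0, 0.3)

    def test_strictly_monotone_in_both_arguments(self, rng):
        for _ in range(50):
            ps, cs = rng.uniform(0, 5), rng.uniform(0, 2)
            assert comp_score(ps + 0.1, cs) > comp_score(ps, cs)
            assert comp_score(ps, cs + 0.1) < comp_score(ps, cs)


class TestScoreReplica:
    def test_stable_trajectory_scores(self, fixture, cv, short_config):
        traj = synth_trajectory(fixture, SyntheticSpec(seed=9), duration_ns=1.0)
        scores, series = score_replica(traj, fixture.complex, cv, short_config)
        assert scores.pose_score == pytest.approx(0.0, abs=1e-9)
        assert scores.contact_score == pytest.approx(1.0)
        assert scores.pers_score == pytest.approx(1.0)
        assert scores.comp_score == pytest.approx(-5.0, abs=1e-9)

    def test_unbinding_trajectory_scores(self, fixture, cv, short_config):
        spec = SyntheticSpec(seed=9, rmsd_schedule=linear_ramp(1000.0, 6.0),
                             contact_schedule=linear_ramp(1000.0, 0.0, 1.0),
                             hbond_schedule=linear_ramp(1000.0, 0.0, 2.0))
        traj = synth_trajectory(fixture, spec, duration_ns=1.0)
        scores, _ = score_replica(traj, fixture.complex, cv, short_config)
        assert scores.pose_score > 4.0
        assert scores.contact_score < 0.4
        assert scores.comp_score > 3.0

    def test_deterministic(self, fixture, cv, short_config):
        spec = SyntheticSpec(seed=4, noise_sigma=0.3)
        t1 = synth_trajectory(fixture, spec, duration_ns=1.0)
        t2 = synth_trajectory(fixture, spec, duration_ns=1.0)
        s1, _ = score_replica(t1, fixture.complex, cv, short_config)
        s2, _ = score_replica(t2, fixture.complex, cv, short_config)
        assert s1 == s2

    def test_invariant_under_global_rigid_transform(self, fixture, cv,
                                                    short_config, rng):
        spec = SyntheticSpec(seed=2, rmsd_schedule=linear_ramp(1000.0, 2.0))
        traj = synth_trajectory(fixture, spec, duration_ns=1.0)
        rot, shift = random_rigid_transform(rng)
        moved = Trajectory(frames=traj.frames @ rot.T + shift, times=traj.times)
        s0, _ = score_replica(traj, fixture.complex, cv, short_config)
        s1, _ = score_replica(moved, fixture.complex, cv, short_config)
        assert s1.pose_score == pytest.approx(s0.pose_score, abs=1e-6)
        assert s1.contact_score == pytest.approx(s0.contact_score)
        assert s1.pers_score == pytest.approx(s0.pers_score)
        assert s1.comp_score == pytest.approx(s0.comp_score, abs=1e-6)
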