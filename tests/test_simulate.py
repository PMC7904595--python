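import numpy as np
import pandas as pd
import pytest

from fidnav.integration import KspaceWeighting
from fidnav.metrics import compute_all_metrics
from fidnav.pipeline import process_series, score_series
from fidnav.simulate import (
    MotionTrajectory,
    NoiseModel,
    forward_fidnav,
    generate_cohort,
    grade_from_trajectory,
    kspace_weights_from_phantom,
    make_coil_array,
    make_phantom,
    sample_trajectory,
)


class TestPhantom:
    def test_empty_semi_axes_give_zero_density(self):
        p = make_phantom(semi_axes_mm=(0.0, 0.0, 0.0))
        assert p.density.sum() == 0.0

    def test_sphere_volume_matches_analytic(self):
        r = 50.0
        p = make_phantom(grid_shape=(96, 96, 96), semi_axes_mm=(r, r, r),
                         spacing_mm=1.5, smooth_voxels=0.0)
        volume = p.density.sum() * p.spacing_mm**3
        assert volume == pytest.approx(4 / 3 * np.pi * r**3, rel=0.02)

    def test_oversized_ellipsoid_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            make_phantom(grid_shape=(16, 16, 16), semi_axes_mm=(200, 50, 50))

    def test_density_linearity_propagates_to_signal(self, phantom, small_coils, noiseless):
        t = sample_trajectory("still", 0.0, 5)
        s1 = forward_fidnav(phantom, small_coils, t, noise=noiseless, seed=0)
        doubled = make_phantom()
        doubled.density *= 2.0
        s2 = forward_fidnav(doubled, small_coils, t, noise=noiseless, seed=0)
        np.testing.assert_allclose(s2.signal, 2 * s1.signal, rtol=1e-12)


class TestCoilArray:
    def test_deterministic_for_seed(self, phantom):
        a = make_coil_array(phantom, n_channels=6, seed=11)
        b = make_coil_array(phantom, n_channels=6, seed=11)
        np.testing.assert_array_equal(a.sensitivities, b.sensitivities)
        np.testing.assert_array_equal(a.phases, b.phases)

    def test_single_channel_is_valid(self, phantom):
        a = make_coil_array(phantom, n_channels=1, seed=0)
        assert a.sensitivities.shape[0] == 1
        assert a.sensitivities.max() > 0

    def test_opposite_coils_respond_with_opposite_sign(self, phantom, noiseless):
        coils = make_coil_array(phantom, n_channels=8, seed=4)
        # lateral step toward +x: coils on the +x side gain signal, -x side lose
        traj = MotionTrajectory(
            np.array([[0.0, 0, 0], [10.0, 0, 0]]), np.zeros((2, 3)), "abrupt"
        )
        s = forward_fidnav(phantom, coils, traj, noise=noiseless, seed=0)
        change = np.abs(s.signal[:, 1]) - np.abs(s.signal[:, 0])
        # recover each coil's x position from its sensitivity centroid
        xx = phantom.coords_mm()[0]
        cx = np.array([(w * xx).sum() / w.sum() for w in coils.sensitivities])
        assert np.any(change[cx > 50] > 0)
        assert np.any(change[cx < -50] < 0)
        assert np.all(np.sign(change[cx > 50]) != np.sign(change[cx < -50][:1]))


class TestTrajectories:
    def test_still_is_identity(self):
        t = sample_trajectory("still", 5.0, 10)
        assert not t.translations_mm.any() and not t.rotations_deg.any()

    def test_abrupt_single_step(self):
        t = sample_trajectory("abrupt", 5.0, 100, event_times=[50], seed=3)
        norms = np.linalg.norm(t.translations_mm, axis=1)
        assert np.all(norms[:49] == 0)
        assert np.allclose(norms[49:], norms[49])
        assert norms[49] == pytest.approx(5.0)

    def test_continuous_zero_magnitude_is_identity(self):
        t = sample_trajectory("continuous", 0.0, 20, seed=1)
        assert not t.translations_mm.any()

    def test_drift_ramps_to_magnitude(self):
        t = sample_trajectory("drift", 3.0, 50, seed=2)
        assert np.linalg.norm(t.translations_mm[-1]) == pytest.approx(3.0)
        assert np.linalg.norm(t.translations_mm[0]) == 0.0

    def test_event_time_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="event time"):
            sample_trajectory("abrupt", 1.0, 10, event_times=[11])

    def test_unknown_profile_rejected(self):
        with pytest.raises(ValueError, match="profile"):
            sample_trajectory("jittery", 1.0, 10)


class TestForwardModel:
    def test_still_noiseless_constant_and_all_metrics_zero(self, phantom, small_coils, noiseless):
        t = sample_trajectory("still", 0.0, 10)
        s = forward_fidnav(phantom, small_coils, t, noise=noiseless, seed=0)
        np.testing.assert_array_equal(s.signal, np.tile(s.signal[:, :1], (1, 10)))
        for trace in compute_all_metrics(s).values():
            np.testing.assert_allclose(trace.values, 0.0, atol=1e-12)

    def test_abrupt_event_localizes_in_metrics(self, phantom, small_coils, noiseless):
        t = sample_trajectory("abrupt", 4.0, 30, event_times=[15], seed=5)
        s = forward_fidnav(phantom, small_coils, t, noise=noiseless, seed=0)
        _, metrics = process_series(s, n_discard=0, n_ref=3)
        delta = metrics["delta"].values  # element k corresponds to TR k+2
        assert delta[13] > 100 * np.max(np.abs(np.delete(delta, 13)))
        dref = metrics["delta_ref"].values
        assert np.all(dref[13:] > 1e-6)
        assert np.all(dref[:13] < 1e-12)

    def test_signal_change_monotone_in_step_size(self, phantom, small_coils, noiseless):
        changes = []
        for mag in (0.5, 1.0, 2.0, 3.5, 5.0):
            traj = MotionTrajectory(
                np.array([[0.0, 0, 0], [mag, 0, 0]]), np.zeros((2, 3)), "abrupt"
            )
            s = forward_fidnav(phantom, small_coils, traj, noise=noiseless, seed=0)
            changes.append(np.abs(s.signal[:, 1] - s.signal[:, 0]).mean())
        assert np.all(np.diff(changes) > 0)

    def test_coil_gain_scale_invariance_end_to_end(self, phantom, small_coils, noiseless):
        from dataclasses import replace as dc_replace

        t = sample_trajectory("continuous", 2.0, 12, seed=8)
        s1 = forward_fidnav(phantom, small_coils, t, noise=noiseless, seed=0)
        gained = dc_replace(small_coils, sensitivities=7.5 * small_coils.sensitivities)
        s2 = forward_fidnav(phantom, gained, t, noise=noiseless, seed=0)
        m1 = compute_all_metrics(s1)
        m2 = compute_all_metrics(s2)
        for name in m1:
            np.testing.assert_allclose(m1[name].values, m2[name].values, rtol=1e-9, atol=1e-12)

    def test_scores_increase_with_motion_magnitude(self, phantom, small_coils):
        """Integrated scores rank-correlate with magnitude across a sweep."""
        from scipy.stats import spearmanr

        mags = np.linspace(0.3, 6.0, 20)
        scores = []
        for k, mag in enumerate(mags):
            t = sample_trajectory("continuous", mag, 40, seed=100 + k)
            s = forward_fidnav(phantom, small_coils, t, seed=200 + k)
            scores.append(score_series(s, n_discard=0)["ccc"])
        rho = spearmanr(mags, scores).statistic
        assert rho > 0.95


class TestGrading:
    def test_still_trajectory_is_grade_5(self):
        t = sample_trajectory("still", 0.0, 20)
        w = KspaceWeighting(np.ones(20))
        assert grade_from_trajectory(t, w) == 5

    def test_displacement_above_largest_threshold_is_grade_1(self):
        trans = np.zeros((20, 3))
        trans[1:, 0] = 10.0
        t = MotionTrajectory(trans, np.zeros((20, 3)), "abrupt")
        w = KspaceWeighting(np.ones(20))
        assert grade_from_trajectory(t, w) == 1

    def test_weighting_changes_grade_for_peripheral_motion(self):
        # motion confined to the last (low-weight) steps
        trans = np.zeros((100, 3))
        trans[90:, 0] = 30.0
        t = MotionTrajectory(trans, np.zeros((100, 3)), "abrupt")
        flat = KspaceWeighting(np.ones(100))
        wv = np.full(100, 0.1)
        wv[40:60] = (100 - 80 * 0.1) / 20  # center-heavy, unit mean
        center_weighted = KspaceWeighting(wv / wv.mean())
        assert grade_from_trajectory(t, center_weighted) > grade_from_trajectory(t, flat)

    def test_non_monotone_thresholds_rejected(self):
        t = sample_trajectory("still", 0.0, 5)
        with pytest.raises(ValueError, match="increasing"):
            grade_from_trajectory(t, KspaceWeighting(np.ones(5)), thresholds_mm=(1, 3, 2, 4))


class TestCohort:
    def test_default_mix_reproduces_group_sizes(self, tmp_path):
        manifest = generate_cohort(tmp_path, n_subjects=102, seed=0,
                                   n_tr=13, n_channels=4, grid_shape=(12, 12, 12))
        counts = manifest["grade"].value_counts().sort_index()
        assert list(counts) == [3, 9, 12, 29, 49]

    def test_one_subject_per_grade(self, tmp_path):
        manifest = generate_cohort(tmp_path, n_subjects=5,
                                   grade_mix=(0.2,) * 5, seed=1,
                                   n_tr=13, n_channels=4, grid_shape=(12, 12, 12))
        assert sorted(manifest["grade"]) == [1, 2, 3, 4, 5]
        assert len(list(tmp_path.glob("S*.csv"))) == 5

    def test_same_seed_byte_identical(self, tmp_path):
        a_dir, b_dir = tmp_path / "a", tmp_path / "b"
        for d in (a_dir, b_dir):
            generate_cohort(d, n_subjects=4, grade_mix=(0, 0.25, 0.25, 0.25, 0.25),
                            seed=7, n_tr=13, n_channels=4, grid_shape=(12, 12, 12))
        for f in sorted(a_dir.iterdir()):
            assert f.read_bytes() == (b_dir / f.name).read_bytes(), f.name

    def test_manifest_grades_match_trajectory_grading(self, tmp_path):
        manifest = generate_cohort(tmp_path, n_subjects=10, seed=3,
                                   n_tr=43, n_channels=4, grid_shape=(12, 12, 12))
        assert (manifest["grade"] == manifest["grade_check"]).all()

    def test_fewer_subjects_than_grade_bins_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="fewer subjects"):
            generate_cohort(tmp_path, n_subjects=3, grade_mix=(0.2,) * 5, seed=0,
                            n_tr=13, n_channels=4, grid_shape=(12, 12, 12))

    def test_bad_mix_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="summing"):
            generate_cohort(tmp_path, n_subjects=4, grade_mix=(0.5, 0.5, 0.5, 0, 0), seed=0)


class TestKspaceWeightsFromPhantom:
    def test_center_peaked_unit_mean(self, phantom):
        w = kspace_weights_from_phantom(phantom, 160)
        assert w.w.mean() == pytest.approx(1.0)
        center = np.argmax(w.w)
        assert abs(center - 80) < 8  # peak near mid-acquisition
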