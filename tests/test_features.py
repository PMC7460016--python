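"""Kinematic primary measures and motor variables against geometric oracles."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import motorkin as mk
from motorkin import features as ft
from motorkin.segmentation import ManeuverSegment, Repetition
from motorkin.skeleton_io import JointName as J
from motorkin.skeleton_io import N_JOINTS, Recording
from motorkin.synthesis import SensorModel, _leg_at_angle, rest_pose, t_pose

RAW = ft.FeatureConfig(smoothing=False)


def _rec_from_poses(poses: list[np.ndarray], rate: float = 30.0) -> Recording:
    pos = np.stack(poses)
    return Recording("S1", 1, np.arange(len(poses)) / rate, pos,
                     nominal_rate=rate)


class TestPrimaryMeasures:
    def test_collinear_triplet_angle_180(self):
        pose = rest_pose(1.75)  # knees lie on the hip-ankle segment
        rec = _rec_from_poses([pose] * 5)
        ang = ft.angle_series(rec, J.HIP_L, J.KNEE_L, J.ANKLE_L)
        assert np.allclose(ang, 180.0)

    def test_static_pair_distance_and_angular_velocity(self):
        pose = rest_pose(1.75)
        pose[J.HAND_L.value] = [0.0, 1.0, 2.0]
        pose[J.HAND_R.value] = [0.5, 1.0, 2.0]
        rec = _rec_from_poses([pose] * 10)
        d = ft.distance_series(rec, J.HAND_L, J.HAND_R)
        assert np.allclose(d, 0.5)
        ang = ft.angle_series(rec, J.HAND_L, J.SHOULDER_CENTER, J.HAND_R)
        w = ft.angular_velocity(ang, rec.times)
        assert np.allclose(w, 0.0)
        assert w.size == ang.size - 2  # one element shorter at each end

    def test_programmed_rotation_rate_recovered(self):
        """A limb rotating at 30 deg/s yields that mean angular velocity."""
        rate, omega = 30.0, 30.0
        poses = []
        base = rest_pose(1.75)
        for i in range(61):
            p = base.copy()
            phi = np.deg2rad(omega * i / rate)
            p[J.HAND_R.value] = p[J.SHOULDER_R.value] + 0.6 * np.array(
                [np.cos(phi), -np.sin(phi), 0.0])
            poses.append(p)
        rec = _rec_from_poses(poses, rate)
        ang = ft.angle_series(rec, J.HAND_R, J.SHOULDER_R, J.SHOULDER_L)
        w = ft.angular_velocity(ang, rec.times)
        assert abs(np.mean(np.abs(w)) - omega) < 0.1

    def test_degenerate_limb_vector_warns_nan(self):
        pose = rest_pose(1.75)
        pose[J.HAND_L.value] = pose[J.SHOULDER_CENTER.value]
        rec = _rec_from_poses([pose] * 3)
        with pytest.warns(UserWarning, match="degenerate"):
            ang = ft.angle_series(rec, J.HAND_L, J.SHOULDER_CENTER, J.HAND_R)
        assert np.all(np.isnan(ang))

    def test_primary_measures_container(self, clean_recording):
        rec, gt = clean_recording
        a, b = gt.segment_frame_spans()[0]
        seg = ManeuverSegment("RT", a, b)
        pm = ft.primary_measures(
            seg, rec, pairs=[(J.HAND_L, J.HAND_R)],
            triplets=[(J.HIP_L, J.KNEE_L, J.ANKLE_L)])
        key = ("HAND_L", "HAND_R")
        assert pm.distances[key].shape == (b - a,)
        assert np.all(pm.distances[key] >= 0)
        tri = ("HIP_L", "KNEE_L", "ANKLE_L")
        assert np.all((pm.angles[tri] >= 0) & (pm.angles[tri] <= 180))
        assert pm.angular_velocities[tri].size == b - a - 2


def _fnt_recording(min_distances, stature=1.75):
    """Hand-built finger-to-nose series: each rep stops short of the nose
    proxy by the programmed distance."""
    tpos = t_pose(stature)
    nose = tpos[J.HEAD.value] + np.array([0.0, 0.0, -0.10])
    poses, reps = [], []
    hold = 15
    poses += [tpos] * hold
    for d in min_distances:
        start = len(poses)
        reach = tpos.copy()
        stop = nose + np.array([0.0, 0.0, -d])  # d meters short, toward camera
        reach[J.HAND_L.value] = stop
        reach[J.WRIST_L.value] = stop + np.array([0.0, 0.0, -0.09])
        poses += [reach] * 10
        poses += [tpos] * hold
        reps.append(Repetition(start - 2, len(poses) - hold + 2, "left"))
    rec = _rec_from_poses(poses)
    seg = ManeuverSegment("FNT", 0, rec.n_frames, "both", tuple(reps))
    return rec, seg


class TestFntFeatures:
    def test_hand_computed_accuracy_mean_and_sd(self):
        """Programmed miss distances {0, 2, 4, 2, 0} cm give a 1.6 cm mean
        and 1.67 cm repetition SD."""
        rec, seg = _fnt_recording([0.0, 0.02, 0.04, 0.02, 0.0])
        out = ft.fnt_features(seg, rec, RAW)["left"]
        assert out.accuracy_distance_m == pytest.approx(0.016, abs=1e-9)
        assert out.min_dist_sd_m == pytest.approx(0.0167332, abs=1e-6)
        assert out.arm_drop_deg == pytest.approx(0.0, abs=1e-9)

    def test_perfect_reaches_have_zero_variability(self):
        rec, seg = _fnt_recording([0.0] * 5)
        out = ft.fnt_features(seg, rec, RAW)["left"]
        assert out.accuracy_distance_m == pytest.approx(0.0, abs=1e-12)
        assert out.min_dist_sd_m == pytest.approx(0.0, abs=1e-12)

    def test_missing_repetitions_flag_invalid(self):
        rec, seg = _fnt_recording([0.0] * 5)
        with pytest.warns(UserWarning, match="missing repetitions"):
            out = ft.fnt_features(seg, rec, RAW)["right"]
        assert not out.valid

    def test_constant_speed_reach(self):
        """A 0.6 m reach at constant speed over 1.0 s moves at 0.6 m/s."""
        tpos = t_pose(1.75)
        start = tpos[J.HAND_L.value]
        target = start + np.array([0.3, 0.3, -np.sqrt(0.6**2 - 0.18)])
        assert np.linalg.norm(target - start) == pytest.approx(0.6)
        poses = [tpos] * 10
        n = 30
        for i in range(1, n + 1):  # out in 1 s
            p = tpos.copy()
            p[J.HAND_L.value] = start + (target - start) * i / n
            poses.append(p)
        for i in range(n - 1, -1, -1):  # and back in 1 s
            p = tpos.copy()
            p[J.HAND_L.value] = start + (target - start) * i / n
            poses.append(p)
        poses += [tpos] * 10
        rec = _rec_from_poses(poses)
        seg = ManeuverSegment("FNT", 0, rec.n_frames, "both",
                              (Repetition(8, rec.n_frames - 8, "left"),))
        out = ft.fnt_features(seg, rec, RAW)["left"]
        assert out.veloc_ms == pytest.approx(0.6, rel=0.05)


class TestStaticFeatures:
    def _static(self, n=400):
        return _rec_from_poses([rest_pose(1.75)] * n)

    def _segs(self, rec):
        n = rec.n_frames
        return (ManeuverSegment("RT", 0, n // 2),
                ManeuverSegment("TT", n // 2, n))

    def test_still_skeleton_zero_sway(self):
        rec = self._static()
        out = ft.static_features(*self._segs(rec), rec, RAW)
        for key in ("hand_left", "hand_right", "head", "hip"):
            assert out[key].range_m == pytest.approx(0.0, abs=1e-12)
            assert out[key].speed_ms == pytest.approx(0.0, abs=1e-12)

    def test_oscillating_hand_range_is_twice_amplitude(self):
        amp = 0.05
        poses = []
        for i in range(400):
            p = rest_pose(1.75)
            p[J.HAND_L.value, 1] += amp * np.sin(2 * np.pi * 0.5 * i / 30.0)
            poses.append(p)
        rec = _rec_from_poses(poses)
        out = ft.static_features(*self._segs(rec), rec, RAW)
        assert out["hand_left"].range_m == pytest.approx(2 * amp, abs=2e-3)

    def test_sensor_noise_floor_gives_positive_sway(self):
        rec = self._static()
        noisy = Recording(
            rec.subject_id, 1, rec.times,
            rec.positions + np.random.default_rng(0).normal(
                0, 1, rec.positions.shape) * SensorModel().sigmas,
            nominal_rate=30.0)
        out = ft.static_features(*self._segs(noisy), noisy, ft.FeatureConfig())
        assert out["hand_left"].range_m > 0
        assert out["hand_left"].speed_ms > 0

    def test_short_segment_flagged(self):
        rec = self._static(n=80)
        rt = ManeuverSegment("RT", 0, 40)
        tt = ManeuverSegment("TT", 40, 80)
        with pytest.warns(UserWarning, match="shorter"):
            out = ft.static_features(rt, tt, rec, RAW)
        assert not out["head"].valid


def _sst_recording(angles_left, stature=1.75):
    rest = rest_pose(stature)
    poses, reps = [], []
    poses += [rest] * 20
    for th in angles_left:
        start = len(poses)
        apex = _leg_at_angle(rest, "left", th)
        poses += [rest] * 5 + [apex] * 10 + [rest] * 5
        reps.append(Repetition(start, len(poses), "left"))
        poses += [rest] * 5
    rec = _rec_from_poses(poses)
    seg = ManeuverSegment("SST", 0, rec.n_frames, "both", tuple(reps))
    return rec, seg


class TestSstFeatures:
    def test_hand_computed_step_angles(self):
        """Apex angles {28, 30, 32, 30, 30} give mean 30 and SD 1.41."""
        rec, seg = _sst_recording([28.0, 30.0, 32.0, 30.0, 30.0])
        out = ft.sst_features(seg, rec, RAW)["left"]
        assert out.step_angle_deg == pytest.approx(30.0, abs=1e-9)
        assert out.step_angle_sd_deg == pytest.approx(np.sqrt(2.0), abs=1e-9)
        assert out.foot_height_m > 0
        assert 0 < out.pct_time_raised < 100

    def test_feet_together_is_null_movement(self):
        rec = _rec_from_poses([rest_pose(1.75)] * 120)
        seg = ManeuverSegment(
            "SST", 0, 120, "both",
            tuple(Repetition(10 + 20 * i, 28 + 20 * i, "left")
                  for i in range(5)))
        out = ft.sst_features(seg, rec, RAW)["left"]
        assert out.foot_height_m == pytest.approx(0.0, abs=1e-12)
        assert out.pct_time_raised == pytest.approx(0.0)


class TestT45Features:
    def test_programmed_hold_recovered(self, clean_recording):
        rec, gt = clean_recording
        a, b = gt.segment_frame_spans()[4]
        seg = ManeuverSegment("T45", a, b, "both")
        out = ft.t45_features(seg, rec, ft.FeatureConfig())
        for side, rep in zip(("left", "right"), gt.maneuver("T45").reps):
            got = out[side]
            assert got.airborne_time_s == pytest.approx(
                rep.programmed["airborne_s"], abs=2 / 30)
            assert got.hold_angle_error_deg < 0.1
            assert got.knee_flexion_deg == pytest.approx(
                rep.programmed["knee_flexion_deg"], abs=0.1)

    def test_offset_hold_angle_error(self, profile, noise_free_script):
        """Holding at 40 degrees is a 5-degree error from the 45 target."""
        script = dataclasses.replace(noise_free_script, t45_angle_deg=40.0)
        rec, gt = mk.simulate_recording(
            profile, script, SensorModel().noiseless(), seed=4)
        a, b = gt.segment_frame_spans()[4]
        out = ft.t45_features(ManeuverSegment("T45", a, b, "both"), rec,
                              ft.FeatureConfig())
        assert out["left"].hold_angle_error_deg == pytest.approx(5.0, abs=0.1)

    def test_foot_never_lifted(self):
        rec = _rec_from_poses([rest_pose(1.75)] * 200)
        with pytest.warns(UserWarning, match="no airborne"):
            out = ft.t45_features(ManeuverSegment("T45", 0, 200, "both"),
                                  rec, RAW)
        assert out["left"].airborne_time_s == 0.0
        assert np.isnan(out["left"].hold_angle_deg)


class TestCstFeatures:
    def test_constant_speed_descent(self):
        """0.45 m of hip descent in 1.5 s moves at 0.30 m/s vertically."""
        rest = rest_pose(1.75)
        poses, reps = [rest] * 10, []
        for _ in range(5):
            start = len(poses)
            for i in range(1, 46):  # 45 frames = 1.5 s, constant speed
                p = rest.copy()
                dy = 0.45 * i / 45
                for j in (J.HIP_CENTER, J.HIP_L, J.HIP_R, J.SPINE,
                          J.SHOULDER_CENTER, J.HEAD):
                    p[j.value, 1] = rest[j.value, 1] - dy
                poses.append(p)
            reps.append(Repetition(start, len(poses), "n/a"))
            poses += [rest] * 10
        rec = _rec_from_poses(poses)
        seg = ManeuverSegment("CST", 0, rec.n_frames, "n/a", tuple(reps))
        out = ft.cst_features(seg, rec, RAW)
        assert out.hip_speed_ms == pytest.approx(0.30, rel=0.03)
        assert out.seat_position_sd_m == pytest.approx(0.0, abs=1e-12)
        assert out.trunk_tilt_deg == pytest.approx(0.0, abs=1e-9)

    def test_programmed_trunk_tilt(self, clean_recording):
        rec, gt = clean_recording
        a, b = gt.segment_frame_spans()[5]
        reps = tuple(
            Repetition(int(r.start_s * 30), int(r.end_s * 30), "n/a")
            for r in gt.maneuver("CST").reps)
        seg = ManeuverSegment("CST", a, b, "n/a", reps)
        out = ft.cst_features(seg, rec, ft.FeatureConfig())
        tilt = gt.maneuver("CST").programmed["tilt_deg"]
        assert out.trunk_tilt_deg == pytest.approx(tilt, abs=0.2)


class TestAsymmetry:
    def test_symmetric_pairs_are_zero(self):
        assert ft.symmetric_percent_difference(1.0, 1.0) == 0.0
        assert ft.symmetric_percent_difference(0.0, 0.0) == 0.0

    def test_double_is_two_thirds(self):
        assert ft.symmetric_percent_difference(2.0, 1.0) == pytest.approx(
            200.0 / 3.0)

    def test_mean_over_pairs(self):
        """Pairs {(1,1), (2,4)} average to 33.33%."""
        m = {"fnt_acc_dist_left": 1.0, "fnt_acc_dist_right": 1.0,
             "fnt_veloc_left": 2.0, "fnt_veloc_right": 4.0}
        out = ft.asymmetry_features(m)
        assert out["asymmetry_ul"] == pytest.approx(100.0 / 3.0)

    def test_all_invalid_warns_nan(self):
        with pytest.warns(UserWarning, match="invalid"):
            out = ft.asymmetry_features({})
        assert np.isnan(out["asymmetry_ul"])


class TestInvariances:
    @pytest.fixture(scope="class")
    def measured(self, noisy_recording):
        rec, gt = noisy_recording
        from motorkin.pipeline import RunConfig, segment_recording
        segs = segment_recording(rec, RunConfig())
        return rec, segs, ft.extract_trial_measures(rec, segs)

    def test_rigid_translation_invariance(self, measured):
        rec, segs, base = measured
        shift = np.array([0.31, -0.12, 0.27])
        moved = Recording(rec.subject_id, 1, rec.times,
                          rec.positions + shift, nominal_rate=30.0)
        out = ft.extract_trial_measures(moved, segs)
        for key, val in base.items():
            assert out[key] == pytest.approx(val, rel=1e-9, abs=1e-9), key

    def test_vertical_axis_rotation_invariance(self, measured):
        """All features except the camera-frame frontal trunk angle are
        invariant under rotation about the vertical axis."""
        rec, segs, base = measured
        th = np.deg2rad(35.0)
        R = np.array([[np.cos(th), 0, np.sin(th)],
                      [0, 1, 0],
                      [-np.sin(th), 0, np.cos(th)]])
        rotated = Recording(rec.subject_id, 1, rec.times,
                            rec.positions @ R.T, nominal_rate=30.0)
        out = ft.extract_trial_measures(rotated, segs)
        for key, val in base.items():
            if key == "cst_trunk_tilt":
                continue  # frontal projection is camera-frame by definition
            assert out[key] == pytest.approx(val, rel=1e-6, abs=1e-7), key

    def test_nose_proxy_rotation_caveat(self, measured):
        # the nose proxy offset is along the camera axis, so FNT accuracy
        # is rotation-sensitive only through that fixed offset; verify the
        # offset itself is what moves
        rec, segs, base = measured
        assert base["fnt_acc_dist_left"] >= 0


class TestVariableAssembly:
    @pytest.fixture(scope="class")
    def cohort_frame(self):
        from motorkin.pipeline import RunConfig, segment_recording
        profiles, recs = mk.simulate_cohort(6, 1, seed=21)
        rows = {}
        cfg = RunConfig()
        for (sid, series), (rec, _) in recs.items():
            segs = segment_recording(rec, cfg)
            rows[(sid, series)] = ft.extract_trial_measures(rec, segs)
        df = pd.DataFrame(rows).T
        df.index.names = ["subject_id", "series_index"]
        return df

    def test_twenty_variables_in_ranges(self, cohort_frame):
        wide = ft.compose_variables(cohort_frame)
        assert list(wide.columns) == list(ft.VARIABLE_NAMES)
        assert wide.notna().all().all()
        for var in ("AmpStep_LL", "AmpStep_RL"):
            assert ((wide[var] >= 0) & (wide[var] <= 90)).all()
        for var in ("Asymmetry_UL", "Asymmetry_LL"):
            assert (wide[var] >= 0).all()

    def test_composites_standardized_against_reference(self, cohort_frame):
        wide = ft.compose_variables(cohort_frame)
        # multi-measure composites are centered on the composite scale
        assert wide["InvMov_LA"].mean() == pytest.approx(
            ft.COMPOSITE_CENTER, abs=1e-9)
        # an external reference shifts values but preserves ordering
        ref = cohort_frame * 1.5
        wide2 = ft.compose_variables(cohort_frame, reference=ref)
        a = wide["Stab_axial"].rank().to_numpy()
        b = wide2["Stab_axial"].rank().to_numpy()
        assert np.array_equal(a, b)
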