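"""Kinematic feature extraction: primary measures and the 20 motor variables.

Primary measures are per-frame joint-pair distances (m), angles between
joint triplets or limb vectors (degrees), and angular velocities (deg/s)
by central difference over the actual inter-frame intervals.  From these,
each maneuver contributes named physical sub-measures (Table-style mapping:
finger-to-nose accuracy/speed/variability, resting and T-position hand and
head sway, step width angles, monopodal balance times, chair-to-stand hip
dispersion and trunk tilt), which are assembled into the 20 motor variables
of the assessment.

Variables backed by several sub-measures are reported both individually and
as an equal-weight z-score composite standardized against a reference
cohort (by default the input cohort itself), shifted to a center of 5 so
the composite scale stays positive.  Single-measure variables keep their
physical units (degrees, meters, m/s, percent).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.spatial.distance import pdist

from .segmentation import ManeuverSegment, central_span, _runs as _bool_runs
from .skeleton_io import JointName as J
from .skeleton_io import Recording

__all__ = [
    "VARIABLE_NAMES",
    "COMPOSITES",
    "FeatureConfig",
    "PrimaryMeasures",
    "primary_measures",
    "distance_series",
    "angle_series",
    "angular_velocity",
    "smooth_positions",
    "speed_series",
    "fnt_features",
    "static_features",
    "sst_features",
    "t45_features",
    "cst_features",
    "asymmetry_features",
    "extract_trial_measures",
    "compose_variables",
    "symmetric_percent_difference",
]

# the 20 motor variables of the assessment
VARIABLE_NAMES = (
    "AccMov_LA", "AccMov_RA", "Veloc_LA", "Veloc_RA",
    "VarMov_LA", "VarMov_RA", "InvMov_LA", "InvMov_RA",
    "VarMov_LL", "VarMov_RL", "MonSt_Bal_LL", "MonSt_Bal_RL",
    "AmpStep_LL", "AmpStep_RL", "Var_Mov_axial", "Stab_axial",
    "Asymmetry_UL", "Asymmetry_LL", "Posture_CST", "Bal_axial",
)

# variable -> physical sub-measures (single entry = natural units kept)
COMPOSITES: dict[str, tuple[str, ...]] = {
    "AccMov_LA": ("fnt_acc_dist_left", "fnt_arm_drop_left"),
    "AccMov_RA": ("fnt_acc_dist_right", "fnt_arm_drop_right"),
    "Veloc_LA": ("fnt_veloc_left",),
    "Veloc_RA": ("fnt_veloc_right",),
    "VarMov_LA": ("fnt_min_dist_sd_left", "fnt_arm_drop_sd_left"),
    "VarMov_RA": ("fnt_min_dist_sd_right", "fnt_arm_drop_sd_right"),
    "InvMov_LA": ("hand_range_left", "hand_speed_left"),
    "InvMov_RA": ("hand_range_right", "hand_speed_right"),
    "VarMov_LL": ("sst_foot_height_left", "sst_pct_raised_left",
                  "sst_step_angle_sd_left"),
    "VarMov_RL": ("sst_foot_height_right", "sst_pct_raised_right",
                  "sst_step_angle_sd_right"),
    "MonSt_Bal_LL": ("t45_air_time_left", "t45_knee_flexion_left"),
    "MonSt_Bal_RL": ("t45_air_time_right", "t45_knee_flexion_right"),
    "AmpStep_LL": ("sst_step_angle_left",),
    "AmpStep_RL": ("sst_step_angle_right",),
    "Var_Mov_axial": ("cst_seat_sd",),
    "Stab_axial": ("head_range", "head_speed"),
    "Bal_axial": ("hip_range", "hip_speed"),
    "Posture_CST": ("cst_hip_speed", "cst_trunk_tilt"),
    "Asymmetry_UL": ("asymmetry_ul",),
    "Asymmetry_LL": ("asymmetry_ll",),
}

COMPOSITE_CENTER = 5.0  # center of the z-composite scale (keeps values > 0)


@dataclass(frozen=True)
class FeatureConfig:
    """Tunables of the feature extractor."""

    nose_offset_m: float = 0.10  # nose proxy: HEAD shifted toward the camera
    smooth_window: int = 5  # moving-average window for speeds (frames)
    smoothing: bool = True
    foot_raised_margin_m: float = 0.02  # step "foot raised" band
    airborne_threshold_m: float = 0.05  # monopodal "foot in air" band
    t45_target_deg: float = 45.0
    baseline_s: float = 0.5
    static_trim_fraction: float = 0.8
    min_static_s: float = 2.0


# --------------------------------------------------------------------------
# primary measures
# --------------------------------------------------------------------------


def smooth_positions(positions: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered moving average along time; edges use shrinking windows."""
    if window <= 1:
        return positions
    return uniform_filter1d(positions, size=window, axis=0, mode="nearest")


def distance_series(rec: Recording, j1: J, j2: J,
                    span: tuple[int, int] | None = None) -> np.ndarray:
    a, b = span if span is not None else (0, rec.n_frames)
    return np.linalg.norm(rec.joint(j1)[a:b] - rec.joint(j2)[a:b], axis=1)


def _vec_angle(v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
    n1 = np.linalg.norm(v1, axis=-1)
    n2 = np.linalg.norm(v2, axis=-1)
    out = np.full(v1.shape[:-1], np.nan)
    ok = (n1 > 0) & (n2 > 0)
    if not ok.all():
        warnings.warn("degenerate (zero-length) limb vector: angle set to NaN",
                      stacklevel=2)
    c = np.einsum("...i,...i->...", v1, v2)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.where(ok, c / (n1 * n2), np.nan)
    out = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return out


def angle_series(rec: Recording, a: J, b: J, c: J,
                 span: tuple[int, int] | None = None) -> np.ndarray:
    """Angle at joint b of the triplet a-b-c, degrees in [0, 180]."""
    s, e = span if span is not None else (0, rec.n_frames)
    return _vec_angle(rec.joint(a)[s:e] - rec.joint(b)[s:e],
                      rec.joint(c)[s:e] - rec.joint(b)[s:e])


def angular_velocity(angles_deg: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Central-difference angular velocity (deg/s) on the interior frames."""
    if angles_deg.size < 3:
        return np.empty(0)
    return (angles_deg[2:] - angles_deg[:-2]) / (times[2:] - times[:-2])


def speed_series(positions: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Central-difference speed magnitude (m/s), one-sided at the edges."""
    v = np.gradient(positions, times, axis=0)
    return np.linalg.norm(v, axis=1)


@dataclass
class PrimaryMeasures:
    """Per-frame distances (m), angles (deg) and angular velocities (deg/s)."""

    times: np.ndarray
    distances: dict[tuple[str, str], np.ndarray]
    angles: dict[tuple[str, str, str], np.ndarray]
    angular_velocities: dict[tuple[str, str, str], np.ndarray]


def primary_measures(
    seg: ManeuverSegment,
    rec: Recording,
    pairs: list[tuple[J, J]] = (),
    triplets: list[tuple[J, J, J]] = (),
) -> PrimaryMeasures:
    """Distances, angles and angular velocities over one maneuver span."""
    if seg.start < 0 or seg.end > rec.n_frames:
        raise ValueError("segment span exceeds the recording")
    span = (seg.start, seg.end)
    t = rec.times[seg.start:seg.end]
    dists = {(a.name, b.name): distance_series(rec, a, b, span)
             for a, b in pairs}
    angs = {(a.name, b.name, c.name): angle_series(rec, a, b, c, span)
            for a, b, c in triplets}
    angv = {k: angular_velocity(v, t) for k, v in angs.items()}
    return PrimaryMeasures(times=t, distances=dists, angles=angs,
                           angular_velocities=angv)


# --------------------------------------------------------------------------
# helpers
# --------------------------------------------------------------------------

_HAND = {"left": J.HAND_L, "right": J.HAND_R}
_SHOULDER = {"left": J.SHOULDER_L, "right": J.SHOULDER_R}
_FOOT = {"left": J.FOOT_L, "right": J.FOOT_R}
_ANKLE = {"left": J.ANKLE_L, "right": J.ANKLE_R}
_KNEE = {"left": J.KNEE_L, "right": J.KNEE_R}
_HIP = {"left": J.HIP_L, "right": J.HIP_R}


def _smoothed(rec: Recording, joint: J, cfg: FeatureConfig) -> np.ndarray:
    p = rec.joint(joint)
    return smooth_positions(p, cfg.smooth_window) if cfg.smoothing else p


def nose_proxy(rec: Recording, offset_m: float = 0.10) -> np.ndarray:
    """Per-frame nose landmark: HEAD shifted forward along the facing
    direction (shoulder line crossed with vertical), 0.10 m by default.

    For a camera-facing subject this equals a shift toward the camera, but
    the body-frame definition keeps it valid under any yaw.
    """
    across = rec.joint(J.SHOULDER_L) - rec.joint(J.SHOULDER_R)
    facing = np.cross(across, np.array([0.0, 1.0, 0.0]))
    norm = np.linalg.norm(facing, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return rec.joint(J.HEAD) + offset_m * facing / norm


def _nose(rec: Recording, cfg: FeatureConfig) -> np.ndarray:
    return nose_proxy(rec, cfg.nose_offset_m)


def _cloud_diameter(points: np.ndarray) -> float:
    """Maximum pairwise distance of a 3-D point cloud."""
    if len(points) < 2:
        return 0.0
    return float(pdist(points).max())


def _between_leg_angle(rec: Recording, a: int, b: int) -> np.ndarray:
    hc = rec.joint(J.HIP_CENTER)[a:b]
    return _vec_angle(rec.joint(J.ANKLE_L)[a:b] - hc,
                      rec.joint(J.ANKLE_R)[a:b] - hc)


def _sd(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1)) if len(x) > 1 else 0.0


# --------------------------------------------------------------------------
# per-maneuver features
# --------------------------------------------------------------------------


@dataclass
class FntSideMeasures:
    accuracy_distance_m: float  # mean over reps of min hand-to-nose distance
    arm_drop_deg: float  # arm tilt below horizontal on return to T
    veloc_ms: float  # mean path-length speed over to-nose / to-T phases
    min_dist_sd_m: float  # variability over the 5 repetitions
    arm_drop_sd_deg: float
    valid: bool = True


def fnt_features(seg: ManeuverSegment, rec: Recording,
                 cfg: FeatureConfig = FeatureConfig()
                 ) -> dict[str, FntSideMeasures]:
    """Finger-to-nose accuracy, speed and variability, per arm."""
    nose = _nose(rec, cfg)
    out: dict[str, FntSideMeasures] = {}
    for side in ("left", "right"):
        reps = seg.reps_for(side)
        if not reps:
            warnings.warn(f"FNT {side}: missing repetitions, flagged invalid",
                          stacklevel=2)
            out[side] = FntSideMeasures(*(np.nan,) * 5, valid=False)
            continue
        hand = _smoothed(rec, _HAND[side], cfg)
        shoulder = _smoothed(rec, _SHOULDER[side], cfg)
        settle = int(round(0.25 / rec.median_dt))
        min_d, drops, speeds = [], [], []
        for rep in reps:
            d = np.linalg.norm(hand[rep.start:rep.end]
                               - nose[rep.start:rep.end], axis=1)
            i_apex = int(np.argmin(d))
            min_d.append(float(d[i_apex]))
            # tilt of the arm vector below horizontal once the return to T
            # has settled (shortly after the reach excursion ends)
            i_ret = min(rep.end - 1 + settle, seg.end - 1)
            v = hand[i_ret] - shoulder[i_ret]
            norm = np.linalg.norm(v)
            drops.append(max(0.0, float(np.degrees(np.arcsin(-v[1] / norm))))
                         if norm > 0 else np.nan)
            # phase speeds: hand path length / phase duration
            t = rec.times[rep.start:rep.end]
            ph = []
            for s, e in ((0, i_apex + 1), (i_apex, len(d))):
                if e - s < 2:
                    continue
                path = float(np.linalg.norm(
                    np.diff(hand[rep.start + s:rep.start + e], axis=0),
                    axis=1).sum())
                ph.append(path / float(t[e - 1] - t[s]))
            speeds.append(float(np.mean(ph)) if ph else np.nan)
        out[side] = FntSideMeasures(
            accuracy_distance_m=float(np.mean(min_d)),
            arm_drop_deg=float(np.mean(drops)),
            veloc_ms=float(np.mean(speeds)),
            min_dist_sd_m=_sd(np.asarray(min_d)),
            arm_drop_sd_deg=_sd(np.asarray(drops)),
        )
    return out


@dataclass
class SwayMeasures:
    range_m: float  # diameter of the joint's 3-D point cloud
    speed_ms: float  # mean speed
    valid: bool = True


def _stable_window(rec: Recording, joint: J, span: tuple[int, int],
                   band_m: float = 0.15) -> tuple[int, int]:
    """Longest run where the joint stays near its median position.

    Drops pose-transition frames at the segment edges (large excursions)
    while keeping genuine postural sway, which is far below the band.
    """
    a, b = span
    p = rec.joint(joint)[a:b]
    med = np.median(p, axis=0)
    near = np.linalg.norm(p - med, axis=1) < band_m
    runs = _bool_runs(near)
    if not runs:
        return a, b
    s, e = max(runs, key=lambda r: r[1] - r[0])
    return a + s, a + e


def _sway(rec: Recording, joint: J, span: tuple[int, int],
          cfg: FeatureConfig) -> SwayMeasures:
    a, b = _stable_window(rec, joint, span)
    a, b = central_span(a, b, cfg.static_trim_fraction)
    raw = rec.joint(joint)[a:b]
    sm = _smoothed(rec, joint, cfg)[a:b]
    t = rec.times[a:b]
    return SwayMeasures(
        range_m=_cloud_diameter(raw),
        speed_ms=float(np.mean(speed_series(sm, t))),
    )


def static_features(rt: ManeuverSegment, tt: ManeuverSegment, rec: Recording,
                    cfg: FeatureConfig = FeatureConfig()
                    ) -> dict[str, SwayMeasures]:
    """Sway of hands (involuntary movement), head and hip center at rest/T.

    Each static segment is trimmed to its central fraction to drop
    transition frames; measures are averaged over the two conditions.
    Returns keys ``hand_left``, ``hand_right``, ``head``, ``hip``.
    """
    dt = rec.median_dt
    out: dict[str, SwayMeasures] = {}
    joints = {"hand_left": J.HAND_L, "hand_right": J.HAND_R,
              "head": J.HEAD, "hip": J.HIP_CENTER}
    spans = []
    valid = True
    for seg in (rt, tt):
        span = (seg.start, seg.end)
        if (span[1] - span[0]) * dt < cfg.min_static_s:
            warnings.warn(f"{seg.maneuver}: static span shorter than "
                          f"{cfg.min_static_s} s, flagged invalid",
                          stacklevel=2)
            valid = False
        spans.append(span)
    for key, joint in joints.items():
        per_cond = [_sway(rec, joint, span, cfg) for span in spans]
        out[key] = SwayMeasures(
            range_m=float(np.mean([m.range_m for m in per_cond])),
            speed_ms=float(np.mean([m.speed_ms for m in per_cond])),
            valid=valid,
        )
    return out


@dataclass
class SstSideMeasures:
    step_angle_deg: float  # mean apex between-leg angle over reps
    step_angle_sd_deg: float
    foot_height_m: float  # mean apex foot rise above baseline
    pct_time_raised: float  # % of rep time foot above baseline band
    valid: bool = True


def sst_features(seg: ManeuverSegment, rec: Recording,
                 cfg: FeatureConfig = FeatureConfig()
                 ) -> dict[str, SstSideMeasures]:
    """Side-step width (between-leg angle) and leg-movement variability."""
    angle = _between_leg_angle(rec, seg.start, seg.end)
    nb = max(3, int(round(cfg.baseline_s / rec.median_dt)))
    out: dict[str, SstSideMeasures] = {}
    for side in ("left", "right"):
        reps = seg.reps_for(side)
        if not reps:
            warnings.warn(f"SST {side}: missing repetitions, flagged invalid",
                          stacklevel=2)
            out[side] = SstSideMeasures(*(np.nan,) * 4, valid=False)
            continue
        foot_y = rec.joint(_FOOT[side])[:, 1]
        base_y = float(np.median(foot_y[seg.start:seg.start + nb]))
        apex_angles, heights, pcts = [], [], []
        for rep in reps:
            local = angle[rep.start - seg.start:rep.end - seg.start]
            apex_angles.append(float(np.max(local)))
            rise = foot_y[rep.start:rep.end] - base_y
            heights.append(float(np.max(rise)))
            pcts.append(100.0 * float(np.mean(
                rise > cfg.foot_raised_margin_m)))
        out[side] = SstSideMeasures(
            step_angle_deg=float(np.mean(apex_angles)),
            step_angle_sd_deg=_sd(np.asarray(apex_angles)),
            foot_height_m=float(np.mean(heights)),
            pct_time_raised=float(np.mean(pcts)),
        )
    return out


@dataclass
class T45SideMeasures:
    airborne_time_s: float  # time the lifted foot stays above the band
    hold_angle_error_deg: float  # mean |between-leg angle - 45| on the hold
    knee_flexion_deg: float  # mean hip-knee-ankle angle of the lifted leg
    hold_angle_deg: float  # mean between-leg angle on the hold plateau
    valid: bool = True


def t45_features(seg: ManeuverSegment, rec: Recording,
                 cfg: FeatureConfig = FeatureConfig()
                 ) -> dict[str, T45SideMeasures]:
    """Monopodal balance: airborne time and leg posture per side.

    The hold window excludes rise/lower transitions: within the airborne
    run, only frames with between-leg angle at >= 98% of the plateau level
    (95th percentile) contribute to the angle measures.
    """
    angle = _between_leg_angle(rec, seg.start, seg.end)
    dt = rec.median_dt
    nb = max(3, int(round(cfg.baseline_s / dt)))
    out: dict[str, T45SideMeasures] = {}
    for side in ("left", "right"):
        foot_y = rec.joint(_FOOT[side])[seg.start:seg.end, 1]
        base_y = float(np.median(foot_y[:nb]))
        mask = foot_y > base_y + cfg.airborne_threshold_m
        runs = [(s, e) for s, e in _bool_runs(mask)]
        if not runs:
            warnings.warn(f"T45 {side}: no airborne frames", stacklevel=2)
            out[side] = T45SideMeasures(0.0, np.nan, np.nan, np.nan)
            continue
        s, e = max(runs, key=lambda r: r[1] - r[0])
        air_t = (e - s) * dt
        run_angle = angle[s:e]
        plateau = np.quantile(run_angle, 0.95)
        hold = run_angle >= 0.98 * plateau
        knee = angle_series(rec, _HIP[side], _KNEE[side], _ANKLE[side],
                            (seg.start + s, seg.start + e))
        out[side] = T45SideMeasures(
            airborne_time_s=float(air_t),
            hold_angle_error_deg=float(np.mean(
                np.abs(run_angle[hold] - cfg.t45_target_deg))),
            knee_flexion_deg=float(np.mean(knee[hold])),
            hold_angle_deg=float(np.mean(run_angle[hold])),
        )
    return out


@dataclass
class CstMeasures:
    seat_position_sd_m: float  # 3-D dispersion of the seated hip extremum
    hip_speed_ms: float  # mean vertical hip speed, descent + ascent
    trunk_tilt_deg: float  # max frontal-plane trunk angle from vertical
    valid: bool = True


def cst_features(seg: ManeuverSegment, rec: Recording,
                 cfg: FeatureConfig = FeatureConfig()) -> CstMeasures:
    """Chair-to-stand: seated-hip dispersion, vertical speed, trunk tilt."""
    reps = [r for r in seg.repetitions]
    if len(reps) != 5:
        warnings.warn(f"CST: expected 5 repetitions, found {len(reps)}; "
                      "flagged invalid", stacklevel=2)
        if not reps:
            return CstMeasures(np.nan, np.nan, np.nan, valid=False)
    hip = _smoothed(rec, J.HIP_CENTER, cfg)
    seated, speeds = [], []
    for rep in reps:
        y = hip[rep.start:rep.end, 1]
        i_seat = int(np.argmin(y))
        seated.append(hip[rep.start + i_seat])
        path = float(np.abs(np.diff(y)).sum())
        dur = float(rec.times[rep.end - 1] - rec.times[rep.start])
        speeds.append(path / dur if dur > 0 else np.nan)
    seated = np.asarray(seated)
    sd3 = (float(np.sqrt(np.sum(np.var(seated, axis=0, ddof=1))))
           if len(seated) > 1 else 0.0)
    # frontal-plane trunk angle: camera-frame x-y projection from vertical
    sc = _smoothed(rec, J.SHOULDER_CENTER, cfg)[seg.start:seg.end]
    hc = hip[seg.start:seg.end]
    u = sc - hc
    tilt = np.degrees(np.arctan2(np.abs(u[:, 0]), u[:, 1]))
    return CstMeasures(
        seat_position_sd_m=sd3,
        hip_speed_ms=float(np.mean(speeds)),
        trunk_tilt_deg=float(np.max(tilt)),
        valid=len(reps) == 5,
    )


def symmetric_percent_difference(left: float, right: float,
                                 atol: float = 1e-9) -> float:
    """100 * |L - R| / ((L + R) / 2); defined as 0 when L + R vanishes."""
    s = left + right
    if abs(s) <= atol:
        return 0.0
    return 100.0 * abs(left - right) / (s / 2.0)


def asymmetry_features(measures: dict[str, float]) -> dict[str, float]:
    """Upper- and lower-limb asymmetry: mean symmetric percent difference
    over the paired physical sub-measures of each limb's variables."""
    ul_pairs = [("fnt_acc_dist_left", "fnt_acc_dist_right"),
                ("fnt_veloc_left", "fnt_veloc_right"),
                ("fnt_min_dist_sd_left", "fnt_min_dist_sd_right"),
                ("hand_range_left", "hand_range_right")]
    ll_pairs = [("sst_foot_height_left", "sst_foot_height_right"),
                ("t45_air_time_left", "t45_air_time_right"),
                ("sst_step_angle_left", "sst_step_angle_right")]
    out = {}
    for key, pairs in (("asymmetry_ul", ul_pairs), ("asymmetry_ll", ll_pairs)):
        vals = []
        for lk, rk in pairs:
            lv, rv = measures.get(lk, np.nan), measures.get(rk, np.nan)
            if np.isfinite(lv) and np.isfinite(rv):
                vals.append(symmetric_percent_difference(lv, rv))
        if vals:
            out[key] = float(np.mean(vals))
        else:
            warnings.warn(f"{key}: all pairs invalid", stacklevel=2)
            out[key] = np.nan
    return out


# --------------------------------------------------------------------------
# trial-level assembly
# --------------------------------------------------------------------------


def extract_trial_measures(
    rec: Recording,
    segments: list[ManeuverSegment],
    cfg: FeatureConfig = FeatureConfig(),
) -> dict[str, float]:
    """All physical sub-measures for one subject-series recording.

    ``segments`` must contain one segment per maneuver; FNT/SST/CST segments
    must carry their repetition sub-spans.
    """
    by_name = {s.maneuver: s for s in segments}
    m: dict[str, float] = {}

    fnt = fnt_features(by_name["FNT"], rec, cfg)
    for side in ("left", "right"):
        f = fnt[side]
        m[f"fnt_acc_dist_{side}"] = f.accuracy_distance_m
        m[f"fnt_arm_drop_{side}"] = f.arm_drop_deg
        m[f"fnt_veloc_{side}"] = f.veloc_ms
        m[f"fnt_min_dist_sd_{side}"] = f.min_dist_sd_m
        m[f"fnt_arm_drop_sd_{side}"] = f.arm_drop_sd_deg

    stat = static_features(by_name["RT"], by_name["TT"], rec, cfg)
    for side in ("left", "right"):
        m[f"hand_range_{side}"] = stat[f"hand_{side}"].range_m
        m[f"hand_speed_{side}"] = stat[f"hand_{side}"].speed_ms
    m["head_range"] = stat["head"].range_m
    m["head_speed"] = stat["head"].speed_ms
    m["hip_range"] = stat["hip"].range_m
    m["hip_speed"] = stat["hip"].speed_ms

    sst = sst_features(by_name["SST"], rec, cfg)
    for side in ("left", "right"):
        s = sst[side]
        m[f"sst_step_angle_{side}"] = s.step_angle_deg
        m[f"sst_step_angle_sd_{side}"] = s.step_angle_sd_deg
        m[f"sst_foot_height_{side}"] = s.foot_height_m
        m[f"sst_pct_raised_{side}"] = s.pct_time_raised

    t45 = t45_features(by_name["T45"], rec, cfg)
    for side in ("left", "right"):
        t = t45[side]
        m[f"t45_air_time_{side}"] = t.airborne_time_s
        m[f"t45_hold_err_{side}"] = t.hold_angle_error_deg
        m[f"t45_knee_flexion_{side}"] = t.knee_flexion_deg

    cst = cst_features(by_name["CST"], rec, cfg)
    m["cst_seat_sd"] = cst.seat_position_sd_m
    m["cst_hip_speed"] = cst.hip_speed_ms
    m["cst_trunk_tilt"] = cst.trunk_tilt_deg

    m.update(asymmetry_features(m))
    return m


def compose_variables(submeasures: pd.DataFrame,
                      reference: pd.DataFrame | None = None) -> pd.DataFrame:
    """Assemble the 20 motor variables from a sub-measure table.

    ``submeasures`` is indexed by (subject_id, series_index) with one column
    per sub-measure.  Multi-measure variables become equal-weight z-score
    composites standardized against ``reference`` (default: the input cohort
    itself), shifted by +5 so the composite scale stays positive;
    single-measure variables keep their natural units.
    """
    ref = reference if reference is not None else submeasures
    out = pd.DataFrame(index=submeasures.index)
    for var in VARIABLE_NAMES:
        parts = COMPOSITES[var]
        if len(parts) == 1:
            out[var] = submeasures[parts[0]]
            continue
        zs = []
        for p in parts:
            mu = ref[p].mean()
            sd = ref[p].std(ddof=1)
            if not np.isfinite(sd) or sd == 0:
                zs.append(pd.Series(0.0, index=submeasures.index))
            else:
                zs.append((submeasures[p] - mu) / sd)
        out[var] = COMPOSITE_CENTER + sum(zs) / len(parts)
    return out
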