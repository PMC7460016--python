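"""Synthetic skeleton recordings of the six-maneuver motor protocol.

The generator replaces the depth-camera hardware: it renders a stick-figure
skeleton (20 joints) performing, in order, a scripted "greeting" (bilateral
wrist flap) followed by each of the six maneuvers -- resting test (RT),
T-position test (TT), finger-to-nose test (FNT, 5 repetitions per arm),
sideways step test (SST, 5 per leg), 45-degree monopodal balance (T45, one
hold per leg) and chair-to-stand (CST, 5 cycles) -- then adds per-axis
Gaussian sensor noise with the published accuracy sigmas of the camera.

Motion templates are minimum-jerk point-to-point trajectories (5th-order
polynomial) and raised-cosine oscillations for the greeting, so every
programmed apex, angle and duration is known exactly and is returned in a
:class:`GroundTruth` object alongside the noisy recording.  That makes the
generator the oracle for every downstream stage: segmentation can be scored
against the true greeting onsets and spans, and feature extraction against
the programmed kinematic values.

A single integer seed drives subject-level effects, trial-level effects and
sensor noise through independent named substreams, so each source of
variation can be zeroed independently.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq

from .skeleton_io import JointName as J
from .skeleton_io import N_JOINTS, Recording, SubjectProfile

__all__ = [
    "SensorModel",
    "MotionScript",
    "VarianceComponents",
    "GroundTruth",
    "ManeuverTruth",
    "RepTruth",
    "DEFAULT_ORDER",
    "simulate_feature_matrix",
    "simulate_recording",
    "simulate_cohort",
    "substream",
    "apply_sensor_noise",
    "rest_pose",
    "t_pose",
]

DEFAULT_ORDER: tuple[str, ...] = ("RT", "TT", "FNT", "SST", "T45", "CST")


def _pair(v) -> tuple[float, float]:
    """Normalize a scalar-or-(left, right) parameter to a pair."""
    if isinstance(v, (tuple, list, np.ndarray)):
        a, b = v
        return float(a), float(b)
    return float(v), float(v)


def substream(seed: int, name: str) -> np.random.Generator:
    """Deterministic named random substream derived from one master seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])
    )


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SensorModel:
    """Depth-camera error model: per-axis accuracy sigmas (m) and geometry."""

    sigma_x: float = 0.0065
    sigma_y: float = 0.0109
    sigma_z: float = 0.0057
    rate: float = 30.0
    operating_range: tuple[float, float] = (1.0, 3.0)
    fov_h_deg: float = 54.0
    fov_v_deg: float = 39.1

    def __post_init__(self) -> None:
        if min(self.sigma_x, self.sigma_y, self.sigma_z) < 0:
            raise ValueError("sensor sigmas must be >= 0")
        lo, hi = self.operating_range
        if not lo < hi:
            raise ValueError("operating_range min must be < max")
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    @property
    def sigmas(self) -> np.ndarray:
        return np.array([self.sigma_x, self.sigma_y, self.sigma_z])

    def noiseless(self) -> "SensorModel":
        return replace(self, sigma_x=0.0, sigma_y=0.0, sigma_z=0.0)


@dataclass(frozen=True)
class MotionScript:
    """Per-maneuver kinematic program (all durations s, angles degrees)."""

    # greeting flap (bilateral wrist oscillation)
    greeting_amplitude_m: float = 0.35
    greeting_freq_hz: float = 1.5
    greeting_cycles: float = 2.0
    # static holds (RT, TT) and repetition count for dynamic maneuvers
    static_hold_s: float = 10.0
    repetitions: int = 5
    # finger-to-nose (scalars apply to both arms; pairs are (left, right))
    fnt_reach_s: float | tuple[float, float] = 0.9
    fnt_dwell_s: float = 0.15
    fnt_jitter_sd_m: float | tuple[float, float] = 0.012
    fnt_droop_deg: float | tuple[float, float] = 3.0
    fnt_droop_sd_deg: float = 0.8
    nose_offset_m: float = 0.10
    # sideways step: programmed between-leg angle per side (left, right)
    sst_step_angle_deg: tuple[float, float] = (28.0, 28.0)
    sst_rise_s: float = 0.7
    sst_dwell_s: float = 0.2
    sst_angle_jitter_deg: float = 1.0
    # monopodal balance at 45 degrees; knee flexion 180 = straight leg
    t45_angle_deg: float = 45.0
    t45_hold_s: float | tuple[float, float] = 10.0
    t45_rise_s: float = 0.8
    t45_knee_flexion_deg: float | tuple[float, float] = 172.0
    # chair-to-stand
    cst_seat_height_m: float | None = None  # default: knee height
    cst_trunk_tilt_deg: float = 8.0
    cst_descent_s: float = 1.2
    cst_dwell_s: float = 0.4
    cst_seat_jitter_m: float = 0.008
    # protocol timing
    rest_gap_s: float = 3.0
    transition_s: float = 1.0
    pause_s: float = 0.5
    pre_greeting_pause_s: float = 0.8
    inter_rep_pause_s: float = 0.3
    # postural sway (slow horizontal whole-body oscillation)
    sway_amplitude_m: float = 0.004
    sway_freqs_hz: tuple[float, float] = (0.25, 0.18)
    # placement
    distance_m: float = 2.6
    camera_height_m: float = 0.9

    def __post_init__(self) -> None:
        for name in (
            "static_hold_s",
            "fnt_reach_s",
            "sst_rise_s",
            "t45_hold_s",
            "t45_rise_s",
            "cst_descent_s",
            "transition_s",
        ):
            if min(_pair(getattr(self, name))) <= 0:
                raise ValueError(f"{name} must be > 0")
        for ang in (*_pair(self.sst_step_angle_deg), self.t45_angle_deg,
                    self.cst_trunk_tilt_deg, *_pair(self.fnt_droop_deg)):
            if not 0.0 <= ang <= 90.0:
                raise ValueError(f"programmed angles must lie in [0, 90], got {ang}")
        for flex in _pair(self.t45_knee_flexion_deg):
            if not 90.0 <= flex <= 180.0:
                raise ValueError("knee flexion must lie in [90, 180] degrees")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if self.greeting_amplitude_m < 0 or self.sway_amplitude_m < 0:
            raise ValueError("amplitudes must be >= 0")

    @property
    def greeting_duration_s(self) -> float:
        return self.greeting_cycles / self.greeting_freq_hz


@dataclass(frozen=True)
class VarianceComponents:
    """Population variance model for one trait measured over repeated trials.

    y_ij = mu + b_i + e_ij, with between-subject variance sigma2_between and
    within-subject (between-trial) variance sigma2_within.  The implied true
    intraclass correlation is sigma2_between / (sigma2_between + sigma2_within).
    """

    mu: float
    sigma2_between: float
    sigma2_within: float

    def __post_init__(self) -> None:
        if self.sigma2_between < 0 or self.sigma2_within < 0:
            raise ValueError("variance components must be >= 0")

    @property
    def icc_true(self) -> float:
        tot = self.sigma2_between + self.sigma2_within
        return self.sigma2_between / tot if tot > 0 else float("nan")

    @classmethod
    def from_icc(cls, mu: float, icc: float, total_var: float = 1.0
                 ) -> "VarianceComponents":
        if not 0.0 <= icc <= 1.0:
            raise ValueError("icc must lie in [0, 1]")
        return cls(mu, icc * total_var, (1.0 - icc) * total_var)


def simulate_feature_matrix(
    n_subjects: int,
    k_trials: int,
    vc: VarianceComponents,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """n x k matrix from the one-way random-effects model of ``vc``."""
    if n_subjects < 2 or k_trials < 2:
        raise ValueError("need n_subjects >= 2 and k_trials >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    b = rng.normal(0.0, np.sqrt(vc.sigma2_between), size=(n_subjects, 1))
    e = rng.normal(0.0, np.sqrt(vc.sigma2_within), size=(n_subjects, k_trials))
    return vc.mu + b + e


# --------------------------------------------------------------------------
# ground truth containers
# --------------------------------------------------------------------------


@dataclass
class RepTruth:
    start_s: float
    end_s: float
    apex_s: float
    side: str  # left / right / n/a
    programmed: dict


@dataclass
class ManeuverTruth:
    maneuver: str
    active_start_s: float
    active_end_s: float
    segment_start_s: float = 0.0
    segment_end_s: float = 0.0
    reps: list[RepTruth] = field(default_factory=list)
    programmed: dict = field(default_factory=dict)


def _frame_of(t: float, rate: float) -> int:
    return int(np.ceil(t * rate - 1e-9))


@dataclass
class GroundTruth:
    """Exact programmed timing and kinematics of a simulated recording."""

    rate: float
    duration_s: float
    greeting_onsets_s: list[float]
    greeting_ends_s: list[float]
    maneuvers: list[ManeuverTruth]

    @property
    def n_greetings(self) -> int:
        return len(self.greeting_onsets_s)

    def greeting_onset_frames(self) -> list[int]:
        return [_frame_of(t, self.rate) for t in self.greeting_onsets_s]

    def segment_frame_spans(self) -> list[tuple[int, int]]:
        return [
            (_frame_of(m.segment_start_s, self.rate),
             _frame_of(m.segment_end_s, self.rate))
            for m in self.maneuvers
        ]

    def active_frame_spans(self) -> list[tuple[int, int]]:
        return [
            (_frame_of(m.active_start_s, self.rate),
             _frame_of(m.active_end_s, self.rate))
            for m in self.maneuvers
        ]

    def maneuver(self, name: str) -> ManeuverTruth:
        for m in self.maneuvers:
            if m.maneuver == name:
                return m
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {
            "rate": self.rate,
            "duration_s": self.duration_s,
            "greeting_onsets_s": list(self.greeting_onsets_s),
            "greeting_ends_s": list(self.greeting_ends_s),
            "maneuvers": [
                {
                    "maneuver": m.maneuver,
                    "active_start_s": m.active_start_s,
                    "active_end_s": m.active_end_s,
                    "segment_start_s": m.segment_start_s,
                    "segment_end_s": m.segment_end_s,
                    "programmed": m.programmed,
                    "reps": [
                        {
                            "start_s": r.start_s,
                            "end_s": r.end_s,
                            "apex_s": r.apex_s,
                            "side": r.side,
                            "programmed": r.programmed,
                        }
                        for r in m.reps
                    ],
                }
                for m in self.maneuvers
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            rate=d["rate"],
            duration_s=d["duration_s"],
            greeting_onsets_s=list(d["greeting_onsets_s"]),
            greeting_ends_s=list(d["greeting_ends_s"]),
            maneuvers=[
                ManeuverTruth(
                    maneuver=m["maneuver"],
                    active_start_s=m["active_start_s"],
                    active_end_s=m["active_end_s"],
                    segment_start_s=m["segment_start_s"],
                    segment_end_s=m["segment_end_s"],
                    programmed=m["programmed"],
                    reps=[RepTruth(**r) for r in m["reps"]],
                )
                for m in d["maneuvers"]
            ],
        )


# --------------------------------------------------------------------------
# pose construction
# --------------------------------------------------------------------------


def _minjerk(tau: np.ndarray | float) -> np.ndarray | float:
    """Minimum-jerk position profile s(tau) on [0, 1]."""
    tau = np.clip(tau, 0.0, 1.0)
    return tau**3 * (10.0 - 15.0 * tau + 6.0 * tau**2)


def rest_pose(stature_m: float, distance_m: float = 2.6,
              camera_height_m: float = 0.9) -> np.ndarray:
    """Neutral standing pose, (20, 3) camera-space meters, arms at sides."""
    H = stature_m
    z0 = distance_m
    y0 = -camera_height_m  # floor height in camera space
    p = np.zeros((N_JOINTS, 3))

    def put(j: J, x: float, y: float, z: float = z0) -> None:
        p[j.value] = (x, y0 + y, z)

    put(J.HIP_CENTER, 0.0, 0.530 * H)
    put(J.SPINE, 0.0, 0.650 * H)
    put(J.SHOULDER_CENTER, 0.0, 0.820 * H)
    put(J.HEAD, 0.0, 0.930 * H)
    for sx, sh, el, wr, ha, hp, an in (
        (-1, J.SHOULDER_L, J.ELBOW_L, J.WRIST_L, J.HAND_L, J.HIP_L, J.ANKLE_L),
        (+1, J.SHOULDER_R, J.ELBOW_R, J.WRIST_R, J.HAND_R, J.HIP_R, J.ANKLE_R),
    ):
        put(sh, sx * 0.120 * H, 0.820 * H)
        put(el, sx * 0.140 * H, 0.650 * H)
        put(wr, sx * 0.150 * H, 0.490 * H)
        put(ha, sx * 0.155 * H, 0.430 * H)
        put(hp, sx * 0.060 * H, 0.530 * H)
        put(an, sx * 0.050 * H, 0.050 * H)
    # knees collinear on the hip->ankle segment; feet rigid offsets of ankles
    for hp, kn, an, ft in (
        (J.HIP_L, J.KNEE_L, J.ANKLE_L, J.FOOT_L),
        (J.HIP_R, J.KNEE_R, J.ANKLE_R, J.FOOT_R),
    ):
        p[kn.value] = p[hp.value] + 0.5 * (p[an.value] - p[hp.value])
        p[ft.value] = p[an.value] + np.array([0.0, -0.030 * H, -0.080 * H])
    return p


_ARM = {
    "left": (J.SHOULDER_L, J.ELBOW_L, J.WRIST_L, J.HAND_L, -1),
    "right": (J.SHOULDER_R, J.ELBOW_R, J.WRIST_R, J.HAND_R, +1),
}
_LEG = {
    "left": (J.HIP_L, J.KNEE_L, J.ANKLE_L, J.FOOT_L, -1),
    "right": (J.HIP_R, J.KNEE_R, J.ANKLE_R, J.FOOT_R, +1),
}


def _set_arm_tilt(pose: np.ndarray, side: str, stature_m: float,
                  droop_deg: float = 0.0) -> np.ndarray:
    """Arm outstretched horizontally (T position), tilted down by droop_deg."""
    H = stature_m
    sh, el, wr, ha, sx = _ARM[side]
    p = pose.copy()
    s = p[sh.value]
    d = np.deg2rad(droop_deg)
    u = np.array([sx * np.cos(d), -np.sin(d), 0.0])
    p[el.value] = s + 0.145 * H * u
    p[wr.value] = s + 0.270 * H * u
    p[ha.value] = s + 0.310 * H * u
    return p


def t_pose(stature_m: float, distance_m: float = 2.6,
           camera_height_m: float = 0.9) -> np.ndarray:
    """Standing pose with both arms outstretched horizontally."""
    p = rest_pose(stature_m, distance_m, camera_height_m)
    p = _set_arm_tilt(p, "left", stature_m)
    p = _set_arm_tilt(p, "right", stature_m)
    return p


def _rotz(phi: float) -> np.ndarray:
    c, s = np.cos(phi), np.sin(phi)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _leg_at_angle(pose_rest: np.ndarray, side: str, phi_deg: float,
                  knee_flexion_deg: float = 180.0) -> np.ndarray:
    """Pose with one leg abducted so the between-leg angle is exactly phi_deg.

    The between-leg angle is measured, as downstream features do, between the
    HIP_CENTER->ANKLE vectors of the two legs.  The moving ankle is placed by
    rotating the stance leg's hip-center->ankle vector by phi in the frontal
    plane; the foot rigidly follows.  The moving knee sits on the hip->ankle
    chord, offset forward so the hip-knee-ankle angle equals
    ``knee_flexion_deg`` (180 = straight leg).
    """
    p = pose_rest.copy()
    other = "right" if side == "left" else "left"
    hp, kn, an, ft, sx = _LEG[side]
    an_st = _LEG[other][2]
    hc = pose_rest[J.HIP_CENTER.value]
    v_st = pose_rest[an_st.value] - hc
    new_dir = _rotz(sx * np.deg2rad(phi_deg)) @ v_st
    foot_off = pose_rest[ft.value] - pose_rest[an.value]
    p[an.value] = hc + new_dir
    mid = p[hp.value] + 0.5 * (p[an.value] - p[hp.value])
    if knee_flexion_deg >= 179.99:
        p[kn.value] = mid
    else:
        L = np.linalg.norm(p[an.value] - p[hp.value])
        cf = np.cos(np.deg2rad(knee_flexion_deg))
        h = 0.5 * L * np.sqrt((1.0 + cf) / (1.0 - cf))
        p[kn.value] = mid + np.array([0.0, 0.0, -h])  # knee bends forward
    p[ft.value] = p[an.value] + foot_off
    return p


def _rest_between_leg_angle(pose_rest: np.ndarray) -> float:
    hc = pose_rest[J.HIP_CENTER.value]
    vl = pose_rest[J.ANKLE_L.value] - hc
    vr = pose_rest[J.ANKLE_R.value] - hc
    c = np.dot(vl, vr) / (np.linalg.norm(vl) * np.linalg.norm(vr))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


# --------------------------------------------------------------------------
# timeline assembly
# --------------------------------------------------------------------------

PoseFn = Callable[[np.ndarray], np.ndarray]  # (m,) local times -> (m, 20, 3)


class _Timeline:
    def __init__(self) -> None:
        self.starts: list[float] = []
        self.durations: list[float] = []
        self.fns: list[PoseFn] = []
        self.t = 0.0

    def add(self, duration: float, fn: PoseFn) -> tuple[float, float]:
        t0 = self.t
        self.starts.append(t0)
        self.durations.append(duration)
        self.fns.append(fn)
        self.t += duration
        return t0, self.t

    def hold(self, pose: np.ndarray, duration: float) -> tuple[float, float]:
        return self.add(duration, lambda tl, p=pose: np.broadcast_to(
            p, (tl.size, N_JOINTS, 3)).copy())

    def interp(self, p0: np.ndarray, p1: np.ndarray, duration: float
               ) -> tuple[float, float]:
        def fn(tl: np.ndarray, a=p0, b=p1, d=duration) -> np.ndarray:
            s = np.asarray(_minjerk(tl / d))[:, None, None]
            return a[None] + s * (b[None] - a[None])
        return self.add(duration, fn)

    def sample(self, rate: float) -> tuple[np.ndarray, np.ndarray]:
        total = self.t
        n = int(np.floor(total * rate - 1e-9)) + 1
        t = np.arange(n) / rate
        pos = np.empty((n, N_JOINTS, 3))
        edges = np.array(self.starts + [total])
        idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0,
                      len(self.fns) - 1)
        for b in range(len(self.fns)):
            mask = idx == b
            if mask.any():
                pos[mask] = self.fns[b](t[mask] - self.starts[b])
        return t, pos


def _greeting_fn(pose: np.ndarray, amp: float, freq: float, dur: float) -> PoseFn:
    wrists = [J.WRIST_L.value, J.WRIST_R.value, J.HAND_L.value, J.HAND_R.value]

    def fn(tl: np.ndarray) -> np.ndarray:
        out = np.broadcast_to(pose, (tl.size, N_JOINTS, 3)).copy()
        env = 0.5 * (1.0 - np.cos(2.0 * np.pi * tl / dur))
        dy = amp * env * np.sin(2.0 * np.pi * freq * tl)
        out[:, wrists, 1] += dy[:, None]
        return out

    return fn


def _piecewise_angle_fn(pose_rest: np.ndarray, side: str, a0: float,
                        a1: float, rise: float, dwell: float, fall: float,
                        knee_flexion_deg: float = 180.0) -> PoseFn:
    """Leg abduction angle profile a0 -> a1 (min-jerk), hold, back to a0.

    Knee flexion follows the same profile, from straight (180) at rest to
    ``knee_flexion_deg`` on the plateau, so the pose stays continuous.
    """

    def fn(tl: np.ndarray) -> np.ndarray:
        s = np.empty_like(tl)
        m1 = tl < rise
        m2 = (tl >= rise) & (tl < rise + dwell)
        m3 = tl >= rise + dwell
        s[m1] = _minjerk(tl[m1] / rise)
        s[m2] = 1.0
        s[m3] = 1.0 - _minjerk((tl[m3] - rise - dwell) / fall)
        phi = a0 + (a1 - a0) * s
        flex = 180.0 + (knee_flexion_deg - 180.0) * s
        out = np.empty((tl.size, N_JOINTS, 3))
        # angles vary slowly within a block; per-frame pose build is exact
        for i in range(tl.size):
            out[i] = _leg_at_angle(pose_rest, side, phi[i], flex[i])
        return out

    return fn


# --------------------------------------------------------------------------
# main generator
# --------------------------------------------------------------------------


def apply_sensor_noise(positions: np.ndarray, sensor: SensorModel,
                       rng: np.random.Generator) -> np.ndarray:
    """Add i.i.d. per-axis Gaussian noise to every joint in every frame."""
    noisy = positions + rng.normal(0.0, 1.0, size=positions.shape) * sensor.sigmas
    return noisy


def _fov_check(positions: np.ndarray, sensor: SensorModel) -> np.ndarray:
    """Frame indices where any joint leaves the field of view / range."""
    x, y, z = positions[..., 0], positions[..., 1], positions[..., 2]
    tan_h = np.tan(np.deg2rad(sensor.fov_h_deg / 2.0))
    tan_v = np.tan(np.deg2rad(sensor.fov_v_deg / 2.0))
    lo, hi = sensor.operating_range
    with np.errstate(divide="ignore", invalid="ignore"):
        bad = (
            (z < lo) | (z > hi)
            | (np.abs(x) > tan_h * z)
            | (np.abs(y) > tan_v * z)
        )
    return np.where(bad.any(axis=1))[0]


def simulate_recording(
    profile: SubjectProfile,
    script: MotionScript | None = None,
    sensor: SensorModel | None = None,
    seed: int = 0,
    series_index: int = 1,
    order: Sequence[str] = DEFAULT_ORDER,
) -> tuple[Recording, GroundTruth]:
    """Render one series of the six-maneuver protocol for one subject.

    Returns the noisy :class:`Recording` and the exact :class:`GroundTruth`
    (greeting onsets, maneuver spans, repetition spans and programmed
    kinematic values).
    """
    script = script or MotionScript()
    sensor = sensor or SensorModel()
    rng_kin = substream(seed, "kinematics")
    rng_noise = substream(seed, "noise")
    rng_sway = substream(seed, "sway")

    H = profile.stature_m
    rest = rest_pose(H, script.distance_m, script.camera_height_m)
    tpos = t_pose(H, script.distance_m, script.camera_height_m)
    a0 = _rest_between_leg_angle(rest)

    tl = _Timeline()
    greet_on: list[float] = []
    greet_off: list[float] = []
    maneuvers: list[ManeuverTruth] = []

    current = rest
    tl.hold(rest, 1.0)  # initial settle

    for name in order:
        start_pose = tpos if name in ("TT", "FNT") else rest
        if not np.array_equal(current, start_pose):
            tl.interp(current, start_pose, script.transition_s)
            current = start_pose
        tl.hold(current, script.pre_greeting_pause_s)  # settle before greeting
        g0, g1 = tl.add(
            script.greeting_duration_s,
            _greeting_fn(current, script.greeting_amplitude_m,
                         script.greeting_freq_hz, script.greeting_duration_s),
        )
        greet_on.append(g0)
        greet_off.append(g1)
        builder = _MANEUVER_BUILDERS[name]
        truth, current = builder(tl, current, rest, tpos, H, a0, script, rng_kin)
        maneuvers.append(truth)
        tl.hold(current, script.rest_gap_s)

    total = tl.t
    for i, m in enumerate(maneuvers):
        m.segment_start_s = greet_off[i]
        m.segment_end_s = greet_on[i + 1] if i + 1 < len(greet_on) else total

    times, pos = tl.sample(sensor.rate)

    # postural sway: slow whole-body horizontal oscillation (x and z)
    if script.sway_amplitude_m > 0:
        ph = rng_sway.uniform(0.0, 2.0 * np.pi, size=4)
        f1, f2 = script.sway_freqs_hz
        a = script.sway_amplitude_m
        sx = a * (np.sin(2 * np.pi * f1 * times + ph[0])
                  + 0.5 * np.sin(2 * np.pi * f2 * times + ph[1]))
        sz = 0.6 * a * (np.sin(2 * np.pi * f1 * times + ph[2])
                        + 0.5 * np.sin(2 * np.pi * f2 * times + ph[3]))
        pos[:, :, 0] += sx[:, None]
        pos[:, :, 2] += sz[:, None]

    out_of_view = _fov_check(pos, sensor)
    if out_of_view.size:
        warnings.warn(
            f"subject {profile.subject_id}: {out_of_view.size} frames outside "
            f"the field of view / operating range (first: "
            f"{out_of_view[:5].tolist()})",
            stacklevel=2,
        )

    pos = apply_sensor_noise(pos, sensor, rng_noise)

    rec = Recording(
        subject_id=profile.subject_id,
        series_index=series_index,
        times=times,
        positions=pos,
        nominal_rate=sensor.rate,
    )
    gt = GroundTruth(
        rate=sensor.rate,
        duration_s=total,
        greeting_onsets_s=greet_on,
        greeting_ends_s=greet_off,
        maneuvers=maneuvers,
    )
    return rec, gt


# ---- per-maneuver builders -------------------------------------------------
# each returns (ManeuverTruth, end_pose) and appends blocks to the timeline


def _build_static(name: str):
    def build(tl, current, rest, tpos, H, a0, script, rng):
        t0, t1 = tl.hold(current, script.static_hold_s)
        truth = ManeuverTruth(
            maneuver=name, active_start_s=t0, active_end_s=t1,
            programmed={"hold_s": script.static_hold_s},
        )
        return truth, current

    return build


def _build_fnt(tl, current, rest, tpos, H, a0, script, rng):
    nose = tpos[J.HEAD.value] + np.array([0.0, 0.0, -script.nose_offset_m])
    t_act0 = tl.t
    reps: list[RepTruth] = []
    pose = current
    tl.hold(pose, script.pause_s)
    jitter_sd = _pair(script.fnt_jitter_sd_m)
    droop_mean = _pair(script.fnt_droop_deg)
    reach_s = _pair(script.fnt_reach_s)
    for i_side, side in enumerate(("left", "right")):
        sh, el, wr, ha, sx = _ARM[side]
        for _ in range(script.repetitions):
            jitter = rng.normal(0.0, jitter_sd[i_side], size=3)
            droop = max(0.0, rng.normal(droop_mean[i_side],
                                        script.fnt_droop_sd_deg))
            target = nose + jitter
            reach = pose.copy()
            s = pose[sh.value]
            u = (s - target)
            u /= np.linalg.norm(u)
            reach[ha.value] = target
            reach[wr.value] = target + 0.09 * u
            reach[el.value] = s + 0.5 * (reach[wr.value] - s) + np.array(
                [0.0, -0.10, 0.0])
            back = _set_arm_tilt(pose, side, H, droop)
            r0, _ = tl.interp(pose, reach, reach_s[i_side])
            ap0, _ = tl.hold(reach, script.fnt_dwell_s)
            _, r1 = tl.interp(reach, back, reach_s[i_side])
            tl.hold(back, script.inter_rep_pause_s)
            pose = back
            reps.append(RepTruth(
                start_s=r0, end_s=r1, apex_s=ap0, side=side,
                programmed={
                    "min_distance_m": float(np.linalg.norm(jitter)),
                    "droop_deg": float(droop),
                },
            ))
        tl.hold(pose, script.pause_s)
    truth = ManeuverTruth(
        maneuver="FNT", active_start_s=t_act0, active_end_s=tl.t, reps=reps,
        programmed={"nose_offset_m": script.nose_offset_m},
    )
    return truth, pose


def _build_sst(tl, current, rest, tpos, H, a0, script, rng):
    t_act0 = tl.t
    reps: list[RepTruth] = []
    tl.hold(rest, script.pause_s)
    for side, base_angle in zip(("left", "right"), script.sst_step_angle_deg):
        for _ in range(script.repetitions):
            theta = float(np.clip(
                base_angle + rng.normal(0.0, script.sst_angle_jitter_deg),
                a0 + 2.0, 88.0))
            dur = script.sst_rise_s + script.sst_dwell_s + script.sst_rise_s
            r0, r1 = tl.add(dur, _piecewise_angle_fn(
                rest, side, a0, theta, script.sst_rise_s, script.sst_dwell_s,
                script.sst_rise_s))
            tl.hold(rest, script.inter_rep_pause_s)
            apex_pose = _leg_at_angle(rest, side, theta)
            foot_rise = float(apex_pose[_LEG[side][3].value, 1]
                              - rest[_LEG[side][3].value, 1])
            reps.append(RepTruth(
                start_s=r0, end_s=r1, apex_s=r0 + script.sst_rise_s,
                side=side,
                programmed={"apex_angle_deg": theta,
                            "apex_foot_rise_m": foot_rise},
            ))
        tl.hold(rest, script.pause_s)
    truth = ManeuverTruth(
        maneuver="SST", active_start_s=t_act0, active_end_s=tl.t, reps=reps,
        programmed={"rest_angle_deg": a0},
    )
    return truth, rest


def _airborne_compensation(rest: np.ndarray, side: str, a0: float,
                           theta: float, rise_s: float,
                           threshold_m: float = 0.05) -> float:
    """Time during one min-jerk rise spent above the airborne threshold.

    Used to shrink the plateau so total time above threshold equals the
    programmed hold duration.
    """
    ft = _LEG[side][3]
    y0 = rest[ft.value, 1]

    def rise_at(phi: float) -> float:
        return _leg_at_angle(rest, side, phi)[ft.value, 1] - y0

    if rise_at(theta) <= threshold_m:
        return 0.0
    phi_c = brentq(lambda p: rise_at(p) - threshold_m, a0, theta, xtol=1e-10)
    s_star = (phi_c - a0) / (theta - a0)
    tau_c = brentq(lambda t: _minjerk(t) - s_star, 0.0, 1.0, xtol=1e-12)
    return rise_s * (1.0 - tau_c)


def _build_t45(tl, current, rest, tpos, H, a0, script, rng):
    t_act0 = tl.t
    reps: list[RepTruth] = []
    tl.hold(rest, script.pause_s)
    holds = _pair(script.t45_hold_s)
    flexions = _pair(script.t45_knee_flexion_deg)
    for side, hold_s, flex in zip(("left", "right"), holds, flexions):
        theta = float(np.clip(script.t45_angle_deg, a0 + 2.0, 88.0))
        extra = _airborne_compensation(rest, side, a0, theta, script.t45_rise_s)
        plateau = max(hold_s - 2.0 * extra, 0.1)
        dur = script.t45_rise_s + plateau + script.t45_rise_s
        r0, r1 = tl.add(dur, _piecewise_angle_fn(
            rest, side, a0, theta, script.t45_rise_s, plateau,
            script.t45_rise_s, knee_flexion_deg=flex))
        tl.hold(rest, script.pause_s)
        reps.append(RepTruth(
            start_s=r0, end_s=r1, apex_s=r0 + script.t45_rise_s, side=side,
            programmed={
                "angle_deg": theta,
                "airborne_s": plateau + 2.0 * extra,
                "plateau_s": plateau,
                "knee_flexion_deg": flex,
            },
        ))
    truth = ManeuverTruth(
        maneuver="T45", active_start_s=t_act0, active_end_s=tl.t, reps=reps,
        programmed={"target_angle_deg": script.t45_angle_deg,
                    "hold_s": script.t45_hold_s},
    )
    return truth, rest


def _cst_pose(rest: np.ndarray, H: float, frac: float, drop: float,
              tilt_deg: float, lateral: np.ndarray) -> np.ndarray:
    """Chair-to-stand pose at descent fraction ``frac`` in [0, 1]."""
    p = rest.copy()
    hc0 = rest[J.HIP_CENTER.value]
    sc0 = rest[J.SHOULDER_CENTER.value]
    trunk_len = np.linalg.norm(sc0 - hc0)
    delta = frac * (np.array([0.0, -drop, 0.0]) + lateral)
    psi = np.deg2rad(tilt_deg * frac)
    hc = hc0 + delta
    for j in (J.HIP_CENTER, J.HIP_L, J.HIP_R):
        p[j.value] = rest[j.value] + delta
    trunk_dir = np.array([np.sin(psi), np.cos(psi), 0.0])
    sc = hc + trunk_len * trunk_dir
    p[J.SHOULDER_CENTER.value] = sc
    p[J.SPINE.value] = hc + 0.55 * trunk_len * trunk_dir
    head_off = rest[J.HEAD.value] - sc0
    hl = np.linalg.norm(head_off)
    p[J.HEAD.value] = sc + hl * trunk_dir
    sc_shift = sc - sc0
    for j in (J.SHOULDER_L, J.SHOULDER_R, J.ELBOW_L, J.ELBOW_R,
              J.WRIST_L, J.WRIST_R, J.HAND_L, J.HAND_R):
        p[j.value] = rest[j.value] + sc_shift
    return p


def _build_cst(tl, current, rest, tpos, H, a0, script, rng):
    t_act0 = tl.t
    reps: list[RepTruth] = []
    knee_y = rest[J.KNEE_L.value, 1]
    seat_y = (script.cst_seat_height_m + rest[J.FOOT_L.value, 1]
              if script.cst_seat_height_m is not None else knee_y)
    drop = float(rest[J.HIP_CENTER.value, 1] - seat_y)
    tilt = script.cst_trunk_tilt_deg
    tl.hold(rest, script.pause_s)
    for _ in range(script.repetitions):
        lateral = rng.normal(0.0, script.cst_seat_jitter_m, size=3)
        lateral[1] = rng.normal(0.0, script.cst_seat_jitter_m)  # depth jitter
        seated = _cst_pose(rest, H, 1.0, drop, tilt, lateral)

        def fn(tlv, lat=lateral):
            frac = np.empty_like(tlv)
            d1, d2 = script.cst_descent_s, script.cst_dwell_s
            m1 = tlv < d1
            m2 = (tlv >= d1) & (tlv < d1 + d2)
            m3 = tlv >= d1 + d2
            frac[m1] = _minjerk(tlv[m1] / d1)
            frac[m2] = 1.0
            frac[m3] = 1.0 - _minjerk((tlv[m3] - d1 - d2) / d1)
            out = np.empty((tlv.size, N_JOINTS, 3))
            for i, f in enumerate(frac):
                out[i] = _cst_pose(rest, H, f, drop, tilt, lat)
            return out

        dur = 2.0 * script.cst_descent_s + script.cst_dwell_s
        r0, r1 = tl.add(dur, fn)
        tl.hold(rest, script.inter_rep_pause_s)
        reps.append(RepTruth(
            start_s=r0, end_s=r1, apex_s=r0 + script.cst_descent_s, side="n/a",
            programmed={
                "seated_hip": (seated[J.HIP_CENTER.value]).tolist(),
                "drop_m": drop,
                "tilt_deg": tilt,
            },
        ))
    truth = ManeuverTruth(
        maneuver="CST", active_start_s=t_act0, active_end_s=tl.t, reps=reps,
        programmed={"drop_m": drop, "tilt_deg": tilt,
                    "descent_s": script.cst_descent_s},
    )
    return truth, rest


_MANEUVER_BUILDERS = {
    "RT": _build_static("RT"),
    "TT": _build_static("TT"),
    "FNT": _build_fnt,
    "SST": _build_sst,
    "T45": _build_t45,
    "CST": _build_cst,
}


# --------------------------------------------------------------------------
# cohort simulation
# --------------------------------------------------------------------------


def _clip(x: float, lo: float, hi: float) -> float:
    return float(np.clip(x, lo, hi))


def sample_profile(index: int, rng: np.random.Generator) -> SubjectProfile:
    """Draw one subject: young healthy adult, half the cohort active."""
    sex = "M" if rng.random() < 0.62 else "F"
    stature = rng.normal(175.0, 7.0) if sex == "M" else rng.normal(163.0, 6.0)
    stature = _clip(stature, 150.0, 200.0)
    bmi = _clip(rng.normal(24.9, 3.4), 17.0, 38.0)
    mass = bmi * (stature / 100.0) ** 2
    age = _clip(rng.normal(24.0, 5.0), 18.0, 40.0)
    if index % 2 == 0:
        minutes = rng.uniform(150.0, 500.0)  # active
    else:
        minutes = rng.uniform(0.0, 149.0)  # sedentary
    return SubjectProfile(
        subject_id=f"S{index + 1:03d}",
        age=round(age, 1),
        sex=sex,
        stature_cm=round(stature, 1),
        mass_kg=round(mass, 1),
        activity_minutes_per_week=round(minutes, 0),
    )


def _subject_script(base: MotionScript, rng: np.random.Generator) -> MotionScript:
    """Subject-level random effects on the kinematic program.

    Per-side draws give every subject a stable lateral asymmetry (reach
    precision, arm droop, movement tempo, step width), which is what the
    limb-asymmetry variables measure across trials.
    """
    droop = _pair(base.fnt_droop_deg)
    jit = _pair(base.fnt_jitter_sd_m)
    reach = _pair(base.fnt_reach_s)
    flex = _pair(base.t45_knee_flexion_deg)
    hold = _pair(base.t45_hold_s)
    return replace(
        base,
        sst_step_angle_deg=(
            _clip(rng.normal(base.sst_step_angle_deg[0], 4.0), 16.0, 60.0),
            _clip(rng.normal(base.sst_step_angle_deg[1], 4.0), 16.0, 60.0),
        ),
        t45_angle_deg=_clip(rng.normal(base.t45_angle_deg, 3.0), 25.0, 70.0),
        t45_hold_s=tuple(
            _clip(rng.normal(h - 0.6, 0.7), 5.0, h) for h in hold),
        t45_knee_flexion_deg=tuple(
            _clip(rng.normal(f, 4.0), 150.0, 180.0) for f in flex),
        cst_trunk_tilt_deg=_clip(rng.normal(base.cst_trunk_tilt_deg, 2.0),
                                 1.0, 25.0),
        fnt_droop_deg=tuple(
            _clip(rng.normal(d, 1.2), 0.0, 15.0) for d in droop),
        fnt_jitter_sd_m=tuple(
            float(j * np.exp(rng.normal(0.0, 0.3))) for j in jit),
        fnt_reach_s=tuple(
            _clip(r * np.exp(rng.normal(0.0, 0.10)), 0.5, 1.6) for r in reach),
        sway_amplitude_m=float(base.sway_amplitude_m
                               * np.exp(rng.normal(0.0, 0.4))),
    )


def _trial_script(subj: MotionScript, rng: np.random.Generator) -> MotionScript:
    """Trial-level (between-series) perturbation of a subject's program."""
    la, ra = subj.sst_step_angle_deg
    return replace(
        subj,
        sst_step_angle_deg=(
            _clip(la + rng.normal(0.0, 1.3), 16.0, 60.0),
            _clip(ra + rng.normal(0.0, 1.3), 16.0, 60.0),
        ),
        t45_angle_deg=_clip(subj.t45_angle_deg + rng.normal(0.0, 1.0),
                            25.0, 70.0),
        t45_hold_s=tuple(
            _clip(h + rng.normal(0.0, 0.35), 4.0, 10.0)
            for h in _pair(subj.t45_hold_s)),
        t45_knee_flexion_deg=tuple(
            _clip(f + rng.normal(0.0, 1.5), 150.0, 180.0)
            for f in _pair(subj.t45_knee_flexion_deg)),
        cst_trunk_tilt_deg=_clip(subj.cst_trunk_tilt_deg
                                 + rng.normal(0.0, 0.6), 1.0, 25.0),
        fnt_droop_deg=tuple(
            _clip(d + rng.normal(0.0, 0.5), 0.0, 15.0)
            for d in _pair(subj.fnt_droop_deg)),
        fnt_reach_s=tuple(
            _clip(r * np.exp(rng.normal(0.0, 0.04)), 0.5, 1.6)
            for r in _pair(subj.fnt_reach_s)),
        sway_amplitude_m=float(subj.sway_amplitude_m
                               * np.exp(rng.normal(0.0, 0.25))),
    )


def simulate_cohort(
    n_subjects: int,
    n_series: int = 3,
    seed: int = 0,
    script: MotionScript | None = None,
    sensor: SensorModel | None = None,
    order: Sequence[str] = DEFAULT_ORDER,
) -> tuple[list[SubjectProfile], dict[tuple[str, int], tuple[Recording, GroundTruth]]]:
    """Simulate a full test-retest study: subjects x series recordings.

    Subject effects, trial effects and sensor noise come from independent
    named substreams of the one master seed.
    """
    base = script or MotionScript()
    sensor = sensor or SensorModel()
    profiles: list[SubjectProfile] = []
    recordings: dict[tuple[str, int], tuple[Recording, GroundTruth]] = {}
    for i in range(n_subjects):
        rng_subj = substream(seed, f"subject:{i}")
        profile = sample_profile(i, rng_subj)
        profiles.append(profile)
        script_i = _subject_script(base, rng_subj)
        for s in range(1, n_series + 1):
            rng_trial = substream(seed, f"trial:{i}:{s}")
            script_is = _trial_script(script_i, rng_trial)
            rec_seed = int(substream(seed, f"recording:{i}:{s}").integers(2**31))
            rec, gt = simulate_recording(
                profile, script_is, sensor, seed=rec_seed,
                series_index=s, order=order,
            )
            recordings[(profile.subject_id, s)] = (rec, gt)
    return profiles, recordings
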