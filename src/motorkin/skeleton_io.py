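"""Skeleton recording data model and file I/O.

A recording is an ordered sequence of frames, each giving the 3-D camera-space
position (meters) of the 20 joints of the classic depth-camera skeleton at a
time stamp in seconds.  Coordinates follow a right-handed camera convention:
+y up, +z pointing from the camera toward the subject, origin at the sensor.

The on-disk format is deliberately plain: a one-line JSON metadata header
(prefixed with ``#``) followed by a CSV body with one row per frame and one
``<JOINT>_{x,y,z}`` column triplet per joint.  Columns are matched by name,
never by position, so any column permutation parses identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "JointName",
    "JOINT_ORDER",
    "N_JOINTS",
    "COORDINATE_CONVENTION",
    "SkeletonFrame",
    "Recording",
    "SubjectProfile",
    "RecordingFormatError",
    "RecordingValidationError",
    "read_recording",
    "write_recording",
    "read_subjects",
    "write_subjects",
]

COORDINATE_CONVENTION = (
    "right-handed camera space, meters; +y up, +z camera->subject, origin at sensor"
)

MAGIC = "#MOTORKIN-RECORDING"

ACTIVE_MINUTES_PER_WEEK = 150.0


class JointName(Enum):
    """The 20 joints of the first-generation depth-camera skeleton."""

    HIP_CENTER = 0
    SPINE = 1
    SHOULDER_CENTER = 2
    HEAD = 3
    SHOULDER_L = 4
    SHOULDER_R = 5
    ELBOW_L = 6
    ELBOW_R = 7
    WRIST_L = 8
    WRIST_R = 9
    HAND_L = 10
    HAND_R = 11
    HIP_L = 12
    HIP_R = 13
    KNEE_L = 14
    KNEE_R = 15
    ANKLE_L = 16
    ANKLE_R = 17
    FOOT_L = 18
    FOOT_R = 19


JOINT_ORDER: tuple[JointName, ...] = tuple(JointName)
N_JOINTS = len(JOINT_ORDER)
assert N_JOINTS == 20


class RecordingFormatError(ValueError):
    """The file does not conform to the recording dialect."""


class RecordingValidationError(ValueError):
    """The parsed content violates a Recording invariant."""


@dataclass(frozen=True)
class SkeletonFrame:
    """One time-stamped skeleton pose: position per joint, meters."""

    time: float
    positions: np.ndarray  # (20, 3), canonical joint order

    def __post_init__(self) -> None:
        p = np.asarray(self.positions, dtype=float)
        if p.shape != (N_JOINTS, 3):
            raise RecordingValidationError(
                f"frame expects ({N_JOINTS}, 3) positions, got {p.shape}"
            )
        if not np.all(np.isfinite(p)):
            raise RecordingValidationError("frame contains non-finite coordinates")
        object.__setattr__(self, "positions", p)

    def __getitem__(self, joint: JointName) -> np.ndarray:
        return self.positions[joint.value]


@dataclass
class Recording:
    """An ordered skeleton time series for one subject and one series (1..3)."""

    subject_id: str
    series_index: int
    times: np.ndarray  # (n,) seconds, strictly increasing
    positions: np.ndarray  # (n, 20, 3) meters
    nominal_rate: float = 30.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.series_index not in (1, 2, 3):
            raise RecordingValidationError(
                f"series_index must be 1..3, got {self.series_index}"
            )
        if self.times.ndim != 1 or self.times.size < 2:
            raise RecordingValidationError(
                "a recording needs at least 2 frames for any kinematic computation"
            )
        n = self.times.size
        if self.positions.shape != (n, N_JOINTS, 3):
            raise RecordingValidationError(
                f"positions shape {self.positions.shape} does not match "
                f"({n}, {N_JOINTS}, 3)"
            )
        bad = np.where(~np.isfinite(self.positions).all(axis=(1, 2)))[0]
        if bad.size:
            raise RecordingValidationError(
                f"non-finite coordinate at frame index {int(bad[0])}"
            )
        dt = np.diff(self.times)
        nonmono = np.where(dt <= 0)[0]
        if nonmono.size:
            i = int(nonmono[0]) + 1
            raise RecordingValidationError(
                f"frame times not strictly increasing at row {i} "
                f"(t[{i - 1}]={self.times[i - 1]:.6f}, t[{i}]={self.times[i]:.6f})"
            )
        if not np.isfinite(self.nominal_rate) or self.nominal_rate <= 0:
            raise RecordingValidationError("nominal_rate must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.times.size)

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    @property
    def median_dt(self) -> float:
        return float(np.median(np.diff(self.times)))

    def joint(self, joint: JointName) -> np.ndarray:
        """(n, 3) trajectory of one joint."""
        return self.positions[:, joint.value, :]

    def frame(self, i: int) -> SkeletonFrame:
        return SkeletonFrame(time=float(self.times[i]), positions=self.positions[i])

    def frames(self) -> Iterator[SkeletonFrame]:
        for i in range(self.n_frames):
            yield self.frame(i)

    def equals(self, other: "Recording", atol: float = 0.0) -> bool:
        """Field-for-field equality (exact by default)."""
        return (
            self.subject_id == other.subject_id
            and self.series_index == other.series_index
            and self.nominal_rate == other.nominal_rate
            and self.times.shape == other.times.shape
            and self.positions.shape == other.positions.shape
            and np.allclose(self.times, other.times, rtol=0.0, atol=atol)
            and np.allclose(self.positions, other.positions, rtol=0.0, atol=atol)
        )


@dataclass(frozen=True)
class SubjectProfile:
    """Subject metadata.  BMI and activity class are derived, never stored."""

    subject_id: str
    age: float
    sex: str  # "M" / "F"
    stature_cm: float
    mass_kg: float
    activity_minutes_per_week: float

    def __post_init__(self) -> None:
        if self.stature_cm <= 0 or self.mass_kg <= 0:
            raise ValueError("stature and mass must be positive")
        if self.age < 0:
            raise ValueError("age must be non-negative")

    @property
    def stature_m(self) -> float:
        return self.stature_cm / 100.0

    @property
    def bmi(self) -> float:
        """Body mass index: mass (kg) / stature (m) squared."""
        return self.mass_kg / self.stature_m**2

    @property
    def activity_class(self) -> str:
        """WHO cut: >= 150 active minutes/week counts as "active"."""
        if self.activity_minutes_per_week >= ACTIVE_MINUTES_PER_WEEK:
            return "active"
        return "sedentary"


def _joint_columns() -> list[str]:
    cols = []
    for j in JOINT_ORDER:
        cols += [f"{j.name}_x", f"{j.name}_y", f"{j.name}_z"]
    return cols


def write_recording(rec: Recording, path: str | Path) -> None:
    """Serialize a recording: JSON header line + CSV body.

    Coordinates are written with 9 significant digits (sub-micrometer at
    camera working distances, far below the ~6-11 mm sensor noise floor).
    """
    if not isinstance(rec, Recording):
        raise TypeError("write_recording expects a Recording")
    path = Path(path)
    header = {
        "subject_id": rec.subject_id,
        "series_index": rec.series_index,
        "nominal_rate": rec.nominal_rate,
        "coordinate_convention": COORDINATE_CONVENTION,
    }
    cols = _joint_columns()
    flat = rec.positions.reshape(rec.n_frames, N_JOINTS * 3)
    df = pd.DataFrame(flat, columns=cols)
    df.insert(0, "time_s", rec.times)
    df.insert(0, "frame", np.arange(rec.n_frames))
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"{MAGIC} {json.dumps(header)}\n")
        df.to_csv(fh, index=False, float_format="%.12g", lineterminator="\n")


def read_recording(path: str | Path) -> Recording:
    """Parse a recording file written by :func:`write_recording`.

    Joints are located by column name, so column order is irrelevant.
    Missing joint columns raise :class:`RecordingFormatError` naming the
    joint; invariant violations raise :class:`RecordingValidationError`.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
        if not first.startswith(MAGIC):
            raise RecordingFormatError(
                f"{path}: missing '{MAGIC}' header line"
            )
        try:
            header = json.loads(first[len(MAGIC):])
        except json.JSONDecodeError as exc:
            raise RecordingFormatError(f"{path}: malformed JSON header: {exc}") from exc
        body = pd.read_csv(fh)
    for key in ("subject_id", "series_index", "nominal_rate"):
        if key not in header:
            raise RecordingFormatError(f"{path}: header missing '{key}'")
    if "time_s" not in body.columns:
        raise RecordingFormatError(f"{path}: missing 'time_s' column")
    for j in JOINT_ORDER:
        for ax in "xyz":
            if f"{j.name}_{ax}" not in body.columns:
                raise RecordingFormatError(
                    f"{path}: missing column for joint {j.name} (axis {ax})"
                )
    n = len(body)
    pos = np.empty((n, N_JOINTS, 3))
    for j in JOINT_ORDER:
        for a, ax in enumerate("xyz"):
            pos[:, j.value, a] = body[f"{j.name}_{ax}"].to_numpy(dtype=float)
    return Recording(
        subject_id=str(header["subject_id"]),
        series_index=int(header["series_index"]),
        times=body["time_s"].to_numpy(dtype=float),
        positions=pos,
        nominal_rate=float(header["nominal_rate"]),
    )


_SUBJECT_COLS = [
    "subject_id",
    "age",
    "sex",
    "stature_cm",
    "mass_kg",
    "activity_minutes_per_week",
]


def write_subjects(profiles: list[SubjectProfile], path: str | Path) -> None:
    """One CSV row per subject; derived fields (BMI, class) are not stored."""
    rows = [
        {
            "subject_id": p.subject_id,
            "age": p.age,
            "sex": p.sex,
            "stature_cm": p.stature_cm,
            "mass_kg": p.mass_kg,
            "activity_minutes_per_week": p.activity_minutes_per_week,
        }
        for p in profiles
    ]
    pd.DataFrame(rows, columns=_SUBJECT_COLS).to_csv(path, index=False)


def read_subjects(path: str | Path) -> list[SubjectProfile]:
    df = pd.read_csv(path)
    missing = [c for c in _SUBJECT_COLS if c not in df.columns]
    if missing:
        raise RecordingFormatError(f"{path}: subjects CSV missing columns {missing}")
    return [
        SubjectProfile(
            subject_id=str(r.subject_id),
            age=float(r.age),
            sex=str(r.sex),
            stature_cm=float(r.stature_cm),
            mass_kg=float(r.mass_kg),
            activity_minutes_per_week=float(r.activity_minutes_per_week),
        )
        for r in df.itertuples(index=False)
    ]
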