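"""Maneuver segmentation from greeting gestures.

The protocol marks the start of each maneuver with a scripted bilateral arm
flap (the "greeting").  The detector band-passes both wrist height traces
(0.5-3 Hz, zero-phase Butterworth), takes Hilbert envelopes, and calls a
greeting wherever BOTH envelopes stay above half the minimum amplitude long
enough to contain a genuine oscillation (duration plus zero-crossing
checks reject monotone pose transitions, which are transient in the band).

Given the detected onsets and the known maneuver order, the recording is
carved into labeled half-open frame spans; dynamic maneuvers are further
split into repetition sub-spans wherever the chosen kinematic signal leaves
and returns to its baseline band.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt

from .skeleton_io import JointName as J
from .skeleton_io import Recording

__all__ = [
    "ManeuverSegment",
    "Repetition",
    "SegmentationError",
    "RepetitionCountError",
    "detect_greetings",
    "segment_protocol",
    "split_repetitions",
    "central_span",
    "DEFAULT_ORDER",
]

DEFAULT_ORDER: tuple[str, ...] = ("RT", "TT", "FNT", "SST", "T45", "CST")

MANEUVER_SIDES = {
    "RT": "n/a", "TT": "n/a", "FNT": "both",
    "SST": "both", "T45": "both", "CST": "n/a",
}


class SegmentationError(RuntimeError):
    pass


class RepetitionCountError(SegmentationError):
    pass


@dataclass(frozen=True)
class Repetition:
    """Half-open frame sub-span of one repetition, with its side."""

    start: int
    end: int
    side: str = "n/a"  # left / right / n/a
    apex: int | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("repetition span must be non-empty")


@dataclass(frozen=True)
class ManeuverSegment:
    """Labeled half-open frame span [start, end) of one maneuver."""

    maneuver: str
    start: int
    end: int
    side: str = "n/a"
    repetitions: tuple[Repetition, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("segment span must be non-empty")
        prev_end = self.start
        for rep in self.repetitions:
            if rep.start < prev_end or rep.end > self.end:
                raise ValueError("repetitions must be disjoint, ordered and "
                                 "contained in the segment span")
            prev_end = rep.end

    @property
    def n_frames(self) -> int:
        return self.end - self.start

    def reps_for(self, side: str) -> list[Repetition]:
        return [r for r in self.repetitions if r.side == side]


def central_span(start: int, end: int, fraction: float = 0.8) -> tuple[int, int]:
    """Central ``fraction`` of a span, trimming transition frames equally."""
    n = end - start
    trim = int(round(n * (1.0 - fraction) / 2.0))
    a, b = start + trim, end - trim
    if b <= a:  # degenerate short span: keep it whole
        return start, end
    return a, b


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) index runs of True in a boolean vector."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = np.where(d == 1)[0] + 1
    ends = np.where(d == -1)[0] + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        ends = np.r_[ends, mask.size]
    return list(zip(starts.tolist(), ends.tolist()))


def detect_greetings(
    rec: Recording,
    min_amplitude: float = 0.2,
    band: tuple[float, float] = (0.5, 3.0),
    min_duration_s: float = 0.5,
    min_crossings: int = 3,
    merge_window_s: float = 0.5,
) -> list[int]:
    """Frame indices of greeting onsets (bilateral wrist flaps).

    Detection requires BOTH wrists to oscillate vertically with band-limited
    envelope above ``min_amplitude / 2``; each detected event contributes one
    strictly increasing onset index.  A motionless or single-arm recording
    yields an empty list.
    """
    if rec.duration < 2.0:
        raise ValueError("greeting detection needs at least 2 s of frames")
    fs = 1.0 / rec.median_dt
    lo, hi = band
    hi = min(hi, 0.45 * fs)
    sos = butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
    filt = np.stack([
        sosfiltfilt(sos, rec.joint(J.WRIST_L)[:, 1]),
        sosfiltfilt(sos, rec.joint(J.WRIST_R)[:, 1]),
    ])
    env = np.abs(hilbert(filt, axis=1))
    both = env.min(axis=0)
    thresh = min_amplitude / 2.0
    onsets: list[int] = []
    for a, b in _runs(both > thresh):
        if (b - a) / fs < min_duration_s:
            continue
        ok = True
        for sig in filt:
            seg = sig[a:b]
            crossings = int(np.sum(np.signbit(seg[:-1]) != np.signbit(seg[1:])))
            if crossings < min_crossings:
                ok = False
                break
        if not ok:
            continue
        # walk the onset back to where the envelope first leaves the floor;
        # capped and monotone so a preceding motion hump is never absorbed
        peak = float(both[a:b].max())
        floor = max(0.08 * peak, 0.02)
        limit = max(0, a - int(round(0.2 * fs)))
        i = a
        while i > limit and both[i - 1] > floor and both[i - 1] <= both[i] * 1.05:
            i -= 1
        onsets.append(int(i))
    # tie-break: candidates within the merge window keep the earlier one
    merged: list[int] = []
    win = int(round(merge_window_s * fs))
    for o in sorted(onsets):
        if not merged or o - merged[-1] > win:
            merged.append(o)
    return merged


def segment_protocol(
    rec: Recording,
    greetings: Sequence[int],
    order: Sequence[str] = DEFAULT_ORDER,
    greeting_duration_s: float = 1.5,
) -> list[ManeuverSegment]:
    """Carve the recording into one labeled segment per expected maneuver.

    Segment i runs from the end of greeting i (onset plus the nominal
    greeting duration) to the onset of greeting i+1; the last segment ends
    at the recording end.
    """
    if len(greetings) != len(order):
        raise SegmentationError(
            f"greeting count mismatch: expected {len(order)}, "
            f"found {len(greetings)}"
        )
    if not order:
        return []
    fs = 1.0 / rec.median_dt
    gdur = int(round(greeting_duration_s * fs))
    segments = []
    g = list(greetings)
    for i, name in enumerate(order):
        start = min(g[i] + gdur, rec.n_frames - 1)
        end = g[i + 1] if i + 1 < len(g) else rec.n_frames
        if end <= start:
            raise SegmentationError(
                f"empty span for maneuver {name}: [{start}, {end})")
        segments.append(ManeuverSegment(
            maneuver=name, start=start, end=end,
            side=MANEUVER_SIDES.get(name, "n/a"),
        ))
    return segments


# --------------------------------------------------------------------------
# repetition splitting
# --------------------------------------------------------------------------


def _between_leg_angle(rec: Recording, a: int, b: int) -> np.ndarray:
    hc = rec.joint(J.HIP_CENTER)[a:b]
    vl = rec.joint(J.ANKLE_L)[a:b] - hc
    vr = rec.joint(J.ANKLE_R)[a:b] - hc
    c = np.einsum("ij,ij->i", vl, vr) / (
        np.linalg.norm(vl, axis=1) * np.linalg.norm(vr, axis=1))
    return np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))


def _nose_proxy(rec: Recording, a: int, b: int,
                nose_offset_m: float = 0.10) -> np.ndarray:
    from .features import nose_proxy
    return nose_proxy(rec, nose_offset_m)[a:b]


def _deviation_signals(rec: Recording, seg: ManeuverSegment, signal: str
                       ) -> dict[str, np.ndarray]:
    """Signals oriented so an excursion (repetition) is a positive deflection."""
    a, b = seg.start, seg.end
    if signal == "reach_distance":
        nose = _nose_proxy(rec, a, b)
        out = {}
        for side, hand in (("left", J.HAND_L), ("right", J.HAND_R)):
            d = np.linalg.norm(rec.joint(hand)[a:b] - nose, axis=1)
            out[side] = -d  # closer to nose = positive excursion
        return out
    if signal == "step_angle":
        return {"any": _between_leg_angle(rec, a, b)}
    if signal == "hip_height":
        return {"n/a": -rec.joint(J.HIP_CENTER)[a:b, 1]}  # sitting = positive
    raise ValueError(f"unknown repetition signal '{signal}'")


def _excursions(sig: np.ndarray, fs: float, baseline_s: float,
                min_duration_s: float = 0.3) -> list[tuple[int, int, int]]:
    """(start, end, apex) of qualifying baseline-band excursions.

    Baseline = median of the first ``baseline_s`` seconds; band = +/- 2x the
    local noise SD (robust, from first differences), floored at 5% of the
    largest excursion so the noise-free case stays well-posed.  Only
    excursions that both leave and return to the band count; noise blips are
    rejected by duration (a genuine repetition stays out of the band for at
    least ``min_duration_s``) and by a noise-relative amplitude floor.
    """
    nb = max(3, int(round(baseline_s * fs)))
    base = np.median(sig[:nb])
    dev = sig - base
    diffs = np.diff(sig[:nb])
    noise_sd = 1.4826 * np.median(np.abs(diffs)) / np.sqrt(2.0) if diffs.size else 0.0
    peak = float(dev.max(initial=0.0))
    if peak <= 0:
        return []
    thresh = max(2.0 * noise_sd, 0.05 * peak, 1e-9)
    min_len = max(2, int(round(min_duration_s * fs)))
    out = []
    for s, e in _runs(dev > thresh):
        if s == 0 or e == dev.size:  # never left / never returned to band
            continue
        if e - s < min_len:
            continue
        if float(dev[s:e].max()) < 2.0 * thresh:
            continue
        apex = s + int(np.argmax(dev[s:e]))
        out.append((s, e, apex))
    return out


def split_repetitions(
    seg: ManeuverSegment,
    rec: Recording,
    n_expected: int = 5,
    signal: str | None = None,
    baseline_s: float = 0.5,
) -> ManeuverSegment:
    """Fill a dynamic segment's repetition sub-spans from a kinematic signal.

    ``signal`` is one of ``reach_distance`` (FNT), ``step_angle`` (SST) or
    ``hip_height`` (CST); by default it is chosen from the maneuver label.
    Sided maneuvers must yield exactly ``n_expected`` repetitions per side,
    unsided ones ``n_expected`` in total, else a
    :class:`RepetitionCountError` reports the count found.
    """
    if n_expected < 1:
        raise ValueError("n_expected must be >= 1")
    if signal is None:
        signal = {"FNT": "reach_distance", "SST": "step_angle",
                  "CST": "hip_height"}.get(seg.maneuver)
        if signal is None:
            raise ValueError(
                f"no default repetition signal for maneuver {seg.maneuver}")
    fs = 1.0 / rec.median_dt
    sigs = _deviation_signals(rec, seg, signal)
    reps: list[Repetition] = []
    if signal == "step_angle":
        sig = sigs["any"]
        found = _excursions(sig, fs, baseline_s)
        # assign side by which ankle moved laterally at the apex
        a = seg.start
        nb = max(3, int(round(baseline_s * fs)))
        xl0 = np.median(rec.joint(J.ANKLE_L)[a:a + nb, 0])
        xr0 = np.median(rec.joint(J.ANKLE_R)[a:a + nb, 0])
        for s, e, apex in found:
            dl = abs(rec.joint(J.ANKLE_L)[a + apex, 0] - xl0)
            dr = abs(rec.joint(J.ANKLE_R)[a + apex, 0] - xr0)
            side = "left" if dl >= dr else "right"
            reps.append(Repetition(a + s, a + e, side, a + apex))
    else:
        for side, sig in sigs.items():
            for s, e, apex in _excursions(sig, fs, baseline_s):
                reps.append(Repetition(seg.start + s, seg.start + e,
                                       side, seg.start + apex))
    reps.sort(key=lambda r: r.start)
    sided = {r.side for r in reps} - {"n/a"}
    expected_sides = ("left", "right") if seg.side == "both" else ("n/a",)
    for side in expected_sides:
        n_found = sum(1 for r in reps if r.side == side)
        if n_found != n_expected:
            label = f" ({side})" if side != "n/a" else ""
            raise RepetitionCountError(
                f"{seg.maneuver}{label}: expected {n_expected} repetitions, "
                f"found {n_found}"
            )
    stray = sided - set(expected_sides)
    if stray:
        raise RepetitionCountError(
            f"{seg.maneuver}: repetitions found for unexpected side(s) {stray}")
    return replace(seg, repetitions=tuple(reps))
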