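"""Behavioral quantification: forelimb coding, state segmentation, open-field
tracking features, the apomorphine rotation criterion and the rotarod
protocol.

Cylinder-test behavior is digitized as a 4-bit forelimb code every 0.25 s
(bits, MSB to LSB: left-wall, right-wall, left-floor, right-floor) plus a
signed body-rotation rate in degrees/s.  Sessions are segmented into three
mutually exclusive states:

* rearing  -- wall contact, i.e. code strictly greater than 4 (0b0100), so
  at least one forepaw is on the cylinder wall;
* stepping -- a non-rearing run whose cumulative absolute body-angle change
  exceeds 45 degrees while the floor-contact bits change at least twice
  (forepaw alternation);
* inactive -- everything else.

The wall-contact rule is the strict numeric one (code > 4); note that the
all-clear code 0000 ("rearing with no support" in some scoring schemes)
cannot satisfy it and is therefore never counted as rearing here.
:func:`qc_unsupported_rearing` flags 0000-runs adjacent to wall-contact runs
so such sessions can be audited instead of silently re-labeled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core_io import (
    ForelimbCodeSeries,
    RotationRateSeries,
    StateIntervals,
    TrackingTrace,
    ValidationError,
)

__all__ = [
    "encode_forelimb",
    "decode_forelimb",
    "is_wall_contact",
    "WALL_CONTACT_CODES",
    "segment_states",
    "qc_unsupported_rearing",
    "time_budget",
    "compute_speed",
    "OpenFieldFeatures",
    "EpisodeFeatures",
    "openfield_features",
    "apomorphine_classify",
    "RotarodProfile",
    "RotarodOutcome",
    "rotarod_profile",
    "rotarod_outcome",
    "TRAINING_SPEEDS_RPM",
]


# ---------------------------------------------------------------------------
# forelimb code
# ---------------------------------------------------------------------------

def encode_forelimb(
    left_wall: bool, right_wall: bool, left_floor: bool, right_floor: bool
) -> int:
    """Pack the four contact flags into a 4-bit code (MSB = left wall).

    ``encode_forelimb(True, True, False, False) == 0b1100 == 12`` means both
    forepaws on the cylinder wall.
    """
    return (
        (int(bool(left_wall)) << 3)
        | (int(bool(right_wall)) << 2)
        | (int(bool(left_floor)) << 1)
        | int(bool(right_floor))
    )


def decode_forelimb(code: int) -> tuple[bool, bool, bool, bool]:
    """Inverse of :func:`encode_forelimb`."""
    _check_code(code)
    return bool(code & 8), bool(code & 4), bool(code & 2), bool(code & 1)


def _check_code(code: int) -> None:
    if not 0 <= int(code) <= 15:
        raise ValidationError(f"forelimb code must lie in [0, 15], got {code}")


def is_wall_contact(code: int) -> bool:
    """True iff ``code > 4``, the strict digitized rearing rule.

    Any code above 0b0100 has a wall bit set beyond a lone right-paw-on-wall,
    i.e. the left-wall bit (8) or both wall bits; the boundary code 4 itself
    (right paw on wall only) is excluded by the strict inequality.
    """
    _check_code(code)
    return int(code) > 4


WALL_CONTACT_CODES = frozenset(c for c in range(16) if c > 4)


# ---------------------------------------------------------------------------
# state segmentation
# ---------------------------------------------------------------------------

def _runs(labels: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs [i, j) of equal values."""
    out = []
    i = 0
    n = labels.size
    while i < n:
        j = i + 1
        while j < n and labels[j] == labels[i]:
            j += 1
        out.append((i, j))
        i = j
    return out


def _cumulative_angle(
    rotation: RotationRateSeries, t_start: float, t_end: float
) -> float:
    """Integral of |rate| dt over [t_start, t_end) with partial-bin overlap."""
    t = rotation.times()
    lo = np.clip(t, t_start, t_end)
    hi = np.clip(t + rotation.dt, t_start, t_end)
    return float(np.sum(np.abs(rotation.rate) * (hi - lo)))


def segment_states(
    codes: ForelimbCodeSeries,
    rotation: RotationRateSeries,
    angle_threshold: float = 45.0,
    min_floor_transitions: int = 2,
    min_duration: float = 0.5,
) -> StateIntervals:
    """Partition a cylinder session into rearing / stepping / inactive.

    Rearing takes precedence (wall contact is unambiguous; body rotation can
    co-occur during rears).  Each maximal non-rearing run is labeled stepping
    when its cumulative absolute body-angle change exceeds ``angle_threshold``
    degrees *and* its floor-contact bits (code & 3) change state at least
    ``min_floor_transitions`` times; otherwise it is inactive.  Runs shorter
    than ``min_duration`` seconds are merged into their preceding neighbor
    (or following, at the session start) to suppress single-frame flicker.
    """
    if abs(codes.t0 - rotation.t0) > 1e-6 or abs(codes.duration - rotation.duration) > max(
        codes.dt, rotation.dt
    ):
        raise ValidationError(
            "codes and rotation series must cover the same session span"
        )
    arr = codes.codes
    if arr.size == 0:
        raise ValidationError("empty code series")

    wall = arr > 4
    labels = np.empty(arr.size, dtype=object)
    labels[wall] = "rearing"
    t = codes.times()
    for i, j in _runs(wall):
        if wall[i]:
            continue
        run_codes = arr[i:j]
        floor = run_codes & 3
        n_trans = int(np.count_nonzero(np.diff(floor) != 0))
        angle = _cumulative_angle(rotation, t[i], codes.t0 + j * codes.dt)
        if angle > angle_threshold and n_trans >= min_floor_transitions:
            labels[i:j] = "stepping"
        else:
            labels[i:j] = "inactive"

    # merge runs shorter than min_duration into a neighbor, then re-merge
    min_frames = int(np.ceil(min_duration / codes.dt))
    runs = _runs(labels)
    merged: list[list] = []  # [start, end, state]
    for i, j in runs:
        if (j - i) >= min_frames or not merged:
            if merged and merged[-1][2] == labels[i]:
                merged[-1][1] = j
            else:
                merged.append([i, j, labels[i]])
        else:
            merged[-1][1] = j  # absorb short run into the preceding one
    if len(merged) > 1 and (merged[0][1] - merged[0][0]) < min_frames:
        # a short leading run could not absorb backwards; give it forward
        merged[1][0] = merged[0][0]
        merged.pop(0)

    intervals = [
        (codes.t0 + i * codes.dt, codes.t0 + j * codes.dt, str(s)) for i, j, s in merged
    ]
    return StateIntervals(intervals)


def qc_unsupported_rearing(codes: ForelimbCodeSeries) -> list[tuple[float, float]]:
    """Spans of all-zero codes directly adjacent to wall-contact runs.

    Code 0000 can mean unsupported rearing, which the strict ``code > 4``
    rule cannot count; runs of zeros flanking wall-contact runs are the
    likeliest candidates and are reported for manual audit.
    """
    arr = codes.codes
    flagged = []
    runs = _runs(arr == 0)
    for k, (i, j) in enumerate(runs):
        if not (arr[i] == 0):
            continue
        prev_wall = i > 0 and arr[i - 1] > 4
        next_wall = j < arr.size and arr[j] > 4
        if prev_wall or next_wall:
            flagged.append((codes.t0 + i * codes.dt, codes.t0 + j * codes.dt))
    return flagged


def time_budget(
    states: StateIntervals, window: tuple[float, float]
) -> dict[str, float]:
    """Seconds spent in each state within ``window`` (half-open).

    The three durations sum exactly to the window length; intervals straddling
    the window edge contribute their overlap only.
    """
    w0, w1 = window
    if not w1 > w0:
        raise ValidationError(f"empty or inverted window {window}")
    if w0 < states.start - 1e-9 or w1 > states.end + 1e-9:
        raise ValidationError(
            f"window {window} not contained in segmented span "
            f"[{states.start}, {states.end}]"
        )
    out = {"rearing": 0.0, "stepping": 0.0, "inactive": 0.0}
    for a, b, s in states.intervals:
        out[s] += max(0.0, min(b, w1) - max(a, w0))
    return out


# ---------------------------------------------------------------------------
# open-field tracking
# ---------------------------------------------------------------------------

def compute_speed(track: TrackingTrace, smooth_win: float = 0.2) -> np.ndarray:
    """Locomotion speed (cm/s) from tracking, one value per frame.

    Coordinates are smoothed with a ``smooth_win``-second moving average
    before centered finite differencing; tracking jitter otherwise inflates
    threshold crossings at the immobility boundary.
    """
    if track.n_frames < 3:
        raise ValidationError("need at least 3 frames to estimate speed")
    k = max(1, int(round(smooth_win * track.fps)))
    if k > 1:
        kernel = np.ones(k) / k
        pad = k // 2
        xp = np.pad(track.x, pad, mode="edge")
        yp = np.pad(track.y, pad, mode="edge")
        x = np.convolve(xp, kernel, mode="same")[pad : pad + track.n_frames]
        y = np.convolve(yp, kernel, mode="same")[pad : pad + track.n_frames]
    else:
        x, y = track.x, track.y
    vx = np.gradient(x) * track.fps
    vy = np.gradient(y) * track.fps
    return np.hypot(vx, vy)


@dataclass
class EpisodeFeatures:
    start: float
    end: float
    dbs_on: bool
    avg_velocity: float
    lm_time: float
    immobility_time: float
    distance: float


@dataclass
class OpenFieldFeatures:
    """Whole-session open-field features with a per-episode breakdown."""

    avg_velocity: float
    lm_time: float
    immobility_time: float
    distance: float
    per_episode: list[EpisodeFeatures] = field(default_factory=list)


def _threshold_run_time(
    mask: np.ndarray, fps: float, min_duration: float
) -> float:
    """Total duration of maximal True-runs strictly longer than min_duration."""
    total = 0.0
    for i, j in _runs(mask):
        if mask[i]:
            dur = (j - i) / fps
            if dur > min_duration:
                total += dur
    return total


def openfield_features(
    speed: np.ndarray,
    fps: float,
    episodes: list[tuple[float, float, bool]],
    lm_speed: float = 4.0,
    immobility_speed: float = 0.5,
    min_duration: float = 2.0,
    t0: float = 0.0,
) -> OpenFieldFeatures:
    """Open-field locomotion features from a frame-wise speed series.

    Large movements (LM) are maximal runs with speed > ``lm_speed`` cm/s
    lasting strictly longer than ``min_duration`` s; immobility uses
    speed < ``immobility_speed`` cm/s with the same duration rule.  Distance
    is the per-frame displacement sum; average velocity is distance over
    episode duration.
    """
    speed = np.asarray(speed, dtype=float)
    per_ep = []
    for start, end, dbs_on in episodes:
        i0 = int(round((start - t0) * fps))
        i1 = int(round((end - t0) * fps))
        if i0 < 0 or i1 > speed.size:
            raise ValidationError(
                f"episode [{start}, {end}) not covered by the speed series"
            )
        s = speed[i0:i1]
        dur = (i1 - i0) / fps
        dist = float(np.sum(s) / fps)
        per_ep.append(
            EpisodeFeatures(
                start=start,
                end=end,
                dbs_on=dbs_on,
                avg_velocity=dist / dur if dur > 0 else 0.0,
                lm_time=_threshold_run_time(s > lm_speed, fps, min_duration),
                immobility_time=_threshold_run_time(s < immobility_speed, fps, min_duration),
                distance=dist,
            )
        )
    total_dur = sum(e.end - e.start for e in per_ep)
    total_dist = sum(e.distance for e in per_ep)
    return OpenFieldFeatures(
        avg_velocity=total_dist / total_dur if total_dur > 0 else 0.0,
        lm_time=sum(e.lm_time for e in per_ep),
        immobility_time=sum(e.immobility_time for e in per_ep),
        distance=total_dist,
        per_episode=per_ep,
    )


# ---------------------------------------------------------------------------
# apomorphine rotation criterion
# ---------------------------------------------------------------------------

def apomorphine_classify(rotation_counts: np.ndarray) -> bool:
    """Lesion-success criterion from the apomorphine rotation test.

    ``rotation_counts`` are contralateral rotations per minute over 30 min;
    the animal is deemed sufficiently lesioned iff the mean is at least 3.0
    rotations/min.
    """
    counts = np.asarray(rotation_counts, dtype=float)
    if counts.shape != (30,):
        raise ValidationError(
            f"expected 30 one-minute rotation counts, got shape {counts.shape}"
        )
    if np.any(counts < 0):
        raise ValidationError("rotation counts must be non-negative")
    return bool(counts.mean() >= 3.0)


# ---------------------------------------------------------------------------
# rotarod
# ---------------------------------------------------------------------------

TRAINING_SPEEDS_RPM = (12, 16, 19, 21, 24, 26, 28, 38)
_TEST_RAMP_TOTAL_S = 472.0  # 7 min 52 s, 2 -> 60 rpm in 1-rpm steps


@dataclass(frozen=True)
class RotarodProfile:
    """Rod speed schedule: list of (speed rpm, duration s) segments."""

    schedule: tuple[tuple[float, float], ...]
    day: str

    def __post_init__(self) -> None:
        if self.day not in ("training", "test"):
            raise ValidationError("day must be 'training' or 'test'")
        if any(spd <= 0 or dur <= 0 for spd, dur in self.schedule):
            raise ValidationError("speeds and durations must be positive")
        if self.day == "test":
            speeds = [s for s, _ in self.schedule]
            if any(b < a for a, b in zip(speeds, speeds[1:])):
                raise ValidationError("test ramp speeds must be non-decreasing")

    @property
    def duration(self) -> float:
        return sum(d for _, d in self.schedule)

    def speed_at(self, t: float) -> float:
        """Rod speed (rpm) at elapsed time ``t``; clamps at the final speed."""
        acc = 0.0
        for spd, dur in self.schedule:
            acc += dur
            if t < acc:
                return spd
        return self.schedule[-1][0]


@dataclass(frozen=True)
class RotarodOutcome:
    time_on_rod: float
    max_speed: float


def rotarod_profile(day: str, trial_duration: float = 60.0) -> RotarodProfile:
    """Standard rod schedules.

    * training: 8 fixed-speed trials (12, 16, 19, 21, 24, 26, 28, 38 rpm),
      each up to ``trial_duration`` s — returned as one profile per trial
      concatenated in order;
    * test: accelerating ramp from 2 to 60 rpm in 1-rpm steps over 7 min 52 s
      (59 equal 8-s steps).
    """
    if day == "training":
        sched = tuple((float(s), float(trial_duration)) for s in TRAINING_SPEEDS_RPM)
        return RotarodProfile(sched, "training")
    if day == "test":
        speeds = np.arange(2, 61)  # 59 levels
        step = _TEST_RAMP_TOTAL_S / speeds.size
        return RotarodProfile(tuple((float(s), step) for s in speeds), "test")
    raise ValidationError("day must be 'training' or 'test'")


def rotarod_outcome(fall_time: float, profile: RotarodProfile) -> RotarodOutcome:
    """Outcome of one rotarod run: time on rod and rod speed at the fall.

    A fall time beyond the profile duration is clamped to the final speed
    with a warning (the animal completed the ramp).
    """
    if fall_time < 0:
        raise ValidationError("fall_time must be non-negative")
    if fall_time > profile.duration:
        warnings.warn(
            f"fall_time {fall_time:.1f}s exceeds profile duration "
            f"{profile.duration:.1f}s; clamping to final speed",
            stacklevel=2,
        )
        fall_time = profile.duration
    return RotarodOutcome(time_on_rod=float(fall_time), max_speed=profile.speed_at(fall_time))
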