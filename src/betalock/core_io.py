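"""Shared domain types, invariant checks and session-directory I/O.

A *session* is one behavioral trial of one animal (cylinder, open-field or
rotarod paradigm) and is stored as a directory containing

* ``lfp.h5``       -- multichannel LFP in an HDF5 container with datasets
  ``lfp/samples`` (channels x time, microvolt), ``lfp/sample_rate`` (Hz),
  ``lfp/t0`` (s) and ``lfp/channels`` (structured: region, hemisphere,
  lesioned, subject_id, group);
* ``tracking.csv`` -- ``time_s,x_cm,y_cm`` arena coordinates (open field);
* ``codes.csv``    -- ``time_s,code`` forelimb 4-bit codes as binary strings;
* ``rotation.csv`` -- ``time_s,deg_per_s`` body rotation rate;
* ``states.tsv``   -- optional BED-like ``start_s<TAB>end_s<TAB>state``;
* ``config.yaml``  -- paradigm, group, DBS episode schedule.

All times are seconds on a common session clock starting at 0; intervals are
half-open ``[start, end)``.  Units are fixed: microvolt, cm, s, Hz, degrees.
Readers reject invariant-violating input; they never silently repair it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "BandDefinition",
    "THETA",
    "LOW_BETA",
    "HIGH_BETA",
    "BANDS",
    "ChannelMeta",
    "LfpRecording",
    "ForelimbCodeSeries",
    "RotationRateSeries",
    "StateIntervals",
    "TrackingTrace",
    "SessionConfig",
    "Episode",
    "PsdEstimate",
    "BandPowerSeries",
    "EdResult",
    "TestResult",
    "SessionBundle",
    "ValidationError",
    "FormatError",
    "read_session",
    "write_session",
    "STATES",
]

STATES = ("rearing", "stepping", "inactive")

_T_ATOL = 1e-9  # tolerance for contiguity / tiling checks on the session clock


class ValidationError(ValueError):
    """An object violates a domain invariant."""


class FormatError(ValueError):
    """A session file is malformed (names the offending field)."""


# ---------------------------------------------------------------------------
# frequency bands
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BandDefinition:
    """A frequency band [f_lo, f_hi] in Hz.

    ``include_upper`` resolves edge ownership when two bands share an edge:
    the default low-beta band is [13, 21) while high beta owns [21, 30].
    """

    name: str
    f_lo: float
    f_hi: float
    include_upper: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise ValidationError(
                f"band {self.name}: need 0 < f_lo < f_hi, got [{self.f_lo}, {self.f_hi}]"
            )

    def mask(self, freqs: np.ndarray) -> np.ndarray:
        """Boolean mask of grid points owned by this band."""
        freqs = np.asarray(freqs)
        if self.include_upper:
            return (freqs >= self.f_lo) & (freqs <= self.f_hi)
        return (freqs >= self.f_lo) & (freqs < self.f_hi)

    @property
    def center(self) -> float:
        return 0.5 * (self.f_lo + self.f_hi)


THETA = BandDefinition("theta", 6.0, 12.0)
LOW_BETA = BandDefinition("low_beta", 13.0, 21.0, include_upper=False)
HIGH_BETA = BandDefinition("high_beta", 21.0, 30.0)
BANDS = {"theta": THETA, "low_beta": LOW_BETA, "high_beta": HIGH_BETA}


# ---------------------------------------------------------------------------
# channels and LFP
# ---------------------------------------------------------------------------

REGIONS = ("M1", "STN")
HEMISPHERES = ("left", "right")
GROUPS = ("PD", "sham")


@dataclass(frozen=True)
class ChannelMeta:
    """Metadata for one recording channel.

    In this hemi-parkinsonian design the right hemisphere of PD animals is
    the 6-OHDA lesioned side and the left is the intact within-animal
    control; sham animals are intact on both sides.
    """

    region: str
    hemisphere: str
    lesioned: bool
    subject_id: str
    group: str

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValidationError(f"region must be one of {REGIONS}, got {self.region!r}")
        if self.hemisphere not in HEMISPHERES:
            raise ValidationError(
                f"hemisphere must be one of {HEMISPHERES}, got {self.hemisphere!r}"
            )
        if self.group not in GROUPS:
            raise ValidationError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.group == "sham" and self.lesioned:
            raise ValidationError(
                f"sham channel {self.subject_id}/{self.region}/{self.hemisphere} "
                "marked lesioned"
            )
        if self.group == "PD" and self.lesioned != (self.hemisphere == "right"):
            raise ValidationError(
                "PD animals are lesioned on the right hemisphere only; channel "
                f"{self.subject_id}/{self.region}/{self.hemisphere} has "
                f"lesioned={self.lesioned}"
            )


@dataclass
class LfpRecording:
    """Multi-channel LFP voltage time series in microvolt.

    ``samples`` has shape (n_channels, n_samples); ``t0`` places the first
    sample on the session clock.
    """

    samples: np.ndarray
    sample_rate: float
    channels: list[ChannelMeta]
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValidationError("samples must be a 2-D (channels x time) array")
        if self.samples.shape[0] == 0:
            raise ValidationError("LFP recording must contain at least one channel")
        if len(self.channels) != self.samples.shape[0]:
            raise ValidationError(
                f"channel metadata count ({len(self.channels)}) does not match "
                f"sample rows ({self.samples.shape[0]})"
            )
        if not self.sample_rate > 0:
            raise ValidationError("sample_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("LFP samples contain non-finite values")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.sample_rate

    def select(self, **criteria) -> "LfpRecording":
        """Sub-recording with channels whose metadata match all criteria.

        ``rec.select(region="M1", hemisphere="right")``
        """
        idx = [
            i
            for i, ch in enumerate(self.channels)
            if all(getattr(ch, k) == v for k, v in criteria.items())
        ]
        if not idx:
            raise ValidationError(f"no channel matches {criteria}")
        return LfpRecording(
            self.samples[idx], self.sample_rate, [self.channels[i] for i in idx], self.t0
        )

    def channel(self, i: int) -> np.ndarray:
        return self.samples[i]


# ---------------------------------------------------------------------------
# behavioral streams
# ---------------------------------------------------------------------------

@dataclass
class ForelimbCodeSeries:
    """Forelimb position codes, one 4-bit integer per frame.

    Bit order (MSB to LSB): left-wall, right-wall, left-floor, right-floor;
    e.g. 0b1100 = 12 means both forepaws on the cylinder wall.  Updated every
    ``dt`` seconds (0.25 s in the standard protocol).
    """

    codes: np.ndarray
    dt: float = 0.25
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=int)
        if self.codes.ndim != 1:
            raise ValidationError("codes must be one-dimensional")
        if not self.dt > 0:
            raise ValidationError("dt must be positive")
        if self.codes.size and (self.codes.min() < 0 or self.codes.max() > 15):
            raise ValidationError("forelimb codes must lie in [0, 15]")

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.codes.size) * self.dt

    @property
    def duration(self) -> float:
        return self.codes.size * self.dt


@dataclass
class RotationRateSeries:
    """Body-rotation rate in degrees per second (signed)."""

    rate: np.ndarray
    dt: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.rate = np.asarray(self.rate, dtype=float)
        if not self.dt > 0:
            raise ValidationError("dt must be positive")
        if not np.all(np.isfinite(self.rate)):
            raise ValidationError("rotation rates must be finite")

    @property
    def duration(self) -> float:
        return self.rate.size * self.dt

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.rate.size) * self.dt


@dataclass
class StateIntervals:
    """Contiguous partition of a session into behavioral states.

    Half-open intervals ``(start, end, state)`` with
    state in {rearing, stepping, inactive}; every instant of the covered span
    belongs to exactly one interval.
    """

    intervals: list[tuple[float, float, str]]

    def __post_init__(self) -> None:
        ivs = [(float(a), float(b), str(s)) for a, b, s in self.intervals]
        if not ivs:
            raise ValidationError("StateIntervals must contain at least one interval")
        for a, b, s in ivs:
            if not b > a:
                raise ValidationError(f"interval end must exceed start: ({a}, {b}, {s})")
            if s not in STATES:
                raise ValidationError(f"unknown state {s!r}; must be one of {STATES}")
        for (a0, b0, _), (a1, _, _) in zip(ivs, ivs[1:]):
            if a1 < a0:
                raise ValidationError("intervals must be sorted by start time")
            if abs(a1 - b0) > _T_ATOL:
                raise ValidationError(
                    f"intervals must be contiguous: gap/overlap between t={b0} and t={a1}"
                )
        self.intervals = ivs

    @property
    def start(self) -> float:
        return self.intervals[0][0]

    @property
    def end(self) -> float:
        return self.intervals[-1][1]

    @property
    def duration(self) -> float:
        return self.end - self.start

    def episodes(self, state: str) -> list[tuple[float, float]]:
        """(start, end) spans labeled with ``state``."""
        return [(a, b) for a, b, s in self.intervals if s == state]

    def state_at(self, t: float) -> str:
        for a, b, s in self.intervals:
            if a - _T_ATOL <= t < b:
                return s
        if abs(t - self.end) <= _T_ATOL:
            return self.intervals[-1][2]
        raise ValidationError(f"t={t} outside covered span [{self.start}, {self.end})")


@dataclass
class TrackingTrace:
    """Arena coordinates in cm at a fixed frame rate (open-field tracking)."""

    x: np.ndarray
    y: np.ndarray
    fps: float
    arena: tuple[float, float] = (74.0, 74.0)
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValidationError("x and y must be 1-D arrays of equal length")
        if not self.fps > 0:
            raise ValidationError("fps must be positive")
        w, h = self.arena
        if self.x.size and (
            self.x.min() < -_T_ATOL
            or self.x.max() > w + _T_ATOL
            or self.y.min() < -_T_ATOL
            or self.y.max() > h + _T_ATOL
        ):
            raise ValidationError(f"tracking coordinates leave the {w}x{h} cm arena")

    @property
    def n_frames(self) -> int:
        return self.x.size

    @property
    def duration(self) -> float:
        return self.n_frames / self.fps

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_frames) / self.fps


# ---------------------------------------------------------------------------
# session configuration
# ---------------------------------------------------------------------------

PARADIGMS = ("cylinder", "openfield", "rotarod")
ASSIGNMENTS = ("PD-DBS ON", "PD-DBS OFF", "sham")


@dataclass(frozen=True)
class Episode:
    start: float
    end: float
    dbs_on: bool

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValidationError(f"episode end must exceed start: {self}")


@dataclass
class SessionConfig:
    """Paradigm, group assignment and the DBS on/off episode schedule."""

    paradigm: str
    episodes: list[Episode]
    group: str
    subject_id: str
    assignment: str
    arena: tuple[float, float] = (74.0, 74.0)
    fps: float = 25.0

    def __post_init__(self) -> None:
        if self.paradigm not in PARADIGMS:
            raise ValidationError(f"paradigm must be one of {PARADIGMS}")
        if self.group not in GROUPS:
            raise ValidationError(f"group must be one of {GROUPS}")
        if self.assignment not in ASSIGNMENTS:
            raise ValidationError(f"assignment must be one of {ASSIGNMENTS}")
        if (self.group == "sham") != (self.assignment == "sham"):
            raise ValidationError("group and DBS assignment disagree")
        eps = sorted(self.episodes, key=lambda e: e.start)
        if not eps:
            raise ValidationError("session must define at least one episode")
        for e0, e1 in zip(eps, eps[1:]):
            if abs(e1.start - e0.end) > _T_ATOL:
                raise ValidationError("episodes must tile the session without gaps")
        if self.group == "sham" and any(e.dbs_on for e in eps):
            raise ValidationError("sham subjects never receive DBS (dbs_on=true found)")
        self.episodes = eps

    @property
    def duration(self) -> float:
        return self.episodes[-1].end - self.episodes[0].start

    def dbs_at(self, t: float) -> bool:
        for e in self.episodes:
            if e.start - _T_ATOL <= t < e.end:
                return e.dbs_on
        return self.episodes[-1].dbs_on


# ---------------------------------------------------------------------------
# analysis products
# ---------------------------------------------------------------------------

@dataclass
class PsdEstimate:
    """One-sided power spectral density in microvolt^2/Hz on a frequency grid."""

    freqs: np.ndarray
    power: np.ndarray
    n_tapers: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.shape != self.power.shape:
            raise ValidationError("freqs and power must have matching shapes")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValidationError("frequency grid must be strictly increasing")
        if np.any(self.power < -1e-12):
            raise ValidationError("PSD values must be non-negative")
        self.power = np.clip(self.power, 0.0, None)


@dataclass
class BandPowerSeries:
    """Band power per analysis window (raw microvolt^2 or relative, see meta)."""

    values: np.ndarray
    band: BandDefinition
    window_len: float
    window_starts: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.window_starts = np.asarray(self.window_starts, dtype=float)
        if self.values.shape != self.window_starts.shape:
            raise ValidationError("values and window_starts must align")
        if np.any(self.values < 0):
            raise ValidationError("band power must be non-negative")
        if self.normalized and np.any(self.values > 1 + 1e-9):
            raise ValidationError("relative band power must lie in [0, 1]")


@dataclass(frozen=True)
class EdResult:
    """Signed difference of band-restricted PSD L2 norms (or pointwise distance).

    In the default ("printed") mode the value is
    ``sqrt(sum_f a(f)^2) - sqrt(sum_f b(f)^2)`` over the grid points in
    ``f_range``; it is antisymmetric under swapping the inputs and zero for
    identical spectra.  The "pointwise" mode is the genuine Euclidean metric
    ``sqrt(sum_f (a(f)-b(f))^2)``.
    """

    value: float
    f_range: tuple[float, float]
    label_a: str
    label_b: str
    mode: str = "printed"


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sample rank test or a rank correlation."""

    statistic: float
    p_value: float
    test: str
    n_a: int
    n_b: int
    tau: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p-value out of [0,1]: {self.p_value}")
        if self.tau is not None and abs(self.tau) > 1 + 1e-12:
            raise ValidationError(f"|tau| must be <= 1, got {self.tau}")
        if self.test not in ("rank_sum", "kendall"):
            raise ValidationError(f"unknown test {self.test!r}")


# ---------------------------------------------------------------------------
# session bundle I/O
# ---------------------------------------------------------------------------

@dataclass
class SessionBundle:
    """Everything recorded in one behavioral session of one animal."""

    config: SessionConfig
    lfp: LfpRecording | None = None
    tracking: TrackingTrace | None = None
    codes: ForelimbCodeSeries | None = None
    rotation: RotationRateSeries | None = None
    states: StateIntervals | None = None


_CH_DTYPE = np.dtype(
    [
        ("region", "S8"),
        ("hemisphere", "S8"),
        ("lesioned", "u1"),
        ("subject_id", "S32"),
        ("group", "S8"),
    ]
)

_FLOAT_FMT = "%.6f"


def _write_lfp(path: Path, rec: LfpRecording) -> None:
    with h5py.File(path, "w", track_order=True) as f:
        g = f.create_group("lfp", track_order=True)
        g.create_dataset("samples", data=rec.samples, track_times=False)
        g.create_dataset("sample_rate", data=float(rec.sample_rate), track_times=False)
        g.create_dataset("t0", data=float(rec.t0), track_times=False)
        chans = np.empty(rec.n_channels, dtype=_CH_DTYPE)
        for i, ch in enumerate(rec.channels):
            chans[i] = (
                ch.region.encode(),
                ch.hemisphere.encode(),
                int(ch.lesioned),
                ch.subject_id.encode(),
                ch.group.encode(),
            )
        g.create_dataset("channels", data=chans, track_times=False)


def _read_lfp(path: Path) -> LfpRecording:
    with h5py.File(path, "r") as f:
        if "lfp" not in f:
            raise FormatError(f"{path.name}: missing 'lfp' group")
        g = f["lfp"]
        for name in ("samples", "sample_rate", "channels"):
            if name not in g:
                raise FormatError(f"{path.name}: missing dataset 'lfp/{name}'")
        samples = np.asarray(g["samples"], dtype=float)
        rate = float(g["sample_rate"][()])
        t0 = float(g["t0"][()]) if "t0" in g else 0.0
        raw = np.asarray(g["channels"])
        channels = [
            ChannelMeta(
                region=r["region"].decode(),
                hemisphere=r["hemisphere"].decode(),
                lesioned=bool(r["lesioned"]),
                subject_id=r["subject_id"].decode(),
                group=r["group"].decode(),
            )
            for r in raw
        ]
    if samples.ndim != 2 or samples.shape[0] != len(channels):
        raise FormatError(
            f"{path.name}: channel count mismatch between 'lfp/samples' and 'lfp/channels'"
        )
    return LfpRecording(samples, rate, channels, t0)


def _df_to_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def _require_columns(df: pd.DataFrame, cols: list[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{name}: missing column(s) {missing}")


def _series_dt(time_s: np.ndarray, name: str) -> float:
    if time_s.size < 2:
        raise FormatError(f"{name}: need at least two samples to infer dt")
    steps = np.diff(time_s)
    dt = float(np.median(steps))
    if dt <= 0 or np.any(np.abs(steps - dt) > 1e-4):
        raise FormatError(f"{name}: time_s must be uniformly spaced")
    return dt


def write_session(bundle: SessionBundle, path: str | Path) -> Path:
    """Write a session bundle to a directory; byte-deterministic per content.

    Raises :class:`ValidationError` if any component violates its invariants
    (validation happens on construction, so a hand-edited bundle is re-checked
    here by re-running ``__post_init__``).
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    # re-validate mutable components in case callers mutated arrays in place
    for obj in (bundle.config, bundle.lfp, bundle.tracking, bundle.codes, bundle.rotation):
        if obj is not None:
            obj.__post_init__()

    cfg = bundle.config
    cfg_doc = {
        "paradigm": cfg.paradigm,
        "group": cfg.group,
        "subject_id": cfg.subject_id,
        "assignment": cfg.assignment,
        "arena": [float(cfg.arena[0]), float(cfg.arena[1])],
        "fps": float(cfg.fps),
        "episodes": [
            {"start_s": float(e.start), "end_s": float(e.end), "dbs_on": bool(e.dbs_on)}
            for e in cfg.episodes
        ],
    }
    (path / "config.yaml").write_text(yaml.safe_dump(cfg_doc, sort_keys=True))

    if bundle.lfp is not None:
        _write_lfp(path / "lfp.h5", bundle.lfp)
    if bundle.tracking is not None:
        tr = bundle.tracking
        _df_to_csv(
            pd.DataFrame({"time_s": tr.times(), "x_cm": tr.x, "y_cm": tr.y}),
            path / "tracking.csv",
        )
    if bundle.codes is not None:
        cs = bundle.codes
        _df_to_csv(
            pd.DataFrame(
                {"time_s": cs.times(), "code": [format(c, "04b") for c in cs.codes]}
            ),
            path / "codes.csv",
        )
    if bundle.rotation is not None:
        rr = bundle.rotation
        _df_to_csv(
            pd.DataFrame({"time_s": rr.times(), "deg_per_s": rr.rate}),
            path / "rotation.csv",
        )
    if bundle.states is not None:
        lines = [
            f"{a:.6f}\t{b:.6f}\t{s}" for a, b, s in bundle.states.intervals
        ]
        (path / "states.tsv").write_text("\n".join(lines) + "\n")
    return path


def read_session(path: str | Path) -> SessionBundle:
    """Read a session directory written by :func:`write_session`.

    All streams are validated against their invariants; malformed files raise
    :class:`FormatError` naming the offending field.
    """
    path = Path(path)
    cfg_path = path / "config.yaml"
    if not cfg_path.exists():
        raise FormatError(f"{path}: missing config.yaml")
    doc = yaml.safe_load(cfg_path.read_text())
    for key in ("paradigm", "group", "subject_id", "assignment", "episodes"):
        if key not in doc:
            raise FormatError(f"config.yaml: missing field {key!r}")
    config = SessionConfig(
        paradigm=doc["paradigm"],
        episodes=[
            Episode(float(e["start_s"]), float(e["end_s"]), bool(e["dbs_on"]))
            for e in doc["episodes"]
        ],
        group=doc["group"],
        subject_id=str(doc["subject_id"]),
        assignment=doc["assignment"],
        arena=tuple(doc.get("arena", (74.0, 74.0))),
        fps=float(doc.get("fps", 25.0)),
    )

    bundle = SessionBundle(config=config)
    if (path / "lfp.h5").exists():
        bundle.lfp = _read_lfp(path / "lfp.h5")
    if (path / "tracking.csv").exists():
        df = pd.read_csv(path / "tracking.csv")
        _require_columns(df, ["time_s", "x_cm", "y_cm"], "tracking.csv")
        t = df["time_s"].to_numpy(float)
        dt = _series_dt(t, "tracking.csv")
        bundle.tracking = TrackingTrace(
            df["x_cm"].to_numpy(float),
            df["y_cm"].to_numpy(float),
            fps=1.0 / dt,
            arena=config.arena,
            t0=float(t[0]),
        )
    if (path / "codes.csv").exists():
        df = pd.read_csv(path / "codes.csv", dtype={"code": str})
        _require_columns(df, ["time_s", "code"], "codes.csv")
        t = df["time_s"].to_numpy(float)
        dt = _series_dt(t, "codes.csv")
        try:
            codes = np.array([int(c, 2) for c in df["code"]])
        except ValueError as exc:
            raise FormatError(f"codes.csv: non-binary code string ({exc})") from None
        bundle.codes = ForelimbCodeSeries(codes, dt=dt, t0=float(t[0]))
    if (path / "rotation.csv").exists():
        df = pd.read_csv(path / "rotation.csv")
        _require_columns(df, ["time_s", "deg_per_s"], "rotation.csv")
        t = df["time_s"].to_numpy(float)
        dt = _series_dt(t, "rotation.csv")
        bundle.rotation = RotationRateSeries(
            df["deg_per_s"].to_numpy(float), dt=dt, t0=float(t[0])
        )
    if (path / "states.tsv").exists():
        rows = []
        for ln in (path / "states.tsv").read_text().splitlines():
            if not ln.strip():
                continue
            parts = ln.split("\t")
            if len(parts) != 3:
                raise FormatError("states.tsv: expected start_s<TAB>end_s<TAB>state")
            rows.append((float(parts[0]), float(parts[1]), parts[2]))
        bundle.states = StateIntervals(rows)
    return bundle
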