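"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates the phenomenology of the hemi-parkinsonian (6-OHDA)
rat preparation so every pipeline stage can be exercised without animal
data:

* LFP = 1/f ("pink") background + a speed-modulated theta (6-12 Hz) tone +
  amplitude-modulated beta bursts (Poisson onsets, random in-band center
  frequency, Hann envelope) whose amplitude depends on lesion status,
  current behavioral state, sub-band and DBS state, plus an optional 130 Hz
  stimulation artifact;
* behavior = a semi-Markov chain over rearing / stepping / inactive with
  group-dependent dwell times (lesioned animals without DBS dwell long in
  inactivity; DBS restores sham-like dwells), emitted as forelimb codes and
  body-rotation rates consistent with the segmentation rules;
* tracking = mean-reverting speed with state-dependent targets, integrated
  in a 74 x 74 cm arena with reflecting walls at 25 frames/s;
* apomorphine screening = Poisson per-minute rotation counts;
* rotarod = per-round fall times with group-dependent means (about 100 s for
  unstimulated lesioned animals vs 200 s for sham).

Default cohort composition is 13 lesioned ("PD") and 12 sham subjects, the
lesioned group split 7 DBS-ON / 6 DBS-OFF.  A fixed seed plus config yields
bit-identical output; all randomness flows from one named generator per
subject.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .behavior import rotarod_outcome, rotarod_profile
from .core_io import (
    BANDS,
    ChannelMeta,
    Episode,
    ForelimbCodeSeries,
    LfpRecording,
    RotationRateSeries,
    SessionBundle,
    SessionConfig,
    StateIntervals,
    TrackingTrace,
    ValidationError,
    write_session,
)

__all__ = [
    "EffectConfig",
    "CohortConfig",
    "gen_behavior_sequence",
    "gen_lfp",
    "gen_tracking",
    "gen_rotation_record",
    "gen_cohort",
    "ROD_RADIUS_CM",
    "rod_speed_cm_s",
]

BEHAVIOR_DT = 0.25  # s, forelimb code update interval
TRACK_FPS = 25.0
LFP_FS = 1100.0
ROD_RADIUS_CM = 3.0  # effective rod radius used to convert rpm to cm/s

_STATE_BANDS = ("low_beta", "high_beta")
_STATES = ("rearing", "stepping", "inactive")


def rod_speed_cm_s(rpm) -> np.ndarray:
    """Linear walking speed on the rod surface for a rod speed in rpm."""
    return np.asarray(rpm, dtype=float) * 2.0 * np.pi * ROD_RADIUS_CM / 60.0


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class EffectConfig:
    """Amplitude model of the synthetic LFP and its lesion/DBS effects.

    Oscillation amplitudes are in microvolt.  ``lesion_gain`` multiplies the
    baseline beta-burst amplitude on the lesioned hemisphere, keyed by
    (state, band); the defaults place excess beta in both sub-bands during
    rearing and in low beta only during stepping, with no excess in
    inactivity.  With ``dbs_suppression`` the gains revert to 1 while
    stimulation is on.  ``subject_scale_sd`` is the sigma of a log-normal
    per-animal amplitude factor shared across hemispheres and channels
    (electrode impedance/placement variability).
    """

    pink_exponent: float = 1.0
    pink_scale: float = 12.0
    theta_base: float = 2.0
    theta_gain: float = 0.5  # microvolt per cm/s
    beta_amp_intact: float = 6.0
    burst_rate: float = 2.0  # bursts/s per band
    burst_duration: float = 0.3  # mean burst length, s
    lesion_gain: dict = field(default_factory=dict)
    dbs_suppression: bool = True
    dbs_artifact_amp: float = 0.0  # 130 Hz artifact, microvolt
    subject_scale_sd: float = 0.3

    def __post_init__(self) -> None:
        defaults = {(s, b): 1.0 for s in _STATES for b in _STATE_BANDS}
        defaults.update(
            {
                ("rearing", "low_beta"): 3.0,
                ("rearing", "high_beta"): 3.0,
                ("stepping", "low_beta"): 3.0,
            }
        )
        defaults.update(self.lesion_gain)
        self.lesion_gain = defaults
        if any(v < 0 for v in self.lesion_gain.values()):
            raise ValidationError("lesion gains must be non-negative")
        for a in ("pink_scale", "theta_base", "theta_gain", "beta_amp_intact",
                  "burst_rate", "dbs_artifact_amp"):
            if getattr(self, a) < 0:
                raise ValidationError(f"{a} must be non-negative")
        if self.burst_duration <= 0:
            raise ValidationError("burst_duration must be positive")

    def beta_amp(self, lesioned: bool, state: str, band: str, dbs_on: bool) -> float:
        """Burst amplitude for one (hemisphere, state, band, DBS) context."""
        key = (state, band)
        if key not in self.lesion_gain:
            raise ValidationError(f"no effect configured for state/band {key}")
        gain = 1.0
        if lesioned and not (dbs_on and self.dbs_suppression):
            gain = self.lesion_gain[key]
        return self.beta_amp_intact * gain

    def nulled(self) -> "EffectConfig":
        """Copy with every lesion/DBS effect removed (all gains 1, no artifact)."""
        return dataclasses.replace(
            self,
            lesion_gain={(s, b): 1.0 for s in _STATES for b in _STATE_BANDS},
            dbs_artifact_amp=0.0,
        )


# dwell-time means (s) of the semi-Markov behavior chain
_DWELL_MOBILE = {"rearing": 5.0, "stepping": 4.0, "inactive": 6.0}
_DWELL_IMPAIRED = {"rearing": 2.5, "stepping": 2.5, "inactive": 15.0}

_SESSION_DURATIONS = {"cylinder": 120.0, "openfield": 600.0}


@dataclass
class CohortConfig:
    """Cohort composition and session design."""

    n_pd: int = 13
    n_sham: int = 12
    n_dbs_on: int = 7
    n_dbs_off: int = 6
    paradigms: tuple[str, ...] = ("cylinder", "openfield", "rotarod")
    durations: dict = field(default_factory=lambda: dict(_SESSION_DURATIONS))
    regions: tuple[str, ...] = ("M1", "STN")
    rotarod_lfp: bool = True
    rotarod_rounds: int = 3
    rotarod_mean_time: dict = field(
        default_factory=lambda: {"sham": 200.0, "pd_off": 100.0, "pd_on": 190.0}
    )
    rotarod_time_sd: float = 25.0
    effects: EffectConfig = field(default_factory=EffectConfig)

    def __post_init__(self) -> None:
        if self.n_dbs_on + self.n_dbs_off != self.n_pd:
            raise ValidationError("n_dbs_on + n_dbs_off must equal n_pd")
        if min(self.n_pd, self.n_sham) < 1:
            raise ValidationError("cohort must contain both groups")
        for p in self.paradigms:
            if p not in ("cylinder", "openfield", "rotarod"):
                raise ValidationError(f"unknown paradigm {p!r}")


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

def _episodes_for(paradigm: str, duration: float, dbs_on_subject: bool) -> list[Episode]:
    if paradigm == "cylinder":
        return [Episode(0.0, 60.0, False), Episode(60.0, duration, dbs_on_subject)]
    if paradigm == "openfield":
        # 3 / 4 / 3-minute design at the standard 600 s, scaled otherwise
        e1, e2 = 0.3 * duration, 0.7 * duration
        return [
            Episode(0.0, e1, False),
            Episode(e1, e2, dbs_on_subject),
            Episode(e2, duration, False),
        ]
    return [Episode(0.0, duration, dbs_on_subject)]


def gen_behavior_sequence(
    duration: float,
    group: str,
    episodes: list[Episode],
    rng: np.random.Generator,
    dt: float = BEHAVIOR_DT,
) -> tuple[StateIntervals, ForelimbCodeSeries, RotationRateSeries]:
    """Semi-Markov behavioral state sequence with consistent codes/rotation.

    Dwell times are gamma-distributed with group-dependent means; lesioned
    animals dwell long in inactivity unless DBS is on during the current
    episode, in which case sham-like dwells apply.  Transitions pass through
    rearing between stepping and inactive bouts so that each non-rearing run
    holds a single generating state — the emitted codes and rotation then
    let :func:`betalock.behavior.segment_states` recover the sequence.
    """
    n_frames = int(round(duration / dt))
    dbs_at = lambda t: any(e.start <= t < e.end and e.dbs_on for e in episodes)

    ivs: list[tuple[float, float, str]] = []
    t = 0.0
    state = "inactive" if group == "PD" else "rearing"
    while t < duration - 1e-9:
        mobile = group == "sham" or dbs_at(t)
        means = _DWELL_MOBILE if mobile else _DWELL_IMPAIRED
        dwell = float(rng.gamma(2.0, means[state] / 2.0))
        dwell = float(np.clip(dwell, 2.0, 30.0))
        dwell = max(1, int(round(dwell / dt))) * dt
        end = min(t + dwell, duration)
        ivs.append((t, end, state))
        if state == "rearing":
            state = "stepping" if rng.random() < 0.5 else "inactive"
        else:
            state = "rearing"
        t = end

    codes = np.empty(n_frames, dtype=int)
    rate = np.empty(n_frames, dtype=float)
    for a, b, s in ivs:
        i0, i1 = int(round(a / dt)), int(round(b / dt))
        i1 = min(i1, n_frames)
        n = i1 - i0
        if n <= 0:
            continue
        if s == "rearing":
            codes[i0:i1] = np.where(rng.random(n) < 0.7, 12, 8)
            rate[i0:i1] = rng.normal(0.0, 2.0, n)
        elif s == "stepping":
            codes[i0:i1] = np.where((np.arange(n) % 2) == 0, 1, 2)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            rate[i0:i1] = sign * (60.0 + rng.normal(0.0, 5.0, n))
        else:
            codes[i0:i1] = 3
            rate[i0:i1] = rng.normal(0.0, 0.5, n)

    states = StateIntervals([(a, min(b, n_frames * dt), s) for a, b, s in ivs if a < n_frames * dt])
    return (
        states,
        ForelimbCodeSeries(codes, dt=dt),
        RotationRateSeries(rate, dt=dt),
    )


# ---------------------------------------------------------------------------
# tracking
# ---------------------------------------------------------------------------

_SPEED_TARGET = {"rearing": 0.5, "stepping": 8.0, "inactive": 0.1}
_SPEED_SIGMA = {"rearing": 0.2, "stepping": 1.5, "inactive": 0.05}


def gen_tracking(
    states: StateIntervals,
    rng: np.random.Generator,
    arena: tuple[float, float] = (74.0, 74.0),
    fps: float = TRACK_FPS,
) -> TrackingTrace:
    """Arena trajectory whose speed mean-reverts to a state-dependent target.

    Positions integrate a heading random walk and reflect at the arena
    walls; output is ``fps`` frames per second covering the segmented span.
    """
    dt = 1.0 / fps
    n = int(round(states.duration * fps))
    t_axis = states.start + np.arange(n) * dt
    # frame-wise state lookup
    starts = np.array([a for a, _, _ in states.intervals])
    labels = [s for _, _, s in states.intervals]
    idx = np.clip(np.searchsorted(starts, t_axis, side="right") - 1, 0, len(labels) - 1)

    tau = 1.0
    x = np.empty(n)
    y = np.empty(n)
    w, h = arena
    x[0], y[0] = w / 2.0, h / 2.0
    speed = 0.0
    heading = rng.uniform(0, 2 * np.pi)
    for i in range(1, n):
        s_lbl = labels[idx[i]]
        mu, sig = _SPEED_TARGET[s_lbl], _SPEED_SIGMA[s_lbl]
        speed += (mu - speed) * dt / tau + sig * np.sqrt(dt) * rng.standard_normal()
        speed = max(speed, 0.0)
        heading += rng.normal(0.0, 0.8) * np.sqrt(dt)
        nx = x[i - 1] + speed * np.cos(heading) * dt
        ny = y[i - 1] + speed * np.sin(heading) * dt
        # reflect at walls
        if nx < 0:
            nx = -nx
            heading = np.pi - heading
        elif nx > w:
            nx = 2 * w - nx
            heading = np.pi - heading
        if ny < 0:
            ny = -ny
            heading = -heading
        elif ny > h:
            ny = 2 * h - ny
            heading = -heading
        x[i], y[i] = min(max(nx, 0.0), w), min(max(ny, 0.0), h)
    return TrackingTrace(x, y, fps=fps, arena=arena, t0=states.start)


# ---------------------------------------------------------------------------
# LFP
# ---------------------------------------------------------------------------

def _pink_noise(n: int, exponent: float, rms: float, rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shape, n=n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def gen_lfp(
    states: StateIntervals,
    config: SessionConfig,
    channels: list[ChannelMeta],
    effects: EffectConfig,
    rng: np.random.Generator,
    speed: np.ndarray | None = None,
    speed_fps: float = TRACK_FPS,
    fs: float = LFP_FS,
    subject_scale: float = 1.0,
) -> LfpRecording:
    """Synthesize the session LFP for the given channels at ``fs`` Hz.

    Each channel gets an independent pink background and burst stream; the
    per-subject amplitude factor ``subject_scale`` multiplies every
    oscillatory and background amplitude of the animal.
    """
    duration = states.duration
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    if speed is not None:
        sp_t = np.arange(speed.size) / speed_fps
        speed_lfp = np.interp(t, sp_t, np.asarray(speed, dtype=float))
    else:
        speed_lfp = None

    # DBS mask on the LFP time axis
    dbs_mask = np.zeros(n, dtype=bool)
    for e in config.episodes:
        if e.dbs_on:
            i0, i1 = int(round(e.start * fs)), int(round(e.end * fs))
            dbs_mask[max(i0, 0) : min(i1, n)] = True

    rows = []
    for ch in channels:
        x = _pink_noise(n, effects.pink_exponent, effects.pink_scale * subject_scale, rng)

        theta_f = rng.uniform(7.0, 9.0)
        theta_amp = effects.theta_base + (
            effects.theta_gain * speed_lfp if speed_lfp is not None else 0.0
        )
        x = x + subject_scale * theta_amp * np.sin(
            2 * np.pi * theta_f * t + rng.uniform(0, 2 * np.pi)
        )

        for band_name in _STATE_BANDS:
            band = BANDS[band_name]
            burst_wave = np.zeros(n)
            n_bursts = rng.poisson(effects.burst_rate * duration)
            onsets = np.sort(rng.uniform(0.0, duration, n_bursts))
            for onset in onsets:
                dur = float(np.clip(rng.exponential(effects.burst_duration), 0.2, 1.0))
                # center-weighted, 1 Hz inside the edges, so burst side-lobes
                # stay essentially in-band
                f0 = rng.triangular(band.f_lo + 1.0, band.center, band.f_hi - 1.0)
                phase = rng.uniform(0, 2 * np.pi)
                st = states.state_at(min(onset, duration - 1e-6))
                amp = effects.beta_amp(
                    ch.lesioned, st, band_name, config.dbs_at(onset)
                ) * subject_scale
                if amp == 0.0:
                    continue
                i0 = int(round(onset * fs))
                i1 = min(int(round((onset + dur) * fs)), n)
                m = i1 - i0
                if m < 2:
                    continue
                env = np.hanning(m)
                tt = t[i0:i1]
                burst_wave[i0:i1] += amp * env * np.sin(2 * np.pi * f0 * tt + phase)
            # short bursts are spectrally broad; confine their energy to the
            # generating band so cross-band effects stay controlled
            sos = signal.butter(
                4, [band.f_lo, band.f_hi], btype="bandpass", fs=fs, output="sos"
            )
            x = x + signal.sosfiltfilt(sos, burst_wave)

        if effects.dbs_artifact_amp > 0 and dbs_mask.any():
            artifact = effects.dbs_artifact_amp * np.sin(2 * np.pi * 130.0 * t)
            x = x + np.where(dbs_mask, artifact, 0.0)
        rows.append(x)

    return LfpRecording(np.vstack(rows), fs, list(channels), t0=states.start)


# ---------------------------------------------------------------------------
# rotation screening
# ---------------------------------------------------------------------------

def gen_rotation_record(
    rate_per_min: float, rng: np.random.Generator, minutes: int = 30
) -> np.ndarray:
    """Per-minute contralateral rotation counts (independent Poisson)."""
    if rate_per_min < 0:
        raise ValidationError("rotation rate must be non-negative")
    return rng.poisson(rate_per_min, minutes)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def _subject_table(config: CohortConfig, seed: int) -> pd.DataFrame:
    master = np.random.SeedSequence(seed)
    n_total = config.n_pd + config.n_sham
    child_seeds = np.random.default_rng(master).integers(0, 2**31 - 1, n_total)
    rows = []
    k = 0
    for i in range(config.n_pd):
        assignment = "PD-DBS ON" if i < config.n_dbs_on else "PD-DBS OFF"
        rows.append(
            {"subject_id": f"PD{i + 1:02d}", "group": "PD", "assignment": assignment,
             "seed": int(child_seeds[k])}
        )
        k += 1
    for i in range(config.n_sham):
        rows.append(
            {"subject_id": f"SH{i + 1:02d}", "group": "sham", "assignment": "sham",
             "seed": int(child_seeds[k])}
        )
        k += 1
    return pd.DataFrame(rows)


def _subject_channels(config: CohortConfig, subject_id: str, group: str) -> list[ChannelMeta]:
    chans = []
    for region in config.regions:
        for hemi in ("left", "right"):
            lesioned = group == "PD" and hemi == "right"
            chans.append(ChannelMeta(region, hemi, lesioned, subject_id, group))
    return chans


def gen_subject_session(
    paradigm: str,
    subject_id: str,
    group: str,
    assignment: str,
    config: CohortConfig,
    rng: np.random.Generator,
    subject_scale: float,
    round_idx: int = 1,
) -> SessionBundle:
    """One full session bundle (behavior + tracking + LFP) for one subject."""
    dbs_subject = assignment == "PD-DBS ON"
    if paradigm == "rotarod":
        profile = rotarod_profile("test")
        dbs_round = dbs_subject and round_idx == config.rotarod_rounds
        key = "sham" if group == "sham" else ("pd_on" if dbs_round else "pd_off")
        fall = float(
            np.clip(
                rng.normal(config.rotarod_mean_time[key], config.rotarod_time_sd),
                20.0,
                profile.duration,
            )
        )
        outcome = rotarod_outcome(fall, profile)
        episodes = [Episode(0.0, fall, dbs_round)]
        sc = SessionConfig(
            paradigm="rotarod", episodes=episodes, group=group,
            subject_id=subject_id, assignment=assignment,
        )
        # forced locomotion: stepping throughout, speed follows the rod
        states = StateIntervals([(0.0, fall, "stepping")])
        n_fr = int(round(fall * TRACK_FPS))
        rod_rpm = np.array([profile.speed_at(i / TRACK_FPS) for i in range(n_fr)])
        speed = rod_speed_cm_s(rod_rpm)
        bundle = SessionBundle(config=sc, states=states)
        if config.rotarod_lfp:
            bundle.lfp = gen_lfp(
                states, sc, _subject_channels(config, subject_id, group),
                config.effects, rng, speed=speed, subject_scale=subject_scale,
            )
        bundle.outcome = outcome  # type: ignore[attr-defined]
        return bundle

    duration = config.durations[paradigm]
    episodes = _episodes_for(paradigm, duration, dbs_subject)
    sc = SessionConfig(
        paradigm=paradigm, episodes=episodes, group=group,
        subject_id=subject_id, assignment=assignment,
    )
    states, codes, rotation = gen_behavior_sequence(duration, group, episodes, rng)
    bundle = SessionBundle(config=sc, codes=codes, rotation=rotation, states=states)
    speed = None
    if paradigm == "openfield":
        bundle.tracking = gen_tracking(states, rng)
        from .behavior import compute_speed

        speed = compute_speed(bundle.tracking)
    bundle.lfp = gen_lfp(
        states, sc, _subject_channels(config, subject_id, group),
        config.effects, rng, speed=speed, subject_scale=subject_scale,
    )
    return bundle


def gen_cohort(config: CohortConfig, out_dir: str | Path, seed: int) -> pd.DataFrame:
    """Generate and write a full cohort; returns the manifest.

    Layout: ``out_dir/<subject_id>/<paradigm>/`` session directories (rotarod
    rounds as ``rotarod_r<k>``), a per-subject ``rotarod.csv`` outcome table,
    and ``manifest.csv`` at the cohort root recording group, DBS assignment
    and per-subject seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = _subject_table(config, seed)
    for rec in manifest.itertuples():
        rng = np.random.default_rng(rec.seed)
        subject_scale = float(np.exp(rng.normal(0.0, config.effects.subject_scale_sd)))
        subj_dir = out_dir / rec.subject_id
        rot_rows = []
        for paradigm in config.paradigms:
            if paradigm == "rotarod":
                for r in range(1, config.rotarod_rounds + 1):
                    bundle = gen_subject_session(
                        paradigm, rec.subject_id, rec.group, rec.assignment,
                        config, rng, subject_scale, round_idx=r,
                    )
                    write_session(bundle, subj_dir / f"rotarod_r{r}")
                    oc = bundle.outcome  # type: ignore[attr-defined]
                    rot_rows.append(
                        {"round": r, "time_on_rod_s": oc.time_on_rod,
                         "max_speed_rpm": oc.max_speed,
                         "dbs_on": bundle.config.episodes[0].dbs_on}
                    )
            else:
                bundle = gen_subject_session(
                    paradigm, rec.subject_id, rec.group, rec.assignment,
                    config, rng, subject_scale,
                )
                write_session(bundle, subj_dir / paradigm)
        if rot_rows:
            pd.DataFrame(rot_rows).to_csv(
                subj_dir / "rotarod.csv", index=False, float_format="%.6f",
                lineterminator="\n",
            )
    manifest.to_csv(out_dir / "manifest.csv", index=False, lineterminator="\n")
    return manifest
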