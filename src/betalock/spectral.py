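"""Multitaper spectral estimation and the PSD-distance statistic.

Power spectral densities are Thomson multitaper estimates with 5 Slepian
(DPSS) tapers and time-bandwidth product NW = 3 (the standard pairing that
yields exactly 2*NW - 1 = 5 usable tapers).  Densities are one-sided and
normalized so that the integral over [0, Nyquist] equals the signal
variance.

The distance statistic between two spectra is, in its default "printed"
mode, the signed difference of band-restricted L2 norms

    ED(a, b) = sqrt(sum_f a(f)^2) - sqrt(sum_f b(f)^2),   f in [13, 30] Hz.

This is not a metric: it vanishes whenever the two norms agree even if the
spectra differ.  The "pointwise" mode computes the genuine Euclidean
distance sqrt(sum_f (a(f) - b(f))^2) and distinguishes such pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.signal import windows

from .core_io import (
    BandDefinition,
    EdResult,
    LfpRecording,
    PsdEstimate,
    StateIntervals,
    ValidationError,
)

__all__ = [
    "multitaper_psd",
    "SpectrogramEstimate",
    "spectrogram",
    "state_locked_psd",
    "band_power",
    "psd_euclidean_distance",
    "average_psds",
]

DEFAULT_N_TAPERS = 5
DEFAULT_NW = 3.0
_NORM_RANGE = (1.0, 100.0)  # denominator band for relative ("normalized") power


@lru_cache(maxsize=64)
def _dpss(n: int, nw: float, k: int) -> np.ndarray:
    return windows.dpss(n, nw, Kmax=k)


def _as_1d(segment) -> tuple[np.ndarray, float, float]:
    """Accept a 1-D array with explicit rate or a single-channel recording."""
    if isinstance(segment, LfpRecording):
        if segment.n_channels != 1:
            raise ValidationError(
                "multitaper_psd operates on a single channel; use .select() first"
            )
        return segment.samples[0], segment.sample_rate, segment.t0
    raise TypeError("pass an LfpRecording or use multitaper_psd(x, sample_rate=...)")


def multitaper_psd(
    segment,
    sample_rate: float | None = None,
    n_tapers: int = DEFAULT_N_TAPERS,
    nw: float = DEFAULT_NW,
    min_duration: float = 1.0,
) -> PsdEstimate:
    """Thomson multitaper one-sided PSD of one LFP segment.

    ``segment`` is either a single-channel :class:`LfpRecording` or a 1-D
    array with ``sample_rate`` given.  Requires at least ``min_duration``
    seconds of signal so the frequency resolution is 1 Hz or better.
    """
    if isinstance(segment, LfpRecording):
        x, fs, _ = _as_1d(segment)
    else:
        if sample_rate is None:
            raise ValidationError("sample_rate is required for array input")
        x, fs = np.asarray(segment, dtype=float), float(sample_rate)
    if x.ndim != 1:
        raise ValidationError("segment must be one-dimensional")
    n_min = int(round(min_duration * fs))
    if x.size < n_min:
        raise ValidationError(
            f"segment too short: {x.size} samples, need >= {n_min} "
            f"({min_duration:g} s at {fs:g} Hz)"
        )
    n = x.size
    tapers = _dpss(n, nw, n_tapers)  # (k, n), each with unit energy
    spectra = np.abs(np.fft.rfft(tapers * x[None, :], axis=1)) ** 2 / fs
    psd = spectra.mean(axis=0)
    # one-sided density: double everything except DC (and Nyquist when n even)
    psd[1:] *= 2.0
    if n % 2 == 0:
        psd[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return PsdEstimate(freqs, psd, n_tapers=n_tapers, meta={"nw": nw, "n_samples": n})


@dataclass
class SpectrogramEstimate:
    """Time-frequency power: one multitaper PSD column per analysis window."""

    times: np.ndarray  # window centers on the session clock, s
    freqs: np.ndarray
    power: np.ndarray  # (n_freqs, n_times), microvolt^2/Hz
    window_len: float
    overlap: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("spectrogram times must be strictly increasing")
        if np.any(self.power < 0):
            raise ValidationError("spectrogram power must be non-negative")


def spectrogram(
    rec: LfpRecording,
    window_len: float = 1.0,
    overlap: float = 0.5,
    n_tapers: int = DEFAULT_N_TAPERS,
    nw: float = DEFAULT_NW,
) -> SpectrogramEstimate:
    """Sliding-window multitaper spectrogram of a single channel.

    Window centers are reported on the session clock so behavioral codes can
    be overlaid directly.
    """
    x, fs, t0 = _as_1d(rec)
    if not 0.0 <= overlap < 1.0:
        raise ValidationError("overlap must lie in [0, 1)")
    n_win = int(round(window_len * fs))
    if x.size < n_win:
        raise ValidationError("recording shorter than one analysis window")
    step = max(1, int(round(n_win * (1.0 - overlap))))
    starts = np.arange(0, x.size - n_win + 1, step)
    cols = []
    for s in starts:
        est = multitaper_psd(
            x[s : s + n_win], fs, n_tapers=n_tapers, nw=nw, min_duration=window_len
        )
        cols.append(est.power)
    freqs = np.fft.rfftfreq(n_win, d=1.0 / fs)
    times = t0 + (starts + n_win / 2) / fs
    return SpectrogramEstimate(
        times=times,
        freqs=freqs,
        power=np.column_stack(cols),
        window_len=window_len,
        overlap=overlap,
    )


def state_locked_psd(
    rec: LfpRecording,
    states: StateIntervals,
    state: str,
    min_episode: float = 1.0,
    window_len: float = 1.0,
    n_tapers: int = DEFAULT_N_TAPERS,
    nw: float = DEFAULT_NW,
) -> PsdEstimate:
    """Average PSD over all episodes of one behavioral state.

    Each qualifying episode (duration >= ``min_episode``) is chopped into
    non-overlapping ``window_len``-second windows (the trailing remainder is
    dropped) so every window shares one frequency grid; the state PSD is the
    window-count-weighted — i.e. duration-weighted — average.  ``meta``
    records the episodes and window count used.
    """
    x, fs, t0 = _as_1d(rec)
    n_win = int(round(window_len * fs))
    used: list[tuple[float, float]] = []
    windows_acc: list[np.ndarray] = []
    for a, b in states.episodes(state):
        if (b - a) < min_episode - 1e-9:
            continue
        i0 = int(round((a - t0) * fs))
        i1 = int(round((b - t0) * fs))
        i0 = max(i0, 0)
        i1 = min(i1, x.size)
        n_full = (i1 - i0) // n_win
        if n_full == 0:
            continue
        for k in range(n_full):
            seg = x[i0 + k * n_win : i0 + (k + 1) * n_win]
            est = multitaper_psd(seg, fs, n_tapers=n_tapers, nw=nw, min_duration=window_len)
            windows_acc.append(est.power)
        used.append((a, b))
    if not windows_acc:
        raise ValidationError(
            f"no {state!r} episode of at least {min_episode} s available"
        )
    freqs = np.fft.rfftfreq(n_win, d=1.0 / fs)
    power = np.mean(windows_acc, axis=0)
    return PsdEstimate(
        freqs,
        power,
        n_tapers=n_tapers,
        meta={
            "state": state,
            "episodes": used,
            "n_windows": len(windows_acc),
            "window_len": window_len,
        },
    )


def average_psds(psds: list[PsdEstimate], weights=None) -> PsdEstimate:
    """(Weighted) mean of PSDs sharing one frequency grid."""
    if not psds:
        raise ValidationError("cannot average an empty PSD list")
    freqs = psds[0].freqs
    for p in psds[1:]:
        if p.freqs.shape != freqs.shape or not np.allclose(p.freqs, freqs):
            raise ValidationError("PSDs must share a common frequency grid")
    stack = np.stack([p.power for p in psds])
    power = np.average(stack, axis=0, weights=weights)
    return PsdEstimate(freqs, power, n_tapers=psds[0].n_tapers, meta={"n_averaged": len(psds)})


def band_power(
    psd: PsdEstimate, band: BandDefinition, normalize: str = "relative"
) -> float:
    """Average band power: trapezoidal integral of the PSD over the band.

    Bands own their grid points per :meth:`BandDefinition.mask` (low beta is
    [13, 21), high beta [21, 30]).  ``normalize="relative"`` divides by the
    integral over 1-100 Hz, yielding a dimensionless value in [0, 1];
    ``normalize="raw"`` returns microvolt^2.
    """
    if normalize not in ("raw", "relative"):
        raise ValidationError("normalize must be 'raw' or 'relative'")
    f, p = psd.freqs, psd.power
    if band.f_lo < f[0] - 1e-9 or band.f_hi > f[-1] + 1e-9:
        raise ValidationError(
            f"band [{band.f_lo}, {band.f_hi}] Hz outside PSD grid "
            f"[{f[0]:g}, {f[-1]:g}] Hz"
        )
    mask = band.mask(f)
    if mask.sum() < 2:
        raise ValidationError("band contains fewer than two grid points")
    raw = float(np.trapezoid(p[mask], f[mask]))
    if normalize == "raw":
        return raw
    lo, hi = _NORM_RANGE
    nmask = (f >= lo) & (f <= hi)
    total = float(np.trapezoid(p[nmask], f[nmask]))
    if total <= 0:
        raise ValidationError("total power over 1-100 Hz is zero; relative power undefined")
    return raw / total


def psd_euclidean_distance(
    psd_a: PsdEstimate,
    psd_b: PsdEstimate,
    f_range: tuple[float, float] = (13.0, 30.0),
    mode: str = "printed",
    label_a: str = "a",
    label_b: str = "b",
) -> EdResult:
    """Distance statistic between two spectra over ``f_range`` (inclusive).

    ``mode="printed"`` returns the signed difference of L2 norms (zero for
    equal-norm spectra, antisymmetric under swapping); ``mode="pointwise"``
    returns the true Euclidean distance.  The two PSDs must share the grid
    over ``f_range`` exactly — no silent interpolation.
    """
    if mode not in ("printed", "pointwise"):
        raise ValidationError("mode must be 'printed' or 'pointwise'")
    lo, hi = f_range
    ma = (psd_a.freqs >= lo - 1e-9) & (psd_a.freqs <= hi + 1e-9)
    mb = (psd_b.freqs >= lo - 1e-9) & (psd_b.freqs <= hi + 1e-9)
    fa, fb = psd_a.freqs[ma], psd_b.freqs[mb]
    if fa.size == 0:
        raise ValidationError(f"no grid points in f_range {f_range}")
    if fa.shape != fb.shape or not np.allclose(fa, fb, atol=1e-9):
        raise ValidationError(
            "frequency grids differ over f_range; resample explicitly before comparing"
        )
    a, b = psd_a.power[ma], psd_b.power[mb]
    if mode == "printed":
        value = float(np.sqrt(np.sum(a**2)) - np.sqrt(np.sum(b**2)))
    else:
        value = float(np.sqrt(np.sum((a - b) ** 2)))
    return EdResult(value=value, f_range=(lo, hi), label_a=label_a, label_b=label_b, mode=mode)
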