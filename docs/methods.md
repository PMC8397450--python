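# Methods

This note documents the models, estimators and design choices behind
`betalock`, in the order data flows through the package.

## Session model and conventions

A session is one behavioral trial of one animal. All streams share one
clock in seconds with session start at 0; intervals are half-open
`[start, end)`, which makes contiguity and time-budget arithmetic exact.
Units are fixed throughout: microvolt (LFP), cm (space), s (time), Hz
(frequency), degrees (rotation). Readers validate and reject; they never
repair. In the hemi-parkinsonian design the right hemisphere of lesioned
("PD") animals is the lesioned side and the left is the intact
within-animal control; sham animals are intact bilaterally and never
receive stimulation — these are enforced invariants, not conventions the
caller must remember.

## Preprocessing

The wideband stage reproduces a 0.3–300 Hz acquisition filter with an
effective 20th-order Butterworth magnitude response. It is applied
zero-phase (forward–backward over cascaded second-order sections) with the
design order halved to 10, so the squared magnitude matches the nominal
single-pass filter; zero-phase filtering is the default because the
analysis aligns LFP features to behavioral events, and a causal mode is
available for completeness (the acquisition literature rarely states
which was used). A direct high-order IIR in transfer-function form is
numerically unstable; second-order sections are not.

Resampling to 1.1 kHz uses the polyphase anti-aliased method with the rate
ratio approximated by a rational factor to relative error < 1e-9.

Band extraction (theta 6–12, low beta 13–21, high beta 21–30 Hz) uses
4th-order zero-phase Butterworth bandpasses. Verified against the designed
frequency response: a 17 Hz tone passes the low-beta filter within 1% and
is attenuated by ~56 dB by the high-beta filter. Where the two beta bands
share the 21 Hz edge, integration assigns the edge to high beta: low beta
owns [13, 21), high beta [21, 30].

## Behavioral quantification

Forelimb positions in the cylinder test are digitized every 0.25 s as a
4-bit code (MSB→LSB: left-wall, right-wall, left-floor, right-floor).
Wall contact — the rearing criterion — is the strict numeric rule
`code > 4`. Two consequences are documented rather than silently patched:
code 4 (right paw on wall only) is *not* rearing under the strict rule, and
code 0 ("unsupported rearing" in some scoring schemes) can never satisfy
it; `qc_unsupported_rearing` flags all-zero runs adjacent to wall-contact
runs for manual audit.

Segmentation partitions the session: maximal wall-contact runs are rearing
(precedence: wall contact is unambiguous and rotation can co-occur during
rears); each maximal non-rearing run is stepping when its cumulative
absolute body-angle change exceeds 45° *and* its floor-contact bits change
at least twice (forepaw alternation), otherwise inactive. The angle rule is
evaluated over the whole run because no evaluation window is part of the
definition; this is the closest deterministic reading. Runs shorter than
0.5 s (2 code frames, configurable) merge into their preceding neighbor to
suppress single-frame flicker. The partition property — state durations sum
exactly to session length — holds for any input and is property-tested.

Open-field features per episode: average velocity, distance (frame-wise
displacement sum), large-movement time (maximal runs with speed > 4 cm/s
lasting > 2 s) and immobility (speed < 0.5 cm/s, > 2 s). Speed is a
centered finite difference on coordinates smoothed with a 0.2 s moving
average — 25 fps tracking jitter otherwise inflates crossings of the
0.5 cm/s immobility boundary. Episode boundaries follow the 3/4/3-minute
design (scaled proportionally for non-standard durations).

The apomorphine screening criterion is `mean rotations/min >= 3.0` over 30
one-minute counts. The rotarod test ramp runs 2→60 rpm in 59 equal 8-s
steps (472 s total); training uses the 8 fixed speeds (12, 16, 19, 21, 24,
26, 28, 38 rpm) at 60 s each. The outcome of a run is the fall time and the
ramp speed at that time.

## Spectral estimation

PSDs are Thomson multitaper estimates with 5 Slepian tapers. The
time–bandwidth product is NW = 3, the standard pairing for which
2·NW − 1 = 5 tapers remain well concentrated. Densities are one-sided and
scaled so the integral over [0, Nyquist] equals the signal variance
(Parseval; tested against white noise within 10% and an analytic tone
within 10% of A²/2).

State-locked PSDs average over all episodes of a state. Episodes of
different lengths have incompatible frequency grids, so each qualifying
episode is chopped into non-overlapping fixed-length windows (default 1 s;
the trailing remainder is dropped) and the state PSD is the
window-count-weighted — i.e. duration-weighted — mean on the common grid.
The window length bounds the spectral smoothing: a T-second window with
NW = 3 smears power over ±3/T Hz. The cylinder hemisphere analysis uses
2-s windows (±1.5 Hz), which cleanly separates the 13–21 and 21–30 Hz
sub-bands; 1-s windows are the floor for short behavioral episodes.

"Normalized band power" is implemented as relative power: the band integral
divided by the 1–100 Hz integral. Raw (microvolt²) power is always
available, and the cylinder report emits both. The within-animal
hemisphere contrast defaults to *raw* power: the per-animal amplitude scale
(electrode impedance, placement) is common to both hemispheres, so raw
power compares like with like, whereas relative normalization divides that
shared scale out and with it the pairing that keeps null contrasts
conservative.

The distance statistic (printed mode) is the signed difference of L2 norms
over the 13–30 Hz grid points, `sqrt(Σ a²) − sqrt(Σ b²)`. As printed it is
not a metric — any two equal-norm spectra are at distance zero — so the
pointwise Euclidean distance is available as a documented alternative mode.
The condition comparison (each lesioned subject's spectrum against the sham
group average, unstimulated vs stimulated subgroups by rank-sum) rescales
every spectrum to unit 1–100 Hz power first, by default, so the statistic
reflects spectral composition rather than per-animal signal amplitude;
without this the amplitude spread across animals swamps the DBS effect at
n = 7 vs 6.

## Rank statistics

Two-sample comparisons are two-sided Wilcoxon rank-sum tests. With pooled
n ≤ 12 the p-value is exact: every C(n, n_a) assignment of the pooled
midranks is enumerated and p = P(|W − μ| ≥ |w_obs − μ|). Above that, a
tie-corrected normal approximation with continuity correction is used,
averaged with the matching Student-t approximation (Iman 1974); the plain
normal approximation deviates from enumeration by up to ~0.04 at pooled
sizes near 12, while the refinement stays within ~0.01 for group sizes ≥ 4
(3-vs-3 remains irreducibly ~0.03 — no asymptotic is meaningful there).
Speed–power correlations are Kendall tau-b with two-sided p-values.

Speed–power tables cut the session into non-overlapping 5-s windows, assign
each window its mean tracked (or rod) speed, bin at 1 cm/s over 1–16 cm/s,
and report the per-bin median power and window count; bins with fewer than
5 windows are dropped (the sparse-high-speed exclusion), and windows
straddling a DBS episode boundary are discarded to prevent ON/OFF
contamination. Per-bin group tests are uncorrected by default, matching
per-speed significance rasters as usually reported; Benjamini–Hochberg
adjustment is available by flag and recorded in the output.

## Synthetic cohorts

The generator emulates the phenomenology the analysis assumes, not the
biophysics. Per channel: 1/f background (spectral shaping of white noise,
slope −1, 12 μV RMS), a theta tone whose amplitude is 2 μV plus
0.5 μV/(cm/s) times locomotion speed, and per-band beta bursts — Poisson
onsets at 2/s, exponential durations of mean 0.3 s (clipped to 0.2–1 s),
carrier frequency drawn center-weighted 1 Hz inside the band edges, Hann
envelope, baseline amplitude 6 μV. Because ~0.3 s bursts are spectrally
broad, each band's burst stream is band-limited with that band's own
4th-order zero-phase Butterworth so that cross-band effects in the
*generator* stay controlled; residual cross-band smoothing in the
*analysis* is then set by the multitaper window alone. A log-normal
per-animal amplitude factor (σ = 0.3) multiplies all of an animal's
amplitudes on both hemispheres, emulating electrode-to-electrode
variability; it is what makes within-animal contrasts powerful and
between-animal null contrasts conservative, exactly as in real recordings.

The lesion effect multiplies burst amplitude on the lesioned hemisphere by
state and band: ×3 for low and high beta during rearing, ×3 for low beta
during stepping, ×1 elsewhere — the pattern the pipeline must recover.
While stimulation is on, lesioned gains revert to 1 (DBS suppression), and
an optional 130 Hz artifact can be injected.

Behavior is a semi-Markov chain over rearing/stepping/inactive with
gamma-distributed dwells (means: mobile 5/4/6 s; impaired 2.5/2.5/15 s,
clipped at 2 s so every bout supports at least one 2-s analysis window).
Sham animals, and lesioned animals while stimulated, use the mobile
dwells. Transitions pass through rearing between stepping and inactive
bouts, so every maximal non-rearing run carries a single generating state
and the run-level stepping rule can recover the ground truth (measured
time-weighted agreement ≥ 95%). Codes and rotation are emitted
consistently: wall codes during rears, alternating single-paw floor codes
with ~60°/s rotation during stepping, constant floor contact and ~0.5°/s
jitter during inactivity. Tracking integrates a mean-reverting speed with
state-dependent targets (0.1 / 8 / 0.5 cm/s) and a heading random walk,
reflecting at the 74 × 74 cm arena walls at 25 fps. Rotarod fall times are
Gaussian (sham 200 s, unstimulated lesioned 100 s, stimulated 190 s,
σ = 25 s) and the rod's linear speed uses an effective 3 cm rod radius.

Default cohort composition is 13 lesioned (7 DBS-ON / 6 DBS-OFF) and 12
sham animals; cylinder sessions are 120 s (stimulation from the second
minute for the ON subgroup), open-field 600 s (stimulation in the middle
4 min), rotarod 3 test rounds (stimulation in round 3).

What the generator does *not* emulate — movement artifacts, volume
conduction, electrode drift, non-stationary background, imperfect
behavioral scoring — bounds what passing tests show: they demonstrate that
the pipeline recovers effects of the modeled kind at the study's group
sizes with controlled false positives, not that it is robust to every
nuisance in real recordings.

## Numerical choices and degenerate inputs

Frequency-grid comparisons for the distance statistic require exact grid
agreement (no silent interpolation). Relative power is undefined for a
zero spectrum and raises. Rank tests refuse empty samples; Kendall refuses
constant inputs. Band filters refuse edges at or above Nyquist. Wall-code
boundary, apomorphine threshold and the speed thresholds are strict
inequalities exactly as defined, and the acceptance script recovers each by
probing the implemented classifier rather than reading a constant.

Analysis problem sizes used in the shipped tests and acceptance script —
cylinder-only cohorts, M1 channels, 20 replicates per condition — are the
package's default evaluation configuration; every knob (regions, paradigms,
durations, replicate counts) is an explicit parameter.

## Known limitations

* The printed-mode distance statistic inherits its blindness to equal-norm
  spectral differences; use the pointwise mode when that matters.
* The stepping rule evaluates cumulative rotation over whole non-rearing
  runs; very long inactive runs with slow drift could in principle
  accumulate 45° without locomotion, though the floor-alternation
  requirement makes this unlikely.
* Exact rank-sum enumeration is combinatorial and capped at pooled n = 12;
  the refined approximation above that is accurate to ~0.01 but not exact.
* Multitaper smoothing couples adjacent bands at short window lengths;
  window length is the only remedy consistent with 5 fixed tapers.
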