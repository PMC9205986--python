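# Methods

This note documents the models, numerical choices and limitations behind
`msalpha`, in the order data flow through the pipeline.

## Synthetic studies

The generator (`msalpha.synth`) emulates the statistical structure of a
retro-cue working-memory experiment: two memory items at ±5.7° horizontal
eccentricity, a central (non-spatial) selection cue at t = 0, 1000-Hz
binocular eye tracking, and posterior EEG epoched from −1000 to +2000 ms.
Cued sides are balanced exactly within each participant. Random streams are
split per participant and per trial (numpy `SeedSequence.spawn`), so any
subset of a study is reproducible in isolation.

**Timing model (the one genuinely open design choice).** Each trial draws a
latent *attentional-selection time* s from the microsaccade latency
distribution (truncated normal, mean 380 ms, sd 90 ms, support 200–600 ms).
If the trial emits an in-window gaze shift (probability
`p_shift_in_window = 0.8`), the first shift is placed at s; the alpha
modulation onset is s + `alpha_onset_lag` (50 ms) in *every* trial,
including those that emit no shift. This implements a threshold account of
the oculomotor link: selection happens at s in all trials, and the
microsaccade is a symptom that sometimes stays below motor threshold. It
also yields the defining property of the emulated study — no-microsaccade
trials carry alpha modulation statistically identical to toward trials.
Away trials (first in-window shift opposite the cue, probability
1 − `p_toward_given_shift` = 0.333) have their modulation depth scaled by
`away_modulation_scale = 0.5`.

**Gaze.** A shift is a minimum-jerk position step (10τ³ − 15τ⁴ + 6τ⁵) of
20 ms; any smooth monotone step would do for detector validation. Drift is
a Gaussian random walk (sd 0.03 %/sample); per-eye jitter is white with sd
0.1 %/sample. Note the jitter parameter is *sample-to-sample* noise at
1000 Hz, which in real trackers is far smaller than the quoted RMS
accuracy because tracker noise is temporally correlated; 0.1% puts the
velocity-threshold detector at an operating point where ~1.5–2% shifts
become detectable, consistent with a bias carried by sub-1° (< 17.5%)
shifts. Shift magnitudes are lognormal (median 5%, σ = 0.7, truncated to
1–110%); the magnitude distribution is a modeller's choice since only its
qualitative shape is constrained. A second in-window shift occurs with
probability 0.2 at 120–250 ms after the first; background shifts (Poisson,
mean 1/trial, unbiased direction) are kept outside a 150–650 ms guard band
so that the in-window toward:away ratio equals `p_toward_given_shift`
exactly — real data would have unbiased background shifts inside the window
too, slightly diluting the ratio. Blinks are Poisson (0.3/trial) NaN
stretches of 100–300 ms in both eyes. Raw traces are expressed in a hidden
per-participant affine tracker frame (≈35 raw units/degree) that the
calibration stage must recover. The vertical channel is drift only, carried
for the 2-D detector.

**EEG.** Generated directly as two pre-averaged cluster channels (contra-
and ipsilateral to the cued side), sidestepping the electrode montage and
surface Laplacian; a 61-channel forward model is out of scope, and the
analysis hooks accept multi-channel data with a user cluster map for real
recordings. Each channel is a 10-Hz sinusoid (random phase per channel) in
1/f^1 background noise (RMS 0.5 relative to alpha amplitude 1.0). After the
modulation onset, the contra amplitude ramps down linearly over 200 ms to
(1 − d) of baseline, d = `alpha_modulation_depth` = 0.3 by default. The
band-power contrast then has the closed form
L = ((1−d)² − 1)/((1−d)² + 1) × 100 in the noiseless case (d = 0.5 →
−60%), which anchors the analytic tests; broadband noise adds equally to
both channels and attenuates the measured plateau toward zero, as in real
EEG.

**Behaviour.** Reproduction error ~ Normal per true class
(toward 13.65°, none 14.0°, away 14.72°; sd 8°, participant offsets sd 2°),
reproducing the toward < away pattern; RT is class-independent
(900 ± 250 ms, participant offsets 100 ms), so any class differences in RT
are null by construction.

**What passing tests do not show.** The generator has no oculomotor
dynamics (no main sequence, no drift–tremor decomposition), no saccadic
spike artifact in the EEG, no microsaccade-evoked potentials, white rather
than correlated tracker noise, and stationary 1/f noise. Recovery results
therefore validate the *analysis code*, not the detectability of these
effects in arbitrary real recordings.

## Gaze preprocessing

Eyes are averaged samplewise; NaN in either eye propagates (a half-blink is
not silently replaced by monocular data). Maximal NaN runs are extended by
100 ms on each side; overlapping extensions merge. The extension is applied
once per trace — extension NaNs are indistinguishable from blink NaNs, so
re-application would widen runs further; the pipeline guarantees a single
application. The calibration reference takes per-position medians over the
500–1000 ms sub-window (the first 500 ms allow the saccade to the new
point) and fits the horizontal affine map by least squares of the seven raw
medians against nominal positions (centre 0%, lateral ±100%); the
"scaled by this coordinate" rule does not pin down a fit rule, and least
squares over all seven points is robust to single-position noise. The
vertical axis is fitted the same way and carried only for the 2-D detector.
Positive % is rightward. Usability requires a NaN-free closed interval
[0, 600] ms — closed boundaries are the conservative reading (more trials
flagged unusable).

## Microsaccade detection

Velocity is |first difference| per ms; smoothing uses a 7-ms Gaussian
kernel with sd = window/5 (the conventional Gaussian-weighted moving
average), truncated to the window and renormalized at trace edges; NaN
anywhere under the kernel support yields NaN velocity. The trial threshold
is 3× the median of all finite *smoothed* velocity samples of the epoch
(maximal data, stationary under the null of no shifts; using the smoothed
trace for both threshold and crossing keeps the two comparable). Onsets are
first samples of supra-threshold runs; NaN terminates a run. The 100-ms
refractory period is enforced between *retained* onsets, and crossings
falling inside it do not restart it. Magnitude is the mean position in the
closed [onset+50, onset+100] ms window minus the closed [onset−50, onset]
window, finite samples only; onsets whose windows leave the epoch are
skipped (counted in diagnostics). Events below 1% magnitude are discarded;
an optional classifier flag additionally dismisses whole trials containing
sub-floor shifts, for the stricter reading in which such trials are
excluded from classification altogether. Trial class is the direction of
the first event in the closed 200–600 ms window ("none" if empty;
"unusable" overrides). An extended-window mode requires no-microsaccade
trials to be shift-free over the whole 0–600 ms.

Rate timecourses use a centred 50-ms window advanced in 1-ms steps,
rate = count/(n_trials × 0.05 s). The time × magnitude map uses overlapping
5%-wide magnitude bins with left edges 1–110% in 1% steps; bin b covers
|magnitude| ∈ [b, b+5) (half-open, fixed here since the binning convention
is not otherwise determined). The early/late split takes each participant's
median first-toward-shift latency; ties at the median alternate sides to
balance counts. The alternative binocular detector uses the 5-point
derivative, an elliptic threshold at λ = 6 median-based velocity SDs per
axis, 6-ms minimum duration and ≥1 sample of binocular overlap (all
configurable), then maps events through the same magnitude windows, floor
and refractory bookkeeping so both detectors emit comparable events.

## Lateralization

Spectral power: Hanning-tapered 300-ms windows advanced in 50-ms steps
(1-ms steps in latency mode), zero-padded to 1 s so the 1–50 Hz axis lands
on integer-Hz DFT bins. Windows extending past the epoch are dropped, not
padded. Power is not normalized by taper energy — the contrast is
scale-invariant, so the factor cancels. The condition contrast averages
power across trials *before* forming ((contra−ipsi)/(contra+ipsi))×100
(contrast of averages; the average of per-trial contrasts is available via
`average="contrast"` — per-trial spectra are noisier and the per-trial
contrast is biased toward zero at low SNR, so the contrast-of-averages is
the default). Zero-denominator cells are NaN. The alpha timecourse is the
unweighted mean over the 8, 9, 10, 11, 12 Hz rows.

## Statistics

Cluster tests: mass-univariate one-sample t per point (paired contrasts
enter as differences), cluster-forming threshold at two-sided α = 0.05,
clusters of adjacent same-signed supra-threshold points (1-D runs;
4-neighbour adjacency on 2-D grids, no diagonals), cluster mass = sum of t.
The null distribution collects the largest |mass| per participant-level
sign flip; observed clusters are compared by absolute mass, making the test
two-sided to match the two-sided forming threshold. When 2^n does not
exceed the requested permutation count, all 2^n assignments are enumerated
(flagged in the result) and the plain proportion over the exhaustive set is
the p-value; otherwise p = (b+1)/(B+1), which can never be zero (the plain
proportion is available via `p_convention`). Degenerate zero-variance
points get t = ±∞ (sign of the mean) so constructed constant effects still
form clusters.

Half-peak latency: the peak is the extremum of the grand-average timecourse
in the search window (0–1000 ms by default — wide enough to contain the
modulations the generator programs; configurable), `peak_sign=-1` selects
the most negative value as appropriate for contralateral attenuation, and
the first crossing of half that value is linearly interpolated between
1-ms samples for sub-sample stability. The latency permutation test swaps
early/late labels within a random subset of participants, recomputes the
grand-average latency difference, and reports the one-sided
p = (b+1)/(B+1) for differences at least as large as observed (one-sided is
the literal reading of "larger than the observed difference"; a two-sided
tail is exposed). Half-peaks are recomputed on permuted *grand averages*,
not per-participant latencies. Permutations with an undefined half-peak are
excluded; if they exceed 5% of the total the test aborts with a diagnostic.

Behaviour: RTs > 3000 ms are removed first, then per-participant trials
beyond mean ± 2.5 SD of the surviving RTs (strict inequalities; zero SD
removes nothing). The steps are deliberately ordered — the hard cut-off
removes gross outliers before they can inflate the SD. Re-running the
procedure is a no-op only when the second step found nothing to trim; the
SD recomputed on a trimmed sample can otherwise exclude further trials, so
the pipeline applies the procedure exactly once. Class comparisons
aggregate to participant × class means, then a one-way repeated-measures
ANOVA (partial η², via pingouin) with Bonferroni-corrected two-sided paired
t-tests and paired Cohen's d (mean difference / SD of differences).

## Pipeline and problem sizes

`run_study_analysis` never reads generator ground truth; recovery checks
live in the tests. Cluster and latency tests default to 2000 permutations
in the pipeline API (10,000 in the underlying stats functions, the
convention for published inference); the test suite and examples use
100–2000 and studies of 2–10 participants × 8–200 trials, sizes at which
every stage's statistical behaviour is already measurable. Reports carry a
config hash, seeds, permutation counts and the package version, and are
deterministic given the study seed and `stats_seed`.

## Known limitations

Only horizontal direction is attention-labelled (vertical exists solely for
the 2-D detector). Real-montage topographies, surface Laplacian, ICA
cleaning and acquisition-file ingestion beyond the documented CSV/ASC
readers are out of scope. The cluster test assumes exchangeability across
participants under the null; the latency test additionally assumes the
half-peak is well-defined for (nearly) all permuted grand averages, which
fails at very low SNR — the abort diagnostic exists for exactly that case.
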