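# Methods

`voicescreen` implements a voice-based screening pipeline for cognitive
functional decline in older adults: acoustic features are extracted from
spontaneous-speech recordings, collapsed into one vector per participant,
compared across MMSE-defined groups, and fed to a nested-cross-validation
ensemble classifier with Shapley-driven feature elimination.  This note
documents the model choices, the tunable parameters, what the synthetic
data does and does not emulate, and the numerical conventions.

## Cohort model

Participants are grouped by Mini-Mental Status Examination score:
group 1 (healthy, MMSE ≥ 27), group 2 (mild impairment, 20–26), group 3
(moderate-to-severe impairment, 11–19).  Scores of 10 or below fall
outside all three bands; such rows are flagged and excluded.  Each
participant contributes four recordings (three 2-minute personal stories
and one picture description) as 16 kHz mono WAV.

## Preprocessing and segmentation

Recordings are averaged to mono and resampled to 16 kHz with a polyphase
filter on read.  Preprocessing imposes positive speech polarity — the
waveform is negated when the skewness of the full recording is negative
(a simple, deterministic proxy; glottal-flow asymmetry makes
positive-polarity speech positively skewed) — and z-scores the whole
recording (not per segment).  The transform is affine per recording, so
all relative timing is preserved and the operation is idempotent.

Feature extraction runs three times, on consecutive non-overlapping
segments of 5, 10 and 15 seconds.  Trailing remainders shorter than the
segment length are discarded (padding would dilute rate and percentage
features with silence); recordings shorter than one segment are skipped
with a logged warning.

## The 23 per-segment features

*Voice periodicity (F1–F10).*  Frames of 40 ms with a 10 ms hop are
classified voiced/unvoiced by the peak of the normalized autocorrelation
over candidate periods between a 70 Hz pitch floor and a 500 Hz ceiling,
against a threshold of 0.45.  The fundamental is read off the first
autocorrelation peak within 3% of the maximum (this guards against
octave-down errors, where the peak at twice the true period equals the
peak at the period) and refined by parabolic interpolation, giving
sub-0.1 Hz resolution at 150 Hz.  F1 is the unvoiced percentage of
frames; F2–F5 and F6–F9 are mean/median/15th/85th percentiles of
voiced-run and unvoiced-run durations.  Glottal pulses are placed once
per period at the waveform's absolute peak inside voiced runs; F10 is the
percentage of inter-pulse intervals longer than 1.25/70 s ≈ 17.86 ms — a
count ratio over intervals, not a duration ratio.

*Shimmer (F11).*  Local shimmer in percent: mean absolute difference of
consecutive within-run pulse amplitudes over the mean amplitude.  Pulse
pairs spanning a voice break are excluded.  The percent-local variant is
used (not dB): typical spontaneous-speech values near 5 match this scale.
Fewer than 3 pulses yield a missing value.

*Syllabic and pause features (F12–F18).*  Syllable nuclei are intensity
peaks (40 ms/10 ms RMS contour in dB) that are above a silence threshold
of −25 dB relative to the segment maximum, have at least 2 dB prominence
over the neighboring dip, and fall on voiced frames — the standard
nuclei-based speech-rate parameters.  Pauses are low-intensity runs
longer than 250 ms.  A segment with no voiced frames and an envelope
dynamic range under 10 dB is treated as one segment-long pause (a purely
relative threshold cannot flag all-silence segments).  F12 = nuclei per
second of segment; F13 = 100 × non-pause time / segment time (the
operative reading of "phonation percentage"); F14 = nuclei per second of
phonation time; F15 = mean inter-nucleus gap exceeding 250 ms; F16 = mean
duration of the intensity hump around each nucleus bounded by the
neighboring valleys (no standard formula exists; this is the natural
envelope-based definition); F17/F18 = pause count and mean duration.

*Spectral features (F19–F23).*  F19/F20 are mean/SD of the pitch track
over voiced frames.  F21 is the SD of the third-formant track obtained by
linear prediction at 10 kHz (pre-emphasis 0.97, 25 ms Hamming frames,
order 12, roots filtered to bandwidth < 400 Hz, third ascending
frequency).  F22 is a speech temporal-regularity index: the maximum of
the normalized autocorrelation of the 50 Hz intensity envelope over lags
0.1–1 s, scaled by a fixed constant of 2000 to a convenient range.  Only
the ordering of F22 (periodic > irregular envelopes) is contractual;
absolute comparability with other implementations of a "temporal
structure" index is not claimed.  F23 is the magnitude-weighted spectral
centroid pooled over frames.

Features undefined on a segment (pitch statistics of silence, shimmer
with too few pulses, F15 with no long gaps) are missing (NaN), excluded
from within-recording averaging rather than zero-filled.

## Aggregation to the participant vector

Per-segment values are pooled per recording by the mean over that
recording's segments (pooling within recordings keeps the "four
recordings collapsed by location/dispersion" structure literal).  The
four recording values per (feature, length) are then collapsed to a
location and a dispersion statistic: mean/SD when an Anderson–Darling
normality test at α = 0.05 on the pooled cohort recording values does not
reject, median/IQR otherwise (type-7 linear-interpolation quantiles).
The decision is made per (feature, length) over the cohort and applied
uniformly; inside cross-validation it is recomputed on the outer-training
participants only and frozen into the fold's model, so held-out
participants never influence it.  Fewer than 8 values or a degenerate
constant sample default to median/IQR.  Fewer than 2 non-missing
recordings leave both entries missing (the row is retained).  The result
is 23 features × 3 segment lengths × 2 statistics = 138 named entries
`F{code}_L{5|10|15}_{loc|disp}`.

## Group statistics

Demographics: one-way ANOVA for age, Kruskal–Wallis for years of
education and MMSE (ordinal), Pearson chi-squared for gender.

Acoustic features are compared with a fixed-effects gamma GLM with log
link (features are positive and right-skewed; group effects act
multiplicatively on the mean).  No random effect is fitted: after
aggregation each participant is one row, so no grouping structure
remains; language can enter as a fixed covariate.  Features that can be
zero (e.g. a voice-break percentage of 0) are shifted by half the
smallest positive observed value.  The omnibus test of the group factor
is the analysis-of-deviance F-test — deviance difference divided by
(2 × Pearson dispersion), referred to F(2, n−3).  A 3000-replicate null
simulation at n = 30/group put its size at 0.050 versus 0.054 for the
chi-squared likelihood-ratio variant, which is why the F-form is used.
Pairwise contrasts (1v2, 1v3, 2v3) are Wald tests, Bonferroni-adjusted
(×3), reported only when the omnibus test is significant.

## Classification harness

Three families: linear-kernel SVM at default parameters, logistic
regression at defaults, and gradient-boosted decision trees (LightGBM)
with four tuned hyperparameters.  The tree parameters keep their
conventional boosting names and map onto LightGBM as: tree depth →
`max_depth` (integer 4–10), L2 leaf regularization → `reg_lambda`
(log-uniform on [1, 10]), bagging temperature t → row subsampling
1 − t/2 with per-iteration bagging (t uniform on [0, 1]), random
strength r → per-tree feature subsampling 1/(1 + 0.05 r) (r uniform on
[0, 10]).  Tuning is a seeded randomized search (30 draws by default)
scored by inner-CV accuracy; the linear families return their defaults
unchanged.  Features are standardized inside each fold's pipeline
(median imputation, then z-scoring, both fit on training data only).

The protocol is stratified nested 10-fold cross-validation.  Within each
outer-training split, an inner stratified 10-fold loop drives recursive
feature elimination: starting from all 138 features, each iteration
records the inner-CV mean accuracy of the current set, computes
per-feature importance as the mean |Shapley value| of the margin from a
fit on the full outer-train, and removes the two least important
features, down to six; the subset with the best accuracy wins (earliest
iteration, i.e. the larger set, on ties; importance ties drop the
lexicographically later name first).  Hyperparameters are then tuned on
the selected subset, and the fold model is fitted on the outer-train.
Validation accuracy is the inner-CV mean of the final configuration;
test accuracy is the fold model's accuracy on its held-out outer fold.
The ten fold models — each with its own feature subset, parameters and
frozen aggregation decisions — form the ensemble, combined by an
unweighted mean of member class probabilities (soft voting).

Shapley values use the exact closed form for linear margins
(w_j (x_j − E[x_j]) per output) and the booster's path-dependent TreeSHAP
for the tree family; an independent permutation-sampling estimator (whose
per-permutation contributions telescope exactly, making it additive by
construction) cross-checks both in the tests.  The SVM obtains
probabilities from a sigmoid calibrator fitted on 5-fold cross-validated
decision scores; class decisions remain the SVM's own.  The global
feature ranking sums the ten per-fold mean-|Shapley| vectors (features a
fold eliminated score zero there), descending, ties broken by name.
Families are compared by a Kruskal–Wallis test over per-fold validation
accuracies with rank-sum follow-ups, Bonferroni-adjusted.

Evaluation pools the per-fold predictions on the held-out folds:
accuracy, confusion matrix, one-vs-rest ROC curves with micro- and
macro-averaged AUC.  The "test" accuracy reported per family is the mean
(SD) over outer folds; the confusion matrix and pooled accuracy are
consistent by construction (trace/total).

## Synthetic data

The generator serves two purposes and deliberately no more.

*Waveforms* (`gen_voice_signal`): voiced stretches carry the first five
harmonics of a fundamental with 1/k amplitude rolloff — realistic,
formant-free periodicity detectable by autocorrelation — with strictly
alternating per-period amplitude factors (1+ε), (1−ε), so the injected
local shimmer has the closed form 200ε percent.  Raised-cosine syllable
bursts (200 ms wide, floor 0.12) shape the intensity envelope; pauses
carry only a noise floor at −35 dB relative to the voiced RMS
(unambiguous for both voicing and intensity-based pause detection);
remaining unvoiced gaps carry noise 15 dB below speech level by default,
like breathy/fricative material — above the pause threshold but
aperiodic.  The ground truth records every schedule exactly.  What is
*not* emulated: formants and vowel quality, language-specific prosody,
channel/microphone effects, jitter, overlapping speakers.  Passing the
extractor oracles therefore shows correctness of the signal-processing
definitions, not robustness to real conversational audio.

*Cohort tables* (`gen_cohort`): 138 feature columns drawn independently
from gamma distributions (so the gamma-regression stage is correctly
specified), with baselines taken from plausible healthy-speaker values
and multiplicative per-group location shifts on a chosen feature set.
The default effect template follows the directions observed with
declining MMSE — mean unvoiced-segment duration scaling 0.5 → 0.6 →
0.71 s from group 1 to group 3, with matching shifts on unvoiced
percentage, voice breaks, syllable duration and pause count.  Columns
are independent; real acoustic features are strongly correlated, so
synthetic classification accuracies are not predictions of real-cohort
performance.  A `STRONG_EFFECTS` preset (shifts ×2/×4, dispersion 0.15)
defines the strongly separated cohort used in separability and
feature-recovery experiments.

Four-recording audio cohorts (`gen_participant_audio`) lengthen unvoiced
gaps and pause probability with the group index, so the full
audio-to-classification chain has a real signal to find.

## Problem sizes and determinism

The analysis scripts and the acceptance script use synthetic recordings
of 30–45 s (not the study's 2 minutes) and cohorts of 60–133
participants; these sizes give every stage stable statistics while
keeping a full run in minutes on one CPU.  The null-calibration and
coverage simulations use 1000 and 200 replicates.  All randomness derives
from explicit integer seeds; a fixed configuration reproduces every
numeric output exactly (LightGBM runs in deterministic single-thread
mode).

## Known limitations

- The voicing/pitch front end is a plain autocorrelation method without
  octave-cost dynamic programming; creaky or diplophonic voice would
  degrade the pulse track and hence shimmer and voice breaks.
- The F22 regularity index is scale-fixed but implementation-specific;
  only orderings are meaningful.
- Table-style group summaries report mean (SD) of the (possibly offset)
  feature on its natural scale, not back-transformed GLM means.
- The per-fold Anderson–Darling refit applies only when recording-level
  values are supplied; cohorts generated directly at participant level
  skip that stage by construction.
- With an odd starting feature count, elimination by two stops at seven
  features, not six.
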