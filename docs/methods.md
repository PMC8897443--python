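# Methods

`fearcortex` re-implements, as a tested library, the analysis chain of a
longitudinal two-photon imaging study of differential auditory fear
conditioning (DFC): behavioral freezing scored from a motion index, learning
specificity, single-neuron and population discriminability of the
conditioned tones with permutation and bootstrap inference, tuning-change
metrics on neurons tracked across days, and a rate-based
thalamus–cortex–amygdala circuit model that ties neuronal discriminability
to behavioral specificity. Everything runs on a synthetic cohort generator
that programs the ground truth the analyses are supposed to recover.

## Behavioral scoring

The motion index is the mean grayscale difference between consecutive video
frames (`motion_index`). A mouse is "freezing" in a frame when the motion
index is strictly below the session's 12.5th percentile
(`freezing_threshold`); ties count as movement so a constant trace scores
0% freezing. Percentiles use linear interpolation between order statistics
(numpy's default); the convention is fixed and documented because different
software disagrees in the far tails of small samples.

Learning specificity is

    LS = mean_i fr_CS+(i) − mean_i fr_CS−(i)

over the per-trial freezing fractions of the retrieval sessions, reported
as a percentage where convenient. LS is antisymmetric under label exchange
and bounded in [−1, 1]. Extended tone presentations (60–120 s) can be split
into four equal sub-trials before scoring (`split_long_trials`).

Learner classification runs, per mouse, a two-way ANOVA on freezing scores
with factors stimulus (CS+/CS−) and period (stimulus vs pre-stimulus
baseline); baseline trials are split evenly between the two stimulus levels
to keep the design crossed. A mouse is a learner when the period main
effect or the interaction is significant at p < 0.05. The ANOVA itself is
delegated to statsmodels; the decision rule is the contract.

A known property of the percentile threshold: it separates freezing from
movement only while freezing occupies less of the session than the
percentile level (12.5%). Retrieval sessions here (eight 30-s stimuli in a
~18-min session) satisfy this; a mouse freezing through most of a session
would be under-scored. The synthetic motion generator emulates this regime:
moving samples are Gaussian around a high level with a hard lower floor
(a camera noise floor), freezing samples sit far below the floor, so the
session percentile lands on the floor and scoring recovers the programmed
freezing fraction to within ±5 percentage points at 30-s windows.

## Single-neuron statistics

Fluorescence is converted to ΔF/F_std per presentation: baseline mean and
SD over the 1 s before tone onset, z-scored frames thereafter; the trial
response is the mean ΔF/F_std over the 2 s after onset. Presentations with
zero baseline SD raise a degenerate flag rather than produce infinities.

A neuron is sound-responsive when any frequency's trial responses differ
from zero (one-sample t-tests, Holm–Bonferroni corrected across
frequencies, α = 0.05). The frequency response function (FRF) is the mean
response per frequency; the best frequency (BF) is its argmax with ties
broken toward the lowest frequency (a measure-zero event on real data,
fixed for determinism). Sparseness is

    a = (Σ r_i / N)² / (Σ r_i² / N),   S = (1 − a) / (1 − 1/N),

0 for a flat positive FRF and 1 for a one-hot FRF. Negative mean responses
are kept (no rectification), so S > 1 is possible and simply reported; an
all-zero FRF returns a missing value.

Discriminability of the conditioned tones (CS+ = 15 kHz, CS− = 11.4 kHz,
0.40 octaves apart) is

    Z_diff = |mean(r_CS+) − mean(r_CS−)| / sqrt(sd(r_CS+)·sd(r_CS−))

with sample SDs (ddof = 1, the small-sample convention). Significance: the
pooled 2N trials are relabelled into two groups of N 250 times; the
observed score is significant when strictly above the null's 95th
percentile. Pooling is unpaired because the stimulus repeats are unpaired.
The relabelling null makes the test exact under exchangeability; its
empirical false-positive rate on silent synthetic neurons is ~5%.

When the CS frequencies themselves were not presented, responses are
linearly interpolated on the log2-frequency axis (stimuli are log-spaced
and all tuning distances are reported in octaves). FRF normalization for
tuning-change analyses divides by the FRF maximum; the definition is
isolated in `normalize_frf` so it can be swapped. Percent change,
100·(post − pre)/|pre| on normalized FRFs, is a relative measure (swapping
pre and post does not merely flip its sign); near-zero pre entries return
missing values. BF-distribution matching across groups uses equal-count
resampling with replacement within 12 log-spaced BF bins; empty bins are
skipped with a warning.

## Population decoding

Single-trial population vectors are classified CS+ vs CS− by a linear-kernel
SVM under stratified 10-fold cross-validation, fold accuracies averaged.
Features are standardized inside each training fold only (no leakage); the
regularization constant is the library default C = 1 and is recorded in the
function signature. Because mice contribute different neuron counts,
per-mouse metrics resample each population with replacement down to the
cohort's minimum neuron count (100 resamples by default) and average.

Drift is quantified two ways: (1) a decoder fitted on one session's tracked
neurons is frozen and scored on the same neurons' trials in a later session;
the transfer deficit (train minus test accuracy) grows with drift; (2) the
Pearson correlation of per-neuron Z_diff between session pairs declines
with session gap.

## Bootstrap inference

Correlation confidence intervals resample the (x, y) pairs jointly 1000
times and take the 2.5th/97.5th percentiles of the bootstrap correlation
distribution. The correlation recomputed inside the bootstrap is Spearman
by default — consistent with the rank-correlation point estimate — with a
Pearson mode available, since mixing a Pearson bootstrap under a Spearman
point estimate is a defensible but inconsistent alternative; the choice is
isolated behind a flag. Two correlations are compared by differencing their
bootstrap distributions, paired over replicates (same resample indices)
when both are computed on the same mice; two-sided
p = 2·min(P(Δ≤0), P(Δ≥0)). Degenerate resamples (constant x or y) are
dropped.

## Synthetic cohort generator

The generator's defaults are the study conditions: 14 conditioned and 9
pseudo-conditioned mice, 60–120 neurons per mouse, 12 log-spaced
frequencies in 5–32 kHz including the exact CS tones, 25 repeats per
frequency, 8 imaging sessions of which the first 4 are pre-DFC, and one
retrieval session after each post-DFC imaging session.

Each neuron carries a Gaussian tuning curve in log2 frequency (widths
uniform in 0.25–1.5 octaves, amplitudes uniform in 1–3 ΔF/F_std units);
trial responses add independent Gaussian noise with SD 1 in the same units,
matching the scale of baseline-z-scored responses. Across sessions the BF
performs a Gaussian random walk (SD `drift_rate` = 0.1 octaves/session) and
the log-gain a slower one — an agnostic drift model chosen to support
session-gap analyses without committing to a mechanism.

A per-mouse discriminability gradient g ∈ [0, 1] (spanning 0…1 across the
conditioned group) programs the CS+/CS− separation: a fraction 0.6·g of
neurons is narrowly tuned (0.25 octaves) exactly at one of the CS tones.
Ground-truth LS for conditioned mice is a saturating (logistic-shaped)
function of the *programmed* expected population separation —
`ls_max·tanh(ls_slope·sep(g))` with ls_max = 0.65, ls_slope = 1.3 — plus
Gaussian noise (SD 0.05); using the programmed rather than the realized
separation makes the gradient→LS link exactly monotone at zero noise.
Pseudo-conditioned mice draw LS from noise around zero. These constants
were chosen once so that the conditioned group spans roughly −10% to +60%
LS with a group SD near 20% and the pseudo group an SD near 3% — the regime
of the real behavioral data — and are not tuned thereafter.

What the generator does not emulate: calcium-indicator dynamics (analyses
start from scalar evoked responses), correlated trial-to-trial noise across
neurons, conditioning-induced tuning plasticity (sessions differ only by
drift), non-stationary freezing across retrieval sessions, and realistic
video. Passing tests therefore validate the statistical machinery and its
calibration, not claims about biological effect sizes.

Motion traces are two-state: within each scheduled window a contiguous
freezing bout occupies the requested fraction of frames. ROI scenes place
non-overlapping disk ROIs uniformly (minimum separation 14 px in a 512 px
field), move them by a known affine transform plus centroid jitter, and
provide exact landmark pairs.

## Cell tracking

Sessions are registered to the first session by a least-squares affine
transform (6 dof — translation, rotation, scale, shear cover field-of-view
realignment) fitted on landmark pairs; at least 3 non-collinear landmarks
are required. Each new ROI is matched to the nearest catalogued centroid.
Review flags: `duplicate` (shared target), `low_overlap` (mask overlap
< 80% of the smaller mask, computed as |A∩B|/min(|A|,|B|) on transformed
pixel masks), `far_centroid` (distance > mean + 2 SD of matched distances).
Far-flagged ROIs and duplicate losers join the catalogue as new cells.
Catalogued ROIs mutually overlapping by more than 50% (configurable) are
excluded as ambiguous identities. Flags are emitted for external review;
no automatic adjudication replaces visual inspection.

## Circuit model

Ten frequency channels on a ring (channel 1 neighbors channel 10) drive a
thalamic population through a Gaussian kernel T^MGB with σ = 0.8 channels.
The cortical population reads the thalamic activity through a broader
Gaussian kernel with a subtractive broad inhibitory term I = 0.9 and gain
1/1.8, rectified at zero:

    T_ij = gain · [exp(−d(i,j)² / (2σ²)) − I]₊ ,  d = ring distance.

The squared-σ (conventional Gaussian) form is the default for two reasons:
(1) it makes the inhibition-normalized cortical kernel at σ_ctx = 3 match
the uninhibited thalamic kernel at σ_mgb = 0.8 (both fall to ≈0.46 at one
channel), so "narrow cortex" genuinely mirrors thalamic tuning; (2) it lets
broad cortical tuning (σ_ctx = 10) reach the CS− channel three steps from
the CS+ channel — the overlap that produces generalization. With σ entering
the exponent unsquared neither holds (the cortical kernel collapses to its
diagonal at σ = 3 and never reaches the CS− channel at σ = 10); that
variant is kept behind `exponent="linear"` for sensitivity checks.

One forward pass resolves the thalamo-cortical loop feedforward-then-
feedback: x0 = T^MGB s, x^ctx = T^ctx x0, x^MGB = x0 + x^ctx (channel-wise,
i.e. tonotopically organized feedback; a `feedback="summed"` variant
broadcasts the total cortical activity to every thalamic channel). An
optional silencing flag zeroes the cortical activity and its feedback.

A single amygdala (BLA) unit reads y = w^MGB·x^MGB + w^ctx·x^ctx. During
conditioning the CS+ channel (3) is paired with a shock for 10 steps and
both weight vectors follow a Delta rule, Δw_i = α·x_i·e with α = 0.1,
clipped to [0, 1] from an initial 0.1. Freezing to a tone is y normalized
by its value with all weights at 1 under the same readout condition;
model LS = freezing(CS+) − freezing(CS−) with CS− on channel 6. After
conditioning, σ_ctx performs a 10,000-step bounded random walk (uniform
±0.25 steps, clipped to [4, 20]); conditioning itself runs at the unclipped
initial σ (3 or 10), and drift involves no plasticity since no shock
occurs. Channel indices are 1-based in configuration and reporting,
0-based internally.

Manipulations: `reduced_inhibition` halves I to 0.45 during conditioning
only (readout and normalizer keep I = 0.9 — applying the reduction at
readout while normalizing with the intact kernel yields freezing above 1,
which the model forbids); `ac_off_conditioning` silences cortex during
learning only; `ac_off_recall` silences it during every freezing readout,
numerator and normalizer alike.

Model behavior, as measured by the test suite and the acceptance script:
narrow cortical tuning yields higher LS than broad deterministically
(0.59 vs 0.41); silencing cortex during conditioning lowers LS (0.57);
drift decorrelates initial tuning width from LS (|r| ≈ 0.92 at
conditioning, ≈ 0.2 after drift). Two behaviors are known limitations of
the difference-form LS under this parameterization: at narrow tuning,
halving inhibition *raises* LS (0.62) because disinhibition amplifies the
CS+-centred cortical activity more than it broadens it (the expected drop
does appear at broad tuning: 0.21 vs 0.41), and silencing cortex at recall
shifts LS by about +0.06 rather than leaving it untouched, because the
cortical term contributes to numerator and normalizer asymmetrically.
Both are reported honestly by the corresponding acceptance tests.

## Problem sizes and numerical choices

Simulation-based checks use deliberately modest sizes chosen once:
calibration of the permutation null uses 2000 synthetic neurons at 25
repeats; parameter-recovery checks use 20 cohort seeds of 14 conditioned
mice with default neuron counts, Z_diff averaged over the 4 pre-DFC
sessions and decoding averaged over 2 of them with 6 neuron-resamples;
drift checks use 20 seeds per drift rate at 50 neurons. Random number use
is everywhere funnelled through `numpy.random.Generator` objects seeded
explicitly; identical configurations are bit-reproducible.
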