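# Methods

This note documents the models, procedures and numerical conventions behind
`seqsleep`, and what the synthetic-data generator does and does not emulate.

## Scientific setting

The package analyses how learning a fixed temporal sequence of images
reorganises stimulus-evoked EEG, and how sleep physiology relates to that
reorganisation. Three measurements are central:

1. **Successor decoding.** A multiclass classifier trained on category-evoked
   EEG patterns from a *pre-learning* session is applied to a held-out
   category's trials in a *post-learning* session. Predictions are scored not
   against the category shown, but against the category of the image's
   neighbour in the learned sequence (offset +1 = successor, −1 =
   predecessor, ±2 = second neighbours). Above-chance successor accuracy
   means that viewing an image evokes category information about the image
   that followed it during learning.
2. **Representational shift.** Time-resolved representational similarity
   matrices (RSMs) of the EEG are compared against model RSMs built from
   per-layer feature vectors of a visual hierarchy (ranks 1–7, shallow to
   deep), using the features of each image's *successor*. The per-layer
   change in EEG–successor similarity from pre to post, correlated with layer
   rank (Spearman, winsorised to ±0.99, Fisher z), gives one "shift" scalar
   per participant: positive when learning-related change concentrates in
   deep, abstract layers.
3. **SO–spindle coupling.** Slow oscillations (SOs) and sleep spindles are
   detected in a post-learning nap; spindles whose envelope maximum falls
   inside an SO are "coupled", and the SO phases at those maxima are
   summarised by pairwise phase consistency (PPC). Cohort analyses correlate
   PPC and slow-wave-sleep proportion with decoding strength and shift.

## Synthetic data generator

All tests run against `seqsleep.synthdata`, which embeds known ground truth.

**Sequence design.** 50 images, five categories (letter strings, scenes,
objects, faces, body parts; two subcategories each), organised into 10
subsequences of five images. Each subsequence holds the four primary
categories in one of two fixed orders (letter–scene–object–face or
object–scene–letter–face), with one body-part image inserted at a seeded
random slot to obscure the regularity. Neighbour lookup is body-transparent
by default (the successor of an object image is the next face image even if
a body part intervenes); a literal mode steps through the sequence as
presented. Sequences do not wrap; boundary trials have no neighbour and are
excluded from decoding.

**Layer features.** Per-layer feature vectors are isotropic Gaussian noise
plus category (and weaker subcategory) centroids scaled by a per-layer depth
profile; centroids are norm-fixed so that a monotone profile yields
within-minus-between category correlation gaps that rise monotonically with
layer rank, the hallmark of trained visual hierarchies. Default: 7 layers,
50 dimensions, profile `linspace(0.25, 1.5, 7)`. The layers of a real
network are mutually correlated far beyond the shared category partition
modelled here; cross-layer feature correlations are *not* emulated.

**Wake sessions.** Epochs are generated at the post-preprocessing stage:
clean, 250 Hz, −0.5 to 1.5 s around onset, 58 channels, 4 trials per image
by default (40 per category — desk scale; a full session would have ~12).
Each trial is the current image's channel pattern under a sustained
stimulus envelope (cosine ramps, plateau over the 1 s presentation), plus
independent Gaussian sensor noise (default s.d. 2.0 against pattern s.d.
1.0, i.e. single-trial SNR 0.5 — deliberately low, as in real evoked data).
Channel patterns are layer features projected through a per-participant
random mixing matrix, fixed across sessions so patterns generalise across
pre/post as cross-session decoding requires; the current-image pattern
weights shallow layers more strongly, matching the perceptual character of
the task. In post-learning sessions with `successor_amp > 0`, the
*successor* image's pattern is added under a Gaussian envelope (default
centre 0.5 s, s.d. 0.15 s — the latency is a design choice, not an
empirical fact; nothing in the analyses assumes it). Pre-learning sessions
with a non-zero leak are rejected, making the leak-free null explicit. What
the generator does **not** model: filtering artefacts, ocular components,
channel covariance of real EEG, 1/f temporal structure in wake noise, or
item-level (within-category) successor structure beyond what the features
imply. Passing tests therefore show pipeline correctness under known
structure, not robustness to real-EEG nuisance.

**Sleep records.** Single channel ("Cz"), 100 Hz, 1/f-amplitude background
noise, nap-like hypnogram (brief W and N1, then alternating N2/SWS blocks of
seeded-random length, REM tail). SOs are single 0.9–1.6 s sine cycles
starting at a positive-to-negative zero crossing; spindles are 13.5 Hz
bursts of 0.6–1.2 s under a sine (sqrt-Hann) taper — chosen so the envelope
maximum is unique (coupling phases need a well-defined centre) and the
annotated onset coincides with actual oscillatory energy; a Hann taper's
first ~100 ms is essentially silent, which would make annotated onsets
unrecoverable in principle. Coupled spindles are placed so the envelope
maximum falls at an SO phase drawn from von Mises(mu, kappa); within one SO
cycle of length T (up-state peak at 3T/4) the instantaneous phase covers the
full circle, so every phase is reachable. Event rates are per NREM minute;
demanding more coupled spindles than SOs, or more events than the record can
hold without overlap, raises an error rather than silently degrading truth.

## Preprocessing

Fixed order: 200 ms centred moving-mean smoothing (edge windows shrink to
the available samples — no padding is invented), baseline correction against
the [−0.2, 0) s pre-stimulus mean, z-scoring of every (channel, time) cell
across trials (sample s.d., n−1; zero-variance cells are set to 0 with a
warning), then sliding-window averaging: 20 ms windows in 12 ms steps
(5 and 3 samples at 250 Hz; non-integral sample counts are rejected with
instructions to pass counts explicitly). Indexing is 0-based, half-open;
window timestamps are centres. Only baseline correction is idempotent, and
the tests assert exactly that.

## Decoding

Multiclass LDA with analytic (Ledoit–Wolf) shrinkage of the pooled
covariance (`scikit-learn`, lsqr solver) — shrinkage keeps 58-channel
covariances invertible at desk-scale trial counts. Labels are encoded in a
fixed canonical category order (letter, scene, object, face, body), so
argmax ties resolve to the lowest index and the whole path is deterministic.
For each held-out category the classifier is trained per training window on
the other four categories' pre-session trials and applied to every test
window (temporal generalization). A prediction is a hit iff it equals the
neighbour category at the requested offset. Hits are averaged across trials
within each image (one image = one sequence position), then across images.
Chance is 25% (four trained classes). Under the leak-free null the grand
mean converges to 25% because each participant draws independent feature
geometry, making the four candidate classes exchangeable in expectation —
individual participants can sit well off 25% through category-similarity
bias, which is why the null is a cohort property, not a per-participant one.

## RSA

EEG RSMs: trial-averaged per-image channel patterns per window (correct,
non-target trials only, after z-scoring), pairwise Spearman with average
ranks. Model RSMs: Spearman between layer feature vectors of either the
current image or its successor. Because successor and current model RSMs
are collinear, the current-image structure is regressed out of the EEG
pair-values (OLS with intercept on the strict upper triangle, canonical
i<j ordering) before correlating residuals with the successor model —
residuals are exactly uncorrelated with each regressor by construction.
Residualisation defaults to the same layer's current RSM; regressing all
seven jointly is available (`residualize_mode="all-layers"`) since either
reading of "the current matrices" is defensible. Only images remembered in
both memory tests (successor pair reported adjacently in both reports)
enter; participants with fewer than three such images are excluded. Every
Fisher-transformed correlation in the module winsorises rho to ±0.99 first.

A caveat the sign-recovery tests exposed: because all layer models share the
category partition, a successor leak mixed *broadly* across layers
correlates with deep-layer models through shared category content even when
weighted toward shallow layers. The shallow/deep cohort conditions therefore
use geometrically concentrated layer weightings (`geomspace(0.05, 2.0, 7)`
and its reverse); with those, deep weighting yields a positive group shift
and shallow weighting a negative one.

## Sleep event detection

Zero-phase Butterworth filters (SOS, forward–backward; order 3 for
0.3–1.25 Hz, order 4 for 12–16 Hz). The IIR choice follows the common
detection protocols in this literature and behaves well on short records
where a 0.3 Hz FIR kernel would consume a large fraction of the signal.

**SOs:** candidates are segments between consecutive positive-to-negative
zero crossings of the SO-filtered signal lying wholly inside NREM (N2+SWS
by default; N1 excluded); keep duration 0.8–2 s; keep candidates whose
trough amplitude AND trough-to-peak amplitude strictly exceed the
mean + 1 s.d. of the duration-valid candidate pool on that channel. With
strictly identical candidates nothing exceeds the threshold — an intended
property of the rule.

**Spindles:** RMS of the sigma-filtered signal in a 200 ms moving window,
smoothed with the same kernel; events are NREM intervals with smoothed RMS
above mean + 1 s.d. (population: NREM samples, per channel) for 0.4–3 s;
intervals containing any sample above mean + 9 s.d. are discarded as
artifacts; events must contain at least six positive peaks of the
band-passed signal. Note the cycle rule binds only for the shortest events:
any suprathreshold sigma-band interval oscillates at 12–16 Hz throughout,
so events beyond ~0.5 s carry six peaks by construction. Onset/offset are
the threshold crossings; the centre is the envelope maximum. Detected
onsets carry a systematic lag of a few tens of milliseconds relative to
injected burst onsets (the envelope must climb to threshold); at amplitude
ratios ≥ 4 the mean onset error stays under 0.1 s.

**Coupling and phase:** a spindle couples to the SO containing its envelope
maximum (one SO may host several spindles). Phase is the angle of the
analytic (Hilbert) signal of the SO-filtered trace at the spindle centre:
0 = up-state peak, ±π = down-state trough, increasing through time. PPC is
evaluated exactly via the resultant identity
`|Σ e^{iφ}|² = N + Σ_{i≠j} cos(φ_i − φ_j)`; it is an unbiased estimate of
the squared population resultant length and its expectation is independent
of event count — verified by simulation at N ∈ {10, 50, 200}. The Rayleigh
test uses the standard approximation
`p = exp(√(1 + 4n + 4(n² − (nR)²)) − (1 + 2n))`, cross-checked against an
independent circular-statistics implementation in the tests.

Stage proportions default to fractions of all scored 30 s epochs (wake in
the denominator); `include_wake=False` restricts to sleep epochs. Both
conventions are defensible; the default is stated rather than assumed.

## Inference

**One-sample cluster permutation test** (decoding grids, 1-D or 2-D):
per-point one-sample t against the reference value; cluster-forming
threshold = parametric p < 0.05 at the stated tail; clusters by adjacency
(4-connectivity in 2-D); cluster mass = sum of t values; null = random
sign flips of subject-level deviations; cluster p carries the +1 correction
(never below 1/(n_perm+1)). Data identically at the reference value yield
an empty result rather than an error; zero variance with a non-zero effect
is an error.

**Session × layer interaction test:** with a two-level session factor the
repeated-measures interaction F equals the RM layer effect on per-subject
session differences, computed per time point with (L−1, (S−1)(L−1)) degrees
of freedom; clusters over time; the null flips session labels independently
within each subject. This scheme is exact under the stronger null of no
session effect at all and approximate for the interaction proper — the
standard caveat for permutation tests of interactions, accepted here.
Both tests control family-wise error at ≈ 0.05 under simulated nulls
(calibration run at 500 permutations × 500 replicates; the larger replicate
count keeps the binomial noise of the error estimate well inside the ±0.02
acceptance band).

**Contrasts:** per-subject dot products with zero-sum weights, two-tailed
one-sample t. Built-ins: linear = centred ranks; cosine =
`cos(π(k−1)/6)` centred, k = 1..7. The cosine family is one defensible
choice for a "curved" component; it is exposed as an argument, and reported
p-values for such decompositions should not be treated as replications of
any particular published value.

**Robust rules:** outliers are values more than 3 scaled MADs
(1.4826 × median absolute deviation) from the median, strict inequality;
participants are excluded only when flagged on either behavioural metric in
*both* the final learning block and the pre-sleep test, or when they show
no sleep beyond N1. Pairwise sequential accuracy is the percentage of
adjacent ordered pairs of the true sequence reproduced adjacently and in
order in the report.

## Cohort orchestration

`pipeline.run_group` estimates the group cluster once and then averages each
participant's matrix inside it ("strength"). Defining the window on the same
cohort used for the subsequent correlations is circular; the procedure is
retained deliberately because it is the procedure under study, and the
circularity is inherited, not corrected. On a null cohort with no
significant cluster the full grid is used and flagged
(`mask_is_fallback=True`). Behaviour reports are simulated by degrading the
true order with adjacent transpositions to a per-participant target
accuracy; when `link_strength_to_coupling` is set, per-participant coupling
concentration kappa is drawn and the successor leak is a noisy increasing
function of the population PPC `(I1(κ)/I0(κ))²`, giving the brain–sleep
correlation a known positive ground truth. Every group result embeds the
config hash, seed and package version.

## Problem sizes and numerical conventions

Default test/acceptance scales: 20 participants × 2 sessions × 200 trials
for the null-chance check; 8 participants for shift recovery; 500
permutations for calibration suites; 600–900 s sleep records. These sizes
were chosen so each property is measured with Monte-Carlo error comfortably
inside its tolerance. Seeds derive from `numpy.random.SeedSequence([seed,
i])` and stay below 2³¹. Ties in classifier scores break to the lowest
canonical category index; Spearman uses average ranks; upper-triangle
vectorisation uses i<j ordering throughout.

## Known limitations

- Wake noise is white across channels and time; real EEG autocorrelation
  would slow the convergence of the null to 25% and widen cluster nulls.
- The generator's successor signal is purely category/feature-based; item
  identity within category is not separately decodable.
- The interaction permutation scheme is approximate (see above).
- EDF export is not provided (no EDF writer dependency); sleep records
  round-trip through HDF5 + CSV, and EDF reading is available through MNE
  when installed.
- Detected spindle onsets lag injected taper onsets by a few tens of
  milliseconds by construction of threshold detection; centre (envelope
  maximum) estimates are substantially more accurate and are what coupling
  analyses use.
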