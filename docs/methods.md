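# Methods

This note documents the models, algorithms, and design choices behind
`moveprof`, in the order the pipeline runs them, together with the
assumptions each stage makes and what the synthetic study does and does not
demonstrate.

## Signal model and the synthetic cohort

The generator treats each movement as a **sum of phase-locked harmonics** of
a slow fundamental (0.22–0.5 Hz depending on the archetype; always far below
the 4 Hz analysis band). For each of the 13 body sites, an archetype fixes
per-axis amplitudes for gyroscope (deg/s) and dynamic acceleration (g),
axis phases (staggered by ~2.1 rad so the 3-axis gyro norm never collapses
mid-repetition), harmonic content (relative amplitudes of harmonics 2 and 3),
an inter-limb coordination phase offset (0 for in-phase movements such as
RTP, π between left and right limbs for alternating movements such as GST),
and a posture: mean pitch/roll plus a sway amplitude oscillating at the
fundamental. The accelerometer reads orientation-consistent gravity plus the
dynamic component; the magnetometer reads a constant world field rotated by
the same orientation. One **repetition is two fundamental cycles**, tapered
to rest by a 0.3 s Tukey ramp; repetitions are separated by configurable
pauses (default 0.5 s) where only white sensor noise remains (the smoothed
gyro envelope stays below 6 deg/s there, which the segmenter relies on).

Two archetypes, GST and WHLC, are drawn from the *same* base template and
then diverged by an amount controlled by `1 − overlap` (default overlap
0.75) plus a small tempo gap (0.33 vs 0.365 Hz). This deliberately
reproduces the situation where two movements share common motion patterns
and are the dominant source of classifier confusion; the degree of overlap
is a configuration parameter, not a constant.

**Proficiency grades** degrade execution along four axes, all strictly
decreasing from low to high grade and all positive even at high grade:

| parameter | low | medium | high | unit / effect |
|---|---|---|---|---|
| jerk noise sd | 14 | 7 | 2.5 | deg/s of 2–6 Hz band-limited noise |
| tempo jitter CV | 0.10 | 0.05 | 0.02 | per-repetition period variability |
| amplitude CV | 0.15 | 0.08 | 0.03 | per-repetition amplitude variability |
| coordination error sd | 0.45 | 0.22 | 0.08 | rad of per-rep phase noise |

Execution quality is expressed **where the movement lives**: grade-dependent
jerk noise is injected at full strength only on each archetype's *skill
sites* (the wrists/arms for the upper-limb movements, the thighs/shanks/
ankles for the stepping and single-leg movements, the trunk for PUSH),
scaled in proportion to the site's motion amplitude, with only a small
residual elsewhere. This choice matters for the modeling comparison below:
it makes the informative feature *subset* movement-specific, which is what
gives movement-specific proficiency models their advantage over a single
unified model. Each archetype also carries mild multipliers on the jerk and
coordination terms (0.8–1.4), so the mapping from raw noise level to grade
is not uniform across movements.

**Subjects** differ through random effects: tempo multiplier (sd 5%),
amplitude multiplier (sd 8%), global posture offsets (sd 3°), and per-site
phase offsets (sd 0.2 rad). These are what make leave-one-subject-out
validation a real generalization test rather than a formality.

Grades are allocated per (subject, movement) by stratified assignment —
grade counts follow the configured proportions up to largest-remainder
rounding, with the assignment shuffled by the seeded RNG — so that every
grade is represented for every movement even at the default 8-subject size.
One gross-competency value is drawn uniformly from the grade's score range
per (subject, movement) and shared by both side variants, matching a
protocol in which experts give one score per movement.

What the generator does **not** model: biomechanically faithful
choreography, soft-tissue artifacts, sensor drift or bias, dropped samples,
and within-subject learning across repetitions. Passing tests on this
cohort therefore demonstrates that the pipeline recovers planted structure
of the kind described above — not that it would reach the same accuracy on
real recordings.

## Preprocessing

Signals are resampled from the acquisition rate to the 32 Hz working rate by
polyphase rational resampling (100→32 Hz uses the ratio 8/25) with the
default Kaiser anti-aliasing window. Upsampling is rejected by default —
the pipeline only ever lowers rates. Markers are stored in seconds, not
samples, precisely so they survive this rate change.

Band splitting uses a 4th-order Chebyshev **Type I** design with 0.5 dB
passband ripple (the conventional reading when only "4th-order Chebyshev"
is fixed; family and ripple are configuration), realized as second-order
sections and applied forward–backward. Zero phase protects segmentation
timing; the effective magnitude response is squared, so the passband floor
is 10^(−ripple/10) ≈ 0.891 — a uniform scaling that cancels in the
orientation features (they are atan2 ratios) and is irrelevant to frequency
locations. The band-pass (0.1–4 Hz) is one band-pass design by default; a
cascade of separate high-pass and low-pass quarters is available as a
configuration flag for alternative readings. Edge transients are bounded by
reflect padding of one settling length.

## Segmentation

"Velocity zero crossings" cannot be literal zeros in noisy data. The
segmenter computes an angular-speed envelope — the Euclidean norm of the
low-pass gyro vector, averaged over configured placements (default: both
wrists, since every protocol movement drives the upper limbs), smoothed by a
0.25 s centered moving average (a monotone low-pass FIR with no ringing
below threshold) — and declares a pause wherever the envelope stays below
10 deg/s for at least 0.2 s. Repetition boundaries sit at pause midpoints
(an envelope-minimum rule is selectable); leading/trailing fragments shorter
than 1 s are dropped. All thresholds are configuration keys, because the
operationalization is a design decision rather than a protocol fact.

The manual-confirmation step of a real study is represented by a review
flag: when an expected repetition count is supplied and the recovered count
differs, the block is flagged rather than coerced, and a boundary-override
file can replace intervals downstream.

On default generator cohorts the segmenter recovers the exact repetition
count in ≥ 95% of blocks with boundaries within ±0.15 s of ground truth
(ground truth is stored in the same pause-midpoint convention, making the
comparison well-defined).

## Feature registry

The registry reconstructs a 378-feature set from its three stated families
(the exact historical composition is not recoverable, so the registry is
data-driven configuration and alternative reconstructions are drop-in):

* 312 spectral: 13 sensors × {accel, gyro} × 3 axes × {dominant frequency,
  mean frequency} × {low-pass, band-pass}. Spectra come from a
  Hann-windowed, constant-detrended periodogram over the full repetition
  (repetitions are too short for segment averaging), zero-padded to a
  0.05 Hz grid; the DC bin is excluded. Zero-power series yield a flagged
  0 Hz sentinel.
* 52 orientation: 13 sensors × {mean pitch, mean roll, pitch range, roll
  range} from the low-pass accelerometer under the gravity-dominant
  assumption, with pitch = atan2(−ax, √(ay²+az²)), roll = atan2(ay, az).
  Sustained gravity magnitude below 0.5 g flags the metrics and falls back
  to unit-normalized directions.
* 14 cross-correlation: normalized peak and signed lag (|lag| ≤ 2 s; ties
  broken toward smallest |lag|, then negative) of band-pass gyro magnitude
  for 7 pairs — the four ankle×wrist combinations (inter-limb synchrony),
  both bilateral pairs, and chest–sacrum. Zero-variance inputs yield a
  flagged (0, 0) sentinel.

The magnetometer is generated but feeds no default feature. Every feature
table embeds a hash of the registry order; mixing tables or models built
under different registries is rejected.

## Feature selection

mRMR uses the additive MID criterion: greedily pick the feature maximizing
(mutual information with the label) − (mean mutual information with the
already-selected set), with continuous features discretized into 3
equal-frequency bins. The variant and bin count are configuration. Two
deliberate details: ties break by registry order for determinism, and
zero-variance features are appended at the end with zero relevance rather
than dropped or ranked by the raw criterion (a constant has zero redundancy
with everything, which would otherwise let it leapfrog informative-but-
redundant features once scores go negative).

The kept count follows the 95% rule: train the evaluator on growing prefixes
of the ranking and keep the smallest *k* whose score reaches 95% of the
score with the full set. The default evaluator is the out-of-bag micro F1
of a 100-tree forest, which avoids an inner cross-validation loop inside
each LOSO fold. On 378-feature tables the curve is evaluated on a coarse
k-grid (1…40 plus the full-set reference) rather than all 378 prefixes;
`chosen_k` is the smallest *evaluated* k meeting the rule. The greedy mRMR
search is likewise truncated at depth 40 on wide tables, with the remainder
appended by relevance; the chosen counts in practice are far below the
truncation depth.

By default, selection runs **inside each training fold** (`selection_mode =
"nested"`), so the held-out subject never influences feature choice; a
`"paper"` mode performs selection once on the full table before
cross-validation for protocols that accept that leakage.

## Models and evaluation

All classifiers are Random Forests with 100 trees, out-of-bag scoring, and
library defaults otherwise (hyperparameters are recorded in the model
bundle). Class imbalance is left untouched. The hierarchical scorer predicts
the movement first and routes each repetition to the *predicted* movement's
3-class proficiency model — routing never peeks at the truth, which is what
makes the misrouting analysis meaningful. Overall grades are majority votes
per (subject, movement, side) — the unit the expert scores attach to — with
ties resolved toward the lower grade, the conservative choice in a
fall-prevention context (no tie rule is inherited; this is a documented
package decision).

Evaluation is leave-one-subject-out: folds are deterministic given the
subject set, and the configured repeats (20 in the full protocol; the
default study here uses 3) re-seed only forest training and the selection
evaluator — the only reading under which repeats produce a spread at all.
Micro F1 is pooled-TP F1, identical to accuracy in single-label multiclass
tasks; it is reported as mean ± sd over repeats at repetition level and
after majority voting. Undefined precision/recall (empty class) is reported
as 0 with a flag, never NaN. With nested selection, no repetition of the
held-out subject is present in training or selection for its fold.

The default study size — 8 subjects, 6 movements with bilateral variants,
6 repetitions per block (528 repetitions), 3-repeat LOSO — is the package's
standard desk-scale experiment; all headline quantities in
`scripts/acceptance.py` come from it.

## Sammon projection

The Sammon map minimizes E = (1/Σdᵢⱼ) Σ (dᵢⱼ−Dᵢⱼ)²/dᵢⱼ by gradient descent
from the PCA initialization with step halving (up to 30 halvings per step),
tolerance 1e-6 on relative stress decrease, and a 500-iteration cap; stress
is non-increasing across accepted steps by construction. Coincident input
points are epsilon-regularized and flagged, with a seeded micro-jitter on
the initialization to keep gradients finite.

## Numerical and degenerate-input conventions

* Readers validate rather than repair: non-monotone time, out-of-range
  samples, missing placements, score granularity violations, and overlapping
  markers are distinct typed errors.
* Sentinels (0 Hz, (0,0) cross-correlation) are always paired with flags on
  the feature vector.
* Seeds: every stochastic component (generator, forests, repeats) derives
  from explicit integer seeds via `SeedSequence`; identical configuration
  and seed reproduce outputs bit for bit, and all derived seeds stay below
  2³¹.
* A movement whose training data contains a single grade still yields a
  model, flagged degenerate, rather than an error — LOSO folds on small
  cohorts hit this legitimately.

## Known limitations

* The harmonic signal model has no movement phases, transitions, or
  non-stationarity within a repetition; features that would exploit phase
  structure are out of scope.
* The 378-feature registry is one documented reconstruction of a set whose
  exact composition is not recoverable; the registry mechanism exists so
  other reconstructions can be swapped in.
* The unified-vs-specific model comparison depends on quality being
  expressed on movement-specific body sites (see the generator section); a
  dataset where quality degrades uniformly across the body would not show
  the same gap.
* Medium-grade cells are small at the default cohort size (2 subjects per
  movement), so per-class recall for the medium grade is noisy — consistent
  with the general observation that middle classes are the hardest to pin
  down.
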