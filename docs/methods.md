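# Methods

## Composite memory score

Each studied object passes through up to three test phases. Item
recognition uses a 6-point confidence scale (1 = "very sure I have seen
it" … 6 = "very sure I have not seen it"): a correct endorsement earns
3/2/1 points for confidence 1/2/3, anything else 0. Cued associative
recall is scored 0 / 0.5 / 1 by each of two independent raters; the rater
mean is multiplied by 3 so the phase carries the same weight as the
recognition phases, giving {0, 0.75, 1.5, 2.25, 3}. Associative
recognition is a 2AFC over two scenes with the same 6-point scale: 1–3
selects the left scene and 4–6 the right, confidence decreasing towards
the middle of the scale; a correct side earns 3/2/1 points for the
outer/middle/inner confidence bands ({1,6}/{2,5}/{3,4}), a wrong side or
timeout 0. The composite score is the sum, 0–9.

Two scoring conventions deserve note. First, the scale direction is fixed
by the worked examples ("correct and highly confident" = 3 points), so
confidence 1 maps to 3 points. Second, the original protocol describes
the intermediate-confidence buttons as "2 and 4"; on a 1–6 scale whose
halves select opposite sides this can only be meant as 2 and 5, and the
band map {2,5} → 2 points is what we implement. A timeout in any phase
scores 0 for that phase only; a failed *item* phase gates the whole trial
to 0, because the later phases were only administered after a correct item
answer. Lures never earn memory points: endorsing one (confidence 1–3) is
a false alarm whose confidence is recorded as 3/2/1 *pseudo*-points for
the chance-level model below.

An exhaustive enumeration of all 1 372 admissible response combinations is
compared in the tests against an independently written rule table.

## Guessing chance level

The null hypothesis for the one-sample tests is not 0: a memory-free
responder can false-alarm on item recognition and then guess the 2AFC
side. Writing p(FA) for the false-alarm rate, p(x|FA) for the distribution
of item pseudo-points x ∈ {1,2,3} given a false alarm, and p(y|FA & x) for
the distribution of associative-recognition points y ∈ {0,1,2,3} given a
chance response with x item points, the expected composite score under
pure guessing is

    C = p(FA) · Σₓ p(x|FA) · ( x + ½ · Σ_y p(y|FA & x) · y )

with ½ the probability of a correct 2AFC side guess and cued recall
contributing 0 at chance. Per participant, p(FA) and p(x|FA) are estimated
from the lure responses; because false alarms had no associative phase by
design, p(y|FA & x) is estimated from the *studied* trials' empirical
(item points → associative points) contingency, row-normalized. An item
level never observed on studied trials falls back to the participant's
marginal y distribution, which keeps C defined without inventing zeros. A
participant with no false alarms gets C = 0, the formula's limit. The
group chance level is the unweighted mean of per-participant C values.

Properties: C is monotone non-decreasing in p(FA) with the conditionals
fixed, and 0 ≤ C ≤ 4.5 · p(FA). A vectorized Monte-Carlo simulation of the
guessing process (false alarm → draw x → coin-flip side → draw y) is kept
as an independent oracle; the closed form agrees within 3 standard errors
at 10⁵ trials across randomized profile sweeps. The model assumes the side
guess is independent of the reported confidence and that recall
contributes exactly 0; claims about real responders beyond this model are
out of scope.

## Condition statistics

Subjective congruency ratings are binned 1–2 → incongruent, 4–5 →
congruent; a rating of 3 (indifferent) drops the trial. Crossing with the
3-level reactivation report gives six within-subject cells of the
per-participant mean score; trials with a missing reactivation response
are excluded (a timeout is not a level).

Participants with fewer than 10 trials in an analyzed condition are
excluded. The threshold is applied to the *marginal* conditions (each
congruency bin and each reactivation level) by default: a crossed-cell
reading of the rule is arithmetically incompatible with the degrees of
freedom this kind of study reports (cell-wise t-tests with varying df and
an ANOVA with fewer complete cases than included participants imply that
included participants may lack individual cells). `on="cells"` applies the
stricter reading.

The 2×3 repeated-measures ANOVA is the standard fully-within
decomposition, each effect tested against its own effect-by-subject
interaction; participants missing any cell are dropped listwise, and
partial η² = SS_effect / (SS_effect + SS_error). No sphericity correction
is applied by default; Greenhouse–Geisser ε is available via
`gg_correction=True` (it never applies to the 2-level congruency factor).
The implementation is the explicit sums-of-squares computation; tests
verify it against statsmodels' `AnovaRM` and a loop-written textbook
decomposition to 1e-10, and that its p-values are uniform over simulated
null datasets. One-sample t-tests report both d = (M − C)/SD (the standard
one-sample Cohen's d) and d = M/SD, which is the convention the field's
printed effect sizes typically follow; both are labelled in the output.
With zero variance the t statistic is undefined and an error is raised.

## Decoding pipeline

Preprocessing is per run: a discrete-cosine high-pass filter (cutoff
128 s, the conventional default — the filter is fit and removed by least
squares together with the run mean) followed by per-voxel standardization
to mean 0, SD 1. Voxels constant within any run are zeroed everywhere and
flagged. Volume indices are 0-based; "3 TRs after onset" is
`onset_index + 3`, i.e. the 4th scan of a block in 1-based counting.

Training scans come from the scene and face localizer blocks only: the
volumes at onset + 3 and onset + 6 TRs of each 12 s block, i.e. 40 scans
(20 per class) for a 10 + 10 design. Cross-validation is
leave-one-chunk-out over 20 chunks of 2 scans; each chunk pairs one scene
and one face scan from different blocks, assigned deterministically from
the seed, so every test fold is class-balanced. Inside every fold, the
top-K voxels by two-class ANOVA F (K = 250 by default; ties break towards
the lower voxel index) are selected *on the training folds only* and an
L2-regularized linear logistic regression (inverse strength C = 1,
deterministic liblinear solver) is fit on them. The permutation null
re-assigns class labels within chunks (a seeded coin flip per chunk swaps
its scene/face labels) and re-runs the complete cross-validation,
feature selection included; p = #(null ≥ observed)/n by default, with the
(k+1)/(n+1) variant behind `plus_one=True`. Because the accuracy statistic
is discrete, the literal p is mildly conservative (super-uniform) under
the null; the calibration tests quantify that it remains approximately
uniform at the study's scan counts.

For event decoding the model is refit on all 40 training scans (standard
practice; a fold-ensemble would also be defensible but mixes
feature-selection sets) and applied to the volume at onset + 3 TRs of each
AC-encoding event after the same per-run preprocessing; the scene-class
probability is the reinstatement read-out. Events whose target volume
falls outside the run are skipped with a logged count. Decoded
probabilities feed the same 2×3 ANOVA as the memory scores.

## Synthetic generator

The generator's defaults define the study-shaped conditions: 25
participants, 120 triads (counterbalanced congruent/incongruent), 60
lures, a 2-run scene/object/face localizer with 10 blocks per class (12 s
on, 7 s ITI, TR 2 s), and one AC-encoding run with 12 s trial spacing.

Behavior follows a latent-variable model with ordered thresholds
everywhere a discrete scale appears: trial strength
s = μ + β_c·congruent + ε(0, σ); reactivation report r from thresholds on
0.35·s + noise; memory strength m = participant intercept + 0.55·s +
β_r·(r−1) + β_cr·(r−1)·congruent + noise; item confidence, rater scores
and recognition confidence are thresholded functions of m, the 2AFC side
is correct with probability ½ + ½·logistic(m − 0.5), and congruency
ratings cluster around the designed condition with some indifferent "3"s.
Lures are answered from a guessing profile whose defaults follow the
reported group rates (false-alarm rate 0.171, split 8.8%/4.8%/3.5% over
1/2/3 pseudo-points). Effect sizes and thresholds were calibrated once so
the six cell means reproduce the qualitative published pattern (congruent
above incongruent at every level, means rising with reactivation,
spanning roughly 1–6.5 of the 0–9 scale, with realistic exclusion rates)
and then frozen; they are design constants, not estimates of real effect
magnitudes.

Patterns: each class has a fixed multivoxel pattern over a random set of
signal voxels (250 of 500 by default). Scene and face take opposite-signed
values of random magnitude 0.5–1.5 at every signal voxel, so each signal
voxel carries genuine between-class contrast and the ground-truth set is
recoverable by the F statistic; the object pattern is an independent
Gaussian draw. A block contributes amplitude SNR·σ_noise (SNR 2 by
default) in a boxcar shifted 2 volumes to mimic hemodynamic delay — a
shift, not an HRF convolution, because the analyses only read volumes at
fixed TR offsets and the shift keeps the generator analytically
transparent. Low-frequency drift (three slow cosines, removable by the
128 s high-pass) and white Gaussian noise complete the scan model. Each
AC event adds the scene pattern at onset + 3 volumes with amplitude
γ·(r−1)/2 + jitter, so γ = 0 yields a null dataset and reactivation level
1 carries no systematic reinstatement.

What the generator does *not* emulate: physiological and motion noise,
spatial autocorrelation, HRF shape and undershoot, anatomical mask
structure, inter-stimulus variability within blocks. Passing tests
therefore demonstrate the pipeline's statistical correctness and
calibration under the stated model, not robustness to realistic fMRI
artifacts.

Randomness is split into independent sub-streams (behavior / localizer /
AC patterns) derived from one seed, so regenerating one component never
perturbs another.

## Numerical choices and degenerate inputs

* Onsets map to volumes by floor(onset/TR); onsets need not be TR-aligned.
* Feature-selection ties break by ascending voxel index for determinism.
* ANOVA F statistics are forced to 0 when both the effect and error sums
  of squares vanish (guarding against 1-ulp residues on constant data);
  a zero error term with a nonzero effect yields F = ∞.
* Zero lures, an empty profile list, fewer than 3 complete ANOVA cases,
  all-zero masks, runs shorter than 3 volumes, out-of-range confidences
  and non-ascending thresholds all raise validation errors rather than
  propagating NaNs.
* Missing responses are preserved as missing through every I/O round-trip;
  they are scored 0 where the rules say so but never written as 0.

## Problem sizes in the test suite

The statistical calibration tests run the full pipeline at reduced voxel
counts (150 voxels, K = 75) and 99 permutations per replicate — the chance
behavior of the decoder is dimension-independent, and these sizes keep the
200-replicate accuracy sweep and the 100-replicate permutation-uniformity
check fast while preserving the 40-scan, 20-chunk training structure that
the inference actually depends on. Parameter-recovery tests use the full
default generator.
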