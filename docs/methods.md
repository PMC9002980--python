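# Methods

This note documents the models, numerical choices and limitations of the
`sarcoemg` pipeline in enough detail to interpret its outputs and its test
suite.

## Clinical labelling model

Subjects are graded by nested screening criteria into three ordinal
sarcopenia confidence levels: level 1 requires SARC-F ≥ 4; level 2
additionally hand-grip strength below the EWGSOP2 sex-specific cut-off
(27 kg men, 16 kg women); level 3 additionally gait speed below 0.8 m/s.
The deepest satisfied level is assigned.  A grip exactly equal to the
cut-off is *not* weak (strict inequality), and SARC-F < 4 raises a
"below screening threshold" error rather than silently assigning a level —
the caller decides exclusion.

## Synthetic signal model

The generator emulates interference-pattern sEMG as **amplitude-modulated
band-limited Gaussian noise**: white noise shaped by a 4th-order Butterworth
band-pass (zero-phase), rescaled to unit RMS, multiplied by
`peak_mv × activation_profile(t)`, plus a white noise floor.  This is the
standard surrogate when motor-unit physiology is not the question; it
reproduces the two signal properties the features rely on — envelope
amplitude and spectral location — without modelling recruitment, firing
statistics, electrode geometry or crosstalk.

Per-subject protocol (1 kHz sampling): 5 s rest baseline, 5 s MVC
contraction of each muscle (sustained activation 1.0 on the corresponding
channels), a 4 s sit-to-stand segment containing a 2 s raised-cosine burst,
and a 5 s gait segment with two modest stance bursts.  Gait sEMG is
generated for protocol completeness but ignored by the default feature
extraction, which uses the sit-to-stand segment only.

Class effects are encoded in **both** amplitude and spectrum, strictly
ordered across levels (healthier = stronger and faster):

| level | sit-to-stand peak (fraction of MVC) | spectral centre (Hz) | bandwidth (Hz) |
|---|---|---|---|
| 1 | 0.80 | 120 | 60 |
| 2 | 0.55 | 95  | 60 |
| 3 | 0.35 | 70  | 60 |

MVC scale is 1.0 mV with ±10% multiplicative subject/channel jitter (the
normalisation stage removes it, which is its purpose); the noise floor is
0.01 mV RMS.  These defaults were chosen once as plausible wearable-sEMG
magnitudes with clinically meaningful effect ordering; they are deliberately
*strong* effects — see Limitations.  Assessments are drawn uniformly within
level-consistent ranges (e.g. level-2 male grip ~ U[15, 26] kg, level-3 gait
~ U[0.3, 0.75] m/s), so the stored level always equals the label recomputed
from the assessment.

## Preprocessing

* Band-pass: `scipy.signal.butter(4, [20, 450], "bandpass")` applied
  **zero-phase** (`sosfiltfilt`) by default.  Offline analysis favours
  zero-phase filtering to avoid phase distortion at window boundaries; a
  causal mode exists for parity with real-time use.  Note the effective
  attenuation is squared by the forward-backward pass.
* Envelope: full-wave rectification then a 10 Hz 4th-order Butterworth
  low-pass; tiny negative residues of zero-phase filtering are clipped to 0.
* MVC reference: mean envelope over the channel's matching MVC segment
  **minus the rest-baseline mean** (sensor-offset removal; can be disabled).
  Non-positive references raise a calibration error.
* Normalisation is **per muscle**: GL channels by the GL reference, TA by
  TA.  Both the envelope and the band-passed signal are offered in MVC
  units.

## Feature extraction

200 ms windows, 50 ms step, trailing partial windows discarded; the first
and last 0.25 s of the segment are excluded to avoid filter transients.
By default all 12 features are computed on the **band-passed, MVC-scaled
signal**, not the 10 Hz envelope: on a non-negative envelope ZC is
identically zero and SSC/WAMP/AIF lose their meaning.  The envelope source
remains available for amplitude-only feature sets.

Formula conventions (fixed by brute-force oracles in the tests):

* MAV1/MAV2 weights use 1-based indices with inclusive bounds
  0.25 N ≤ i ≤ 0.75 N; the MAV2 outer ramps are 4i/N (rise) and 4(N−i)/N
  (fall) — the published falling ramp 4(i−N)/N is negative and is treated
  as a typesetting error.
* VAR = Σxᵢ²/(N−1) (a stray weight factor in the printed formula is
  dropped); consequently SSI = N·RMS² and VAR = SSI/(N−1) hold exactly.
* ZC counts i with xᵢ·xᵢ₊₁ < 0 **and** |xᵢ − xᵢ₊₁| ≥ thr (the printed
  guard "≥ 0" is vacuous; the standard thresholded form is used).
* SSC thresholds the *product* (xᵢ−xᵢ₋₁)(xᵢ−xᵢ₊₁) ≥ thr as printed, so its
  threshold scales as c² under amplitude scaling by c (ZC and WAMP scale
  as c).
* The count threshold is 0.1 mV on raw/filtered signals; after MVC scaling
  it becomes 0.1 / reference per channel, preserving its physical meaning.
* AIF is the window mean of d(unwrapped ∠hilbert(x))/dt / 2π, clamped to
  [0, fs/2], reported in Hz; an all-zero window yields 0 with a warning.
  On band-limited noise it tracks the spectral centre, but in low-activation
  windows the broadband noise floor pulls it toward fs/4 — a real effect of
  the estimator, not a bug.

Instances are **per-subject means** over windows by default (one
48-dimensional vector per subject), matching an augmentation step that
speaks of "patients"; per-window instances are available.

## Balancing

SMOTE + ENN, implemented directly (imbalanced-learn is not available in the
target environment): synthetic minority points xᵢ + λ(xₙₙ − xᵢ), λ ~ U(0,1),
xₙₙ among the 5 nearest same-class neighbours (k shrinks for tiny classes);
then one ENN pass removing every instance whose label disagrees with ≥ 2 of
its 3 nearest Euclidean neighbours, decided on the original set.  Distances
use raw feature columns by default (no scaling step is part of the published
pipeline); neighbour ties break by lowest index, making the stage
deterministic under seed.  The module default target equalises to the
majority count; the full-pipeline default targets 50 per class, which after
ENN yields ≈150 instances — the published augmented-cohort size.  Note the
single ENN pass does not *guarantee* the cleaned set re-satisfies the
2-of-3 rule (removals change neighbourhoods); on separable data it does,
and the tests check it there.

## Feature selection

The default mode is the fixed published subset {IEMG, RMS, AIF} × 4
channels.  The metaheuristic mode is a standard binary tree-growth search
(the original "modified" operators are unpublished and not claimed):
population 20 over {0,1}⁴⁸ via continuous positions and an S-shaped
transfer function; per generation the best 6 trees take greedy single-bit
local-search steps with a shrinking flip budget, 6 move toward a random
convex combination of the two best, 4 are fresh random trees and the worst
4 are replaced.  Fitness = 0.99 · (5-fold k-NN error on z-scored masked
features) + 0.01 · (bits/48), minimised; empty masks are repaired by setting
one random bit; the best-so-far trace is non-increasing by construction.

**Known behaviour:** when classes are separable enough that the inner CV
error saturates at zero, the subset-size term dominates and the search
returns *minimal* zero-error masks (often a single column) rather than the
full informative set.  This is the correct optimum of the stated objective,
not a search failure; recovering redundant informative columns would
require a different objective (e.g. stability selection or an error term
that is not saturated).

## Evaluation

Stratified 10-fold CV, shuffled under the global seed.  Within each fold a
further 10% of the training data is held out as a validation set for
contract fidelity; none of the eight estimators consumes it during fitting,
so it is logged only (and skipped when the training fold is too small to
stratify).  Optional in-fold SMOTE+ENN is fit on the training portion only,
so test folds never contain synthetic instances.

Classifiers and their fixed hyper-parameters: SVM (linear, C=0.1, one-vs-one,
max 100 iterations), decision tree (gini, depth 10), random forest (10
trees, depth 10), one-vs-rest logistic regression (newton-cg, C=0.001, max
50 iterations), k-NN (5 neighbours, Minkowski, distance weights), Gaussian
naive Bayes (variance smoothing 1e-5), MLP (identity activation, hidden
layers (10, 10), alpha 1e-4, lbfgs), and gradient boosting (learning rate
0.001, depth 2, 214 estimators) standing in for XGBoost, which is not
available in the target environment.  Convergence warnings from the
deliberately iteration-capped SVM/LR are suppressed.

Metrics: accuracy = trace/total; per-class one-vs-rest precision and recall
macro-averaged (a never-predicted class contributes precision 0); F1 is the
per-class harmonic mean 2PR/(P+R) — the published F1 denominator containing
TN is treated as a typo.  Cohen's κ = (p₀ − pₑ)/(1 − pₑ); the degenerate
all-mass-on-one-diagonal-cell case is defined as κ = 1.  Agreement bands are
half-open — slight (κ ≤ 0.20), fair (≤ 0.40), moderate (≤ 0.60), good
(≤ 0.80), perfect (≤ 1.00) — so the published boundary values are all
defined.  Fold-averaged metrics are the default; pooled-prediction metrics
are also reported.

## What a green test establishes — and what it does not

The synthetic cohort makes the three levels close to linearly separable by
design (strict amplitude and spectral ordering, modest jitter).  Green
benchmark tests therefore establish that the *machinery* is correct —
windowing, formulas, balancing, fold bookkeeping, determinism — and that
the feature set genuinely carries class signal.  They do **not** establish
clinical performance: real patients overlap between adjacent levels,
electrode placement varies, and the published per-classifier accuracy
spread (which came from non-public patient data) is not reproduced here.
Near-ceiling accuracies on the synthetic cohort are expected and should not
be read as a clinical claim.

## Known limitations

* No powerline notch filter, motion-artifact detection or adaptive
  filtering; only the stated band-pass.
* The gait segment is generated but unused; gait speed enters only through
  the labelling rule.
* The sEMG surrogate omits motor-unit recruitment, fatigue drift within a
  contraction, and inter-channel crosstalk.
* Global balancing before CV (the published order, and the package default
  for the 3/22/7 cohort where per-fold balancing is infeasible) lets
  interpolated copies of training information reach test folds; accuracies
  under this protocol are optimistic.  Use `balance_in_fold` when the raw
  cohort is large enough.
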