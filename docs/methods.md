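# Methods

`prefog` implements a two-stage explainable analysis of pre-freezing gait: a
small 1D convolutional network (CNN) that separates the last gait cycle before
a freezing-of-gait (FOG) episode from functional gait cycles (FGC), and
epsilon layer-wise relevance propagation (ε-LRP) that attributes each
prediction to the hip, knee and ankle angle samples that drove it. Because
clinical motion-capture datasets of this kind are not freely available, the
package includes a synthetic cohort generator that reproduces the statistical
structure the analysis assumes; everything downstream (preprocessing,
training, nested cross-validation, attribution) is agnostic to the data's
origin.

## Synthetic gait cohorts

Each subject is assigned noiseless template trajectories for sagittal hip,
knee and ankle angles over one normalized gait cycle. Templates are truncated
Fourier series (six harmonics; coefficients are generator defaults fit to
normative sagittal gait shapes, with the 5th–6th harmonics suppressed so the
curves stay band-limited well below the 7 Hz preprocessing cut-off at
physiological cadences). Subject-level random effects perturb per-joint
amplitude (±12 % of the deviation from the curve mean), phase (±2 % of the
cycle) and offset (±1°); these bounds keep the typical knee swing-phase peak
inside 50–70° by construction. A "stooped" archetype adds constant +20° hip
and +15° knee flexion offsets, emulating a severely flexed gait signature.

A pre-FOG cycle applies a reduced range-of-motion signature of strength
δ ∈ [0, 1] to the templates before noise:

- **knee** — swing excursion above the swing minimum scaled by (1 − δ),
  i.e. reduced swing-peak flexion;
- **ankle** — swing trajectory pulled toward its swing mean by the factor δ
  (emulating dorsiflexion fixed during swing);
- **hip** — whole-cycle excursion about the mean scaled by (1 − δ/2). The
  hip reduction is a modeling choice: clinical reports quantify hip
  involvement less precisely than knee/ankle, and the factor δ/2 marks it as
  secondary.

The swing window follows the standard 60–100 % convention. Its onset weight
is a logistic ramp (center 63 %, scale 1.8 % of the cycle) rather than a hard
step: the weight is effectively 0 through stance and ≥ 0.99 from the swing
knee peak (~73 %) onward, so the knee swing excursion still scales by exactly
(1 − δ) while the perturbed curves stay smooth. Measurement noise is i.i.d.
Gaussian per sample and channel (default SD 2°), a deliberately simple model
of marker/model jitter.

Cohort defaults mirror the reference study design at desk scale: 7 freezer
subjects contributing 8 pre-FOG and 8 functional cycles each (56 pre-FOG
cycles in total), 7 "NoLab" freezers (freezer-group subjects contributing
functional cycles only), 7 non-freezers and 7 controls with 8 functional
cycles each, one stooped subject among the freezers, δ = 0.5 (mid-range of
the 31–61.5 % range-of-motion reductions reported before freezing), and
stride durations uniform on 0.8–1.3 s at 100 Hz. The entire cohort is a pure
function of the master seed.

What the generator does **not** emulate: frontal/transverse-plane
kinematics, marker-level artifacts, correlated (non-white) measurement
noise, within-subject fatigue or progression trends, and the freezing
episodes themselves (only the cycles preceding them). Passing tests on this
cohort therefore demonstrate that the pipeline recovers a known injected
signature under realistic noise and inter-subject variability — not clinical
performance on real recordings.

## Preprocessing

Each raw cycle is processed per cycle, in this order:

1. **Low-pass filter**, 4th-order Butterworth, 7 Hz cut-off at the native
   100 Hz rate, applied zero-phase (forward–backward). Because the unit of
   analysis is a single cycle, boundaries are handled cyclically: the line
   joining the first and last samples is removed, the residual is filtered
   under a periodic extension by applying the squared Butterworth magnitude
   to its discrete spectrum, and the line is restored. This is exactly the
   forward–backward response in the interior and avoids the edge transients
   (~0.1–0.4°) that padded filtering produces on 1-second segments.
2. **Time normalization** to 101 samples (one per percent of the gait
   cycle) by cubic-spline resampling. Splines rather than linear
   interpolation: the kink content of piecewise-linear resampling is large
   enough (~2–4 × 10⁻³ in rescaled units) to defeat the pipeline's
   own stability target below.
3. **Rescaling** of each channel of each cycle to [−1, 1] by the affine map
   taking its minimum to −1 and maximum to +1, so every joint contributes at
   equal scale. A constant channel maps to all zeros (midpoint). Rescaling
   is per cycle, not per subject: each trajectory is normalized individually.

Stability: applying the pipeline to its own output (re-interpreted as a raw
101-sample cycle) changes values by < 10⁻³ for band-limited inputs —
functional cycles at any physiological duration (measured ≤ 5 × 10⁻⁴).
Pre-FOG cycles with large δ carry a deliberately sharp swing-onset feature
whose spectral content reaches past the 7 Hz band edge after time
normalization, so exact idempotence cannot hold for them; the filter keeps
trimming that content on every pass (up to ~8 × 10⁻² at δ = 0.5). Labels are
one-hot encoded with fixed column order (FGC, pre-FOG).

**Matching.** Each pre-FOG cycle is paired with one same-subject functional
cycle — preferring the same protocol condition (turning direction/amplitude ×
single/dual task), falling back to any same-subject cycle — and one
condition-matched functional cycle from a seeded-randomly chosen NoLab
freezer. No functional cycle is reused across pairs. Surplus functional
cycles stay in the training set but are flagged and excluded from
attribution analysis. The balanced per-subject evaluation set used in
cross-validation is each pre-FOG cycle plus its same-subject match.

## Classifier

The CNN comprises B blocks of [same-padded 1D convolution → ReLU → width-m
max pooling], global average pooling to a p-dimensional feature vector
(p = number of filters), dropout, and a dense softmax head over the two
classes. Training minimizes the class-weighted categorical cross-entropy
L(Y, Ŷ) = −Σᵢ αᵢ Yᵢ log Ŷᵢ with inverse-frequency weights
αᵢ = M / (2 · countᵢ) (unit weights on balanced data) and a 10⁻¹² probability
floor inside the log. The optimizer is Adam under a sigmoidal decaying
learning rate lr(t) = lr₀ · σ(−s (t − t_mid)) over epochs t; after every
update each weight vector (per conv filter, per dense output unit) is
renormalized to the max-norm cap if it exceeds it; dropout acts only during
training. ReLU is used for the nonlinearity and max pooling for the local
pooling because both have standard, well-defined ε-LRP backward rules.
Prediction ties at probability 0.5 resolve to FGC, favoring specificity for
a screening-style classifier. Defaults: 2 blocks, 8 filters, kernel 9, pool
2, dropout 0.1, max-norm 2, lr₀ = 3 × 10⁻³, 40 epochs, batch 16 — sized for
~100 training cycles of 101 × 3 samples.

The baseline is a linear support-vector classifier on the flattened
303-sample cycles with regularization C = 0.01.

**Hyperparameter search.** `tune_hyperparameters` evaluates candidate
settings by inner leave-one-subject-out accuracy and returns the argmax
(ties to the first candidate). The default strategy is a seeded random
search over filters {4, 8, 16, 32}, kernel {5, 9, 15, 25}, blocks {1, 2, 3},
dropout U(0, 0.6) and lr₀ log-U(10⁻⁴, 10⁻²); the strategy is pluggable (any
callable proposing candidates), so model-based samplers can be swapped in.

## Evaluation

Model selection and assessment use nested leave-one-subject-out
cross-validation: the outer loop holds out each subject; the inner loop
tunes hyperparameters over the remaining subjects; the winning setting is
retrained on all inner subjects and predicts the held-out subject. Every
cycle is predicted exactly once, by a model that never saw its subject;
preprocessing is strictly per-cycle, so no statistics leak across folds.

Metrics follow the confusion-matrix definitions with pre-FOG positive
(accuracy, sensitivity, specificity, PPV, NPV, reported as percentages to one
decimal; undefined ratios are flagged, never silently zero). The overall
figure is the macro (per-subject) mean accuracy with its sample standard
deviation (n − 1). Classifiers are compared with McNemar's test on paired
out-of-fold predictions: exact binomial when the discordant count b + c < 25,
continuity-corrected chi-square otherwise (a common convention), two-sided.
Cross-cohort generalization applies a model trained on the freezer group to
the functional-only non-freezer and control cohorts; accuracy there is the
fraction predicted functional.

## Relevance propagation

Relevance starts at the pre-softmax score (logit) of the explained class —
standard LRP practice, numerically stabler than the probability — and is
redistributed layer by layer by the proportional rule with the ε-stabilized
denominator (ε default 10⁻⁴, configurable). Convolutions are handled via
weight sharing (each output position is a linear unit over its input patch),
global average pooling as a linear layer with uniform weights 1/n, max
pooling winner-take-all with ties split equally, ReLU and (inference-mode)
dropout as identity. Each layer's bias enters the denominator; the relevance
share it absorbs is dropped from propagation but accumulated and reported,
so the conservation audit can separate bias absorption from ε leakage. A
zero denominator that would receive nonzero relevance is an error at ε = 0
(the rule is undefined there); dead units — zero denominator, zero incoming
relevance — contribute an exact zero. For bias-free networks at ε = 0 the
total input relevance equals the start value to < 10⁻⁴ relative tolerance
(measured ~10⁻¹⁵).

Group attribution plots average the rescaled trajectories and relevance
curves over a named set of cycles, with per-subject subsampling to a fixed
stride count (default 3 per class) so every subject contributes equally;
unmatched functional cycles are excluded. Positive relevance (red) marks
contribution toward the pre-FOG class, negative (blue) toward functional
gait. The explained class is explicit per run rather than inferred from each
cycle's prediction.

## Reproducibility and problem sizes

One master seed fans out to per-stage seeds (simulate, match,
cross-validation, final fit, attribution) through a fixed counter scheme, so
each stage is independently reproducible and two runs from the same
configuration produce identical numeric artifacts.

The shipped benchmark sizes are chosen so a full run completes in a few
minutes on one CPU core: nested cross-validation on the default cohort uses
a random-search budget of 4 candidate settings (each evaluated on 6 inner
folds), and the class-exchangeability check at δ = 0 trains
fixed-default-setting models. Because near-tie predictions at δ = 0 make the
single-cohort leave-one-subject-out accuracy noisy (SD ≈ 5 percentage points
per cohort), that check reports the mean over four replicate cohorts
(SD ≈ 2.4), an unbiased lower-variance estimator of the same quantity.

## Known limitations

- The numpy CNN is CPU-only and sized for small cohorts; it is not a
  general-purpose deep-learning stack.
- Per-cycle rescaling removes absolute amplitude information; signatures
  that are purely affine per channel (e.g. the stooped archetype's constant
  offsets, or the hip's uniform excursion scaling) are invisible to the
  classifier by design. The injected knee/ankle signature is a shape change
  and survives rescaling.
- Attribution heatmaps have no ground truth on real data; the swing-window
  localization check is meaningful only because the synthetic signature's
  location is known.
- Relevance rules cover the layer types used here; other architectures
  (residual connections, recurrence, attention) are out of scope.
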