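# Methods

This note documents the models and procedures implemented in `eegic`, the
defaults chosen where the design was genuinely open, and what the synthetic
data can and cannot establish.

## Label aggregation

Experts annotate each independent component (IC) with a non-empty label set
from a fixed vocabulary (Eyes, Horizontal/Vertical eye movements, Line
noise, Channel noise, Brain, Alpha, Mu, Muscle, Heart, Other, Uncertain).
Before voting, classes are merged: the two directional eye-movement labels
fold into Eyes; Line noise is dropped (an annotation left empty becomes
Uncertain, preserving the row so agreement denominators stay consistent);
Alpha or Mu imply Brain. Other and Uncertain travel through the vote matrix
but receive no aggregation target by default — they are annotation-quality
flags, not classes a model should learn.

Two voting strategies produce a per-component probability per class:

- *Majority vote*: the mean of the experts' binary votes.
- *Probabilistic vote*: each expert's single vote is split equally (1/k)
  over the k classes they chose, then averaged. Splitting is what
  disambiguates mixed components: an expert who lists four classes
  contributes only 0.25 to each, so classes mentioned in passing fall
  below the threshold.

The boolean target is `probability > threshold`, strictly, with the default
threshold stored as 0.33 and probabilities rounded to 12 decimals before
comparison. This makes the boundary case unambiguous: a one-of-three vote
(p = 1/3 = 0.333…) passes a 0.33 threshold, reflecting the intent that a
component with three or fewer labels still represents a simple pattern. The
default per-class plan uses the probabilistic vote for the well-populated
classes (Brain, Eyes, Muscle, Channel noise) and the majority vote where
positives are scarce (Alpha, Mu, Heart), threshold 0.33 throughout.

Experts who did not annotate a component are excluded from its denominator
rather than counted as all-zero votes: only cast votes are averaged. A
component with no annotator at all is an error, not a silent zero.

## Agreement statistics

Cohen's κ = (p₀ − pₑ)/(1 − pₑ) is computed per class over the components
both experts annotated, from the binary marginals. Fleiss' κ extends this
to m ≥ 3 raters with pooled class proportions; rows must be rated by
exactly m raters (subsampling ragged tables is the caller's decision, not
an implicit behavior). Both are implemented directly from the formulas —
five-line computations — because the degenerate case pₑ = 1 (both raters
constant, identical marginals) needs defined behavior: 1.0 on perfect
agreement, else 0.0, with a warning. Tests cross-check both statistics
against the scikit-learn and statsmodels implementations.

The inter-expert correlation (IEC) is the mean over jointly annotated
components of the Pearson correlation between two experts' binary
per-component label vectors. Components where either vector is constant
(correlation undefined) are skipped and counted. Agreement is computed
after class merging, on the final class set.

## Features

All features are deterministic functions of a component's topomap weights
w (one per channel) and source time series. Weights are normalized to unit
sum of absolute values, preserving sign. Because an ICA component is only
defined up to a *joint* sign flip of weights and source, sign-sensitive
quantities (SED's signed means, signed template correlations) are computed
after orienting the component so its largest-magnitude weight is positive;
every |·|-based feature is invariant to scaling and to the joint flip by
construction.

- **Kurtosis**: the fourth standardized moment, Pearson convention (a
  Gaussian scores 3, a sinusoid 1.5), computed per epoch and averaged;
  zero-variance epochs are skipped with a warning. An excess-kurtosis flag
  is available in the config.
- **Max epoch variance**: per-epoch variances with the top ceil(0.01·n)
  values removed from the statistic entirely, then max/mean of the
  remainder. The trim makes the ratio robust to isolated huge epochs while
  still flagging components with sparse large deflections (blinks).
- **SAD / SVD / SED**: frontal-minus-posterior mean and variance of |w|,
  and the difference of the absolute left/right periocular mean weights.
  The regional sets default to frontal {Fp1,Fpz,Fp2,F3,Fz,F4,F7,F8},
  posterior {P3,Pz,P4,O1,Oz,O2,P7,P8}, left eye {Fp1,F7}, right eye
  {Fp2,F8}; all intersect with the montage (missing members dropped with a
  warning) and are overridable. SED's default convention is
  |mean left| − |mean right|; the alternative |mean left − mean right|,
  which responds to dipolar saccade topographies, is a config switch.
- **MIF**: integrated PSD over [20, min(100, Nyquist)] divided by the
  integrated PSD over all positive frequencies; lies in [0, 1] and is high
  for myogenic components.
- **Template correlations**: Pearson correlation of each epoch with a
  z-scored blink template (centered Gaussian hump, σ = 10% of epoch
  length) and saccade template (logistic step at mid-epoch); the reported
  value is the maximum absolute correlation over epochs, signed by the
  correlation at the maximizing epoch. The sign can invert when the
  best-matching epoch carries an off-center event, so the magnitude is the
  class signature.
- **MT / AT**: Σ|w| inside minus outside the mu set {Fp1,Fpz,Fp2,F3,Fz,F4,
  FC3,FCz,FC4,C3,Cz,C4} and the alpha set {C3,Cz,C4,CP3,CPz,CP4,P3,Pz,P4,
  O1,Oz,O2} (C3/Cz/C4 belong to both), on normalized weights. On a uniform
  31-channel topomap both equal (12 − 19)/31.
- **AMALB**: the amplitude spectrum is the square root of the epoch-averaged
  Welch PSD; AMALB is the sum of amplitudes at grid frequencies inside
  [6, 12] Hz divided by the sum outside, up to Nyquist. The band extends
  down to 6 Hz because children's alpha sits lower than the adult 8–12 Hz.
  The 12–13 Hz bins belong to the denominator (the band is the closed
  interval [6, 12], nothing else).

Spectral estimation is Welch with 1-second Hann segments and 50% overlap,
per epoch then averaged, giving ≤ 1 Hz grid resolution; integrated PSD
matches signal variance within 5% on stationary noise (checked). A
continuous recording is treated as a single epoch so epoch-wise features
degrade gracefully; features that require ≥ 2 epochs (max epoch variance)
report an error that `extract_features` records as a missing value with
the component flagged.

## Classification

Per class, one-vs-rest models with fixed hyperparameters — logistic
regression (C = 1.0, L2, liblinear), linear SVM (C = 1.0), gradient-boosted
trees (30 estimators, max depth 4) — validated by repeated stratified
70/30 train/test splits (default 50 repeats). No hyperparameters are tuned.
Stratification is required to keep rare classes represented in every test
set; without it an 8%-positive class frequently yields degenerate PR
curves. Linear models see features standardized on the training fold only;
trees take raw features. Ranking scores are probabilities for logistic
regression and the trees, signed margins for the SVM (no calibration). F1
is evaluated at each model's natural decision point (probability 0.5,
margin 0). ROC and PR curves are interpolated to a 101-point grid; the
band is the pointwise 2.5/97.5 percentile over repeats.

Model selection is balance-aware: a class whose positive fraction is below
0.25 is judged on mean PR-AUC, otherwise on mean ROC-AUC; ties break on
the other metric, then on the fixed family order (logreg, trees, svm).
The 0.25 default encodes "relatively balanced" as used for classes with
roughly a third of positives versus rare classes near 10%.

Final models are fit on all complete components and exported as a
self-describing JSON archive (family, hyperparameters, feature schema,
scaler parameters, coefficients or the boosters' own JSON) rather than an
opaque pickle; prediction validates the input schema and reports missing
feature columns.

## Synthetic data

The generator emulates a pediatric ERP recording: a 31-channel 10-10
montage (with legacy T3/T4/T5/T6 names canonicalized to T7/T8/P7/P8),
250 Hz sampling, 100 one-second epochs per component. Topographies are
parametric Gaussians over schematic 2-D electrode coordinates — occipital
for alpha, lateralized central for mu, frontal-polar for blinks,
antisymmetric periocular for horizontal eye movements, edge-concentrated
for muscle, a low-contrast gradient for heart, one dominant channel
(85–95% of absolute mass) for channel noise, and a broad dipolar pattern
for generic brain activity. Signals follow per-class recipes over a 1/f
background: amplitude-modulated 8–12 Hz for alpha; a 10 Hz arch wave
(fundamental plus second harmonic) for mu; sparse Gaussian humps at 0.3
events/s for blinks; step deflections for horizontal eye movements;
20–100 Hz band-limited bursts for muscle; biphasic spikes at 1.2 Hz for
heart; white noise for channel noise. Each component receives a random
joint sign flip of weights and signal — the true ICA sign ambiguity.
A configurable fraction of components are convex combinations of two class
recipes carrying both label sets, the motivating case for the
probabilistic vote. Everything is deterministic given the seed.

Annotation simulation models the two labeling styles observed among human
raters: a *purist* reports only the dominant activity, missing it at rate
1 − sensitivity (reporting Uncertain); a *splitter* reports every activity
present plus spurious labels at a false-label rate.

What passing tests show — and what they do not: the synthetic classes are
deliberately clean. Class-conditional feature separations (MT: mu > alpha;
AT: alpha > muscle; MIF: muscle > brain; AMALB: alpha > muscle) hold in
≥ 95% of seeds, and brain/eyes/muscle-vs-rest classification reaches mean
ROC-AUC ≥ 0.9 — in fact the linear models often separate synthetic classes
perfectly, which real ICs (volume-conducted, mixed, nonstationary) never
allow. The synthetic benchmark validates the machinery and the qualitative
orderings, not absolute performance on real EEG; it also omits volume
conduction, realistic noise coupling across components, and line noise.

## Numerical choices and edge cases

- Vote probabilities are rounded to 12 decimals before the strict
  threshold comparison; the default threshold is stored exactly as 0.33.
- Degenerate κ (pₑ = 1) returns 1.0 iff observed agreement is perfect,
  else 0.0, with a warning; undefined per-component correlations (constant
  vectors) are skipped and counted.
- All-zero weight vectors, all-constant epochs and an empty electrode set
  after montage intersection are explicit feature errors; per-component
  failures become missing values plus an error log instead of aborting the
  table.
- Splits that would produce a single-class test set are resampled with an
  incremented sub-seed (stratification makes this unreachable in
  practice).
- Dataset interchange is plain text (CSV manifest, weights table,
  per-component signal files; optionally raw little-endian float64 with
  the shape in the manifest). Weights round-trip at ≥ 12 significant
  digits, text signals at 9.

## Problem sizes used in the checks

The test suite validates the end-to-end claims on a 1,400-component
synthetic dataset (200 per IC class, the eyes class split between blink
and horizontal-movement recipes) under the full 50-repeat protocol, and
the feature-separation claims on 20 independent seeds with 6 components
per class, which is ample for comparing class means.
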