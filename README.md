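# eegic

Labeling, agreement analysis, feature extraction and classification for EEG
independent components (ICs).

Cleaning EEG with ICA requires deciding, for every independent component,
whether it carries brain activity or an artifact (eye movements, muscle,
heartbeat, a broken channel) — and, among brain components, whether it is an
occipital alpha rhythm or a sensorimotor mu rhythm. In practice these
decisions come from human experts who often disagree, and from supervised
classifiers trained on those expert labels. `eegic` is a library (with a
thin CLI) for the whole computational chain around that problem, aimed at
EEG researchers building or evaluating automatic IC classifiers:

- **Multi-expert label aggregation.** Each expert annotates component *c*
  with a label set. Under the *majority vote*, the probability of class *k*
  is the mean of the binary votes over the experts who annotated *c*; under
  the *probabilistic vote*, each expert's single vote is split equally over
  the *k* classes they chose (1/k each) before averaging. Either probability
  is compared strictly against a threshold (default 0.33) to form the
  boolean training target, so a three-way split (p = 1/3) still counts.
  Horizontal/vertical eye movements are merged into Eyes, line-noise labels
  dropped, and Alpha/Mu labels imply Brain before voting.
- **Inter-expert agreement.** Per-class Cohen's κ = (p₀ − pₑ)/(1 − pₑ) for
  two experts, Fleiss' κ for more, and the inter-expert correlation (IEC):
  the mean over components of the Pearson correlation between two experts'
  binary label vectors.
- **Spatio-spectral features** per component: epoch-averaged kurtosis,
  trimmed max/mean epoch-variance ratio, ADJUST-style SAD/SVD/SED
  topographic contrasts, the myogenic fraction MIF (relative 20–100 Hz
  power), blink/saccade template correlations, and three rhythm-oriented
  features — MT = Σ_{e∈Mu}|w_e| − Σ_{e∉Mu}|w_e| and the analogous AT over a
  central-posterior set, plus AMALB, the ratio of average spectral amplitude
  inside 6–12 Hz to the average outside it.
- **Classification.** Per-class one-vs-rest models with fixed
  hyperparameters (logistic regression C=1, linear SVM C=1,
  gradient-boosted trees with 30 estimators of depth 4), validated by 50
  repeated stratified 70/30 splits reporting ROC-AUC, PR-AUC and F1 with
  mean curves and 95% bands; model selection uses ROC-AUC for balanced
  classes and PR-AUC for rare ones. Models export to a self-describing JSON
  archive.
- **Synthetic data.** A seeded generator of class-typical topographies
  (parametric patterns over 2-D 10-10 coordinates) and signals (occipital
  8–12 Hz alpha, central arch-shaped mu, frontal blink humps, >20 Hz
  muscle bursts, QRS-like heart spikes, single-channel noise), plus
  simulated purist/splitter annotators — so every stage runs and is tested
  without any EEG download.

## Worked example

`examples/01_vote_aggregation.py` aggregates one mixed component annotated
by a "splitter" ({Eyes, Muscle, Heart, Brain}) and a "purist" ({Brain}):

```
     majority vote: Brain=1.000, Eyes=0.500, Muscle=0.500, Heart=0.500  ->  classes kept: ['Brain', 'Eyes', 'Muscle', 'Heart']
probabilistic vote: Brain=0.625, Eyes=0.125, Muscle=0.125, Heart=0.125  ->  classes kept: ['Brain']
```

Majority voting keeps every class the splitter mentioned (0.5 > 0.33);
probabilistic voting dilutes the four-way annotation to 0.25 per class, so
only Brain ((0.25 + 1)/2 = 0.625) survives the threshold — the vote-split
rule is what disambiguates mixed components.

`examples/03_feature_extraction.py` prints per-class feature means on
synthetic data (seed 5):

```
           MT     AT  AMALB    MIF  kurtosis
alpha  -0.915  0.870  1.011  0.014     1.847
brain  -0.148 -0.025  0.156  0.253     2.837
mu      0.331 -0.247  0.599  0.046     2.087
muscle -0.865 -0.848  0.004  0.998     2.957
```

Mu components maximize MT, alpha components AT and AMALB, muscle MIF —
the separations the classifiers rely on. The remaining examples cover
agreement statistics and end-to-end training/selection; the same pipeline
is scriptable via the `eegic` CLI (`simulate`, `extract-features`,
`aggregate`, `agreement`, `train`, `select`, `predict`, `report`).

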