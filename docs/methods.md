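# Methods

## The problem and the model

`tierstack` predicts a binary obstetric outcome — preterm birth (PTB, the
positive and minority class) versus term birth (TB) — from mostly binary
clinical, behavioral and social risk factors, each flagged *primary*
(critical) or *secondary*. The core algorithm is a three-tier stacked
generalization:

1. **Base tier.** A roster of m diverse classifiers is trained under
   stratified k-fold cross-validation (k = 10 by default). For every
   instance i and learner j the out-of-fold (OOF) score `S[i, j]` — the
   probability of PTB from the model trained on the folds that exclude i —
   is recorded, and each learner is refit on all rows for deployment.
2. **Ensemble tier.** Fixed (non-trained) combination schemes are applied
   row-wise to the OOF predictions. Each scheme emits one meta-feature in
   [0, 1]. Defaults: arithmetic mean of scores, majority vote of hard
   labels (ties → PTB), maximum score, and the product rule (geometric
   mean, i.e. the m-th root of the product so the output stays in [0, 1]).
3. **Generalization tier.** A meta-learner (logistic regression by
   default) is trained on the s meta-features concatenated with the k_meta
   (default 3) raw features most correlated in absolute value with the
   label, selected from the feature subset active in the experiment.

The traditional stacked ensemble (SE) baseline trains the same
meta-learner directly on the n×m OOF score matrix. Both variants share
fold plans under a common seed so comparisons are paired.

The decision threshold is fixed at 0.5 on the meta-learner score; ROC
curves vary the threshold only inside evaluation. Vote ties resolve to
PTB because a missed PTB (false negative) withholds treatment from a
patient who needs it — the costlier error in this domain.

## Preprocessing protocol

Fixed order: **impute → outlier screen → SMOTE → mean cancellation**, all
statistics fitted on training rows only (a leakage guard in the test suite
asserts that transforming held-out rows never changes fitted parameters).

- **Imputation** is criticality-aware: gaps in primary features are filled
  with the feature's training mean, gaps in secondary features with the
  schema-declared default value. A critical feature with no observed
  training values is a fit error.
- **Outlier screen.** The top-5 label-correlated binary features are
  concatenated into a 5-bit code per instance; instances whose
  (code, label) pair occurs fewer than `min_count` times (default
  `max(2, ceil(0.001 n))`) are dropped from training. This is a computable
  analog of plotting the concatenated feature against the label and
  discarding points far from the central mass. Mean-imputed fractional
  cells contribute the nearer binary state to the code. The screen is
  never applied to evaluation data.
- **SMOTE** oversamples the minority class to exact parity: each synthetic
  row is `x + u (x_nn − x)` with `u ~ U(0, 1)` and `x_nn` one of the k = 5
  nearest minority neighbors (Euclidean). Applied to the training
  partition only (`smote_scope: train`), so synthetic rows never reach
  evaluation; `full` is available to mimic whole-dataset balancing.
  Synthetic values of binary features are kept continuous by default
  (`smote_round_binary` enables rounding).
- **Mean cancellation** centers every column (binary ones included) by its
  training mean, refit after screening/SMOTE so centering reflects the
  matrix the model actually trains on.

## Feature ranking

Association with the label is the absolute Pearson product-moment
correlation, which for a binary feature against the binary label equals
the phi coefficient — one code path for binary and numeric columns.
Constant columns score 0; ties break toward the lower feature index.
Absolute value is used because a strong protective factor is as
informative as a risk factor.

## Default learner roster

Five diverse, moderately performing classifiers: logistic regression,
a depth-limited decision tree (`max_depth=5`, `min_samples_leaf=25`),
Gaussian naive Bayes, k-nearest neighbors (k = 25), and a linear-kernel
SVM scored by mapping its decision margin through a logistic sigmoid.
Two of these choices deserve comment:

- **Regularization of the tree and k-NN.** In the tiered algorithm the
  meta-learner never sees individual learner scores, only scheme outputs,
  so a single overfitting base learner contaminates every meta-feature and
  cannot be down-weighted. At the problem sizes this package targets
  (thousands of rows of weak binary signals) an unpruned tree or 5-NN
  overfits; the shipped limits size each learner's complexity to that
  regime. The roster and all hyperparameters are config-driven.
- **SVM scoring.** The sigmoid-of-margin score is monotone in the SVM
  decision function and lies in [0, 1]; it is not a calibrated
  probability, but averaging-type schemes only need comparable bounded
  scores, and it avoids the heavy internal cross-validation of Platt-style
  calibration.

## Evaluation harness

Each experiment evaluates one feature-subset rule (all factors, primary
only, all secondary, top-5 secondary, primary + top-5 secondary) over
`n_trials = 10` independent trials. Per trial t: seed = base_seed + t; a
stratified 80/20 train/test row split preserving the four-case mix
(any-primary-factor presence × outcome, falling back to outcome-only
strata when a case is too small to stratify); preprocessing fitted on the
training rows; both algorithms fitted on the same split; metrics computed
on the untouched test rows. Averages over trials are macro (means of
per-trial metrics, never pooled confusion counts). Metrics are accuracy,
precision, sensitivity (PTB recall), F1, and trapezoidal AUC of the ROC
swept over unique score thresholds. Precision with no positive
predictions is defined as 0 with a warning.

The `top5_secondary` subset is resolved once per dataset by correlation
ranking over the secondary block — the analog of a fixed clinical
shortlist — rather than per trial.

## Synthetic data generator

The generator emulates the structure reported for masked obstetric
registries: n = 2,600 patients; 8 primary and 12 secondary independent
Bernoulli risk factors; latent logistic outcome
`P(PTB) = σ(β₀ + Σ wⱼ xⱼ)` with intercept β₀ = −2.2, primary log-odds
weights descending 1.5 → 0.4 and secondary weights 0.3 → 0.05; labels
drawn Bernoulli and flipped with probability 0.02 (so achievable accuracy
plateaus below 100% like real data); 1% of feature cells missing at
random (never the label). Per-factor prevalences follow the rule
*within each criticality block, prevalence declines with effect size from
20% down to 5%* — the strong clinical indicators are the moderately
common ones — which yields a PTB prevalence near 34% (clearly the
minority) and makes the planted signal recoverable by correlation
ranking: the model-implied |phi| of the strongest primary factor is ≈0.24
against ≈0.05 for the best secondary factor. Generation retries label
draws (up to 100 times) until all four patient cases (any-primary-factor
presence × outcome) are present.

What the generator does **not** emulate: correlation between risk factors
(a hook for a pairwise-correlation matrix exists), non-binary clinical
measurements, informative missingness, and the unpublished marginal
distributions of any real registry. Passing tests on this generator
demonstrate correctness and internal consistency of the pipeline, not
clinical performance on real data.

`generate_separable` is a noise-free fixture (label = OR of the first two
primary factors, no missingness) used for exactness tests: any sensible
configuration must reach held-out accuracy and AUC of 1.0 on it.

## Numerical and design notes

- All randomness flows from explicit integer seeds; repeated runs with the
  same seed are bit-identical (fold dealing, SMOTE draws, splits).
- Stratified folds are built by per-class round-robin dealing after an
  in-class shuffle, so per-fold counts of every class differ by at most 1
  even when a class has fewer members than folds (singleton folds at
  n = n_folds are supported).
- Hard labels for vote schemes derive from scores at threshold 0.5
  (`score ≥ 0.5 → 1`).
- Correlation of a zero-variance column is defined as 0 rather than NaN.
- Degenerate configuration (one learner, averaging scheme, `k_meta=0`,
  pass-through meta-learner) reproduces the single learner's predictions
  exactly; this equivalence is tested.

## Known limitations

- At the generator's default conditions the secondary factors add only
  ≈0.009 model-implied AUC over the primary factors alone, while adding
  12 weak dimensions costs diverse base learners a finite-sample penalty
  of the same order. The measured mean-AUC gap between the all-factors
  and primary-only experiments is therefore inside trial noise and its
  sign is not guaranteed; the package reports whatever the paired runs
  produce. Sensitivity-oriented metrics behave the same way.
- SMOTE balancing trades accuracy for sensitivity when prevalence is far
  from 50%: models trained on balanced data predict PTB more liberally
  than the test prevalence warrants. This is a property of the protocol,
  not a defect.
- The outlier screen assumes the screening features are binary; datasets
  dominated by continuous features should disable it or supply a custom
  rule.
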