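# Methods

## Problem setting

`copdstage` classifies the four GOLD strata of chronic obstructive pulmonary
disease (stage 0, I, II, and the merged III–IV stratum, encoded 0–3) from a
participant × feature table of lung radiomics descriptors extracted from
chest HRCT.  The package does not touch images: segmentation and radiomics
extraction are upstream concerns, and the cohort it was designed around is
private.  Everything downstream of the feature table — selection, graph
classification, benchmarking — is implemented and validated here on
synthetic cohorts with matched statistical structure.

## The combination vector

Two feature subsets are selected from the (standardized) training split and
then frozen:

* **Risk factors (K, default 3).**  Every feature is scored by the
  coefficient of determination R² of a univariate identity-link Gaussian GLM
  of the ordinal stage on that feature; the top K features are kept.  For
  this family R² equals the squared Pearson correlation, which is what the
  implementation computes (vectorized) and what the tests check against
  `statsmodels` OLS.  Ties break lexicographically on feature name so the
  ranking is deterministic.
* **Node features (d).**  A Lasso regression of stage on all features,

      (1/2n) Σᵢ (yᵢ − β₀ − xᵢᵀβ)² + λ‖β‖₁,

  over a 100-point geometric λ path spanning four decades below the smallest
  all-zero penalty.  λ* minimizes the mean CV squared error over 10
  stage-stratified folds; the non-zero-coefficient features at λ* are the
  node features.  The λ = 0 limit is solved by ordinary least squares (the
  exact minimizer there), which gives the tests a clean closed-form anchor
  alongside the soft-threshold oracle on orthonormal designs.

Design choices worth stating: the stage enters both regressions as a single
ordinal response (the merged III–IV stratum is one level), the GLM uses the
identity link (the squared-error objective above is only meaningful for a
continuous response), and the minimum-CV rule is used rather than the
1-SE rule because it maximizes selected-set stability on planted-feature
cohorts.  PCA fusion (`pca_fuse`) is provided purely as the experimental
comparator; risk factors may alternatively be the leading component scores.

## The auto-metric graph classifier

Classification happens on small episodic graphs, not on a fixed cohort
graph.  One episode holds `n_way × k_shot` labelled support nodes (default
4-way-10-shot = 40) plus query node(s).  The initial representation of a
node concatenates its d node features with a label channel: the one-hot
stage for support nodes, the uniform distribution for queries.

Per layer, with V the current (N × w) representation:

1. **Learned metric.**  For each unordered node pair, the elementwise
   absolute difference |vᵢ − vⱼ| is pushed through a 1×1 convolution stack
   (channels w → h → 1, LeakyReLU between, h = max(32, w/4)) and a logistic
   squash, giving Wᵢⱼ ∈ (0,1).  W is symmetric by construction — the network
   is evaluated once per unordered pair — and the diagonal is computed like
   any pair (zero difference).
2. **Risk-factor constraint.**  Eᵢⱼ = Πₖ exp(−(rᵢₖ − rⱼₖ)²/τₖ) over the K
   standardized risk factors, τₖ = 1 by default.  E ∈ (0,1], symmetric, unit
   diagonal; participants with dissimilar risk factors are nearly
   disconnected.  E is computed once per episode and reused by both layers.
   The Gaussian product kernel is this package's concrete choice of
   "probability constraint"; it is isolated in one function
   (`edge_constraint_matrix`) so it can be swapped.
3. **Adjacency and update.**  Ã = row-normalize(W ⊙ E), so Ã is a
   convex-combination operator and layer scale is independent of N (a row of
   all-zero edge mass raises a degenerate-graph error rather than dividing
   by zero).  The update is Gn(V) = LeakyReLU(FC(Ã V)) with hidden width 48,
   and the next representation is the concatenation [V ‖ Gn(V)].

Two layers are used; W is recomputed from the current representation at each
layer (the "auto-metric" reading: the metric adapts as representations
deepen).  After the second update block a linear head and softmax produce
query-stage probabilities; argmax ties resolve to the lowest stage.

**Meta-training.**  Each iteration samples a batch (default 28) of
independent episodes from the training pool — the query is itself a training
sample — and applies one Adam step (lr 1e-3) on the mean query
cross-entropy.  Defaults follow the published recipe where one is stated:
600 iterations, batch 28, 4-way-10-shot, seed 42.  The total number of
training episodes (iterations × batch) is the count of meta tasks.

**Prediction.**  A held-out row is inserted as the single unknown node into
`ensemble_size` (default 5) independently sampled support graphs and the
softmax outputs are averaged.  A single published-style graph corresponds to
`ensemble_size=1`; the ensemble only reduces support-draw variance.

By default the risk factors feed only E; a config switch
(`concat_risk_to_nodes`) additionally concatenates them into the node
representation for users who read the combination vector that way.

## Numerical implementation

The network is small but its adjacency depends on the representations, so
gradients are obtained from a purpose-built reverse-mode autodiff engine
over numpy arrays (`copdstage.autodiff`), verified against central finite
differences in the test suite (worst error ~1e-10 away from LeakyReLU
kinks).  The pairwise metric is fused into a single hand-backpropagated
operation over the N(N+1)/2 unordered pairs; this is an exact
reformulation — loss histories are bit-identical to the naive N² version —
that roughly halves memory traffic, the model's actual bottleneck.  All
computation is float64 and seeded; two runs of `fit()` with the same seed
produce identical loss histories.  Checkpoints are a single JSON file
(float64 round-trips exactly through `repr`).

One environment-era note: the published logistic-regression definition uses
the liblinear solver, which handled multiclass one-vs-rest implicitly in
older scikit-learn; current scikit-learn makes that explicit, so the
baseline wraps `LogisticRegressionCV(solver="liblinear")` in
`OneVsRestClassifier` — the same effective model.

## The synthetic cohort generator

`generate_cohort` emulates the statistical shape the pipeline assumes:

* four ordered classes with default strata sizes 129/108/121/107 (the
  reference cohort's GOLD distribution) and feature count 1316;
* informative features shift their class mean by `effect_size` within-class
  SDs per adjacent stage (μ_c = c · effect_size · noise_sd) — the monotone
  tissue-change assumption made explicit;
* features live in correlated blocks (default size 8, within-block
  correlation ρ = 0.5 via a shared latent factor with loading √ρ), mimicking
  the redundancy of wavelet/LoG-derived radiomics families; informative
  columns are spread round-robin across blocks;
* everything else is pure Gaussian noise.

`generate_cnn_like_features` reuses the same model with one block per
feature map (default 512 maps of 3×3×3 → 13,824 columns), emulating
flattened 3D-CNN encoder output.

What the generator does **not** emulate: heavy-tailed and bounded radiomics
distributions, scanner/protocol batch effects, nonlinear feature–stage
relationships, label noise from spirometry variability, and class-dependent
covariance.  Passing tests therefore demonstrate that the pipeline's
machinery is correct and that it recovers planted structure under its own
assumptions — not that the published clinical accuracies transfer.

## Validation study and problem sizes

`copdstage.validation.run_recovery_study` is the package's end-to-end check,
used by both the acceptance script and the test suite.  Cohort: 4 × 80
participants, 200 features (20 informative, effect size 2.0, ρ = 0.5),
stratified 70/30 split.  It verifies that Lasso recovers ≥ 80 % of the
planted features, that the full pipeline (GLM K=3 + Lasso node features +
graph classifier, 600 iterations × 28 episodes) reaches high held-out
accuracy, that retraining on permuted labels collapses to chance (≈ 0.25
for four balanced classes), and that the classifier's macro one-vs-rest AUC
is within 0.05 of the best of the six reference baselines on the same
selected features.  These sizes are the package's chosen desk scale: large
enough for the selection stage to be well-posed, small enough that the whole
study runs in minutes on one CPU.  The experiment grid
(`run_experiment_grid`) reproduces the structure of the published
Experiments 1–4 at configurable scale; its `--quick` mode substitutes
lighter iterative-baseline settings (smaller MLP/LR iteration caps) and a
single AMGNN fit per cell (`amgnn_cv_folds=1`) so a smoke run completes
promptly, while the benchmark configuration remains the default elsewhere.

## Known limitations

* The edge-constraint kernel is a declared stand-in for an unpublished
  formula; only its contract (symmetric, unit diagonal, (0,1] range,
  similarity-gating semantics) is fixed.
* The GLM link and the Lasso response encoding are the package's concrete
  readings of an underspecified recipe; multinomial/ordinal-logit variants
  are deliberately out of scope.
* A new participant requires re-running episodic inference (and the model
  must be retrained to incorporate new labelled data) — inherent to the
  episodic design.
* Metrics assume all four stages present in the evaluation split; a missing
  stage's AUC is excluded from the macro mean with a warning.
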