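# copdstage

Four-class GOLD staging of chronic obstructive pulmonary disease (COPD) from
lung-radiomics feature tables, using a **combination vector** of selected
features and an **auto-metric graph neural network (AMGNN)** trained by
episodic few-shot meta-learning.

COPD severity is graded by spirometry into GOLD stages; radiomics features
computed from chest HRCT capture the underlying tissue change directly.
Given a participant × feature table (n ≈ 465, p ≈ 1316 in the setting this
package targets) with a stage label in {0, I, II, III–IV}, the pipeline is:

1. **Risk factors (K = 3).**  Rank every feature by the R² of a univariate
   identity-link Gaussian GLM of the ordinal stage y ∈ {0,1,2,3} on that
   feature, g(μ_y) = β₀ + β·x; keep the top K.
2. **Node features (d).**  Lasso with 10-fold cross-validation,
   argmin (1/2n) Σᵢ(yᵢ − β₀ − xᵢᵀβ)² + λ‖β‖₁, keeping the features with
   non-zero coefficients at the CV-optimal λ.
3. **Classification.**  Episodic graphs of 40 labelled support nodes
   (4-way-10-shot) plus query nodes.  Per layer, a learned metric turns
   pairwise absolute feature differences |vᵢ − vⱼ| into edge weights
   W = σ(f_θ(|vᵢ − vⱼ|)) via a 1×1-kernel convolution stack; the K risk
   factors gate edges through a constraint matrix
   E_ij = Πₖ exp(−(r_ik − r_jk)²/τₖ); the adjacency is the row-normalized
   Ã = W ⊙ E and nodes update as V ← [V ‖ LeakyReLU(FC(Ã V))].  Two layers,
   then softmax on the query rows.  Meta-training: 600 iterations of 28
   independent episodes each, Adam, cross-entropy on the query.

The six standard classifiers the method is benchmarked against (SVM, MLP,
random forest, logistic regression, gradient boosting, LDA) and the
Experiment 1–4 comparison grids are included, as is a synthetic-cohort
generator that reproduces the statistical shape of the clinical data
(ordered stage-mean shifts, correlated wavelet/LoG-style feature blocks) so
the entire pipeline is testable without the private cohort.  See
`docs/methods.md` for the model details and design decisions.

## Worked example

```python
import numpy as np
from copdstage import (CohortSpec, generate_cohort, stratified_split, standardize,
                       lasso_select, glm_rank, build_combination, AutoMetricGNN,
                       compute_metrics)

spec = CohortSpec(n_per_class=(40, 40, 40, 40), p_total=60, p_informative=10,
                  effect_size=2.0, seed=7)
table, labels, truth = generate_cohort(spec)
train_ids, test_ids = stratified_split(labels, test_fraction=0.3, seed=0)
std, _ = standardize(table, fit_on=train_ids)
X_train, y_train = std.select_samples(train_ids), labels.select_samples(train_ids)

lasso = lasso_select(X_train, y_train, n_folds=10, seed=0)
_, risk = glm_rank(X_train, y_train, K=3)
combo = build_combination(risk, lasso.selected)
print(f"combination vector: K={combo.K} risk factors + d={combo.d} node features")
print(f"planted features recovered: {len(set(lasso.selected) & set(truth))}/{len(truth)}")

model = AutoMetricGNN(X_train, y_train, combo, iterations=150, batch_size=8, seed=42)
res = model.fit()
print(res.summary())

preds, probs = res.predict(std.select_samples(test_ids), seed=1)
print(compute_metrics(labels.select_samples(test_ids).stage, preds, probs))
```

prints

```
combination vector: K=3 risk factors + d=38 node features
planted features recovered: 10/10
Auto-Metric Graph Neural Network Results
==============================================
episodes per step           8
episode shape               4-way-10-shot + 1 query
node features (d)           38
risk factors (K)            3
learnable parameters        10982
iterations run              150
mean loss (first 50 it)     0.9784
mean loss (last 50 it)      0.1033
final loss                  0.0497
==============================================
accuracy=0.938 precision=0.945 recall=0.938 f1=0.935 auc=0.997
```

The combination vector found all ten planted informative features; the mean
episode cross-entropy fell by an order of magnitude over training; and the
held-out split of 48 participants is staged with accuracy 0.938 and macro
one-vs-rest AUC 0.997 (the synthetic cohort is deliberately well separated —
effect size 2 SD per adjacent stage).

The same pipeline is available from the shell:

```bash
copdstage simulate --seed 42 --out cohort.csv
copdstage select   --input-csv cohort.csv --k 3 --out-dir sel/
copdstage train    --input-csv cohort.csv --combination sel/combination_vector.json --out-dir fit/
copdstage evaluate --input-csv cohort.csv --checkpoint fit/checkpoint.json --out-dir eval/
copdstage grid --quick --out-dir grid/    # the full Experiment 1-4 design, smoke scale
```

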