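"""Benchmarking harness: baselines, CV model selection, experiment grids.

Reproduces the published experimental design on any (typically synthetic)
cohort: six reference classifiers under different feature selectors
(Experiment 1) and the auto-metric GNN with K = 2..6 risk factors chosen by
PCA or GLM crossed with node-feature sources (Experiments 2-4).  The printed
clinical results themselves are not reproducible (the cohort is private);
the harness reproduces the *structure* of the comparison.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .amgnn import AMGNNConfig, AutoMetricGNN
from .cohort import FeatureTable, StageLabels, generate_cohort, stratified_split
from .metrics import MetricsReport, compute_metrics
from .selection import (
    CombinationVectorSpec,
    build_combination,
    glm_rank,
    lasso_select,
    pca_fuse,
    standardize,
)

__all__ = [
    "ExperimentResult",
    "ConfigurationError",
    "make_classifier",
    "cross_validate",
    "run_baselines",
    "run_experiment_grid",
    "CLASSIFIER_KEYS",
]


class ConfigurationError(ValueError):
    pass


CLASSIFIER_KEYS = ("svm", "mlp", "rf", "lr", "gb", "lda")


def make_classifier(key: str, seed: int = 0, quick: bool = False):
    """The six reference classifiers, configured as in the published benchmark.

    `quick` substitutes lighter settings for the iterative models (MLP/LR) so
    smoke runs finish promptly; the benchmark configuration is the default.
    """
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
    from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
    from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
    from sklearn.neural_network import MLPClassifier
    from sklearn.svm import SVC

    if key == "svm":
        return SVC(kernel="rbf", probability=True, random_state=seed)
    if key == "mlp":
        return MLPClassifier(
            hidden_layer_sizes=(400, 100),
            alpha=0.01,
            max_iter=200 if quick else 10000,
            random_state=seed,
        )
    if key == "rf":
        return RandomForestClassifier(n_estimators=200, random_state=seed)
    if key == "lr":
        if quick:
            return LogisticRegression(max_iter=2000)
        # liblinear is binary-only in current scikit-learn; the OvR wrapper
        # reproduces the one-vs-rest behavior the solver historically applied
        from sklearn.multiclass import OneVsRestClassifier

        return OneVsRestClassifier(
            LogisticRegressionCV(max_iter=100000, solver="liblinear", random_state=seed)
        )
    if key == "gb":
        return GradientBoostingClassifier(random_state=seed)
    if key == "lda":
        return LinearDiscriminantAnalysis()
    raise ConfigurationError(f"unknown classifier key {key!r}; expected one of {CLASSIFIER_KEYS}")


@dataclass
class ExperimentResult:
    experiment_id: str
    feature_source: str
    selector: str
    classifier: str
    metrics: MetricsReport | None
    K: int | None = None
    seed: int = 0
    error: str | None = None

    def row(self) -> dict:
        base = {
            "experiment": self.experiment_id,
            "feature_source": self.feature_source,
            "selector": self.selector,
            "K": self.K,
            "classifier": self.classifier,
        }
        if self.metrics is not None:
            base.update({k: round(v, 6) for k, v in self.metrics.as_dict().items()})
        else:
            base["error"] = self.error
        return base


def cross_validate(X: np.ndarray, y: np.ndarray, factory, n_folds: int = 5, seed: int = 0):
    """Stratified K-fold model selection by macro one-vs-rest AUC.

    `factory()` returns a fresh unfitted estimator with fit / predict /
    predict_proba.  Returns (per-fold MetricsReports, model refitted on the
    best fold's training portion, best fold index).
    """
    from sklearn.model_selection import StratifiedKFold

    if n_folds < 2:
        raise ConfigurationError("n_folds must be >= 2")
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < n_folds:
        raise ConfigurationError("a stage has fewer samples than folds; stratification impossible")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    reports = []
    models = []
    for train_idx, val_idx in skf.split(X, y):
        model = factory()
        model.fit(X[train_idx], y[train_idx])
        probs = model.predict_proba(X[val_idx])
        probs = _expand_proba(probs, getattr(model, "classes_", None))
        preds = probs.argmax(axis=1)
        reports.append(compute_metrics(y[val_idx], preds, probs))
        models.append(model)
    aucs = [r.auc_macro_ovr for r in reports]
    best = int(np.nanargmax(aucs))
    return reports, models[best], best


def _expand_proba(probs: np.ndarray, classes) -> np.ndarray:
    """Map predict_proba columns onto the full 4-stage layout."""
    if classes is None or len(classes) == 4:
        return probs
    full = np.zeros((probs.shape[0], 4))
    for j, c in enumerate(classes):
        full[:, int(c)] = probs[:, j]
    return full


def _evaluate_model(model, X_test, y_test) -> MetricsReport:
    probs = _expand_proba(model.predict_proba(X_test), getattr(model, "classes_", None))
    preds = probs.argmax(axis=1)
    return compute_metrics(y_test, preds, probs)


def run_baselines(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    classifiers=CLASSIFIER_KEYS,
    n_folds: int = 5,
    seed: int = 0,
    quick: bool = False,
    experiment_id: str = "exp1",
    feature_source: str = "radiomics-like",
    selector: str = "raw",
):
    """Fit the six reference classifiers under best-AUC K-fold selection."""
    results = []
    for key in classifiers:
        make_classifier(key, seed, quick)  # validate the key eagerly
        _, best_model, _ = cross_validate(
            X_train, y_train, lambda k=key: make_classifier(k, seed, quick), n_folds, seed
        )
        metrics = _evaluate_model(best_model, X_test, y_test)
        results.append(
            ExperimentResult(experiment_id, feature_source, selector, key, metrics, seed=seed)
        )
    return results


# ---------------------------------------------------------------------------
# Experiment grid


@dataclass
class GridConfig:
    """Layout and scale of the Experiment 1-4 grid."""

    k_range: tuple = (2, 3, 4, 5, 6)
    risk_selectors: tuple = ("pca", "glm")
    classifiers: tuple = CLASSIFIER_KEYS
    n_folds: int = 5
    amgnn: AMGNNConfig = field(default_factory=AMGNNConfig)
    amgnn_cv_folds: int = 1
    quick: bool = False
    seed: int = 42


def _risk_factors(
    method: str,
    K: int,
    source_table: FeatureTable,
    source_labels: StageLabels,
    working: dict,
):
    """Risk-factor columns by GLM ranking or PCA fusion of `source_table`.

    GLM returns existing column names; PCA appends derived score columns
    (``riskpc_*``) to every split's working table and returns their names.
    """
    if method == "glm":
        _, top = glm_rank(source_table, source_labels, K)
        return top
    if method == "pca":
        scores, pca = pca_fuse(source_table, K)
        names = [f"riskpc_{source_table.n_features}_{i + 1:02d}" for i in range(K)]
        mu = scores.values.mean(axis=0)
        sd = scores.values.std(axis=0)
        sd[sd == 0] = 1.0
        for split, tbl in list(working.items()):
            rows = tbl.select_features(source_table.feature_names).values
            sc = (pca.transform(rows) - mu) / sd  # standardized like the other features
            merged = FeatureTable(
                tbl.sample_ids,
                tbl.feature_names + names,
                np.concatenate([tbl.values, sc], axis=-1),
            )
            working[split] = merged
        return names
    raise ConfigurationError(f"unknown risk selector {method!r}")


def _amgnn_cell(
    working: dict,
    labels_train: StageLabels,
    labels_test: StageLabels,
    spec: CombinationVectorSpec,
    grid: GridConfig,
):
    cfg = grid.amgnn
    model = AutoMetricGNN(working["train"], labels_train, spec, config=cfg)
    res = model.fit()
    _, probs = res.predict(working["test"], seed=cfg.seed)
    preds = probs.argmax(axis=1)
    return compute_metrics(labels_test.stage, preds, probs)


def run_experiment_grid(
    table: FeatureTable,
    labels: StageLabels,
    grid: GridConfig | None = None,
    out_dir=None,
    feature_source: str = "radiomics-like",
    test_fraction: float = 0.3,
):
    """Run the Experiment 1-4 design on one cohort; returns results + tables.

    Infeasible cells (e.g. Lasso selecting nothing, K exceeding the feature
    count) are recorded as failed and the run continues.
    """
    grid = grid or GridConfig()
    seed = grid.seed
    train_ids, test_ids = stratified_split(labels, test_fraction, seed)
    y_train = labels.select_samples(train_ids)
    y_test = labels.select_samples(test_ids)

    std_all, report = standardize(table, fit_on=train_ids)
    base = {
        "train": std_all.select_samples(train_ids),
        "test": std_all.select_samples(test_ids),
    }

    lasso_folds = int(min(10, np.bincount(y_train.stage, minlength=4).min()))
    try:
        lasso = lasso_select(base["train"], y_train, n_folds=lasso_folds, seed=seed)
        lasso_names = lasso.selected
    except Exception:
        lasso_names = []
    d = len(lasso_names)
    _, glm_names = glm_rank(base["train"], y_train, max(d, 1))

    results: list[ExperimentResult] = []

    # ---- Experiment 1: six classifiers x feature selectors -----------------
    def matrix(names):
        return (
            base["train"].select_features(names).values,
            base["test"].select_features(names).values,
        )

    n_comp_cap = min(base["train"].n_samples - 1, base["train"].n_features)
    selectors: dict = {"raw": list(base["train"].feature_names)}
    if d:
        selectors["lasso"] = lasso_names
        selectors["glm"] = glm_names
    pca_tables = None
    if d:
        n_comp = min(d, n_comp_cap)
        scores, pca = pca_fuse(base["train"], n_comp)
        pca_tables = (
            scores.values,
            pca.transform(base["test"].values),
        )
    for sel, names in selectors.items():
        Xtr, Xte = matrix(names)
        try:
            results += run_baselines(
                Xtr, y_train.stage, Xte, y_test.stage,
                classifiers=grid.classifiers, n_folds=grid.n_folds, seed=seed,
                quick=grid.quick, feature_source=feature_source, selector=sel,
            )
        except Exception as exc:  # infeasible cell: record and continue
            results.append(
                ExperimentResult("exp1", feature_source, sel, "*", None, seed=seed, error=str(exc))
            )
    if pca_tables is not None:
        pca_cases = {"pca": pca_tables}
        for extra_sel, names in (("lasso+pca", lasso_names), ("glm+pca", glm_names)):
            Xtr, Xte = matrix(names)
            pca_cases[extra_sel] = (
                np.concatenate([Xtr, pca_tables[0]], axis=1),
                np.concatenate([Xte, pca_tables[1]], axis=1),
            )
        for sel, (Xtr, Xte) in pca_cases.items():
            try:
                results += run_baselines(
                    Xtr, y_train.stage, Xte, y_test.stage,
                    classifiers=grid.classifiers, n_folds=grid.n_folds, seed=seed,
                    quick=grid.quick, feature_source=feature_source, selector=sel,
                )
            except Exception as exc:
                results.append(
                    ExperimentResult("exp1", feature_source, sel, "*", None, seed=seed, error=str(exc))
                )

    # ---- Experiments 2-4: AMGNN over K x risk-selector x node source -------
    # exp2: nodes = raw features, risk from raw; exp3: nodes = lasso-selected,
    # risk from the selected set; exp4: nodes = lasso-selected, risk from raw.
    node_sources = {
        "exp2": list(base["train"].feature_names),
        "exp3": lasso_names,
        "exp4": lasso_names,
    }
    risk_sources = {
        "exp2": list(base["train"].feature_names),
        "exp3": lasso_names,
        "exp4": list(base["train"].feature_names),
    }
    for exp_id in ("exp2", "exp3", "exp4"):
        node_names = node_sources[exp_id]
        for method in grid.risk_selectors:
            for K in grid.k_range:
                working = dict(base)
                try:
                    if not node_names:
                        raise ConfigurationError("empty node-feature set")
                    src = working["train"].select_features(risk_sources[exp_id])
                    if K > min(src.n_features, src.n_samples - 1):
                        raise ConfigurationError(f"K={K} infeasible for this source")
                    risk_names = _risk_factors(method, K, src, y_train, working)
                    spec = build_combination(risk_names, node_names)
                    metrics = _amgnn_cell(working, y_train, y_test, spec, grid)
                    results.append(
                        ExperimentResult(
                            exp_id, feature_source, method, "amgnn", metrics, K=K, seed=seed
                        )
                    )
                except Exception as exc:
                    results.append(
                        ExperimentResult(
                            exp_id, feature_source, method, "amgnn", None, K=K, seed=seed,
                            error=str(exc),
                        )
                    )

    tables = _result_tables(results)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for exp_id, df in tables.items():
            df.to_csv(out_dir / f"{exp_id}_{feature_source}.csv", index=False)
        combined = [r.row() for r in results]
        with open(out_dir / f"results_{feature_source}.json", "w", encoding="utf-8") as fh:
            json.dump(combined, fh, indent=2)
    return results, tables


def _result_tables(results) -> dict:
    tables = {}
    for exp_id in sorted({r.experiment_id for r in results}):
        rows = [r.row() for r in results if r.experiment_id == exp_id]
        tables[exp_id] = pd.DataFrame(rows)
    return tables
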