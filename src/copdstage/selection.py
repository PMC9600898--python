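"""Construction of the radiomics combination vector.

The graph classifier consumes two feature sets selected from the same table:

* K *risk factors* — the features with the largest univariate R^2 against
  the ordinal GOLD stage under an identity-link Gaussian GLM.  They gate the
  graph's edges (the constraint matrix E).
* d *node features* — the non-zero-coefficient features of a Lasso regression
  of stage on all features, with the penalty chosen by 10-fold
  cross-validation.  They form the per-node representation.

Stages are encoded ordinally (0, 1, 2, 3; 3 is the merged III-IV stratum) so
both selectors regress a single continuous response.  PCA fusion is provided
as the experimental comparator.  Selection is meant to be fitted on the
training split only and then frozen.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import FeatureTable, StageLabels

__all__ = [
    "StandardizationReport",
    "GlmFit",
    "LassoFit",
    "CombinationVectorSpec",
    "SelectionError",
    "standardize",
    "glm_rank",
    "lasso_select",
    "pca_fuse",
    "build_combination",
]


class SelectionError(ValueError):
    pass


@dataclass
class StandardizationReport:
    """Frozen per-feature location/scale plus the dropped (zero-variance) columns."""

    feature_names: list
    means: np.ndarray
    sds: np.ndarray
    dropped: list

    def apply(self, table: FeatureTable) -> FeatureTable:
        sub = table.select_features(self.feature_names)
        return FeatureTable(
            sub.sample_ids, sub.feature_names, (sub.values - self.means) / self.sds
        )


def standardize(table: FeatureTable, fit_on=None):
    """Zero-mean/unit-SD transform fitted on `fit_on` rows, applied to all rows.

    Zero-variance columns (on the fit rows) carry no information and are
    dropped; their names are listed in the report.
    """
    fit_ids = list(fit_on) if fit_on is not None else list(table.sample_ids)
    if not fit_ids:
        raise SelectionError("fit_on must be non-empty")
    fit_rows = table.select_samples(fit_ids).values
    means = fit_rows.mean(axis=0)
    sds = fit_rows.std(axis=0, ddof=0)
    keep = sds > 0
    if not keep.any():
        raise SelectionError("all columns are zero-variance on the fit rows")
    names = [n for n, k in zip(table.feature_names, keep) if k]
    dropped = [n for n, k in zip(table.feature_names, keep) if not k]
    report = StandardizationReport(names, means[keep], sds[keep], dropped)
    return report.apply(table), report


@dataclass
class GlmFit:
    """One univariate identity-link Gaussian fit: stage ~ beta0 + beta * x_j."""

    feature_name: str
    beta0: float
    beta: float
    r_squared: float


def glm_rank(X: FeatureTable, y: StageLabels, K: int):
    """Rank features by univariate GLM R^2; return (all fits sorted, top-K names).

    For an identity-link Gaussian GLM the coefficient of determination equals
    the squared Pearson correlation of (x_j, y).  Zero-variance features get
    R^2 = 0 by convention.  Ties break lexicographically on feature name so
    the ranking is deterministic.
    """
    if K < 1:
        raise SelectionError("K must be >= 1")
    if K > X.n_features:
        raise SelectionError(f"K={K} exceeds the {X.n_features} usable features")
    if not y.aligned_with(X):
        raise SelectionError("labels not aligned with feature table")
    yv = y.stage.astype(np.float64)
    yc = yv - yv.mean()
    ss_y = float(yc @ yc)
    xc = X.values - X.values.mean(axis=0)
    ss_x = (xc**2).sum(axis=0)
    cross = xc.T @ yc
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(ss_x > 0, cross / np.where(ss_x > 0, ss_x, 1.0), 0.0)
        r2 = np.where(ss_x > 0, cross**2 / (np.where(ss_x > 0, ss_x, 1.0) * ss_y), 0.0)
    beta0 = yv.mean() - beta * X.values.mean(axis=0)
    fits = [
        GlmFit(name, float(b0), float(b), float(min(r, 1.0)))
        for name, b0, b, r in zip(X.feature_names, beta0, beta, r2)
    ]
    fits.sort(key=lambda f: (-f.r_squared, f.feature_name))
    return fits, [f.feature_name for f in fits[:K]]


@dataclass
class LassoFit:
    """Lasso path summary: chosen penalty, coefficients, selected features."""

    lambda_path: np.ndarray
    lambda_star: float
    intercept: float
    coefficients: np.ndarray
    selected: list
    cv_folds: int
    cv_mean_mse: np.ndarray | None = None

    def report(self, feature_names) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature": feature_names, "coefficient": self.coefficients, "selected": self.coefficients != 0.0}
        )


def _lambda_path(X: np.ndarray, y: np.ndarray, n_lambdas: int, decades: float) -> np.ndarray:
    n = X.shape[0]
    yc = y - y.mean()
    lam_max = np.abs(X.T @ yc).max() / n
    return np.geomspace(lam_max, lam_max * 10.0 ** (-decades), n_lambdas)


def lasso_select(
    X: FeatureTable,
    y: StageLabels,
    n_folds: int = 10,
    seed: int = 0,
    lambda_override: float | None = None,
    n_lambdas: int = 100,
    decades: float = 4.0,
) -> LassoFit:
    """Lasso of ordinal stage on standardized features, penalty by CV.

    Minimizes ``(1/2n) * sum_i (y_i - b0 - x_i b)^2 + lambda * |b|_1`` over a
    geometric path of ``n_lambdas`` penalties spanning ``decades`` decades
    below the smallest all-zero penalty; lambda* minimizes the mean CV squared
    error over ``n_folds`` stage-stratified folds.  ``lambda_override`` skips
    the CV and fits at the given penalty (0 yields the least-squares fit).
    """
    from sklearn.linear_model import Lasso, LassoCV
    from sklearn.model_selection import StratifiedKFold

    if not y.aligned_with(X):
        raise SelectionError("labels not aligned with feature table")
    n = X.n_samples
    if not np.all(np.isfinite(X.values)):
        raise SelectionError("non-finite feature values")
    Xv = X.values
    yv = y.stage.astype(np.float64)

    if lambda_override is not None:
        if lambda_override < 0:
            raise SelectionError("lambda must be >= 0")
        if lambda_override == 0.0:
            # lambda -> 0 limit: the objective's minimizer is ordinary least squares
            A = np.column_stack([np.ones(n), Xv])
            coef, *_ = np.linalg.lstsq(A, yv, rcond=None)
            beta0, beta = float(coef[0]), coef[1:]
        else:
            model = Lasso(alpha=lambda_override, max_iter=100000)
            model.fit(Xv, yv)
            beta0, beta = float(model.intercept_), model.coef_
        selected = [n_ for n_, b in zip(X.feature_names, beta) if b != 0.0]
        path = np.array([lambda_override])
        return LassoFit(path, float(lambda_override), beta0, np.asarray(beta), selected, 0)

    if n_folds < 2 or n_folds > n:
        raise SelectionError(f"n_folds must be in [2, {n}]")
    path = _lambda_path(Xv, yv, n_lambdas, decades)
    folds = list(
        StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed).split(Xv, y.stage)
    )
    cv = LassoCV(alphas=path, cv=folds, max_iter=100000)
    cv.fit(Xv, yv)
    # sklearn sorts the path descending internally; report it that way
    order = np.argsort(cv.alphas_)[::-1]
    selected = [n_ for n_, b in zip(X.feature_names, cv.coef_) if b != 0.0]
    return LassoFit(
        lambda_path=cv.alphas_[order],
        lambda_star=float(cv.alpha_),
        intercept=float(cv.intercept_),
        coefficients=cv.coef_,
        selected=selected,
        cv_folds=n_folds,
        cv_mean_mse=cv.mse_path_.mean(axis=1)[order],
    )


def pca_fuse(X: FeatureTable, n_components: int):
    """Scores on the leading principal components of X (already standardized).

    Returns a FeatureTable of component scores (columns ``pc_01``...) ordered
    by explained variance, plus the fitted sklearn PCA object so the same
    rotation can be applied to held-out rows.
    """
    from sklearn.decomposition import PCA

    limit = min(X.n_samples - 1, X.n_features)
    if not 1 <= n_components <= limit:
        raise SelectionError(f"n_components must be in [1, {limit}]")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X.values)
    names = [f"pc_{i + 1:02d}" for i in range(n_components)]
    return FeatureTable(X.sample_ids, names, scores), pca


@dataclass
class CombinationVectorSpec:
    """Ordered combination vector: K risk-factor names then d node-feature names.

    A feature may legitimately appear in both roles.
    """

    risk_factors: list
    node_features: list

    @property
    def K(self) -> int:
        return len(self.risk_factors)

    @property
    def d(self) -> int:
        return len(self.node_features)

    @property
    def combined(self) -> list:
        return list(self.risk_factors) + list(self.node_features)

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {"risk_factors": list(self.risk_factors), "node_features": list(self.node_features)},
            indent=2,
        )
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(payload + "\n")
        return payload

    @classmethod
    def from_json(cls, source) -> "CombinationVectorSpec":
        if isinstance(source, (str, bytes)) and "{" in str(source):
            data = json.loads(source)
        else:
            with open(source, encoding="utf-8") as fh:
                data = json.load(fh)
        return cls(list(data["risk_factors"]), list(data["node_features"]))


def build_combination(risk_factors, node_features) -> CombinationVectorSpec:
    """Concatenate K risk factors and d node features into one ordered spec."""
    if not node_features:
        raise SelectionError("node_features must be non-empty")
    return CombinationVectorSpec(list(risk_factors), list(node_features))
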