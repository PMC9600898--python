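import numpy as np
import pytest

from copdstage import (
    CohortSpec,
    build_combination,
    generate_cohort,
    glm_rank,
    lasso_select,
    standardize,
    stratified_split,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A small separable cohort: 4 x 15 samples, 30 features, 6 informative."""
    spec = CohortSpec(
        n_per_class=(15, 15, 15, 15),
        p_total=30,
        p_informative=6,
        effect_size=1.5,
        block_size=5,
        rho=0.4,
        seed=11,
    )
    table, labels, truth = generate_cohort(spec)
    return table, labels, truth


@pytest.fixture(scope="session")
def small_pipeline(small_cohort):
    """Standardized split + combination vector on the small cohort."""
    table, labels, truth = small_cohort
    train_ids, test_ids = stratified_split(labels, 0.3, seed=5)
    std, report = standardize(table, fit_on=train_ids)
    X_train = std.select_samples(train_ids)
    y_train = labels.select_samples(train_ids)
    lasso = lasso_select(X_train, y_train, n_folds=5, seed=5)
    _, risk = glm_rank(X_train, y_train, 3)
    node_features = lasso.selected if lasso.selected else truth
    combo = build_combination(risk, node_features)
    return {
        "std": std,
        "train_ids": train_ids,
        "test_ids": test_ids,
        "X_train": X_train,
        "y_train": y_train,
        "X_test": std.select_samples(test_ids),
        "y_test": labels.select_samples(test_ids),
        "combo": combo,
        "truth": truth,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
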