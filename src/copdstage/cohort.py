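"""Synthetic radiomics cohorts for COPD stage classification.

The reference cohort this package targets — 465 participants with 1316
lung-radiomics features per participant and four GOLD strata (0, I, II,
III–IV merged) — is clinical and private.  This module generates feature
tables with the same statistical shape so every downstream stage (feature
selection, graph classification, benchmarking) is testable:

* four ordered classes whose informative-feature means shift monotonically
  with stage (``mu_c = c * effect_size``), emulating progressive tissue
  change across GOLD stages;
* features organised in correlated blocks (a shared latent factor per block
  with loading ``sqrt(rho)``), emulating the redundancy of wavelet/LoG-derived
  radiomics families;
* the remaining features are pure nuisance noise.

Informative columns are spread round-robin across blocks so planted signal is
not confined to a single correlated family.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CohortSpec",
    "FeatureTable",
    "StageLabels",
    "InvalidSpecError",
    "generate_cohort",
    "generate_cnn_like_features",
    "stratified_split",
]

N_STAGES = 4
#: Per-stage participant counts of the reference cohort (GOLD 0, I, II, III-IV).
DEFAULT_N_PER_CLASS = (129, 108, 121, 107)
#: Radiomics feature count per participant in the reference cohort.
DEFAULT_P_TOTAL = 1316

_FAMILIES = (
    "original",
    "wavelet-LLH",
    "wavelet-LHL",
    "wavelet-HLL",
    "wavelet-HHH",
    "log-sigma-1mm",
    "log-sigma-3mm",
    "log-sigma-5mm",
)


class InvalidSpecError(ValueError):
    """Raised for cohort specifications that violate their invariants."""


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort draw.

    ``effect_size`` is the between-adjacent-stage mean shift of each
    informative feature in units of the within-class SD (``noise_sd``).
    """

    n_per_class: tuple = DEFAULT_N_PER_CLASS
    p_total: int = DEFAULT_P_TOTAL
    p_informative: int = 100
    effect_size: float = 1.0
    block_size: int = 8
    rho: float = 0.5
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if len(self.n_per_class) != N_STAGES:
            raise InvalidSpecError("n_per_class must have one count per GOLD stage (4)")
        if any(int(n) < 1 for n in self.n_per_class):
            raise InvalidSpecError("every stage needs at least one participant")
        if self.p_total < 1 or self.block_size < 1:
            raise InvalidSpecError("p_total and block_size must be positive")
        if not 0 <= self.p_informative <= self.p_total:
            raise InvalidSpecError("p_informative must lie in [0, p_total]")
        if not 0.0 <= self.rho < 1.0:
            raise InvalidSpecError("rho must be in [0, 1)")
        if self.effect_size < 0 or self.noise_sd <= 0:
            raise InvalidSpecError("effect_size must be >= 0 and noise_sd > 0")

    @property
    def n_total(self) -> int:
        return int(sum(self.n_per_class))

    def replace(self, **kw) -> "CohortSpec":
        return dataclasses.replace(self, **kw)


@dataclass
class FeatureTable:
    """Participant x feature matrix with unique sample IDs and feature names."""

    sample_ids: list
    feature_names: list
    values: np.ndarray

    def __post_init__(self):
        self.sample_ids = list(self.sample_ids)
        self.feature_names = list(self.feature_names)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.sample_ids), len(self.feature_names)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_names)} features"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample_ids")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("duplicate feature_names")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature table contains non-finite values")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_names)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FeatureTable":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=np.float64))

    def select_features(self, names) -> "FeatureTable":
        idx = [self.feature_names.index(n) for n in names]
        return FeatureTable(self.sample_ids, list(names), self.values[:, idx])

    def select_samples(self, ids) -> "FeatureTable":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in ids]
        return FeatureTable(list(ids), self.feature_names, self.values[idx])


@dataclass
class StageLabels:
    """GOLD stage per participant: 0..3, with 3 the merged III-IV stratum."""

    sample_ids: list
    stage: np.ndarray

    def __post_init__(self):
        self.sample_ids = list(self.sample_ids)
        self.stage = np.asarray(self.stage, dtype=np.int64)
        if self.stage.shape != (len(self.sample_ids),):
            raise ValueError("one stage per sample_id required")
        if self.stage.size and (self.stage.min() < 0 or self.stage.max() > 3):
            raise ValueError("stages must lie in {0,1,2,3}")

    def __len__(self) -> int:
        return len(self.sample_ids)

    def select_samples(self, ids) -> "StageLabels":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        return StageLabels(list(ids), self.stage[[pos[s] for s in ids]])

    def aligned_with(self, table: FeatureTable) -> bool:
        return self.sample_ids == table.sample_ids


def _informative_indices(p_total: int, p_informative: int, block_size: int) -> np.ndarray:
    """Round-robin assignment of informative columns across blocks."""
    n_blocks = -(-p_total // block_size)
    chosen: list = []
    offset = 0
    while len(chosen) < p_informative:
        for b in range(n_blocks):
            col = b * block_size + offset
            if col < p_total:
                chosen.append(col)
                if len(chosen) == p_informative:
                    break
        offset += 1
        if offset >= block_size:  # all columns exhausted
            break
    return np.array(sorted(chosen[:p_informative]), dtype=np.int64)


def _feature_names(p_total: int, block_size: int) -> list:
    names = []
    for j in range(p_total):
        family = _FAMILIES[(j // block_size) % len(_FAMILIES)]
        names.append(f"{family}_f{j:04d}")
    return names


def _correlated_noise(rng: np.random.Generator, n: int, p: int, block_size: int, rho: float) -> np.ndarray:
    """Unit-variance noise with within-block correlation rho (shared latent factor)."""
    n_blocks = -(-p // block_size)
    latent = rng.standard_normal((n, n_blocks))
    eps = rng.standard_normal((n, p))
    block_of = np.arange(p) // block_size
    return np.sqrt(rho) * latent[:, block_of] + np.sqrt(1.0 - rho) * eps


def generate_cohort(spec: CohortSpec):
    """Draw one synthetic cohort.

    Returns
    -------
    (FeatureTable, StageLabels, list of str)
        The feature table, aligned stage labels, and the ground-truth names of
        the informative columns.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_total
    stages = np.repeat(np.arange(N_STAGES), [int(c) for c in spec.n_per_class])

    noise = _correlated_noise(rng, n, spec.p_total, spec.block_size, spec.rho)
    values = spec.noise_sd * noise
    info_idx = _informative_indices(spec.p_total, spec.p_informative, spec.block_size)
    if info_idx.size:
        values[:, info_idx] += (stages[:, None] * spec.effect_size) * spec.noise_sd

    sample_ids = [f"P{i + 1:04d}" for i in range(n)]
    names = _feature_names(spec.p_total, spec.block_size)
    table = FeatureTable(sample_ids, names, values)
    labels = StageLabels(sample_ids, stages)
    ground_truth = [names[j] for j in info_idx]
    return table, labels, ground_truth


def generate_cnn_like_features(
    n: int,
    n_maps: int = 512,
    map_shape: tuple = (3, 3, 3),
    seed: int = 0,
    stages: np.ndarray | None = None,
    effect_size: float = 0.0,
    p_informative: int = 0,
    rho: float = 0.3,
    noise_sd: float = 1.0,
):
    """Emulate flattened 3D-CNN encoder features (n_maps maps of map_shape).

    Same noise + class-shift model as :func:`generate_cohort`, with one
    correlated block per feature map.  ``stages`` (length n, values 0-3) is
    required whenever ``effect_size > 0`` so informative columns can shift.
    """
    if n < 1 or n_maps < 1 or any(int(s) < 1 for s in map_shape):
        raise InvalidSpecError("all dimensions must be positive")
    map_size = int(np.prod([int(s) for s in map_shape]))
    p = n_maps * map_size
    if not 0 <= p_informative <= p:
        raise InvalidSpecError("p_informative must lie in [0, p]")
    rng = np.random.default_rng(seed)
    values = noise_sd * _correlated_noise(rng, n, p, map_size, rho)
    info_idx = _informative_indices(p, p_informative, map_size)
    if info_idx.size and effect_size > 0:
        if stages is None:
            raise InvalidSpecError("stages required when effect_size > 0")
        stages = np.asarray(stages, dtype=np.int64)
        values[:, info_idx] += (stages[:, None] * effect_size) * noise_sd
    names = [f"cnn_m{j // map_size:04d}_u{j % map_size:02d}" for j in range(p)]
    sample_ids = [f"P{i + 1:04d}" for i in range(n)]
    return FeatureTable(sample_ids, names, values)


def stratified_split(labels: StageLabels, test_fraction: float = 0.3, seed: int = 0):
    """Stratified train/test split of sample IDs (default 70/30)."""
    from sklearn.model_selection import train_test_split

    train_ids, test_ids = train_test_split(
        labels.sample_ids,
        test_size=test_fraction,
        stratify=labels.stage,
        random_state=seed,
    )
    return list(train_ids), list(test_ids)
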