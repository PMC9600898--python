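"""Cohort CSV dialect, run configuration, and seed management.

One CSV holds a cohort: header row, first column ``sample_id``, last column
``gold_stage`` in {0,1,2,3}, every other column a numeric feature.  UTF-8,
comma-separated, '.' decimal.  Ground truth (the planted informative columns
of a synthetic cohort) is a plain-text list, one feature name per line.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import FeatureTable, StageLabels

__all__ = [
    "FormatError",
    "read_feature_table",
    "write_feature_table",
    "write_ground_truth",
    "read_ground_truth",
    "RunConfig",
    "derive_seed",
    "write_manifest",
]

STAGE_COLUMN = "gold_stage"
ID_COLUMN = "sample_id"


class FormatError(ValueError):
    pass


def read_feature_table(path):
    """Read one cohort CSV -> (FeatureTable, StageLabels)."""
    df = pd.read_csv(path, dtype={ID_COLUMN: str})
    for col in (ID_COLUMN, STAGE_COLUMN):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path}")
    if df[ID_COLUMN].duplicated().any():
        dupes = df.loc[df[ID_COLUMN].duplicated(), ID_COLUMN].tolist()
        raise FormatError(f"duplicate sample_ids: {dupes[:5]}")
    stage_raw = df[STAGE_COLUMN]
    stage = pd.to_numeric(stage_raw, errors="coerce")
    if stage.isna().any() or not np.array_equal(stage, stage.astype(int)):
        raise FormatError("gold_stage must be integers in {0,1,2,3}")
    stage = stage.astype(int)
    if stage.min() < 0 or stage.max() > 3:
        bad = stage[(stage < 0) | (stage > 3)]
        raise FormatError(f"gold_stage outside 0-3 at rows {bad.index.tolist()[:5]}")
    feature_cols = [c for c in df.columns if c not in (ID_COLUMN, STAGE_COLUMN)]
    feats = df[feature_cols].apply(pd.to_numeric, errors="coerce")
    if feats.isna().any().any():
        col = feats.columns[feats.isna().any()][0]
        row = int(feats.index[feats[col].isna()][0])
        raise FormatError(f"non-numeric feature cell at row {row}, column {col!r}")
    ids = df[ID_COLUMN].tolist()
    table = FeatureTable(ids, feature_cols, feats.to_numpy(dtype=np.float64))
    labels = StageLabels(ids, stage.to_numpy())
    return table, labels


def write_feature_table(table: FeatureTable, labels: StageLabels, path) -> None:
    if not labels.aligned_with(table):
        raise FormatError("labels not aligned with feature table")
    df = table.to_dataframe()
    df.insert(0, ID_COLUMN, table.sample_ids)
    df[STAGE_COLUMN] = labels.stage
    df.to_csv(path, index=False)


def write_ground_truth(names, path) -> None:
    Path(path).write_text("\n".join(names) + "\n", encoding="utf-8")


def read_ground_truth(path):
    return [line for line in Path(path).read_text(encoding="utf-8").splitlines() if line]


@dataclass
class RunConfig:
    """Full pipeline configuration; round-trips losslessly through YAML."""

    input_csv: str | None = None
    output_dir: str = "copdstage_out"
    test_fraction: float = 0.3
    master_seed: int = 42
    # selection
    n_lasso_folds: int = 10
    K: int = 3
    lambda_decades: float = 4.0
    n_lambdas: int = 100
    # AMGNN
    iterations: int = 600
    batch_size: int = 28
    n_way: int = 4
    k_shot: int = 10
    hidden_dim: int = 48
    learning_rate: float = 1e-3
    tau: float = 1.0
    ensemble_size: int = 5
    # grid
    quick: bool = False

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        text = Path(source).read_text(encoding="utf-8") if Path(str(source)).exists() else str(source)
        return cls(**yaml.safe_load(text))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def derive_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: SeedSequence(master, crc32(stage)) < 2^31."""
    ss = np.random.SeedSequence([int(master_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def write_manifest(out_dir, config: RunConfig, extra: dict | None = None) -> Path:
    """Every output directory carries the config hash and master seed."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        "config_sha256": config.digest(),
        "master_seed": config.master_seed,
        "config": asdict(config),
    }
    if extra:
        payload.update(extra)
    path = out_dir / "run_manifest.json"
    path.write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
    return path
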