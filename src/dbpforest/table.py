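"""Samples-by-features table, the interchange object between pipeline stages."""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError


@dataclass
class FeatureTable:
    """N samples x M named real-valued features, with optional binary labels.

    Written to disk as TSV: first column ``sample_id``, then ``label`` if
    labels are present, then one column per feature. Values are serialised
    with 12 significant digits — identical tables serialise to identical
    bytes, so written artifacts are reproducible given a seed.
    """

    sample_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.feature_names)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_names)} features"
            )
        if np.isnan(self.values).any():
            raise ValidationError("feature table contains missing values")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (len(self.sample_ids),):
                raise ValidationError("labels length does not match sample count")
            if not np.isin(self.labels, (0, 1)).all():
                raise ValidationError("labels must be binary 0/1")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def require_both_classes(self) -> None:
        if self.labels is None:
            raise ValidationError("operation requires labels")
        if len(np.unique(self.labels)) < 2:
            raise ValidationError("both classes must be present")

    def subset(self, names: list[str]) -> "FeatureTable":
        """Column subset in the given order; unknown names raise SchemaError."""
        index = {n: j for j, n in enumerate(self.feature_names)}
        missing = [n for n in names if n not in index]
        if missing:
            raise SchemaError(f"unknown features: {missing[:5]}")
        cols = [index[n] for n in names]
        return FeatureTable(
            sample_ids=list(self.sample_ids),
            feature_names=list(names),
            values=self.values[:, cols].copy(),
            labels=None if self.labels is None else self.labels.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "sample_id", self.sample_ids)
        if self.labels is not None:
            df.insert(1, "label", self.labels)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureTable":
        if "sample_id" not in df.columns:
            raise SchemaError("table is missing the 'sample_id' column")
        labels = df["label"].to_numpy() if "label" in df.columns else None
        feature_cols = [c for c in df.columns if c not in ("sample_id", "label")]
        return cls(
            sample_ids=df["sample_id"].astype(str).tolist(),
            feature_names=feature_cols,
            values=df[feature_cols].to_numpy(dtype=float),
            labels=labels,
        )

    def write_tsv(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.12g")

    @classmethod
    def read_tsv(cls, path: str | os.PathLike) -> "FeatureTable":
        return cls.from_frame(pd.read_csv(path, sep="\t"))
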