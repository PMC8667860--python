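"""Random-forest training, prediction and binary-classification metrics.

The final model is a forest of 800 trees, each grown to a maximum depth of
50 and allowed to consider every feature at each split. Predicted scores
are the fraction of trees voting for the positive class; the decision
threshold is fixed at 0.5 (the full ROC sweep is always available).

Reported metrics: accuracy (ACC), sensitivity (SN) and specificity (SP) as
percentages, Matthews correlation coefficient (MCC, 0 by convention when a
denominator factor vanishes), the ROC curve from a descending-threshold
sweep with tie grouping, and the trapezoid AUC (equal to the Mann-Whitney
concordance probability with ties half-weighted).
"""

from __future__ import annotations

import hashlib
import json
import math
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from .errors import DegenerateInputError, SchemaError, ValidationError
from .table import FeatureTable


@dataclass(frozen=True)
class ForestConfig:
    """Random-forest hyperparameters.

    ``features_per_split`` is ``"all"`` (every feature considered at each
    split), ``"sqrt"``, or a fraction in (0, 1]. ``max_depth=None`` grows
    unlimited trees.
    """

    n_trees: int = 800
    max_depth: int | None = 50
    features_per_split: str | float = "all"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValidationError("n_trees must be >= 1")
        if self.max_depth is not None and self.max_depth < 1:
            raise ValidationError("max_depth must be >= 1 or None")

    def build(self, seed: int | None = None) -> RandomForestClassifier:
        mf = self.features_per_split
        max_features = None if mf == "all" else mf
        return RandomForestClassifier(
            n_estimators=self.n_trees,
            max_depth=self.max_depth,
            max_features=max_features,
            random_state=self.seed if seed is None else seed,
            n_jobs=1,
        )


#: Final-model configuration: 800 trees, depth 50, all features per split.
DEFAULT_FOREST = ForestConfig()

#: Library-default forest used inside incremental subset selection.
SELECTION_FOREST = ForestConfig(n_trees=100, max_depth=None, features_per_split="sqrt")


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class EvalReport:
    """Confusion matrix, ACC/SN/SP (percent), MCC, ROC points and AUC."""

    cm: ConfusionMatrix
    acc: float
    sn: float
    sp: float
    mcc: float
    mcc_degenerate: bool = False
    roc: list[tuple[float, float]] | None = None
    auc: float | None = None
    fold_acc: list[float] | None = None

    def to_json_dict(self) -> dict:
        d = {
            "confusion": asdict(self.cm),
            "acc": self.acc,
            "sn": self.sn,
            "sp": self.sp,
            "mcc": self.mcc,
            "mcc_degenerate": self.mcc_degenerate,
            "auc": self.auc,
        }
        if self.fold_acc is not None:
            d["fold_acc"] = self.fold_acc
            d["fold_acc_mean"] = float(np.mean(self.fold_acc))
            d["fold_acc_sd"] = float(np.std(self.fold_acc, ddof=1)) if len(self.fold_acc) > 1 else 0.0
        return d

    def write_json(self, path: str | os.PathLike) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=1) + "\n")

    def write_roc_tsv(self, path: str | os.PathLike) -> None:
        lines = ["FPR\tTPR"] + [f"{f:.12g}\t{t:.12g}" for f, t in (self.roc or [])]
        Path(path).write_text("\n".join(lines) + "\n")


def metrics(cm: ConfusionMatrix) -> EvalReport:
    """ACC/SN/SP in percent and MCC from a confusion matrix.

    MCC returns 0 (flagged) when any denominator factor is zero; SN/SP are
    0 when their class is empty.
    """
    if cm.total == 0:
        raise DegenerateInputError("empty confusion matrix")
    tp, fp, tn, fn = cm.tp, cm.fp, cm.tn, cm.fn
    acc = (tp + tn) / cm.total * 100.0
    sn = tp / (tp + fn) * 100.0 if tp + fn else 0.0
    sp = tn / (tn + fp) * 100.0 if tn + fp else 0.0
    denom = (tp + fn) * (tn + fn) * (tp + fp) * (tn + fp)
    degenerate = denom == 0
    mcc = 0.0 if degenerate else (tp * tn - fp * fn) / math.sqrt(denom)
    return EvalReport(cm=cm, acc=acc, sn=sn, sp=sp, mcc=mcc, mcc_degenerate=degenerate)


def roc_auc(labels: np.ndarray, scores: np.ndarray) -> tuple[list[tuple[float, float]], float]:
    """ROC points (FPR, TPR) from a full threshold sweep, and trapezoid AUC."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValidationError("ROC needs both classes present")
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def confusion_from_predictions(labels: np.ndarray, predicted: np.ndarray) -> ConfusionMatrix:
    labels = np.asarray(labels, dtype=int)
    predicted = np.asarray(predicted, dtype=int)
    return ConfusionMatrix(
        tp=int(((labels == 1) & (predicted == 1)).sum()),
        fp=int(((labels == 0) & (predicted == 1)).sum()),
        tn=int(((labels == 0) & (predicted == 0)).sum()),
        fn=int(((labels == 1) & (predicted == 0)).sum()),
    )


@dataclass
class Model:
    """A fitted forest plus the feature schema it was trained on."""

    forest: RandomForestClassifier
    feature_names: list[str]
    config: ForestConfig
    training_hash: str = ""

    def save(self, path: str | os.PathLike) -> None:
        """Persist with joblib plus a JSON sidecar (config, schema, hash)."""
        path = Path(path)
        joblib.dump(self.forest, path, compress=3)
        sidecar = {
            "feature_names": self.feature_names,
            "config": asdict(self.config),
            "training_hash": self.training_hash,
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=1) + "\n"
        )

    @classmethod
    def load(cls, path: str | os.PathLike) -> "Model":
        path = Path(path)
        sidecar_path = path.with_suffix(path.suffix + ".json")
        if not path.exists() or not sidecar_path.exists():
            raise FileNotFoundError(
                f"model requires both {path} and its {sidecar_path.name} sidecar"
            )
        sidecar = json.loads(sidecar_path.read_text())
        return cls(
            forest=joblib.load(path),
            feature_names=sidecar["feature_names"],
            config=ForestConfig(**sidecar["config"]),
            training_hash=sidecar.get("training_hash", ""),
        )


def _training_hash(t: FeatureTable, cfg: ForestConfig) -> str:
    h = hashlib.sha256()
    h.update(json.dumps(asdict(cfg), sort_keys=True).encode())
    h.update("\t".join(t.feature_names).encode())
    h.update(t.values.tobytes())
    h.update(t.labels.tobytes())
    return h.hexdigest()


def train(t: FeatureTable, cfg: ForestConfig = DEFAULT_FOREST) -> Model:
    """Fit the forest on a labelled feature table; deterministic given cfg.seed."""
    t.require_both_classes()
    forest = cfg.build()
    forest.fit(t.values, t.labels)
    return Model(
        forest=forest,
        feature_names=list(t.feature_names),
        config=cfg,
        training_hash=_training_hash(t, cfg),
    )


def predict(model: Model, t: FeatureTable) -> tuple[np.ndarray, np.ndarray]:
    """Vote-fraction scores in [0, 1] and 0/1 labels at the 0.5 threshold.

    Feature names must match training in order; a mismatch raises
    :class:`SchemaError` listing missing and extra names.
    """
    if list(t.feature_names) != list(model.feature_names):
        missing = [n for n in model.feature_names if n not in t.feature_names]
        extra = [n for n in t.feature_names if n not in model.feature_names]
        raise SchemaError(
            f"feature schema mismatch; missing={missing[:5]} extra={extra[:5]}"
            + ("" if missing or extra else " (order differs)")
        )
    votes = np.stack(
        [tree.predict(t.values) for tree in model.forest.estimators_]
    )
    scores = (votes == 1).mean(axis=0)  # each tree predicts a class label
    labels = (scores >= 0.5).astype(int)
    return labels, scores


def evaluate(model: Model, t: FeatureTable) -> EvalReport:
    """Predict on a labelled table and report all metrics plus ROC/AUC."""
    t.require_both_classes()
    predicted, scores = predict(model, t)
    report = metrics(confusion_from_predictions(t.labels, predicted))
    report.roc, report.auc = roc_auc(t.labels, scores)
    return report


def cross_validate(
    t: FeatureTable,
    cfg: ForestConfig = DEFAULT_FOREST,
    folds: int = 10,
    seed: int = 0,
) -> EvalReport:
    """Stratified k-fold CV; out-of-fold predictions pooled into one report.

    Per-fold accuracies are kept alongside the pooled confusion matrix
    (mean ± sd reported in the JSON form). Deterministic given ``seed``.
    """
    t.require_both_classes()
    if folds < 2:
        raise ValidationError("folds must be >= 2")
    if t.n_samples < folds:
        raise ValidationError(f"N={t.n_samples} < folds={folds}")
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    oof_pred = np.empty(t.n_samples, dtype=int)
    oof_score = np.empty(t.n_samples, dtype=float)
    fold_acc: list[float] = []
    for train_idx, test_idx in splitter.split(t.values, t.labels):
        sub = FeatureTable(
            sample_ids=[t.sample_ids[i] for i in train_idx],
            feature_names=list(t.feature_names),
            values=t.values[train_idx],
            labels=t.labels[train_idx],
        )
        model = train(sub, cfg)
        test = FeatureTable(
            sample_ids=[t.sample_ids[i] for i in test_idx],
            feature_names=list(t.feature_names),
            values=t.values[test_idx],
            labels=t.labels[test_idx],
        )
        pred, score = predict(model, test)
        oof_pred[test_idx] = pred
        oof_score[test_idx] = score
        fold_acc.append(float((pred == t.labels[test_idx]).mean()))
    report = metrics(confusion_from_predictions(t.labels, oof_pred))
    report.roc, report.auc = roc_auc(t.labels, oof_score)
    report.fold_acc = fold_acc
    return report
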