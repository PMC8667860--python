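"""Max-relevance / max-distance (MRMD) feature ranking and subset selection.

Each feature column ``f_i`` is scored by two criteria:

* relevance to the binary class vector C: ``maxMR_i = |PCC(f_i, C)|``
  (absolute sample Pearson correlation);
* distance to the other feature columns, averaged over three measures —
  Euclidean distance, cosine similarity and the Tanimoto coefficient:
  ``maxMD_i = (ED_i + COS_i + TC_i) / 3`` where each term is the mean of the
  pairwise value of ``f_i`` against every other feature.

Because ED is unbounded while COS and TC lie in [-1, 1], the per-feature
mean Euclidean distances are min-max normalised to [0, 1] before averaging
(disable with ``normalize_ed=False``). The default combined score is the
equally weighted sum ``maxMR + maxMD``; an alternative PageRank aggregation
over the four constituent rankings is available. Both are deterministic.

The optimal prefix subset is then found incrementally: features are added
one at a time in rank order, each prefix is evaluated by stratified k-fold
cross-validated accuracy with a random forest, and the smallest prefix with
maximal mean accuracy wins.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ValidationError
from .table import FeatureTable


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation; 0 by convention for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValidationError("need at least 2 observations")
    xc, yc = x - x.mean(), y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0.0:
        return 0.0
    return float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))


def distances(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Euclidean distance, cosine similarity and Tanimoto coefficient.

    COS and TC are defined as 0 when either vector is all-zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.shape} vs {y.shape}")
    ed = float(np.sqrt(((x - y) ** 2).sum()))
    dot = float(x @ y)
    nx2, ny2 = float(x @ x), float(y @ y)
    if nx2 == 0.0 or ny2 == 0.0:
        return ed, 0.0, 0.0
    cos = dot / np.sqrt(nx2 * ny2)
    tc = dot / (nx2 + ny2 - dot)
    return ed, float(cos), float(tc)


@dataclass
class FeatureRanking:
    """Per-feature relevance/distance scores and the resulting rank order."""

    feature_names: list[str]
    maxmr: np.ndarray
    ed: np.ndarray
    cos: np.ndarray
    tc: np.ndarray
    maxmd: np.ndarray
    score: np.ndarray
    rank: np.ndarray  # permutation of 1..M; 1 = best
    method: str = "score"

    def __post_init__(self) -> None:
        m = len(self.feature_names)
        if sorted(self.rank.tolist()) != list(range(1, m + 1)):
            raise ValidationError("ranks must be a permutation of 1..M")

    @property
    def order(self) -> list[str]:
        """Feature names sorted best-first."""
        return [self.feature_names[j] for j in np.argsort(self.rank)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.feature_names,
                "maxMR": self.maxmr,
                "ED": self.ed,
                "COS": self.cos,
                "TC": self.tc,
                "maxMD": self.maxmd,
                "score": self.score,
                "rank": self.rank,
            }
        )

    def write_tsv(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.12g")

    @classmethod
    def read_tsv(cls, path: str | os.PathLike) -> "FeatureRanking":
        df = pd.read_csv(path, sep="\t")
        return cls(
            feature_names=df["feature"].tolist(),
            maxmr=df["maxMR"].to_numpy(),
            ed=df["ED"].to_numpy(),
            cos=df["COS"].to_numpy(),
            tc=df["TC"].to_numpy(),
            maxmd=df["maxMD"].to_numpy(),
            score=df["score"].to_numpy(),
            rank=df["rank"].to_numpy(),
        )


def _rank_descending(values: np.ndarray) -> np.ndarray:
    """1-based ranks, highest value first; ties broken by original index."""
    order = np.argsort(-values, kind="stable")
    ranks = np.empty(len(values), dtype=int)
    ranks[order] = np.arange(1, len(values) + 1)
    return ranks


def rank_features(
    t: FeatureTable,
    weight: float = 0.5,
    normalize_ed: bool = True,
    method: str = "score",
) -> FeatureRanking:
    """Rank all features by combined relevance + distance.

    ``weight`` balances relevance against distance in the combined score
    ``2(w·maxMR + (1-w)·maxMD)``; at the default 0.5 this is exactly
    ``maxMR + maxMD``. ``method="pagerank"`` instead aggregates the four
    constituent rankings (maxMR, ED, COS, TC) through PageRank on a feature
    dominance graph (edge j→i whenever i outranks j in any constituent,
    damping 0.85).
    """
    t.require_both_classes()
    if not 0.0 <= weight <= 1.0:
        raise ValidationError("weight must be in [0, 1]")
    if method not in ("score", "pagerank"):
        raise ValidationError(f"unknown ranking method {method!r}")
    x = t.values
    n, m = x.shape
    labels = t.labels.astype(float)

    # relevance: column-wise |Pearson| against the class vector
    xc = x - x.mean(axis=0)
    lc = labels - labels.mean()
    denom = np.sqrt((xc**2).sum(axis=0) * (lc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, xc.T @ lc / np.where(denom > 0, denom, 1.0), 0.0)
    maxmr = np.abs(np.clip(corr, -1.0, 1.0))

    # pairwise distances via the Gram matrix; O(M^2 N) overall
    gram = x.T @ x
    sq = np.diag(gram).copy()
    ed_pair = np.sqrt(np.maximum(sq[:, None] + sq[None, :] - 2.0 * gram, 0.0))
    norms = np.sqrt(sq)
    norm_outer = norms[:, None] * norms[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_pair = np.where(norm_outer > 0, gram / np.where(norm_outer > 0, norm_outer, 1.0), 0.0)
        tc_den = sq[:, None] + sq[None, :] - gram
        tc_pair = np.where(tc_den != 0, gram / np.where(tc_den != 0, tc_den, 1.0), 0.0)

    if m > 1:
        ed_i = (ed_pair.sum(axis=1) - np.diag(ed_pair)) / (m - 1)
        cos_i = (cos_pair.sum(axis=1) - np.diag(cos_pair)) / (m - 1)
        tc_i = (tc_pair.sum(axis=1) - np.diag(tc_pair)) / (m - 1)
    else:
        ed_i = cos_i = tc_i = np.zeros(1)

    ed_used = ed_i
    if normalize_ed and m > 1:
        lo, hi = ed_i.min(), ed_i.max()
        ed_used = np.zeros_like(ed_i) if hi == lo else (ed_i - lo) / (hi - lo)
    maxmd = (ed_used + cos_i + tc_i) / 3.0

    if method == "score":
        score = 2.0 * (weight * maxmr + (1.0 - weight) * maxmd)
        rank = _rank_descending(score)
    else:
        score = _pagerank_scores(maxmr, ed_used, cos_i, tc_i)
        rank = _rank_descending(score)

    return FeatureRanking(
        feature_names=list(t.feature_names),
        maxmr=maxmr,
        ed=ed_i,
        cos=cos_i,
        tc=tc_i,
        maxmd=maxmd,
        score=score,
        rank=rank,
        method=method,
    )


def _pagerank_scores(*criteria: np.ndarray, damping: float = 0.85) -> np.ndarray:
    """PageRank over the feature dominance graph.

    For each criterion, feature i receives an edge from feature j whenever
    i strictly outranks j (higher value). Uniform edge weights; rank by
    stationary PageRank probability.
    """
    m = len(criteria[0])
    g = nx.DiGraph()
    g.add_nodes_from(range(m))
    edges = set()
    for values in criteria:
        order = np.argsort(-values, kind="stable")
        for better_pos in range(m):
            i = order[better_pos]
            for worse_pos in range(better_pos + 1, m):
                j = order[worse_pos]
                if values[i] > values[j]:
                    edges.add((int(j), int(i)))
    g.add_edges_from(edges)
    pr = nx.pagerank(g, alpha=damping)
    return np.array([pr[i] for i in range(m)])


@dataclass
class SelectionResult:
    """Incremental-prefix CV accuracy curve and the chosen subset."""

    ranking: FeatureRanking
    cv_accuracy_curve: np.ndarray  # mean CV accuracy, in [0, 1], per prefix size
    best_k: int
    selected_names: list[str] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "cv_accuracy_curve": [float(v) for v in self.cv_accuracy_curve],
            "best_k": int(self.best_k),
            "selected_names": list(self.selected_names),
        }

    def write_json(self, path: str | os.PathLike) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=1) + "\n")


def select_subset(
    t: FeatureTable,
    ranking: FeatureRanking,
    folds: int = 10,
    seed: int = 0,
    cfg=None,
    max_k: int | None = None,
) -> SelectionResult:
    """Pick the best rank-order prefix by incremental cross-validated accuracy.

    For k = 1..M (or ``max_k``) the top-k features are evaluated by
    stratified ``folds``-fold CV accuracy with a random forest
    (:data:`dbpforest.classify.SELECTION_FOREST` defaults unless ``cfg`` is
    given); ``best_k`` is the smallest k attaining the maximal mean accuracy.
    Deterministic given ``seed``.
    """
    from sklearn.model_selection import StratifiedKFold, cross_val_score

    from .classify import SELECTION_FOREST

    t.require_both_classes()
    if folds < 2:
        raise ValidationError("folds must be >= 2")
    if t.n_samples < folds:
        raise ValidationError(
            f"N={t.n_samples} < folds={folds}; use a smaller fold count"
        )
    cfg = cfg if cfg is not None else SELECTION_FOREST
    order = ranking.order
    k_max = len(order) if max_k is None else min(max_k, len(order))
    index = {n: j for j, n in enumerate(t.feature_names)}
    cols = [index[n] for n in order]

    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    curve = np.empty(k_max)
    for k in range(1, k_max + 1):
        clf = cfg.build(seed)
        scores = cross_val_score(
            clf, t.values[:, cols[:k]], t.labels, cv=splitter, scoring="accuracy"
        )
        curve[k - 1] = scores.mean()
    best_k = int(np.argmax(curve)) + 1  # argmax takes the smallest index on ties
    return SelectionResult(
        ranking=ranking,
        cv_accuracy_curve=curve,
        best_k=best_k,
        selected_names=order[:best_k],
    )
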