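from __future__ import annotations

import numpy as np
import pytest

from dbpforest import (
    Dataset,
    FeatureTable,
    ProteinSequence,
    PSSMMatrix,
    SimSpec,
    simulate,
)
from dbpforest.pssm_io import AA_ORDER


def random_pssm(seed: int, length: int | None = None) -> PSSMMatrix:
    """A structurally valid random PSSM, reproducible by seed."""
    rng = np.random.default_rng(seed)
    if length is None:
        length = int(rng.integers(5, 30))
    residues = "".join(rng.choice(list(AA_ORDER), size=length))
    scores = rng.integers(-8, 13, size=(length, 20))
    return PSSMMatrix(
        sequence=ProteinSequence(id=f"rnd{seed}", residues=residues), scores=scores
    )


@pytest.fixture
def pssm() -> PSSMMatrix:
    return random_pssm(3, length=30)


@pytest.fixture
def small_dataset() -> Dataset:
    return simulate(SimSpec(n_pos=15, n_neg=15, length_range=(20, 40), effect=6.0, seed=0))


def separable_table(n: int = 40, seed: int = 0) -> FeatureTable:
    """Two features, the first perfectly separating the classes."""
    rng = np.random.default_rng(seed)
    labels = np.array([1] * (n // 2) + [0] * (n - n // 2))
    f1 = labels * 10.0 + rng.normal(0, 0.5, size=n)
    f2 = rng.normal(0, 1, size=n)
    return FeatureTable(
        sample_ids=[f"s{i}" for i in range(n)],
        feature_names=["sep", "noise"],
        values=np.column_stack([f1, f2]),
        labels=labels,
    )


def random_table(seed: int, n: int | None = None, m: int | None = None) -> FeatureTable:
    rng = np.random.default_rng(seed)
    n = n if n is not None else int(rng.integers(10, 30))
    m = m if m is not None else int(rng.integers(2, 12))
    labels = np.zeros(n, dtype=int)
    labels[: n // 2] = 1
    rng.shuffle(labels)
    return FeatureTable(
        sample_ids=[f"s{i}" for i in range(n)],
        feature_names=[f"f{j}" for j in range(m)],
        values=rng.normal(size=(n, m)),
        labels=labels,
    )
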