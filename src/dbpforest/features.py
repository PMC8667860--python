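"""PSSM-derived evolutionary feature descriptors and their fusion.

Three descriptor blocks are computed from an L x 20 log-odds matrix
``p`` with residues ``a_1 … a_L``:

* **AADP-PSSM** (420-d) — per-column means (AAC-PSSM, 20-d)
  ``x_j = (1/L) Σ_i p_{i,j}`` concatenated with the dipeptide cross-product
  (DPC-PSSM, 400-d) ``y_{i,j} = (1/(L-1)) Σ_k p_{k,i} p_{k+1,j}``.
* **PSSM-COMPOSITION** (400-d) — rows grouped by the residue type occupying
  each position, summed and divided by L, flattened 20 x 20 and min-max
  scaled to [-1, 1].
* **RPSSM** (110-d) — the 20 columns are first reduced to a 10-letter
  alphabet (mean of grouped columns); then 10 per-column variances
  ``D_s`` plus 100 consecutive-position dipeptide terms
  ``D_{s,t} = (1/(L-1)) Σ_i (p̃_{i,s} - p̃_{i+1,t})² / 2``.

Fusing the three blocks in the fixed order AADP | COMPOSITION | RPSSM gives
the 930-dimensional vector the downstream selection and classification
stages consume. All extractors are pure functions of the matrix and residue
string; raw integer log-odds are used by default, with an optional
element-wise sigmoid ``1/(1+e^-x)`` transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, ValidationError
from .pssm_io import AA_INDEX, AA_ORDER, Dataset, PSSMMatrix
from .table import FeatureTable

BLOCK_DIMS = {"aac": 20, "dpc": 400, "aadp": 420, "composition": 400, "rpssm": 110, "fused": 930}

#: Order in which blocks are fused into the 930-d vector.
FUSION_ORDER = ("aadp", "composition", "rpssm")


@dataclass(frozen=True)
class FeatureVector:
    """One named, ordered descriptor block for one sample."""

    sample_id: str
    block: str
    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.names),):
            raise ValidationError(
                f"{self.block}: {values.shape[0]} values for {len(self.names)} names"
            )
        expected = BLOCK_DIMS.get(self.block)
        if expected is not None and len(self.names) != expected:
            raise ValidationError(
                f"block {self.block!r} must have {expected} dims, got {len(self.names)}"
            )
        values.setflags(write=False)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.names)


@dataclass(frozen=True)
class ReductionScheme:
    """Ordered partition of the 20 amino acids into 10 reduced-alphabet groups."""

    groups: tuple[str, ...]
    group_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.groups) != 10:
            raise ValidationError(f"expected 10 groups, got {len(self.groups)}")
        letters = "".join(self.groups)
        if sorted(letters) != sorted(AA_ORDER):
            raise ValidationError(
                "groups must partition the 20 amino acids exactly once each"
            )
        if self.group_names is None:
            object.__setattr__(self, "group_names", tuple(self.groups))
        elif len(self.group_names) != 10:
            raise ValidationError("need exactly 10 group names")

    def column_indices(self) -> list[list[int]]:
        return [[AA_INDEX[a] for a in g] for g in self.groups]


#: Default 10-letter reduced alphabet: aromatic {FYW}, {ML}, {IV}, small
#: {ATS}, {NH}, acid/amide {QED}, basic {RK}, and singletons C, G, P.
DEFAULT_REDUCTION = ReductionScheme(
    groups=("FYW", "ML", "IV", "ATS", "NH", "QED", "RK", "C", "G", "P")
)


def _scores(m: PSSMMatrix, sigmoid: bool) -> np.ndarray:
    s = m.scores.astype(float)
    return 1.0 / (1.0 + np.exp(-s)) if sigmoid else s


def aac_pssm(m: PSSMMatrix, sigmoid: bool = False) -> FeatureVector:
    """20-d evolutionary amino-acid composition: per-column PSSM mean."""
    if m.length == 0:
        raise DegenerateInputError("empty PSSM")
    values = _scores(m, sigmoid).mean(axis=0)
    names = tuple(f"AAC:{a}" for a in AA_ORDER)
    return FeatureVector(m.sequence.id, "aac", names, values)


def dpc_pssm(m: PSSMMatrix, sigmoid: bool = False) -> FeatureVector:
    """400-d dipeptide cross-product of consecutive PSSM rows."""
    if m.length < 2:
        raise DegenerateInputError(f"DPC-PSSM needs L >= 2, got L={m.length}")
    s = _scores(m, sigmoid)
    y = s[:-1].T @ s[1:] / (m.length - 1)  # y[i, j] = mean_k p[k,i] p[k+1,j]
    names = tuple(f"DPC:{a}>{b}" for a in AA_ORDER for b in AA_ORDER)
    return FeatureVector(m.sequence.id, "dpc", names, y.ravel())


def aadp_pssm(m: PSSMMatrix, sigmoid: bool = False) -> FeatureVector:
    """420-d concatenation of AAC-PSSM and DPC-PSSM."""
    aac = aac_pssm(m, sigmoid)
    dpc = dpc_pssm(m, sigmoid)
    return FeatureVector(
        m.sequence.id,
        "aadp",
        aac.names + dpc.names,
        np.concatenate([aac.values, dpc.values]),
    )


def pssm_composition(m: PSSMMatrix, sigmoid: bool = False) -> FeatureVector:
    """400-d residue-type-grouped PSSM composition, min-max scaled to [-1, 1].

    Rows whose residue is X (or any letter outside the 20) contribute to the
    1/L normalisation but to no composition group. A constant 20 x 20 matrix
    maps to all zeros (degenerate scaling).
    """
    if m.length == 0:
        raise DegenerateInputError("empty PSSM")
    s = _scores(m, sigmoid)
    comp = np.zeros((20, 20))
    for pos, res in enumerate(m.sequence.residues):
        row = AA_INDEX.get(res)
        if row is not None:
            comp[row] += s[pos]
    comp /= m.length
    flat = comp.ravel()
    lo, hi = flat.min(), flat.max()
    scaled = np.zeros_like(flat) if hi == lo else 2.0 * (flat - lo) / (hi - lo) - 1.0
    names = tuple(f"COMP:{a}|{b}" for a in AA_ORDER for b in AA_ORDER)
    return FeatureVector(m.sequence.id, "composition", names, scaled)


def reduce_pssm(
    m: PSSMMatrix,
    scheme: ReductionScheme = DEFAULT_REDUCTION,
    sigmoid: bool = False,
    aggregate: str = "mean",
) -> np.ndarray:
    """Collapse the 20 columns to the scheme's 10 groups (mean per row).

    ``aggregate="sum"`` is available for comparison; the default mean keeps
    multi-member groups on the same scale as singletons.
    """
    if aggregate not in ("mean", "sum"):
        raise ValidationError(f"aggregate must be 'mean' or 'sum', got {aggregate!r}")
    s = _scores(m, sigmoid)
    cols = scheme.column_indices()
    op = np.mean if aggregate == "mean" else np.sum
    return np.column_stack([op(s[:, c], axis=1) for c in cols])


def rpssm(
    m: PSSMMatrix,
    scheme: ReductionScheme = DEFAULT_REDUCTION,
    sigmoid: bool = False,
    difference: bool = True,
) -> FeatureVector:
    """110-d reduced-alphabet descriptor.

    The first 10 values are per-reduced-column population variances
    ``D_s``; the remaining 100 are consecutive-position dipeptide terms
    ``D_{s,t}``, squared half-differences by default (``difference=False``
    uses squared half-sums instead, for comparison with descriptor variants
    that print the sum form).
    """
    if m.length < 2:
        raise DegenerateInputError(f"RPSSM needs L >= 2, got L={m.length}")
    r = reduce_pssm(m, scheme, sigmoid)
    d_s = r.var(axis=0)  # population variance, ddof=0
    a, b = r[:-1, :, None], r[1:, None, :]  # (L-1, s, t)
    pair = a - b if difference else a + b
    d_st = (pair**2 / 2.0).mean(axis=0)
    names = tuple(f"RPSSM:D[{s}]" for s in range(10)) + tuple(
        f"RPSSM:D[{s},{t}]" for s in range(10) for t in range(10)
    )
    return FeatureVector(
        m.sequence.id, "rpssm", names, np.concatenate([d_s, d_st.ravel()])
    )


def fuse(parts: list[FeatureVector]) -> FeatureVector:
    """Concatenate the three blocks of one sample into the 930-d vector.

    Output order is fixed (AADP | COMPOSITION | RPSSM) regardless of the
    argument order; mismatched sample ids or a missing/duplicate block raise
    :class:`ValidationError`.
    """
    by_block = {p.block: p for p in parts}
    if len(by_block) != len(parts) or set(by_block) != set(FUSION_ORDER):
        raise ValidationError(
            f"fuse needs exactly one each of {FUSION_ORDER}, "
            f"got {sorted(p.block for p in parts)}"
        )
    ids = {p.sample_id for p in parts}
    if len(ids) != 1:
        raise ValidationError(f"mismatched sample ids: {sorted(ids)}")
    ordered = [by_block[b] for b in FUSION_ORDER]
    return FeatureVector(
        parts[0].sample_id,
        "fused",
        tuple(n for p in ordered for n in p.names),
        np.concatenate([p.values for p in ordered]),
    )


def extract_features(m: PSSMMatrix, blocks=FUSION_ORDER, scheme: ReductionScheme = DEFAULT_REDUCTION, sigmoid: bool = False) -> FeatureVector:
    """Compute the requested blocks for one PSSM; fuses when all three asked."""
    extractors = {
        "aadp": lambda: aadp_pssm(m, sigmoid),
        "composition": lambda: pssm_composition(m, sigmoid),
        "rpssm": lambda: rpssm(m, scheme, sigmoid),
    }
    unknown = set(blocks) - set(extractors)
    if unknown:
        raise ValidationError(f"unknown blocks: {sorted(unknown)}")
    parts = [extractors[b]() for b in FUSION_ORDER if b in blocks]
    if len(parts) == 1:
        return parts[0]
    if set(blocks) == set(FUSION_ORDER):
        return fuse(parts)
    joined = FeatureVector(
        m.sequence.id,
        "partial",
        tuple(n for p in parts for n in p.names),
        np.concatenate([p.values for p in parts]),
    )
    return joined


def build_feature_table(
    ds: Dataset,
    blocks=FUSION_ORDER,
    scheme: ReductionScheme = DEFAULT_REDUCTION,
    sigmoid: bool = False,
) -> FeatureTable:
    """One feature row per sample of the dataset, with labels attached."""
    labels = ds.labels
    ids = ds.ids
    rows, names = [], None
    for sample_id in ids:
        fv = extract_features(ds.pssms[sample_id], blocks, scheme, sigmoid)
        if names is None:
            names = list(fv.names)
        rows.append(fv.values)
    return FeatureTable(
        sample_ids=ids,
        feature_names=names or [],
        values=np.vstack(rows) if rows else np.empty((0, 0)),
        labels=np.array([labels[i] for i in ids]) if ds.positives else None,
    )
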