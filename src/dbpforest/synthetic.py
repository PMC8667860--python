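"""Synthetic labelled PSSM datasets with a controllable class signal.

The generator emulates the *structure* of PSI-BLAST profiles — integer
log-odds in a realistic band, variable sequence length, residues over the
20-letter alphabet — so the full extract/select/classify pipeline can be
exercised and its signal-recovery behaviour tested without running
PSI-BLAST. It makes no attempt at real DNA-binding-protein biology.

Scores are rounded draws from a normal distribution clipped to the score
band. Positive-class samples receive a mean shift of ``effect`` on a fixed
4-column subset, which makes the per-column means (the AAC-PSSM features of
those columns) informative by construction: feature ranking therefore has a
known ground truth, and ``effect=0`` makes the two classes exchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .pssm_io import AA_ORDER, Dataset, ProteinSequence, PSSMMatrix

#: Columns shifted in positive-class samples (A, R, N, D).
SHIFTED_COLUMNS: tuple[int, ...] = (0, 1, 2, 3)


@dataclass(frozen=True)
class SimSpec:
    """Simulation parameters.

    ``effect`` is the mean log-odds shift (dimensionless, same scale as the
    scores) applied to the designated columns in positive samples; 0 makes
    the classes exchangeable. ``score_sd`` is the spread of the base score
    distribution before rounding and clipping.
    """

    n_pos: int = 100
    n_neg: int = 100
    length_range: tuple[int, int] = (50, 200)
    score_band: tuple[int, int] = (-8, 12)
    effect: float = 0.0
    score_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValidationError("need at least one sample per class")
        lmin, lmax = self.length_range
        if lmin < 2 or lmax < lmin:
            raise ValidationError("length_range must satisfy 2 <= Lmin <= Lmax")
        lo, hi = self.score_band
        if lo >= hi:
            raise ValidationError("score_band must be a non-empty range")
        if self.effect < 0:
            raise ValidationError("effect must be >= 0")
        if self.score_sd <= 0:
            raise ValidationError("score_sd must be > 0")


def _sample_matrix(
    rng: np.random.Generator, spec: SimSpec, sample_id: str, positive: bool
) -> PSSMMatrix:
    lmin, lmax = spec.length_range
    length = int(rng.integers(lmin, lmax + 1))
    residues = "".join(rng.choice(list(AA_ORDER), size=length))
    mean = np.zeros(20)
    if positive:
        mean[list(SHIFTED_COLUMNS)] = spec.effect
    raw = rng.normal(loc=mean, scale=spec.score_sd, size=(length, 20))
    lo, hi = spec.score_band
    scores = np.clip(np.rint(raw), lo, hi).astype(np.int64)
    return PSSMMatrix(
        sequence=ProteinSequence(id=sample_id, residues=residues), scores=scores
    )


def simulate(spec: SimSpec) -> Dataset:
    """Generate a labelled synthetic dataset; fully reproducible by seed."""
    rng = np.random.default_rng(spec.seed)
    pssms: dict[str, PSSMMatrix] = {}
    positives, negatives = [], []
    for i in range(spec.n_pos):
        sid = f"pos_{i:04d}"
        pssms[sid] = _sample_matrix(rng, spec, sid, positive=True)
        positives.append(sid)
    for i in range(spec.n_neg):
        sid = f"neg_{i:04d}"
        pssms[sid] = _sample_matrix(rng, spec, sid, positive=False)
        negatives.append(sid)
    return Dataset(positives=positives, negatives=negatives, pssms=pssms)
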