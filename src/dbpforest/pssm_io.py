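"""Reading, validating and writing PSI-BLAST ASCII PSSM profiles.

A position-specific scoring matrix (PSSM) for a protein of length L is an
L x 20 matrix of integer log-odds scores: entry (i, j) scores the
substitution of the residue at position i by amino acid j, as produced by
iterative profile search (typically three PSI-BLAST iterations against a
large sequence database with an E-value threshold of 0.001; generating the
profiles is outside the scope of this package — it consumes the
``-out_ascii_pssm`` text files).

Only the first 20-column block (log-odds) of the ASCII dialect is modelled;
the weighted-percentage block and trailing information-content columns are
ignored on read and zero-filled on write.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

from .errors import EmptyInputError, ParseError, ValidationError

#: Canonical amino-acid column order — the native PSI-BLAST header order.
#: Every downstream feature index refers to this constant.
AA_ORDER: tuple[str, ...] = tuple("ARNDCQEGHILKMFPSTVWY")

AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(AA_ORDER)}

#: Log-odds scores outside this band indicate a parse error, not biology.
SCORE_BAND_LIMIT = 32

#: The profile-generating command this package expects upstream (documented,
#: never executed): ``psiblast -num_iterations 3 -evalue 0.001 -db <nr>
#: -query <seq.fasta> -out_ascii_pssm <id>.pssm``.
PSIBLAST_COMMAND_NOTE = "psiblast, 3 iterations, E-value 0.001, -out_ascii_pssm"


@dataclass(frozen=True)
class ProteinSequence:
    """An amino-acid sequence; residues are uppercase, X is permitted."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        if len(self.residues) < 2:
            raise ValidationError(
                f"sequence {self.id!r}: length {len(self.residues)} < 2 "
                "(dipeptide descriptors need at least one residue pair)"
            )
        bad = sorted(set(self.residues) - set(AA_ORDER) - {"X"})
        if bad:
            raise ValidationError(
                f"sequence {self.id!r}: illegal characters {''.join(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class PSSMMatrix:
    """L x 20 integer log-odds matrix paired with its residue string."""

    sequence: ProteinSequence
    scores: np.ndarray
    column_order: tuple[str, ...] = AA_ORDER

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores)
        if scores.ndim != 2 or scores.shape[1] != 20:
            raise ValidationError(
                f"PSSM {self.sequence.id!r}: expected L x 20 scores, "
                f"got shape {scores.shape}"
            )
        if scores.shape[0] != len(self.sequence):
            raise ValidationError(
                f"PSSM {self.sequence.id!r}: {scores.shape[0]} score rows for "
                f"{len(self.sequence)} residues"
            )
        if not np.issubdtype(scores.dtype, np.integer):
            if not np.all(scores == np.round(scores)):
                raise ValidationError(
                    f"PSSM {self.sequence.id!r}: non-integer log-odds entries"
                )
            scores = scores.astype(np.int64)
        if np.abs(scores).max(initial=0) > SCORE_BAND_LIMIT:
            raise ValidationError(
                f"PSSM {self.sequence.id!r}: |score| > {SCORE_BAND_LIMIT}; "
                "likely a parse error"
            )
        if tuple(self.column_order) != AA_ORDER:
            raise ValidationError("column_order must be the canonical PSI-BLAST order")
        scores = scores.astype(np.int64)
        scores.setflags(write=False)
        object.__setattr__(self, "scores", scores)

    @property
    def length(self) -> int:
        return self.scores.shape[0]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PSSMMatrix):
            return NotImplemented
        return (
            self.sequence == other.sequence
            and np.array_equal(self.scores, other.scores)
        )


@dataclass
class Dataset:
    """Labelled collection of PSSMs: S = S+ ∪ S-, disjoint by construction."""

    positives: list[str]
    negatives: list[str]
    pssms: dict[str, PSSMMatrix] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.positives) & set(self.negatives)
        if overlap:
            raise ValidationError(
                f"ids in both classes: {sorted(overlap)[:5]}"
            )
        missing = [i for i in self.ids if i not in self.pssms]
        if missing:
            raise ValidationError(f"ids without a PSSM: {missing[:5]}")

    @property
    def ids(self) -> list[str]:
        return list(self.positives) + list(self.negatives)

    @property
    def labels(self) -> dict[str, int]:
        out = {i: 1 for i in self.positives}
        out.update({i: 0 for i in self.negatives})
        return out

    def __len__(self) -> int:
        return len(self.positives) + len(self.negatives)


# ---------------------------------------------------------------------------
# ASCII PSSM dialect


def _is_header_line(tokens: list[str]) -> bool:
    return len(tokens) == 40 and all(len(t) == 1 and t.isalpha() for t in tokens)


def parse_pssm(path: str | os.PathLike) -> PSSMMatrix:
    """Parse one PSI-BLAST ``-out_ascii_pssm`` file.

    Returns only the first 20 columns (the log-odds block). The residue
    string is reconstructed from the body row labels. Raises
    :class:`ParseError` on a missing header, a body row without 40 integer
    score fields, or non-consecutive position indices.
    """
    path = Path(path)
    lines = path.read_text().splitlines()

    header_at = None
    for ln, line in enumerate(lines):
        if _is_header_line(line.split()):
            header_at = ln
            break
    if header_at is None:
        raise ParseError(f"{path}: no 40-letter PSSM column header found")
    header = lines[header_at].split()
    if tuple(header[:20]) != AA_ORDER or tuple(header[20:]) != AA_ORDER:
        raise ParseError(f"{path}: unexpected amino-acid column order in header")

    rows: list[list[int]] = []
    residues: list[str] = []
    expected_idx = 1
    for ln in range(header_at + 1, len(lines)):
        tokens = lines[ln].split()
        if not tokens:
            break  # blank line terminates the body; K/Lambda footer optional
        if len(tokens) < 42:
            raise ParseError(
                f"{path}:{ln + 1}: body row has {max(len(tokens) - 2, 0)} "
                "numeric fields, expected 40"
            )
        try:
            idx = int(tokens[0])
        except ValueError as exc:
            raise ParseError(f"{path}:{ln + 1}: bad position index {tokens[0]!r}") from exc
        if idx != expected_idx:
            raise ParseError(
                f"{path}:{ln + 1}: position index {idx} where {expected_idx} "
                "was expected (missing or duplicated row?)"
            )
        expected_idx += 1
        residues.append(tokens[1])
        try:
            fields = [int(t) for t in tokens[2:42]]
        except ValueError as exc:
            raise ParseError(
                f"{path}:{ln + 1}: non-integer log-odds field"
            ) from exc
        rows.append(fields[:20])

    if not rows:
        raise ParseError(f"{path}: header present but no body rows")

    seq = ProteinSequence(id=path.stem, residues="".join(residues))
    return PSSMMatrix(sequence=seq, scores=np.array(rows, dtype=np.int64))


def write_pssm(m: PSSMMatrix, path: str | os.PathLike) -> None:
    """Write *m* in the ASCII dialect ``parse_pssm`` accepts.

    The log-odds block round-trips bit-identically; the percentage block is
    zero-filled.
    """
    path = Path(path)
    out = [
        "",
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapped matches",
        "            " + "  ".join(AA_ORDER) + "   " + "   ".join(AA_ORDER),
    ]
    for i in range(m.length):
        scores = " ".join(f"{v:3d}" for v in m.scores[i])
        pct = " ".join(f"{0:3d}" for _ in range(20))
        out.append(f"{i + 1:5d} {m.sequence.residues[i]}  {scores}  {pct}  0.00 0.00")
    out += [
        "",
        "                      K         Lambda",
        "Standard Ungapped    0.1337     0.3177",
    ]
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# FASTA and label tables


def read_fasta(path: str | os.PathLike) -> list[ProteinSequence]:
    """Read a FASTA file into :class:`ProteinSequence` records.

    Record ids are taken up to the first whitespace; wrapped sequence lines
    are concatenated. Raises :class:`EmptyInputError` on an empty file and
    :class:`ValidationError` if a sequence contains letters outside the
    20-letter alphabet plus X.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise EmptyInputError(f"{path}: no FASTA records")
    return [ProteinSequence(id=r.id, residues=str(r.seq)) for r in records]


def read_labels(path: str | os.PathLike) -> dict[str, int]:
    """Read a two-column TSV ``id<TAB>{0,1}`` label table."""
    labels: dict[str, int] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2 or parts[1] not in ("0", "1"):
            raise ParseError(f"{path}:{ln}: expected 'id<TAB>0|1', got {line!r}")
        labels[parts[0]] = int(parts[1])
    if not labels:
        raise EmptyInputError(f"{path}: no label rows")
    return labels


def write_labels(labels: Mapping[str, int], path: str | os.PathLike) -> None:
    Path(path).write_text(
        "".join(f"{k}\t{int(v)}\n" for k, v in labels.items())
    )


def write_dataset(ds: Dataset, directory: str | os.PathLike) -> None:
    """Write one ``<id>.pssm`` file per sample plus ``labels.tsv``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for sample_id in ds.ids:
        write_pssm(ds.pssms[sample_id], directory / f"{sample_id}.pssm")
    write_labels({i: ds.labels[i] for i in ds.ids}, directory / "labels.tsv")


def load_dataset(
    pssm_dir: str | os.PathLike,
    labels_path: str | os.PathLike | None = None,
    skip_bad: bool = False,
) -> Dataset:
    """Load every ``*.pssm`` file in a directory into a :class:`Dataset`.

    Without a label table all samples are placed in the negative (unlabelled)
    partition; prediction does not need labels.
    """
    pssm_dir = Path(pssm_dir)
    files = sorted(pssm_dir.glob("*.pssm"))
    if not files:
        raise EmptyInputError(f"{pssm_dir}: no .pssm files")
    pssms: dict[str, PSSMMatrix] = {}
    bad: list[str] = []
    for f in files:
        try:
            pssms[f.stem] = parse_pssm(f)
        except ParseError:
            if not skip_bad:
                raise
            bad.append(f.name)
    if labels_path is None:
        labels_file = pssm_dir / "labels.tsv"
        labels = read_labels(labels_file) if labels_file.exists() else {}
    else:
        labels = read_labels(labels_path)
    if labels:
        missing = [i for i in pssms if i not in labels]
        if missing:
            raise ValidationError(f"samples without a label: {missing[:5]}")
        positives = [i for i in pssms if labels[i] == 1]
        negatives = [i for i in pssms if labels[i] == 0]
    else:
        positives, negatives = [], list(pssms)
    return Dataset(positives=positives, negatives=negatives, pssms=pssms)
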