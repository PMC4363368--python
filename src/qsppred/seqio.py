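"""Peptide containers and FASTA input/output.

Quorum-sensing peptides (QSPs) are short linear oligopeptides; everything
downstream (composition vectors, dipeptide tables, terminal one-hot blocks)
indexes the 20 standard one-letter amino-acid codes, so validation is strict
by default: a record containing B/J/O/U/X/Z or any other symbol is rejected
(or, in lenient mode, dropped with a warning) rather than silently recoded.

Class labels travel in a sidecar ``label`` field, keeping the FASTA files
themselves standard; an optional ``|label=positive`` suffix on the header is
parsed if present.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 standard residues in fixed alphabetical order; every feature
#: encoding in the package uses this ordering.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AMINO_ACIDS)
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

POSITIVE = "positive"
NEGATIVE = "negative"
UNKNOWN = "unknown"
LABELS = (POSITIVE, NEGATIVE, UNKNOWN)


class SequenceValidationError(ValueError):
    """A sequence contains characters outside the 20-letter alphabet."""


class DuplicateIdError(ValueError):
    """Two records in one set share an identifier."""


def validate_sequence(seq: str, record_id: str = "?") -> str:
    """Uppercase ``seq`` and verify it is a non-empty standard peptide.

    Raises :class:`SequenceValidationError` naming the record and the offset
    of the first offending character.
    """
    s = seq.upper()
    if not s:
        raise SequenceValidationError(f"record {record_id!r}: empty sequence")
    for i, ch in enumerate(s):
        if ch not in AA_SET:
            raise SequenceValidationError(
                f"record {record_id!r}: invalid residue {ch!r} at offset {i}"
            )
    return s


@dataclass(frozen=True)
class Peptide:
    """One validated peptide sequence with identifier and class label."""

    id: str
    seq: str
    label: str = UNKNOWN

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("peptide id must be non-empty")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        object.__setattr__(self, "seq", validate_sequence(self.seq, self.id))

    def __len__(self) -> int:
        return len(self.seq)

    def with_label(self, label: str) -> "Peptide":
        return replace(self, label=label)


@dataclass
class PeptideSet:
    """Ordered collection of peptides with unique identifiers."""

    peptides: list[Peptide] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for p in self.peptides:
            if p.id in seen:
                raise DuplicateIdError(f"duplicate peptide id {p.id!r} in set {self.name!r}")
            seen.add(p.id)

    def __len__(self) -> int:
        return len(self.peptides)

    def __iter__(self) -> Iterator[Peptide]:
        return iter(self.peptides)

    def __getitem__(self, i: int) -> Peptide:
        return self.peptides[i]

    @property
    def ids(self) -> list[str]:
        return [p.id for p in self.peptides]

    @property
    def sequences(self) -> list[str]:
        return [p.seq for p in self.peptides]

    def relabelled(self, label: str) -> "PeptideSet":
        return PeptideSet([p.with_label(label) for p in self.peptides], name=self.name)


def read_fasta(
    path: str | Path,
    label: str = UNKNOWN,
    *,
    strict: bool = True,
    name: str | None = None,
) -> PeptideSet:
    """Read a (multi-)FASTA file into a :class:`PeptideSet`.

    ``label`` is attached to every record unless the header carries an
    explicit ``|label=...`` tag. In strict mode a record with a non-standard
    residue raises; in lenient mode it is skipped with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    peptides: list[Peptide] = []
    n_records = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n_records += 1
        rec_label = label
        rec_id = rec.id
        if "|label=" in rec.description:
            tag = rec.description.split("|label=", 1)[1].split()[0].split("|")[0]
            if tag in LABELS:
                rec_label = tag
            rec_id = rec.id.split("|label=", 1)[0]
        try:
            peptides.append(Peptide(rec_id, str(rec.seq), rec_label))
        except SequenceValidationError:
            if strict:
                raise
            logger.warning("skipping invalid record %r in %s", rec.id, path)
    if n_records == 0:
        raise ValueError(f"no FASTA records in {path}")
    return PeptideSet(peptides, name=name if name is not None else path.stem)


def write_fasta(s: PeptideSet | Iterable[Peptide], path: str | Path, *, with_labels: bool = False) -> None:
    """Write peptides as unwrapped FASTA; round-trips byte-identically."""
    records = []
    for p in s:
        header = f"{p.id}|label={p.label}" if with_labels else p.id
        records.append(SeqRecord(Seq(p.seq), id=header, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=None)
        writer.write_file(records)


def deduplicate(s: PeptideSet) -> tuple[PeptideSet, int]:
    """Drop peptides whose sequence is 100% identical to an earlier one.

    Keeps the first occurrence of each distinct sequence in input order.
    Returns the reduced set and the number of records removed.
    """
    seen: set[str] = set()
    kept: list[Peptide] = []
    for p in s:
        if p.seq not in seen:
            seen.add(p.seq)
            kept.append(p)
    return PeptideSet(kept, name=s.name), len(s) - len(kept)


@dataclass(frozen=True)
class SplitSpec:
    """Per-class holdout size and seed for the train/validation split."""

    n_holdout_per_class: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_holdout_per_class < 0:
            raise ValueError("n_holdout_per_class must be >= 0")


def split(
    s_pos: PeptideSet, s_neg: PeptideSet, spec: SplitSpec
) -> tuple[PeptideSet, PeptideSet]:
    """Split positives+negatives into train and validation sets.

    Exactly ``n_holdout_per_class`` peptides are sampled uniformly without
    replacement (seeded) from each class into the validation set; the
    remainder, in input order, form the training set.
    """
    n = spec.n_holdout_per_class
    for cls in (s_pos, s_neg):
        if n > len(cls):
            raise ValueError(
                f"holdout {n} exceeds class size {len(cls)} ({cls.name!r})"
            )
    rng = random.Random(spec.seed)
    train: list[Peptide] = []
    valid: list[Peptide] = []
    for cls in (s_pos, s_neg):
        held = set(rng.sample(range(len(cls)), n))
        for i, p in enumerate(cls):
            (valid if i in held else train).append(p)
    return PeptideSet(train, name="train"), PeptideSet(valid, name="validation")


def scramble(s: PeptideSet, seed: int) -> PeptideSet:
    """Shuffle each peptide's residues (Fisher–Yates), labelling as negative.

    The per-sequence residue multiset is preserved exactly, so composition
    features of a peptide and its scramble are identical — this is how the
    composition-matched negative class is built.
    """
    rng = random.Random(seed)
    out: list[Peptide] = []
    for p in s:
        residues = list(p.seq)
        rng.shuffle(residues)
        out.append(Peptide(f"{p.id}_scr", "".join(residues), NEGATIVE))
    return PeptideSet(out, name=f"{s.name}_scrambled" if s.name else "scrambled")
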