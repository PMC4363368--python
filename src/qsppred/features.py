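"""Fixed-length feature encodings of variable-length peptides.

The classifier cannot consume raw sequences, so each peptide is mapped to a
fixed-length numeric vector under one of the schemes used for quorum-sensing
peptide prediction:

AAC
    amino-acid composition — the 20 residue fractions.
DPC
    dipeptide composition — 400 overlapping-pair fractions.
N5Bin / C5Bin / N5C5Bin
    one-hot ("binary") profiles of the first and/or last *k* residues
    (default 5), 20 slots per position.
Physico
    per-peptide means of selected AAindex per-residue scales.
hybrid
    concatenation of any of the above.

Residue order is fixed alphabetical (ACDEFGHIKLMNPQRSTVWY) everywhere;
dipeptides are the 20x20 row-major product of that order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .aaindex import AAIndexTable
from .seqio import AA_INDEX, AMINO_ACIDS, Peptide, PeptideSet

DIPEPTIDES = [a + b for a in AMINO_ACIDS for b in AMINO_ACIDS]

SCHEMES = ("AAC", "DPC", "N5Bin", "C5Bin", "N5C5Bin", "Physico", "hybrid")


class EncodingError(ValueError):
    """A peptide violates a scheme's length precondition."""


@dataclass(frozen=True)
class EncodingSpec:
    """Declarative description of one feature encoding.

    For terminal binary schemes ``n_term_len``/``c_term_len`` set the window
    sizes; for ``Physico`` the ordered ``aaindex_ids`` select the scales; a
    ``hybrid`` concatenates its ``components`` in order.
    """

    scheme: str
    n_term_len: int = 5
    c_term_len: int = 5
    aaindex_ids: tuple[str, ...] = ()
    components: tuple["EncodingSpec", ...] = ()

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}; expected one of {SCHEMES}")
        if self.scheme == "hybrid" and not self.components:
            raise ValueError("hybrid spec requires components")
        if self.scheme == "Physico" and not self.aaindex_ids:
            raise ValueError("Physico spec requires aaindex_ids")

    @property
    def n_features(self) -> int:
        if self.scheme == "AAC":
            return 20
        if self.scheme == "DPC":
            return 400
        if self.scheme == "N5Bin":
            return 20 * self.n_term_len
        if self.scheme == "C5Bin":
            return 20 * self.c_term_len
        if self.scheme == "N5C5Bin":
            return 20 * (self.n_term_len + self.c_term_len)
        if self.scheme == "Physico":
            return len(self.aaindex_ids)
        return sum(c.n_features for c in self.components)

    @property
    def min_length(self) -> int:
        """Shortest peptide the scheme can encode."""
        if self.scheme == "AAC":
            return 1
        if self.scheme == "DPC":
            return 2
        if self.scheme == "N5Bin":
            return self.n_term_len
        if self.scheme == "C5Bin":
            return self.c_term_len
        if self.scheme == "N5C5Bin":
            return max(self.n_term_len, self.c_term_len)
        if self.scheme == "Physico":
            return 1
        return max(c.min_length for c in self.components)

    @property
    def feature_names(self) -> list[str]:
        if self.scheme == "AAC":
            return [f"AAC_{aa}" for aa in AMINO_ACIDS]
        if self.scheme == "DPC":
            return [f"DPC_{dp}" for dp in DIPEPTIDES]
        if self.scheme in ("N5Bin", "N5C5Bin"):
            names = [f"N{i+1}_{aa}" for i in range(self.n_term_len) for aa in AMINO_ACIDS]
            if self.scheme == "N5Bin":
                return names
            return names + [f"C{i+1}_{aa}" for i in range(self.c_term_len) for aa in AMINO_ACIDS]
        if self.scheme == "C5Bin":
            return [f"C{i+1}_{aa}" for i in range(self.c_term_len) for aa in AMINO_ACIDS]
        if self.scheme == "Physico":
            return [f"PC_{acc}" for acc in self.aaindex_ids]
        names: list[str] = []
        for c in self.components:
            names.extend(c.feature_names)
        return names

    def describe(self) -> str:
        if self.scheme == "hybrid":
            return "+".join(c.describe() for c in self.components)
        return self.scheme


def hybrid(*components: EncodingSpec) -> EncodingSpec:
    return EncodingSpec("hybrid", components=tuple(components))


def encode_aac(p: Peptide | str) -> np.ndarray:
    """Fraction of each amino acid; components sum to 1."""
    seq = p.seq if isinstance(p, Peptide) else p
    v = np.zeros(20)
    for ch in seq:
        v[AA_INDEX[ch]] += 1.0
    return v / len(seq)


def encode_dpc(p: Peptide | str) -> np.ndarray:
    """Overlapping dipeptide fractions; L-1 counts, components sum to 1."""
    seq = p.seq if isinstance(p, Peptide) else p
    if len(seq) < 2:
        raise EncodingError(f"DPC requires length >= 2, got {len(seq)}")
    v = np.zeros(400)
    for a, b in zip(seq, seq[1:]):
        v[AA_INDEX[a] * 20 + AA_INDEX[b]] += 1.0
    return v / (len(seq) - 1)


def encode_binary(
    p: Peptide | str, n_term_len: int = 5, c_term_len: int = 5
) -> np.ndarray:
    """One-hot encode the N-terminal and C-terminal windows.

    N blocks (position-major) precede C blocks. For peptides shorter than
    ``n_term_len + c_term_len`` the two windows overlap, which is permitted;
    a peptide shorter than either single window cannot be encoded.
    """
    seq = p.seq if isinstance(p, Peptide) else p
    need = max(n_term_len, c_term_len)
    if len(seq) < need:
        raise EncodingError(
            f"binary profile requires length >= {need}, got {len(seq)}"
        )
    v = np.zeros(20 * (n_term_len + c_term_len))
    for i in range(n_term_len):
        v[20 * i + AA_INDEX[seq[i]]] = 1.0
    c_tail = seq[-c_term_len:] if c_term_len else ""
    for i, ch in enumerate(c_tail):
        v[20 * (n_term_len + i) + AA_INDEX[ch]] = 1.0
    return v


def encode_physico(
    p: Peptide | str, table: AAIndexTable, ids: Sequence[str]
) -> np.ndarray:
    """Mean per-residue value of each selected AAindex scale.

    Averaging is the simplest length-invariant reduction of a per-residue
    scale to one peptide descriptor; it makes the feature order-free.
    """
    seq = p.seq if isinstance(p, Peptide) else p
    out = np.empty(len(ids))
    for j, acc in enumerate(ids):
        row = table[acc]
        out[j] = sum(row[ch] for ch in seq) / len(seq)
    return out


def encode_peptide(
    p: Peptide, spec: EncodingSpec, table: AAIndexTable | None = None
) -> np.ndarray:
    """Encode one peptide under ``spec`` (hybrids concatenate in order)."""
    try:
        if spec.scheme == "AAC":
            return encode_aac(p)
        if spec.scheme == "DPC":
            return encode_dpc(p)
        if spec.scheme == "N5Bin":
            return encode_binary(p, spec.n_term_len, 0)
        if spec.scheme == "C5Bin":
            return encode_binary(p, 0, spec.c_term_len)
        if spec.scheme == "N5C5Bin":
            return encode_binary(p, spec.n_term_len, spec.c_term_len)
        if spec.scheme == "Physico":
            if table is None:
                raise ValueError("Physico encoding requires an AAIndexTable")
            return encode_physico(p, table, spec.aaindex_ids)
        return np.concatenate(
            [encode_peptide(p, c, table) for c in spec.components]
        )
    except EncodingError as e:
        raise EncodingError(f"peptide {p.id!r}: {e}") from None


@dataclass
class FeatureMatrix:
    """Peptide-by-feature matrix under a named encoding."""

    row_ids: list[str]
    values: np.ndarray
    spec: EncodingSpec

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape != (len(self.row_ids), self.spec.n_features):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.row_ids)} peptides x {self.spec.n_features} features"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.spec.feature_names)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="peptide_id")


def encode(
    spec: EncodingSpec, s: PeptideSet, table: AAIndexTable | None = None
) -> FeatureMatrix:
    """Encode a peptide set; row order follows the set."""
    rows = [encode_peptide(p, spec, table) for p in s]
    values = np.vstack(rows) if rows else np.empty((0, spec.n_features))
    return FeatureMatrix(s.ids, values, spec)


def select_top_indices(
    train: PeptideSet,
    labels: Sequence[int],
    table: AAIndexTable,
    k: int = 10,
    *,
    n_folds: int = 10,
    seed: int = 0,
    C: float = 1.0,
    gamma: str | float = "scale",
) -> list[str]:
    """Rank AAindex scales by single-feature SVM cross-validation accuracy.

    Each accession in ``table`` is evaluated as a one-dimensional RBF-SVM
    classifier under stratified ``n_folds``-fold CV on the training set; the
    ``k`` accessions with highest accuracy are returned (descending accuracy,
    ties broken by accession string, so the ranking is deterministic).
    """
    from sklearn.model_selection import StratifiedKFold, cross_val_score
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import MinMaxScaler
    from sklearn.svm import SVC

    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("index screening requires both classes in the training set")
    if k > len(table):
        raise ValueError(f"k={k} exceeds table size {len(table)}")
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    scored: list[tuple[float, str]] = []
    for acc in table.accessions:
        X = np.array([
            [sum(table[acc][ch] for ch in p.seq) / len(p.seq)] for p in train
        ])
        clf = make_pipeline(MinMaxScaler(), SVC(kernel="rbf", C=C, gamma=gamma))
        score = cross_val_score(clf, X, y, cv=cv, scoring="accuracy").mean()
        scored.append((score, acc))
    scored.sort(key=lambda t: (-t[0], t[1]))
    return [acc for _, acc in scored[:k]]


def physico_spec(table: AAIndexTable, ids: Sequence[str] | None = None) -> EncodingSpec:
    """Physico EncodingSpec over ``ids`` (default: every scale in the table)."""
    return EncodingSpec("Physico", aaindex_ids=tuple(ids if ids is not None else table.accessions))
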