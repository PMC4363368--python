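"""Seeded synthetic peptide sets emulating the QSP / non-QSP data structure.

The real training corpus (220 experimentally verified quorum-sensing
peptides and 220 UniProt-derived non-QSPs) is not redistributable, so this
module generates sets that reproduce its *reported statistical structure*:

* positives: short peptides (lengths 5-30, mean ~11.5) whose residue
  frequencies are the Swiss-Prot background re-weighted by the published
  QSP fold changes — aromatic residues (Trp 3.11x, Phe 2.74x, Tyr 1.51x)
  and Cys/Asn enriched, Asp/Glu/His/Val/Arg/Lys depleted — giving a mean
  aromaticity near 0.18; terminal positional preferences (Ser at
  N-positions 1, 2, 3, 5; Gly at 1, 2; Phe at C-positions 1, 3, 5; Cys at
  C-5) are applied on top;
* negatives: longer peptides (lengths 7-77, mean ~31.8) drawn from the
  Swiss-Prot background composition (aromatic fraction ~0.08).

Everything is deterministic given the seed. :func:`make_separable` builds a
deliberately easy two-class set (Trp-rich vs Trp-free) for classifier
sanity checks, and :func:`scramble` (from seqio) provides the
composition-matched negative strategy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .analysis import SWISSPROT_COMPOSITION
from .seqio import AMINO_ACIDS, NEGATIVE, POSITIVE, Peptide, PeptideSet

#: Published fold changes of QSP composition relative to Swiss-Prot
#: (>1 applied multiplicatively for enriched residues, divisively for
#: depleted ones).
QSP_FOLD_ENRICHED: dict[str, float] = {"C": 3.48, "W": 3.11, "F": 2.74, "N": 1.79, "Y": 1.51}
QSP_FOLD_DEPLETED: dict[str, float] = {"E": 2.68, "H": 2.20, "D": 1.74, "V": 1.54, "R": 1.48, "K": 1.24}

#: Terminal positional multipliers for positives. N-side keys are 1-based
#: positions from the N-terminus; C-side keys are negative (-1 = last).
POSITIONAL_WEIGHTS: dict[int, dict[str, float]] = {
    1: {"S": 3.0, "G": 2.0}, 2: {"S": 3.0, "G": 2.0}, 3: {"S": 3.0}, 5: {"S": 3.0},
    -1: {"F": 2.0}, -3: {"F": 2.0}, -5: {"F": 2.0, "C": 2.0},
}


def qsp_like_composition() -> dict[str, float]:
    """Positive-class residue frequencies (sum to 1)."""
    freq = {aa: SWISSPROT_COMPOSITION[aa] for aa in AMINO_ACIDS}
    for aa, f in QSP_FOLD_ENRICHED.items():
        freq[aa] *= f
    for aa, f in QSP_FOLD_DEPLETED.items():
        freq[aa] /= f
    total = sum(freq.values())
    return {aa: v / total for aa, v in freq.items()}


def background_composition() -> dict[str, float]:
    total = sum(SWISSPROT_COMPOSITION.values())
    return {aa: SWISSPROT_COMPOSITION[aa] / total for aa in AMINO_ACIDS}


@dataclass(frozen=True)
class FixtureSpec:
    """Generation parameters; the defaults emulate the study datasets."""

    n_pos: int = 220
    n_neg: int = 220
    pos_length_range: tuple[int, int] = (5, 30)
    neg_length_range: tuple[int, int] = (7, 77)
    #: lognormal length parameters (median, sigma of log) per class; chosen
    #: so clipped means land near the reported 11.5 and 31.8 residues
    pos_length_lognorm: tuple[float, float] = (11.0, 0.45)
    neg_length_lognorm: tuple[float, float] = (28.5, 0.50)
    pos_residue_bias: dict[str, float] = field(default_factory=qsp_like_composition)
    neg_composition: dict[str, float] = field(default_factory=background_composition)
    positional_weights: dict[int, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in POSITIONAL_WEIGHTS.items()}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name, (lo, hi) in (("pos", self.pos_length_range), ("neg", self.neg_length_range)):
            if not (1 <= lo <= hi):
                raise ValueError(f"invalid {name} length range ({lo}, {hi})")
        for comp in (self.pos_residue_bias, self.neg_composition):
            if any(v <= 0 for v in comp.values()):
                raise ValueError("residue weights must be positive")


def _sample_lengths(
    rng: np.random.Generator, n: int, median: float, sigma: float, lo: int, hi: int
) -> np.ndarray:
    lengths = rng.lognormal(np.log(median), sigma, size=n)
    return np.clip(np.rint(lengths), lo, hi).astype(int)


def _sample_sequence(
    rng: np.random.Generator,
    length: int,
    base: dict[str, float],
    positional: dict[int, dict[str, float]] | None = None,
) -> str:
    aas = list(AMINO_ACIDS)
    base_p = np.array([base[aa] for aa in aas])
    chars: list[str] = []
    for i in range(length):
        p = base_p
        if positional:
            # a position within the last 5 gets its C-side weights; C-side
            # wins over N-side when windows overlap in short peptides
            signed = i - length if i >= length - 5 else i + 1
            weights = positional.get(signed) or (positional.get(i + 1) if i < 5 else None)
            if weights:
                p = base_p.copy()
                for aa, w in weights.items():
                    p[aas.index(aa)] *= w
                p = p / p.sum()
        chars.append(rng.choice(aas, p=p))
    return "".join(chars)


def generate(spec: FixtureSpec = FixtureSpec()) -> tuple[PeptideSet, PeptideSet]:
    """Generate (positives, negatives) deterministically from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    pos_total = sum(spec.pos_residue_bias.values())
    pos_bias = {aa: v / pos_total for aa, v in spec.pos_residue_bias.items()}
    neg_total = sum(spec.neg_composition.values())
    neg_comp = {aa: v / neg_total for aa, v in spec.neg_composition.items()}

    pos_lengths = _sample_lengths(
        rng, spec.n_pos, *spec.pos_length_lognorm, *spec.pos_length_range
    )
    positives = PeptideSet(
        [
            Peptide(f"qsp_{i+1:04d}",
                    _sample_sequence(rng, int(L), pos_bias, spec.positional_weights),
                    POSITIVE)
            for i, L in enumerate(pos_lengths)
        ],
        name="synthetic_qsp",
    )
    neg_lengths = _sample_lengths(
        rng, spec.n_neg, *spec.neg_length_lognorm, *spec.neg_length_range
    )
    negatives = PeptideSet(
        [
            Peptide(f"nonqsp_{i+1:04d}", _sample_sequence(rng, int(L), neg_comp), NEGATIVE)
            for i, L in enumerate(neg_lengths)
        ],
        name="synthetic_nonqsp",
    )
    return positives, negatives


def make_separable(n: int = 400, seed: int = 0, length: int = 15) -> PeptideSet:
    """A linearly separable two-class set for classifier sanity checks.

    Class A (positive): at least 40% Trp per sequence. Class B (negative):
    no Trp at all. A single threshold on the Trp fraction separates the
    classes, so any competent composition-based classifier should approach
    perfect cross-validated accuracy.
    """
    if n < 20:
        raise ValueError("need n >= 20")
    rng = np.random.default_rng(seed)
    others = [aa for aa in AMINO_ACIDS if aa != "W"]
    n_pos = n // 2
    peptides: list[Peptide] = []
    min_w = int(np.ceil(0.4 * length))
    for i in range(n_pos):
        n_w = int(rng.integers(min_w, length + 1))
        chars = ["W"] * n_w + [str(rng.choice(others)) for _ in range(length - n_w)]
        rng.shuffle(chars)
        peptides.append(Peptide(f"sepA_{i+1:04d}", "".join(chars), POSITIVE))
    for i in range(n - n_pos):
        seq = "".join(str(rng.choice(others)) for _ in range(length))
        peptides.append(Peptide(f"sepB_{i+1:04d}", seq, NEGATIVE))
    return PeptideSet(peptides, name="separable")
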