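"""Descriptive sequence analyses: composition, fold change, positional enrichment.

Three complementary views of what distinguishes a peptide class:

* pooled per-residue percent composition of a set;
* fold change of a set's composition against a background composition
  (e.g. Swiss-Prot), reported with an enriched/depleted direction so that
  both directions read as a ratio >= 1;
* two-sample positional enrichment at the first and last *k* residue
  positions (two-proportion z-test with continuity correction), the
  statistic behind a two-sample sequence logo.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy.stats import norm

from .seqio import AMINO_ACIDS, PeptideSet

#: Approximate Swiss-Prot overall amino-acid composition (percent), the
#: customary background for peptide-class comparisons. Values are the
#: well-known UniProtKB/Swiss-Prot release statistics rounded to 0.01;
#: normalized to 100 on load.
SWISSPROT_COMPOSITION: dict[str, float] = {
    "A": 8.25, "R": 5.53, "N": 4.06, "D": 5.45, "C": 1.38,
    "Q": 3.93, "E": 6.72, "G": 7.07, "H": 2.27, "I": 5.91,
    "L": 9.65, "K": 5.80, "M": 2.41, "F": 3.86, "P": 4.74,
    "S": 6.65, "T": 5.36, "W": 1.10, "Y": 2.92, "V": 6.86,
}


@dataclass
class CompositionTable:
    """Per-residue percent composition of a named peptide set."""

    name: str
    percent: dict[str, float]
    n_peptides: int = 0
    total_residues: int = 0

    def __post_init__(self) -> None:
        total = sum(self.percent.values())
        if total <= 0:
            raise ValueError("composition must have positive total")
        # normalize defensively; valid inputs already sum to 100
        self.percent = {aa: 100.0 * self.percent.get(aa, 0.0) / total for aa in AMINO_ACIDS}

    def __getitem__(self, aa: str) -> float:
        return self.percent[aa]

    def to_series(self) -> pd.Series:
        return pd.Series(self.percent, name=self.name)


def swissprot_background() -> CompositionTable:
    return CompositionTable("Swiss-Prot", dict(SWISSPROT_COMPOSITION))


def read_composition_tsv(path: str | Path, name: str | None = None) -> CompositionTable:
    """Read a two-column residue<TAB>percent table."""
    percent: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        aa, val = line.split("\t")
        percent[aa.strip().upper()] = float(val)
    return CompositionTable(name or Path(path).stem, percent)


def composition(s: PeptideSet) -> CompositionTable:
    """Pooled residue counts across the set, as percentages."""
    if len(s) == 0:
        raise ValueError("empty peptide set")
    counts = {aa: 0 for aa in AMINO_ACIDS}
    total = 0
    for p in s:
        for ch in p.seq:
            counts[ch] += 1
        total += len(p)
    percent = {aa: 100.0 * c / total for aa, c in counts.items()}
    return CompositionTable(s.name or "set", percent, n_peptides=len(s), total_residues=total)


def fold_change(query: CompositionTable, background: CompositionTable) -> pd.DataFrame:
    """Per-residue fold change of ``query`` against ``background``.

    Enriched residues (query > background) report query/background and
    depleted ones background/query, so every fold is >= 1 and carries a
    direction; a residue absent from the query is flagged
    (direction ``absent``, fold infinite).
    """
    rows = []
    for aa in AMINO_ACIDS:
        q, b = query[aa], background[aa]
        if b <= 0:
            raise ValueError(f"background composition for {aa} must be > 0")
        if q == 0:
            rows.append((aa, q, b, math.inf, "absent"))
        elif q >= b:
            rows.append((aa, q, b, q / b, "enriched"))
        else:
            rows.append((aa, q, b, b / q, "depleted"))
    return pd.DataFrame(
        rows, columns=["residue", "query_pct", "background_pct", "fold", "direction"]
    ).set_index("residue")


def two_proportion_test(x1: int, n1: int, x2: int, n2: int) -> float:
    """Two-sided two-proportion z-test p-value with continuity correction.

    Tests H0: p1 == p2 using the pooled-variance z statistic with Yates'
    continuity correction. Degenerate cases (pooled proportion 0 or 1)
    return p = 1.
    """
    if min(n1, n2) == 0:
        raise ValueError("sample sizes must be positive")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    var = pooled * (1 - pooled) * (1 / n1 + 1 / n2)
    if var == 0:
        return 1.0
    cc = 0.5 * (1 / n1 + 1 / n2)
    z = (abs(p1 - p2) - cc) / math.sqrt(var)
    z = max(z, 0.0)
    return float(2 * norm.sf(z))


@dataclass(frozen=True)
class PositionEnrichment:
    """One significant residue/position contrast between two sets.

    ``position`` is signed: +1..+k from the N-terminus, -1..-k from the
    C-terminus (-1 = last residue).
    """

    position: int
    residue: str
    freq_pos: float
    freq_neg: float
    p_value: float
    direction: str  # enriched | depleted (in the positive set)


def positional_enrichment(
    pos: PeptideSet,
    neg: PeptideSet,
    n_positions: int = 5,
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> tuple[list[PositionEnrichment], dict[str, int]]:
    """Two-sample residue enrichment at terminal positions.

    Peptides shorter than ``n_positions`` are excluded (their terminal
    windows would overlap); the returned ``info`` dict reports how many were
    skipped per set. For each terminal position and residue, frequencies in
    the two sets are compared by a two-sided two-proportion z-test with
    continuity correction; entries with p < alpha (optionally
    Bonferroni-adjusted across the 20 residues x 2k positions family) are
    returned sorted by position then p-value.
    """
    pos_kept = [p for p in pos if len(p) >= n_positions]
    neg_kept = [p for p in neg if len(p) >= n_positions]
    info = {
        "pos_skipped": len(pos) - len(pos_kept),
        "neg_skipped": len(neg) - len(neg_kept),
        "pos_used": len(pos_kept),
        "neg_used": len(neg_kept),
    }
    if not pos_kept or not neg_kept:
        raise ValueError("a set is empty after length filtering")
    positions = [i + 1 for i in range(n_positions)] + [-(i + 1) for i in range(n_positions)]
    threshold = alpha / (len(positions) * 20) if bonferroni else alpha
    results: list[PositionEnrichment] = []
    n1, n2 = len(pos_kept), len(neg_kept)
    for signed in positions:
        idx = signed - 1 if signed > 0 else signed
        for aa in AMINO_ACIDS:
            x1 = sum(1 for p in pos_kept if p.seq[idx] == aa)
            x2 = sum(1 for p in neg_kept if p.seq[idx] == aa)
            if x1 == 0 and x2 == 0:
                continue
            pval = two_proportion_test(x1, n1, x2, n2)
            if pval < threshold:
                results.append(
                    PositionEnrichment(
                        position=signed, residue=aa,
                        freq_pos=x1 / n1, freq_neg=x2 / n2, p_value=pval,
                        direction="enriched" if x1 / n1 > x2 / n2 else "depleted",
                    )
                )
    results.sort(key=lambda e: (abs(e.position), e.position < 0, e.p_value))
    return results, info


def enrichment_table(results: list[PositionEnrichment]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.position, e.residue, e.freq_pos, e.freq_neg, e.p_value, e.direction)
         for e in results],
        columns=["position", "residue", "freq_pos", "freq_neg", "p_value", "direction"],
    )
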