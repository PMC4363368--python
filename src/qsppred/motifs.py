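"""Bracket-class motif patterns: parsing, scanning and PPV/coverage.

Motif expressions use the PROSITE-like bracket notation: a pattern is a
string of positions, each either a literal residue (``D``) or a class of
alternatives (``[YP]``). The nine quorum-sensing peptide motifs extracted at
E-value 1 ship as the default pattern set; users may supply their own in a
one-``id<TAB>expression``-per-line file.

Evaluation counts at the peptide level: a peptide is "motif-positive" if
any pattern matches anywhere in it. Over a positive and a negative set,
TP/FP/FN are motif-positive positives, motif-positive negatives and
motif-negative positives; PPV = TP/(TP+FP) and % coverage = 100*TP/(TP+FN).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .seqio import AA_SET, PeptideSet

#: Default quorum-sensing peptide motif set (E-value 1 tier).
DEFAULT_MOTIF_EXPRESSIONS: dict[str, str] = {
    "Motif 1": "LSTFFRLFNRSFTQA",
    "Motif 2": "[YP][NS][PTI][CF]GQ[YW][MF]",
    "Motif 3": "[TA]S[NS][IL][SV][KE]CVFS[FL]FKKC",
    "Motif 4": "E[SM]R[LI][SP][KR]I[LI][LR]DF",
    "Motif 5": "[DE]I[IL]IIVGG",
    "Motif 6": "LPYF[AF][GK][CH]L",
    "Motif 7": "[DS]SAC[VY][VW][GC]",
    "Motif 8": "G[LW]WE[DE][LI]L[YH]",
    "Motif 9": "DPITRQW",
}


class MotifParseError(ValueError):
    """Malformed bracket-class expression."""


@dataclass(frozen=True)
class MotifPattern:
    """A parsed bracket-class motif.

    ``positions`` holds one frozenset of allowed residues per pattern
    position; the compiled regex finds all (overlapping) matches.
    """

    id: str
    expression: str
    positions: tuple[frozenset, ...]
    source_evalue_tier: float = 1.0
    _regex: re.Pattern = field(repr=False, compare=False, default=None)

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def regex(self) -> re.Pattern:
        return self._regex

    def matches_at(self, seq: str, start: int) -> bool:
        if start < 0 or start + len(self) > len(seq):
            return False
        return all(seq[start + i] in cls for i, cls in enumerate(self.positions))


def parse_pattern(expr: str, motif_id: str = "", evalue_tier: float = 1.0) -> MotifPattern:
    """Parse a bracket-class expression into a :class:`MotifPattern`."""
    if not expr:
        raise MotifParseError("empty expression")
    positions: list[frozenset] = []
    i = 0
    while i < len(expr):
        ch = expr[i]
        if ch == "[":
            j = expr.find("]", i)
            if j < 0:
                raise MotifParseError(f"{expr!r}: unbalanced '[' at offset {i}")
            members = expr[i + 1 : j]
            if not members:
                raise MotifParseError(f"{expr!r}: empty class at offset {i}")
            bad = set(members) - AA_SET
            if bad:
                raise MotifParseError(f"{expr!r}: invalid residue(s) {sorted(bad)}")
            positions.append(frozenset(members))
            i = j + 1
        elif ch == "]":
            raise MotifParseError(f"{expr!r}: unmatched ']' at offset {i}")
        elif ch in AA_SET:
            positions.append(frozenset(ch))
            i += 1
        else:
            raise MotifParseError(f"{expr!r}: invalid residue {ch!r} at offset {i}")
    # lookahead wrapper reports every overlapping occurrence
    body = "".join(
        next(iter(cls)) if len(cls) == 1 else "[" + "".join(sorted(cls)) + "]"
        for cls in positions
    )
    rx = re.compile(f"(?=({body}))")
    return MotifPattern(
        id=motif_id or expr, expression=expr,
        positions=tuple(positions), source_evalue_tier=evalue_tier, _regex=rx,
    )


def default_patterns() -> list[MotifPattern]:
    return [parse_pattern(expr, mid) for mid, expr in DEFAULT_MOTIF_EXPRESSIONS.items()]


def read_pattern_file(path: str | Path) -> list[MotifPattern]:
    """Read ``id<TAB>expression`` lines (``#`` comments, blank lines skipped)."""
    patterns = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            mid, expr = line.split("\t", 1)
        except ValueError:
            raise MotifParseError(f"{path}:{lineno}: expected 'id<TAB>expression'")
        patterns.append(parse_pattern(expr.strip(), mid.strip()))
    if not patterns:
        raise MotifParseError(f"{path}: no patterns")
    return patterns


def scan(s: PeptideSet, patterns: list[MotifPattern] | None = None) -> pd.DataFrame:
    """All (overlapping) motif matches over a peptide set.

    Returns a frame with columns peptide_id, motif_id, start (0-based) and
    the matched substring; empty if nothing matches.
    """
    if patterns is None:
        patterns = default_patterns()
    rows = []
    for p in s:
        for pat in patterns:
            for m in pat.regex.finditer(p.seq):
                rows.append((p.id, pat.id, m.start(), m.group(1)))
    return pd.DataFrame(rows, columns=["peptide_id", "motif_id", "start", "match"])


def motif_positive_ids(s: PeptideSet, patterns: list[MotifPattern]) -> set[str]:
    hits = scan(s, patterns)
    return set(hits["peptide_id"])


@dataclass
class MotifScanResult:
    """Set-level evaluation of a pattern list against labelled sets."""

    tp: int
    fp: int
    fn: int
    tn: int
    ppv: float | None  # None when TP+FP == 0 (undefined)
    percent_coverage: float
    hits_pos: pd.DataFrame
    hits_neg: pd.DataFrame
    #: per-motif counts: peptides hit and total occurrences, in each set
    per_motif: pd.DataFrame = None

    @property
    def ppv_defined(self) -> bool:
        return self.ppv is not None


def evaluate(
    pos: PeptideSet, neg: PeptideSet, patterns: list[MotifPattern] | None = None
) -> MotifScanResult:
    """Peptide-level PPV and % coverage of a motif set.

    ``per_motif`` reports, for each motif, both the number of distinct
    peptides hit and the total occurrence count (the two readings of a
    "number of motifs" tally), per set.
    """
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both sets must be non-empty")
    if patterns is None:
        patterns = default_patterns()
    hits_pos = scan(pos, patterns)
    hits_neg = scan(neg, patterns)
    tp = hits_pos["peptide_id"].nunique()
    fp = hits_neg["peptide_id"].nunique()
    fn = len(pos) - tp
    tn = len(neg) - fp
    ppv = tp / (tp + fp) if (tp + fp) > 0 else None
    coverage = 100.0 * tp / (tp + fn)
    per_motif_rows = []
    for pat in patterns:
        hp = hits_pos[hits_pos["motif_id"] == pat.id]
        hn = hits_neg[hits_neg["motif_id"] == pat.id]
        per_motif_rows.append(
            (pat.id, hp["peptide_id"].nunique(), len(hp),
             hn["peptide_id"].nunique(), len(hn))
        )
    per_motif = pd.DataFrame(
        per_motif_rows,
        columns=["motif_id", "pos_peptides", "pos_occurrences",
                 "neg_peptides", "neg_occurrences"],
    )
    return MotifScanResult(
        tp=tp, fp=fp, fn=fn, tn=tn, ppv=ppv, percent_coverage=coverage,
        hits_pos=hits_pos, hits_neg=hits_neg, per_motif=per_motif,
    )
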