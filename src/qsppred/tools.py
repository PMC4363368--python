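"""Peptide design and protein-scanning tools built on the trained classifier.

* :func:`mutgen` — enumerate all single-position mutants of a peptide
  (19 alternatives x L positions, position-major, residues alphabetical).
* :func:`protfrag` — cut a protein into sliding windows of fixed length.
* :func:`qspepdesign` — score the parent and every mutant, ranked by
  decision value, to suggest substitutions that strengthen or weaken the
  predicted quorum-sensing signal.
* :func:`qspepmap` — score every window of a protein and merge contiguous
  predicted-positive windows into candidate regions.

All machine-readable coordinates are 0-based, half-open.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .model import TrainedModel, predict
from .seqio import AMINO_ACIDS, Peptide, PeptideSet


@dataclass(frozen=True)
class MutantRecord:
    parent_id: str
    position: int  # 0-based
    original: str
    substituted: str
    seq: str


@dataclass(frozen=True)
class WindowRecord:
    protein_id: str
    start: int  # 0-based, half-open [start, start+w)
    seq: str


def mutgen(p: Peptide) -> list[MutantRecord]:
    """All 19*L single-position mutants, deterministic order.

    Position-major; within a position, substitutes run alphabetically over
    the 19 residues differing from the original.
    """
    mutants: list[MutantRecord] = []
    for i, orig in enumerate(p.seq):
        for aa in AMINO_ACIDS:
            if aa == orig:
                continue
            seq = p.seq[:i] + aa + p.seq[i + 1 :]
            mutants.append(MutantRecord(p.id, i, orig, aa, seq))
    return mutants


def protfrag(protein: Peptide, w: int, step: int = 1) -> list[WindowRecord]:
    """Sliding windows of length ``w`` at stride ``step``.

    Starts are 0, step, 2*step, ... while start+w <= L, giving
    floor((L-w)/step)+1 windows.
    """
    L = len(protein)
    if w < 1 or w > L:
        raise ValueError(f"window {w} must be in [1, {L}]")
    if step < 1:
        raise ValueError("step must be >= 1")
    return [
        WindowRecord(protein.id, start, protein.seq[start : start + w])
        for start in range(0, L - w + 1, step)
    ]


def _mutant_set(parent: Peptide, mutants: list[MutantRecord]) -> PeptideSet:
    peptides = [Peptide(f"{parent.id}|parent", parent.seq)]
    peptides += [
        Peptide(f"{m.parent_id}|{m.position}{m.original}>{m.substituted}", m.seq)
        for m in mutants
    ]
    return PeptideSet(peptides, name=f"{parent.id}_mutants")


def qspepdesign(model: TrainedModel, parent: Peptide) -> pd.DataFrame:
    """Score the parent and all its single-position mutants.

    Returns one row per variant (19*L + 1 rows), sorted by decision value
    descending, with the parent row flagged. Unscorable variants (encoding
    precondition violations) keep their row with ``scorable=False``.
    """
    mutants = mutgen(parent)
    scored = predict(model, _mutant_set(parent, mutants))
    meta = {f"{parent.id}|parent": (None, parent.seq[0] if parent.seq else "", "", parent.seq)}
    for m in mutants:
        meta[f"{m.parent_id}|{m.position}{m.original}>{m.substituted}"] = (
            m.position, m.original, m.substituted, m.seq
        )
    out = scored.copy()
    out["position"] = [meta[i][0] for i in out.index]
    out["original"] = [meta[i][1] for i in out.index]
    out["substituted"] = [meta[i][2] for i in out.index]
    out["seq"] = [meta[i][3] for i in out.index]
    out["is_parent"] = [i.endswith("|parent") for i in out.index]
    return out.sort_values("decision_value", ascending=False, kind="stable")


def merge_positive_windows(frame: pd.DataFrame, w: int) -> list[tuple[int, int]]:
    """Merge contiguous (touching or overlapping) positive windows.

    Returns 0-based half-open regions [start of first window, end of last].
    """
    starts = sorted(frame.loc[frame["label"] == "positive", "start"])
    regions: list[tuple[int, int]] = []
    for s in starts:
        if regions and s <= regions[-1][1]:
            regions[-1] = (regions[-1][0], max(regions[-1][1], s + w))
        else:
            regions.append((s, s + w))
    return regions


def qspepmap(
    model: TrainedModel, protein: Peptide, w: int = 12, step: int = 1
) -> tuple[pd.DataFrame, list[tuple[int, int]]]:
    """Score every window of a protein; report merged positive regions.

    The default window of 12 residues matches the typical quorum-sensing
    peptide length. Returns (per-window frame sorted by start, merged
    regions as 0-based half-open intervals).
    """
    windows = protfrag(protein, w, step)
    pepset = PeptideSet(
        [Peptide(f"{protein.id}|{win.start}", win.seq) for win in windows],
        name=f"{protein.id}_windows",
    )
    scored = predict(model, pepset)
    scored = scored.assign(
        start=[win.start for win in windows],
        end=[win.start + w for win in windows],
        seq=[win.seq for win in windows],
    ).sort_values("start", kind="stable")
    regions = merge_positive_windows(scored, w)
    return scored, regions
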