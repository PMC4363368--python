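"""Per-residue physicochemical scales (AAindex-style) for feature encoding.

An AAindex entry assigns one numeric value to each of the 20 standard
residues; a peptide feature is derived from such a scale by averaging over
the peptide's residues (see :mod:`qsppred.features`). This module provides

* :class:`AAIndexTable`, a mapping of accession → 20 values,
* a reader for the AAindex1 flat-file format (``H``/``I`` records),
* :func:`curated_table`, genuine literature scales available at run time
  (hydropathy, hydrophilicity, flexibility, buried-surface scales, residue
  mass), and
* :func:`synthetic_screening_table`, a seeded generator of AAindex-like
  scales used to exercise large-scale index screening when the full AAindex
  release (544 indices) is not distributed with the package.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from pathlib import Path

from Bio.Data.IUPACData import protein_weights
from Bio.SeqUtils import ProtParamData

from .seqio import AMINO_ACIDS

#: AAindex accessions named in the quorum-sensing peptide study as the best
#: performing candidate indices (mostly secondary-structure propensities).
#: Shipped as identifiers only; their numeric values are not bundled.
CANDIDATE_ACCESSIONS = [
    "NAGK730101",  # normalized frequency of alpha-helix
    "KANM800101",  # average relative probability of helix
    "AURR980118",  # positional residue frequency at helix termini C"
    "AURR980103",  # positional residue frequency at helix termini N"
    "AURR980101",  # positional residue frequency at helix termini N4'
    "CHAM830101",  # Chou-Fasman coil parameter
    "CHOP780210",  # normalized frequency of N-terminal non-beta region
    "CHOP780101",  # normalized frequency of beta-turn
    "FASG760105",  # pK-C
    "LEVM760105",  # radius of gyration of side chain
    "RICJ880105",  # relative preference value at N2
    "WOEC730101",  # polar requirement
]


@dataclass
class AAIndexTable:
    """Mapping of accession → (20 per-residue values, description)."""

    values: dict[str, dict[str, float]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for acc, row in self.values.items():
            if set(row) != set(AMINO_ACIDS):
                raise ValueError(f"index {acc}: must define all 20 residues")
            if not all(math.isfinite(v) for v in row.values()):
                raise ValueError(f"index {acc}: non-finite value")

    @property
    def accessions(self) -> list[str]:
        return list(self.values)

    def __len__(self) -> int:
        return len(self.values)

    def __contains__(self, acc: str) -> bool:
        return acc in self.values

    def __getitem__(self, acc: str) -> dict[str, float]:
        try:
            return self.values[acc]
        except KeyError:
            raise KeyError(f"unknown AAindex accession {acc!r}") from None

    def add(self, acc: str, row: dict[str, float], description: str = "") -> None:
        if set(row) != set(AMINO_ACIDS):
            raise ValueError(f"index {acc}: must define all 20 residues")
        self.values[acc] = dict(row)
        self.descriptions[acc] = description

    def merged(self, other: "AAIndexTable") -> "AAIndexTable":
        vals = {**self.values, **other.values}
        desc = {**self.descriptions, **other.descriptions}
        return AAIndexTable(vals, desc)


# AAindex1 "I" records list values for residues in this fixed order
# (two rows: A/R/N/D/C/Q/E/G/H/I then L/K/M/F/P/S/T/W/Y/V).
_AAINDEX_ORDER = "ARNDCQEGHILKMFPSTWYV"


def read_aaindex_flatfile(path: str | Path) -> AAIndexTable:
    """Parse an AAindex1 flat file (``H``, ``D``, ``I`` records, ``//`` ends)."""
    table = AAIndexTable()
    acc = ""
    desc = ""
    numbers: list[float] = []
    in_values = False
    with open(path) as fh:
        for line in fh:
            if line.startswith("H "):
                acc = line[2:].strip()
                desc, numbers, in_values = "", [], False
            elif line.startswith("D "):
                desc = line[2:].strip()
            elif line.startswith("I "):
                in_values = True
            elif line.startswith("//"):
                if acc:
                    if len(numbers) != 20:
                        raise ValueError(f"index {acc}: expected 20 values, got {len(numbers)}")
                    row = dict(zip(_AAINDEX_ORDER, numbers))
                    table.add(acc, row, desc)
                acc, desc, numbers, in_values = "", "", [], False
            elif in_values:
                numbers.extend(
                    float("nan") if tok in ("NA", "-") else float(tok)
                    for tok in line.split()
                )
    return table


def write_aaindex_flatfile(table: AAIndexTable, path: str | Path) -> None:
    """Write a table in AAindex1 flat-file form (round-trips with the reader)."""
    with open(path, "w") as fh:
        for acc in table.accessions:
            row = table[acc]
            fh.write(f"H {acc}\n")
            fh.write(f"D {table.descriptions.get(acc, '')}\n")
            fh.write("I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V\n")
            first = " ".join(f"{row[aa]:8.3f}" for aa in _AAINDEX_ORDER[:10])
            second = " ".join(f"{row[aa]:8.3f}" for aa in _AAINDEX_ORDER[10:])
            fh.write(f"  {first}\n  {second}\n//\n")


def curated_table() -> AAIndexTable:
    """Genuine per-residue scales, loaded from Biopython reference data.

    These are real literature scales (with their customary AAindex-style
    accessions) covering hydropathy, hydrophilicity, chain flexibility,
    burial preference, transfer energy, and residue mass — enough to drive
    the physicochemical feature encoding with interpretable descriptors.
    """
    t = AAIndexTable()
    t.add("KYTJ820101", dict(ProtParamData.kd), "Kyte-Doolittle hydropathy")
    t.add("HOPT810101", dict(ProtParamData.hw), "Hopp-Woods hydrophilicity")
    t.add("VINM940101", dict(ProtParamData.Flex), "Vihinen normalized flexibility")
    t.add("JANJ780101", dict(ProtParamData.ja), "Janin transfer free energy (buried scale)")
    t.add("ENGD860101", dict(ProtParamData.em), "Engelman GES transmembrane transfer energy")
    residue_mass = {
        aa: protein_weights[aa] - 18.0153 for aa in AMINO_ACIDS
    }
    t.add("FAUJ880103", residue_mass, "average residue mass (Da)")
    aromatic = {aa: 1.0 if aa in "FWY" else 0.0 for aa in AMINO_ACIDS}
    t.add("AROM000101", aromatic, "aromatic residue indicator (F/W/Y)")
    charge = {aa: {"K": 1.0, "R": 1.0, "H": 0.5, "D": -1.0, "E": -1.0}.get(aa, 0.0) for aa in AMINO_ACIDS}
    t.add("CHRG000101", charge, "nominal side-chain charge at neutral pH")
    return t


def synthetic_screening_table(
    n_indices: int = 544, seed: int = 0, prefix: str = "SYN"
) -> AAIndexTable:
    """Synthetic AAindex-style table for screening-scale tests.

    Generates ``n_indices`` seeded pseudo-scales (standard-normal per-residue
    values). These are *synthetic stand-ins*, not real AAindex entries: they
    carry no biochemical meaning and exist so that top-k index screening can
    be exercised at the full 544-index scale without distributing the AAindex
    database. Accessions are ``{prefix}000001`` … and sort deterministically.
    """
    rng = random.Random(seed)
    t = AAIndexTable()
    for i in range(1, n_indices + 1):
        row = {aa: rng.gauss(0.0, 1.0) for aa in AMINO_ACIDS}
        t.add(f"{prefix}{i:06d}", row, f"synthetic screening scale {i}")
    return t


def default_table(seed: int = 0, n_total: int = 544) -> AAIndexTable:
    """Curated genuine scales padded with synthetic ones to ``n_total``.

    Mirrors the scale of a full AAindex screening run while keeping the
    genuine, interpretable scales first.
    """
    base = curated_table()
    n_syn = max(0, n_total - len(base))
    return base.merged(synthetic_screening_table(n_syn, seed=seed))
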