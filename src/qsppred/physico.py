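"""Physicochemical property panel for peptides (PhysicoProp).

Computes, per peptide: length, aromaticity, Guruprasad instability index,
isoelectric point, average molecular weight and GRAVY — the panel used to
contrast quorum-sensing peptides with non-QSPs — plus per-set summary
statistics (mean/min/quartiles/max) for the same six properties.

Reference tables (dipeptide instability weights, Kyte–Doolittle hydropathy,
Bjellqvist pK values, average residue masses) are taken from Biopython's
ProtParam data, matching the ExPASy ProtParam conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import pandas as pd
from Bio.Data.IUPACData import protein_weights
from Bio.SeqUtils import ProtParamData
from Bio.SeqUtils import IsoelectricPoint as _IP

from .seqio import Peptide, PeptideSet

WATER_MASS = 18.0153  # average mass of H2O, Da

#: Guruprasad dipeptide instability weight values (DIWV), nested dict
#: DIWV[x][y] for the dipeptide x-y.
DEFAULT_DIWV: dict[str, dict[str, float]] = ProtParamData.DIWV

#: Kyte-Doolittle 1982 hydropathy scale.
KYTE_DOOLITTLE: dict[str, float] = ProtParamData.kd

#: Bjellqvist pK sets used by ProtParam (N/C termini and ionizable side
#: chains). The terminal pKs are adjusted by the identity of the first/last
#: residue, as in ProtParam.
POSITIVE_PKS: dict[str, float] = dict(_IP.positive_pKs)  # Nterm, K, R, H
NEGATIVE_PKS: dict[str, float] = dict(_IP.negative_pKs)  # Cterm, D, E, C, Y
NTERM_PK_BY_RESIDUE: dict[str, float] = dict(_IP.pKnterminal)
CTERM_PK_BY_RESIDUE: dict[str, float] = dict(_IP.pKcterminal)

AROMATIC = frozenset("FYW")

STABILITY_THRESHOLD = 40.0  # II below this is conventionally "stable"

PROPERTIES = ("length", "aromaticity", "instability_index", "pI", "molecular_weight", "gravy")


def _seq(p: Peptide | str) -> str:
    return p.seq if isinstance(p, Peptide) else p


def aromaticity(p: Peptide | str) -> float:
    """Relative frequency of aromatic residues (Phe, Tyr, Trp)."""
    s = _seq(p)
    return sum(1 for ch in s if ch in AROMATIC) / len(s)


def instability_index(p: Peptide | str, diwv: dict[str, dict[str, float]] | None = None) -> float:
    """Guruprasad instability index: (10/L) * sum of DIWV over dipeptides.

    Order-sensitive (unlike the composition-based properties); a value
    below 40 is conventionally read as a stable peptide.
    """
    s = _seq(p)
    if len(s) < 2:
        raise ValueError("instability index requires length >= 2")
    t = DEFAULT_DIWV if diwv is None else diwv
    total = sum(t[a][b] for a, b in zip(s, s[1:]))
    return 10.0 / len(s) * total


def is_stable(p: Peptide | str) -> bool:
    return instability_index(p) < STABILITY_THRESHOLD


def gravy(p: Peptide | str, scale: dict[str, float] | None = None) -> float:
    """Grand average of hydropathy: mean Kyte-Doolittle value over residues."""
    s = _seq(p)
    sc = KYTE_DOOLITTLE if scale is None else scale
    return sum(sc[ch] for ch in s) / len(s)


def molecular_weight(p: Peptide | str) -> float:
    """Average molecular weight in Daltons: residue masses plus one water."""
    s = _seq(p)
    return sum(protein_weights[ch] for ch in s) - (len(s) - 1) * WATER_MASS


def net_charge(p: Peptide | str, pH: float) -> float:
    """Henderson–Hasselbalch net charge at ``pH`` (Bjellqvist pK set).

    Positive groups (N-terminus, Lys, Arg, His) contribute
    ``1/(1+10^(pH-pK))`` each; negative groups (C-terminus, Asp, Glu, Cys,
    Tyr) contribute ``-1/(1+10^(pK-pH))``.
    """
    s = _seq(p)
    counts = {aa: s.count(aa) for aa in "KRHDECY"}
    nterm_pk = NTERM_PK_BY_RESIDUE.get(s[0], POSITIVE_PKS["Nterm"])
    cterm_pk = CTERM_PK_BY_RESIDUE.get(s[-1], NEGATIVE_PKS["Cterm"])
    charge = 1.0 / (1.0 + 10 ** (pH - nterm_pk))
    for aa in "KRH":
        charge += counts[aa] / (1.0 + 10 ** (pH - POSITIVE_PKS[aa]))
    charge -= 1.0 / (1.0 + 10 ** (cterm_pk - pH))
    for aa in "DECY":
        charge -= counts[aa] / (1.0 + 10 ** (NEGATIVE_PKS[aa] - pH))
    return charge


def isoelectric_point(p: Peptide | str, tol: float = 1e-4) -> float:
    """pH at which the peptide's net charge is zero, by bisection on (0, 14).

    Net charge is strictly decreasing in pH, positive at pH 0 (free
    N-terminus) and negative at pH 14 (free C-terminus), so the root always
    exists and bisection converges.
    """
    lo, hi = 0.0, 14.0
    mid = 7.0
    for _ in range(100):
        mid = (lo + hi) / 2.0
        c = net_charge(p, mid)
        if abs(c) < tol:
            break
        if c > 0:
            lo = mid
        else:
            hi = mid
    return mid


@dataclass(frozen=True)
class PhysicoProfile:
    """The six-property vector for one peptide."""

    length: int
    aromaticity: float
    instability_index: float
    pI: float
    molecular_weight: float
    gravy: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def profile(p: Peptide | str) -> PhysicoProfile:
    """Compute the full property panel for one peptide (length >= 2)."""
    s = _seq(p)
    return PhysicoProfile(
        length=len(s),
        aromaticity=aromaticity(s),
        instability_index=instability_index(s),
        pI=isoelectric_point(s),
        molecular_weight=molecular_weight(s),
        gravy=gravy(s),
    )


def profile_table(s: PeptideSet) -> pd.DataFrame:
    """One row per peptide with the six properties (index = peptide id)."""
    if len(s) == 0:
        raise ValueError("empty peptide set")
    rows = {p.id: profile(p).as_dict() for p in s}
    return pd.DataFrame.from_dict(rows, orient="index")[list(PROPERTIES)]


@dataclass
class SetSummary:
    """Per-property mean/min/quartiles/max over a peptide set."""

    name: str
    n_peptides: int
    stats: pd.DataFrame  # rows: properties; cols: mean, min, q25, median, q75, max

    def mean(self, prop: str) -> float:
        return float(self.stats.loc[prop, "mean"])


def profile_set(s: PeptideSet) -> SetSummary:
    """Summary statistics of the property panel over a whole set."""
    table = profile_table(s)
    stats = pd.DataFrame(
        {
            "mean": table.mean(),
            "min": table.min(),
            "q25": table.quantile(0.25),
            "median": table.median(),
            "q75": table.quantile(0.75),
            "max": table.max(),
        }
    )
    return SetSummary(name=s.name, n_peptides=len(s), stats=stats)
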