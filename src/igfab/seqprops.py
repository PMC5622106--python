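"""Sequence-based properties of immunoglobulin domains.

Computes amino-acid composition, Shannon sequence entropy, lysine-minus-arginine
content, aromatic content, isoelectric point and a charge/hydropathy folding
propensity, and expresses each as a z-score deviation from a reference
population (e.g. a proteome-scale solubility dataset).
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Maximum composition entropy in bits: log2(20).
MAX_ENTROPY_BITS = math.log2(20)

#: EMBOSS pKa values used for the isoelectric point by default.
EMBOSS_PKA = {
    "Nterm": 8.6,
    "Cterm": 3.6,
    "C": 8.5,
    "D": 3.9,
    "E": 4.1,
    "H": 6.5,
    "K": 10.8,
    "R": 12.5,
    "Y": 10.1,
}
BASIC_GROUPS = frozenset({"Nterm", "H", "K", "R"})
ACIDIC_GROUPS = frozenset({"Cterm", "C", "D", "E", "Y"})

#: Kyte-Doolittle hydropathy (raw scale, range [-4.5, 4.5]).
KYTE_DOOLITTLE = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8,
    "G": -0.4, "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8,
    "M": 1.9, "N": -3.5, "P": -1.6, "Q": -3.5, "R": -4.5,
    "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
}

#: Formal residue charges at neutral pH used by the folding-propensity net
#: charge. His is treated as neutral (model pKa ~6.3 < 7).
NEUTRAL_PH_CHARGE = {"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0, "H": 0.0}

PROPERTY_NAMES = ("k_minus_r", "pI", "entropy", "aromatic", "folding_propensity")


class SequenceError(ValueError):
    """Raised for sequences that cannot be analysed."""


@dataclass(frozen=True)
class DomainSequence:
    """An amino-acid sequence with an identity and a region label.

    Parameters
    ----------
    id : str
        Identifier (e.g. ``"1hzh_H_CH1"`` or ``"VSIG2:143-233"``).
    sequence : str
        Residues over the canonical 20-letter alphabet. Non-canonical letters
        (X, B, Z, U, gaps) are dropped with a warning before analysis.
    region : str
        One of ``VH, CH1, VL, CL, CDR, IgSF, other``.
    source_range : tuple of (int, int), optional
        1-based inclusive positions in the parent chain.
    """

    id: str
    sequence: str
    region: str = "other"
    source_range: tuple[int, int] | None = None

    VALID_REGIONS = frozenset({"VH", "CH1", "VL", "CL", "CDR", "IgSF", "other"})

    def __post_init__(self) -> None:
        if self.region not in self.VALID_REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        cleaned = clean_sequence(self.sequence, warn_id=self.id)
        object.__setattr__(self, "sequence", cleaned)
        if not cleaned:
            raise SequenceError(f"{self.id}: empty sequence after cleaning")
        if self.source_range is not None:
            start, end = self.source_range
            if end - start + 1 != len(cleaned):
                raise ValueError(
                    f"{self.id}: source_range {self.source_range} inconsistent "
                    f"with length {len(cleaned)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


def clean_sequence(sequence: str, warn_id: str = "?") -> str:
    """Uppercase and drop non-canonical letters (X/B/Z/U, gaps) with a warning."""
    seq = sequence.upper().replace("-", "").replace(".", "").replace("*", "")
    kept = [a for a in seq if a in AMINO_ACIDS]
    n_dropped = len(seq) - len(kept)
    if n_dropped:
        logger.warning("%s: dropped %d non-canonical residues", warn_id, n_dropped)
    return "".join(kept)


@dataclass(frozen=True)
class CompositionVector:
    """Per-amino-acid fractions of a sequence; sums to one."""

    fractions: Mapping[str, float]
    n_residues: int

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {total}, not 1")
        if any(f < 0 for f in self.fractions.values()):
            raise ValueError("negative composition fraction")

    def as_array(self, order: str = AMINO_ACIDS) -> np.ndarray:
        """The 20 fractions as a vector in the given alphabet order."""
        return np.array([self.fractions.get(a, 0.0) for a in order])

    @classmethod
    def from_array(cls, values: np.ndarray, n_residues: int = 0,
                   order: str = AMINO_ACIDS) -> "CompositionVector":
        values = np.asarray(values, dtype=float)
        return cls(dict(zip(order, values / values.sum())), n_residues)


@dataclass(frozen=True)
class SequenceProperties:
    """The scalar sequence properties of one domain."""

    k_minus_r: float          # percentage points, %K - %R
    pI: float                 # pH units
    entropy: float            # bits
    aromatic: float           # percent, F+W+Y
    folding_propensity: float # dimensionless; > 0 predicts folded

    def __post_init__(self) -> None:
        if not (0.0 <= self.entropy <= MAX_ENTROPY_BITS + 1e-9):
            raise ValueError(f"entropy {self.entropy} outside [0, log2 20]")
        if not (-100.0 <= self.k_minus_r <= 100.0):
            raise ValueError("k_minus_r outside [-100, 100]")
        if not (0.0 <= self.aromatic <= 100.0):
            raise ValueError("aromatic outside [0, 100]")
        if not (0.0 <= self.pI <= 14.0):
            raise ValueError("pI outside [0, 14]")

    def as_dict(self) -> dict[str, float]:
        return {
            "k_minus_r": self.k_minus_r,
            "pI": self.pI,
            "entropy": self.entropy,
            "aromatic": self.aromatic,
            "folding_propensity": self.folding_propensity,
        }


@dataclass(frozen=True)
class ReferencePopulation:
    """Per-property mean and standard deviation of a reference sequence set."""

    mean: Mapping[str, float]
    sd: Mapping[str, float]
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        for name, s in self.sd.items():
            if s <= 0:
                raise ValueError(f"sd for {name!r} must be > 0 (got {s})")

    @classmethod
    def from_sequences(cls, seqs: Iterable[DomainSequence],
                       provenance: str = "computed",
                       **kwargs) -> "ReferencePopulation":
        """Fit (mean, sd) of every property over a sequence set."""
        rows = [sequence_properties(s, **kwargs).as_dict() for s in seqs]
        df = pd.DataFrame(rows)
        if len(df) < 2:
            raise ValueError("need at least 2 sequences to fit a population")
        return cls(df.mean().to_dict(), df.std(ddof=1).to_dict(), provenance)


# ---------------------------------------------------------------------------
# operations

def composition(seq: DomainSequence) -> CompositionVector:
    """Amino-acid composition: count(a)/n for each of the 20 amino acids."""
    n = len(seq.sequence)
    counts = {a: 0 for a in AMINO_ACIDS}
    for a in seq.sequence:
        counts[a] += 1
    # exact simple fractions keep the sum-to-one invariant to rounding only
    fractions = {a: c / n for a, c in counts.items()}
    total = sum(fractions.values())
    fractions = {a: f / total for a, f in fractions.items()}
    return CompositionVector(fractions, n)


def sequence_entropy(comp: CompositionVector) -> float:
    """Shannon entropy of the composition, in bits; in [0, log2 20] = [0, 4.32]."""
    return max(0.0, float(-sum(f * math.log2(f)
                               for f in comp.fractions.values() if f > 0)))


def lysine_minus_arginine(comp: CompositionVector) -> float:
    """%K - %R, in percentage points."""
    return 100.0 * (comp.fractions.get("K", 0.0) - comp.fractions.get("R", 0.0))


def aromatic_content(comp: CompositionVector) -> float:
    """Combined F+W+Y content, percent."""
    return 100.0 * sum(comp.fractions.get(a, 0.0) for a in "FWY")


def net_charge(sequence: str, pH: float, pka: Mapping[str, float] = EMBOSS_PKA) -> float:
    """Henderson-Hasselbalch net charge at a given pH, termini included."""
    counts = Counter(sequence)
    counts["Nterm"] += 1
    counts["Cterm"] += 1
    q = 0.0
    for g, n in counts.items():
        if g in pka:
            if g in BASIC_GROUPS:
                q += n / (1.0 + 10.0 ** (pH - pka[g]))
            else:
                q -= n / (1.0 + 10.0 ** (pka[g] - pH))
    return q


def isoelectric_point(seq: DomainSequence,
                      pka: Mapping[str, float] = EMBOSS_PKA,
                      tol: float = 1e-6) -> float:
    """pH of zero net charge, by bisection to |Q| < tol.

    Sequences whose titratable groups are exclusively basic (acidic) have no
    zero crossing; the declared cap 14.0 (0.0) is returned and a warning
    logged.
    """
    if not seq.sequence:
        raise SequenceError("empty sequence")
    groups = [g for g in list(seq.sequence) + ["Nterm", "Cterm"] if g in pka]
    has_basic = any(g in BASIC_GROUPS for g in groups)
    has_acidic = any(g in ACIDIC_GROUPS for g in groups)
    if not has_acidic:
        logger.warning("%s: only basic groups; pI capped at 14", seq.id)
        return 14.0
    if not has_basic:
        logger.warning("%s: only acidic groups; pI capped at 0", seq.id)
        return 0.0
    lo, hi = 0.0, 14.0
    # net charge is strictly decreasing in pH
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        q = net_charge(seq.sequence, mid, pka)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def folding_propensity(seq: DomainSequence,
                       c1: float = 2.785,
                       c0: float = 1.151,
                       hydropathy: Mapping[str, float] = KYTE_DOOLITTLE,
                       charge: Mapping[str, float] = NEUTRAL_PH_CHARGE) -> float:
    """Charge/hydropathy folded-vs-disordered discriminant; > 0 predicts folded.

    FP = c1*<H> - |<R>| - c0, with <H> the mean Kyte-Doolittle hydropathy
    rescaled to [0, 1] and <R> the mean formal net charge per residue at
    neutral pH. The default (c1, c0) place the boundary along the classic
    charge-hydropathy discrimination line; both are configurable.
    """
    if not seq.sequence:
        raise SequenceError("empty sequence")
    hmin = min(hydropathy.values())
    hmax = max(hydropathy.values())
    h = np.mean([(hydropathy[a] - hmin) / (hmax - hmin) for a in seq.sequence])
    r = np.mean([charge.get(a, 0.0) for a in seq.sequence])
    return float(c1 * h - abs(r) - c0)


def zscore(value: float, pop: ReferencePopulation, prop: str) -> float:
    """(value - mu) / sigma for the named property."""
    if prop not in pop.mean or prop not in pop.sd:
        raise KeyError(f"property {prop!r} absent from population")
    sd = pop.sd[prop]
    if sd <= 0:
        raise ValueError(f"sd for {prop!r} must be > 0")
    return (value - pop.mean[prop]) / sd


def sequence_properties(seq: DomainSequence,
                        pka: Mapping[str, float] = EMBOSS_PKA,
                        fp_kwargs: Mapping | None = None) -> SequenceProperties:
    """All scalar properties of one sequence."""
    comp = composition(seq)
    return SequenceProperties(
        k_minus_r=lysine_minus_arginine(comp),
        pI=isoelectric_point(seq, pka=pka),
        entropy=sequence_entropy(comp),
        aromatic=aromatic_content(comp),
        folding_propensity=folding_propensity(seq, **(fp_kwargs or {})),
    )


# ---------------------------------------------------------------------------
# I/O

def read_fasta(path, region: str = "other") -> list[DomainSequence]:
    """Read a FASTA file into DomainSequence records."""
    return [DomainSequence(rec.id, str(rec.seq), region=region)
            for rec in SeqIO.parse(str(path), "fasta")]


def properties_table(seqs: Iterable[DomainSequence],
                     population: ReferencePopulation | None = None,
                     pka: Mapping[str, float] = EMBOSS_PKA) -> pd.DataFrame:
    """One row per sequence: id, region, n, properties and optional z-scores."""
    rows = []
    for s in seqs:
        props = sequence_properties(s, pka=pka)
        row = {"id": s.id, "region": s.region, "n": len(s)}
        row.update(props.as_dict())
        if population is not None:
            for name, value in props.as_dict().items():
                if name in population.mean:
                    row[f"{name}_z"] = zscore(value, population, name)
        rows.append(row)
    return pd.DataFrame(rows)


def write_properties_tsv(seqs: Iterable[DomainSequence], path,
                         population: ReferencePopulation | None = None) -> pd.DataFrame:
    df = properties_table(seqs, population)
    df.to_csv(path, sep="\t", index=False)
    return df
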