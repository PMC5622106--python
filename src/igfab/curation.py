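"""Curation of a Fab-fragment structure dataset.

Builds the analysis set from PDB-format files: retains the heavy (H) and
light (L) chains, filters by interquartile chain length, splits each chain
into its variable and constant domain at a conserved interdomain motif
(heavy: ``VS[SA]``; light: ``E[LIV]KR`` then ``TVL[GSA]``), applies a
per-domain length filter, and assembles the VL:VH and CL:CH1 dimers.

Sequences come from observed ATOM-record residues in author order, so every
counted residue has coordinates; positions and search windows are 1-based
indices into that observed sequence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.PDB import PDBIO
from Bio.PDB.Model import Model
from Bio.PDB.Chain import Chain
from Bio.PDB.Structure import Structure

from ._pdb import chain_sequence, parse_structure, residues_of
from .seqprops import DomainSequence

#: Interdomain-motif search windows (1-based inclusive positions of the
#: motif's first residue) and patterns.
HEAVY_WINDOW = (110, 130)
LIGHT_WINDOW = (100, 115)
HEAVY_MOTIF = r"VS[SA]"
LIGHT_MOTIFS = (r"E[LIV]KR", r"TVL[GSA]")


class CurationError(ValueError):
    pass


class MissingChainError(CurationError):
    pass


class AmbiguousChainError(CurationError):
    pass


class UnsplittableError(CurationError):
    """No interdomain motif in the search window."""


@dataclass
class FabRecord:
    """One Fab fragment: chains, split points, domains and dimers."""

    pdb_id: str
    heavy_seq: DomainSequence
    light_seq: DomainSequence
    heavy_residues: list = field(default_factory=list, repr=False)
    light_residues: list = field(default_factory=list, repr=False)
    heavy_split: int | None = None   # 1-based first residue of CH1
    light_split: int | None = None   # 1-based first residue of CL
    heavy_motif: str | None = None
    light_motif: str | None = None
    domains: dict = field(default_factory=dict, repr=False)  # region -> DomainSequence
    domain_residues: dict = field(default_factory=dict, repr=False)
    dimers: dict = field(default_factory=dict, repr=False)   # name -> residue list
    cdr_seq: DomainSequence | None = None

    @property
    def is_split(self) -> bool:
        return bool(self.domains)


@dataclass
class CurationReport:
    """Stage-by-stage record counts plus the filter parameters used."""

    stage_counts: dict = field(default_factory=dict)
    quartile_bounds: dict = field(default_factory=dict)
    motifs: dict = field(default_factory=dict)       # pdb_id -> (heavy, light)
    exclusions: dict = field(default_factory=dict)   # pdb_id -> reason code
    domain_means: dict = field(default_factory=dict)

    def add_stage(self, name: str, count: int) -> None:
        if self.stage_counts and count > min(self.stage_counts.values()):
            raise ValueError("stage counts must be non-increasing")
        self.stage_counts[name] = count

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"stage": list(self.stage_counts), "count": list(self.stage_counts.values())})

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# loading

def load_fab_structure(path, pdb_id: str | None = None) -> FabRecord:
    """Load a PDB-format Fab, retaining exactly the H and L chains.

    Raises MissingChainError if either chain is absent and
    AmbiguousChainError if a chain id occurs more than once across models.
    """
    structure = parse_structure(path)
    pdb_id = pdb_id or str(path)
    chains: dict[str, list] = {}
    for model in structure:
        for chain in model:
            chains.setdefault(chain.id, []).append(chain)
    for cid in ("H", "L"):
        if cid not in chains:
            raise MissingChainError(f"{pdb_id}: no H/L chains")
        if len(chains[cid]) > 1:
            raise AmbiguousChainError(f"{pdb_id}: ambiguous chain {cid}")
    heavy = residues_of(chains["H"][0])
    light = residues_of(chains["L"][0])
    if not heavy or not light:
        raise MissingChainError(f"{pdb_id}: empty H or L chain")
    return FabRecord(
        pdb_id=pdb_id,
        heavy_seq=DomainSequence(f"{pdb_id}_H", chain_sequence(heavy)),
        light_seq=DomainSequence(f"{pdb_id}_L", chain_sequence(light)),
        heavy_residues=heavy,
        light_residues=light,
    )


# ---------------------------------------------------------------------------
# filters and splitting

def quartile_length_filter(records: Sequence[FabRecord],
                           report: CurationReport | None = None,
                           ) -> tuple[list[FabRecord], CurationReport]:
    """Keep records with both chain lengths inside [Q1, Q3], bounds inclusive.

    Quartiles are linear-interpolation quartiles of the observed chain-length
    distributions, computed separately for heavy and light chains.
    """
    if len(records) < 4:
        raise CurationError("quartile filter needs at least 4 records")
    report = report or CurationReport()
    h_len = np.array([len(r.heavy_seq) for r in records])
    l_len = np.array([len(r.light_seq) for r in records])
    q1h, q3h = np.percentile(h_len, [25, 75])
    q1l, q3l = np.percentile(l_len, [25, 75])
    report.quartile_bounds = {"heavy": (float(q1h), float(q3h)),
                              "light": (float(q1l), float(q3l))}
    kept = []
    for r in records:
        if q1h <= len(r.heavy_seq) <= q3h and q1l <= len(r.light_seq) <= q3l:
            kept.append(r)
        else:
            report.exclusions[r.pdb_id] = "chain_length_quartile"
    report.add_stage("input", len(records))
    report.add_stage("quartile_length", len(kept))
    return kept, report


def find_interdomain_split(seq: DomainSequence, chain_kind: str,
                           heavy_window: tuple[int, int] = HEAVY_WINDOW,
                           light_window: tuple[int, int] = LIGHT_WINDOW,
                           ) -> tuple[int, str]:
    """First interdomain-motif position (1-based) in the search window.

    Heavy chains are searched for ``VS[SA]`` with the first residue between
    positions 110 and 130; light chains for ``E[LIV]KR`` and, only if that
    fails, ``TVL[GSA]``, between positions 100 and 115. The motif's first
    residue starts the constant domain. Returns (position, matched motif).
    """
    if chain_kind == "heavy":
        window, patterns = heavy_window, (HEAVY_MOTIF,)
    elif chain_kind == "light":
        window, patterns = light_window, LIGHT_MOTIFS
    else:
        raise ValueError(f"chain_kind must be 'heavy' or 'light', got {chain_kind!r}")
    lo, hi = window
    if len(seq.sequence) <= hi:
        raise UnsplittableError(f"{seq.id}: sequence shorter than search window")
    for pattern in patterns:
        for m in re.finditer(pattern, seq.sequence):
            pos = m.start() + 1
            if lo <= pos <= hi:
                return pos, m.group(0)
    raise UnsplittableError(f"{seq.id}: no interdomain motif in window {window}")


def split_domains(record: FabRecord) -> FabRecord:
    """Partition chains (and their residues) into VH/CH1 and VL/CL at the splits."""
    if record.heavy_split is None or record.light_split is None:
        hpos, hmotif = find_interdomain_split(record.heavy_seq, "heavy")
        lpos, lmotif = find_interdomain_split(record.light_seq, "light")
        record.heavy_split, record.heavy_motif = hpos, hmotif
        record.light_split, record.light_motif = lpos, lmotif
    for split, seq in ((record.heavy_split, record.heavy_seq),
                       (record.light_split, record.light_seq)):
        if split <= 1 or split > len(seq):
            raise CurationError(f"{record.pdb_id}: degenerate domain (split {split})")

    def cut(seq, residues, split, v_region, c_region):
        v = DomainSequence(f"{record.pdb_id}_{v_region}",
                           seq.sequence[:split - 1], region=v_region)
        c = DomainSequence(f"{record.pdb_id}_{c_region}",
                           seq.sequence[split - 1:], region=c_region)
        return v, c, residues[:split - 1], residues[split - 1:]

    vh, ch1, vh_res, ch1_res = cut(record.heavy_seq, record.heavy_residues,
                                   record.heavy_split, "VH", "CH1")
    vl, cl, vl_res, cl_res = cut(record.light_seq, record.light_residues,
                                 record.light_split, "VL", "CL")
    record.domains = {"VH": vh, "CH1": ch1, "VL": vl, "CL": cl}
    record.domain_residues = {"VH": vh_res, "CH1": ch1_res,
                              "VL": vl_res, "CL": cl_res}
    record.dimers = {"VL:VH": vl_res + vh_res, "CL:CH1": cl_res + ch1_res}
    return record


def domain_length_filter(records: Sequence[FabRecord],
                         report: CurationReport | None = None,
                         tolerance: int = 10,
                         ) -> tuple[list[FabRecord], CurationReport]:
    """Keep records whose four domains all lie within ±tolerance of the
    per-domain-class mean length over the input (inclusive)."""
    report = report or CurationReport()
    if not records:
        return [], report
    classes = ("VH", "CH1", "VL", "CL")
    means = {c: float(np.mean([len(r.domains[c]) for r in records]))
             for c in classes}
    report.domain_means = means
    kept = []
    for r in records:
        if all(abs(len(r.domains[c]) - means[c]) <= tolerance for c in classes):
            kept.append(r)
        else:
            report.exclusions[r.pdb_id] = "domain_length"
    report.add_stage("domain_length", len(kept))
    return kept, report


def concatenate_cdrs(record: FabRecord, annotations: pd.DataFrame) -> DomainSequence | None:
    """Concatenate the CDR subsequences of one Fab, in table order.

    ``annotations`` columns: pdb_id, chain (H|L), cdr_name, start, end
    (1-based inclusive, observed-sequence coordinates). Returns None when the
    record has no annotation rows.
    """
    rows = annotations[annotations["pdb_id"] == record.pdb_id]
    if rows.empty:
        record.cdr_seq = None
        return None
    parts = []
    for idx, row in rows.iterrows():
        chain = record.heavy_seq if row["chain"] == "H" else record.light_seq
        start, end = int(row["start"]), int(row["end"])
        if start < 1 or end > len(chain) or start > end:
            raise CurationError(
                f"{record.pdb_id}: CDR row {idx} ({row['cdr_name']}) out of "
                f"chain bounds ({start}-{end} vs length {len(chain)})")
        parts.append(chain.sequence[start - 1:end])
    record.cdr_seq = DomainSequence(f"{record.pdb_id}_CDR", "".join(parts),
                                    region="CDR")
    return record.cdr_seq


# ---------------------------------------------------------------------------
# pipeline

def curate_fabs(records: Iterable[FabRecord],
                domain_tolerance: int = 10,
                ) -> tuple[list[FabRecord], CurationReport]:
    """Full curation: quartile filter, motif splitting, domain-length filter."""
    records = list(records)
    kept, report = quartile_length_filter(records)
    split_ok = []
    for r in kept:
        try:
            split_ok.append(split_domains(r))
            report.motifs[r.pdb_id] = (r.heavy_motif, r.light_motif)
        except UnsplittableError:
            report.exclusions[r.pdb_id] = "no_interdomain_motif"
    report.add_stage("motif_split", len(split_ok))
    final, report = domain_length_filter(split_ok, report, domain_tolerance)
    return final, report


# ---------------------------------------------------------------------------
# output

def build_structure_from_residues(residues, structure_id="fragment") -> Structure:
    """Assemble detached copies of residues into a new single-model structure."""
    structure = Structure(structure_id)
    model = Model(0)
    structure.add(model)
    chains: dict[str, Chain] = {}
    for res in residues:
        cid = res.get_parent().id if res.get_parent() else "A"
        if cid not in chains:
            chains[cid] = Chain(cid)
            model.add(chains[cid])
        copy = res.copy()
        copy.detach_parent()
        chains[cid].add(copy)
    return structure


def write_fragment_pdb(residues, path) -> None:
    io = PDBIO()
    io.set_structure(build_structure_from_residues(residues))
    io.save(str(path))


def write_domain_fasta(records: Sequence[FabRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            for region, seq in r.domains.items():
                fh.write(f">{seq.id} region={region}\n{seq.sequence}\n")
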