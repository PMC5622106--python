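"""Synthetic fixtures for every pipeline stage, without external downloads.

Generators for: Fab-like heavy/light chain pairs carrying the interdomain
motifs at controlled positions; toy PDB-format structures with ionisable
groups at controlled coordinates; reference populations with known property
mean/SD; and IgSF-like cohorts of composition vectors with planted CH1-like
members. Every generator is a pure function of its parameters and seed.

The toy structures place charged-group centroids exactly; they make no
attempt to mimic real immunoglobulin fold geometry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .curation import HEAVY_WINDOW, LIGHT_WINDOW
from .seqprops import (AMINO_ACIDS, MAX_ENTROPY_BITS, CompositionVector,
                       DomainSequence, ReferencePopulation)

# ---------------------------------------------------------------------------
# Fab-like sequences


def _random_seq(rng, length: int, alphabet: str = AMINO_ACIDS) -> np.ndarray:
    return rng.choice(list(alphabet), size=length)


def generate_fab_sequences(n: int,
                           heavy_motif_pos: int = 118,
                           light_motif_pos: int = 108,
                           heavy_length_range: tuple[int, int] = (219, 228),
                           light_length_range: tuple[int, int] = (213, 218),
                           light_motif_family: str = "ELKR",
                           seed: int = 0,
                           ) -> list[tuple[DomainSequence, DomainSequence]]:
    """Paired heavy/light chains with interdomain motifs planted in-window.

    Each heavy chain carries ``VS[SA]`` exactly once with its first residue
    inside the 110-130 search window, at ``heavy_motif_pos``; each light
    chain carries one motif of the requested family (``"ELKR"`` for
    ``E[LIV]KR`` or ``"TVL"`` for ``TVL[GSA]``) at ``light_motif_pos`` inside
    100-115. Default chain-length ranges follow the interquartile bounds of
    the curated Fab set (219-228 heavy, 213-218 light).
    """
    if not (HEAVY_WINDOW[0] <= heavy_motif_pos <= HEAVY_WINDOW[1]):
        raise ValueError(f"heavy motif position {heavy_motif_pos} outside "
                         f"window {HEAVY_WINDOW}")
    if not (LIGHT_WINDOW[0] <= light_motif_pos <= LIGHT_WINDOW[1]):
        raise ValueError(f"light motif position {light_motif_pos} outside "
                         f"window {LIGHT_WINDOW}")
    if light_motif_family not in ("ELKR", "TVL"):
        raise ValueError("light_motif_family must be 'ELKR' or 'TVL'")
    rng = np.random.default_rng(seed)
    pairs = []
    no_v = AMINO_ACIDS.replace("V", "")
    no_et = AMINO_ACIDS.replace("E", "").replace("T", "")
    for i in range(n):
        hl = int(rng.integers(heavy_length_range[0], heavy_length_range[1] + 1))
        ll = int(rng.integers(light_length_range[0], light_length_range[1] + 1))

        heavy = _random_seq(rng, hl)
        # no spurious motif may *start* inside the window: keep V out of it
        lo, hi = HEAVY_WINDOW
        heavy[lo - 1:hi] = _random_seq(rng, hi - lo + 1, no_v)
        motif = "VS" + rng.choice(["S", "A"])
        heavy[heavy_motif_pos - 1:heavy_motif_pos + 2] = list(motif)

        light = _random_seq(rng, ll)
        lo, hi = LIGHT_WINDOW
        light[lo - 1:hi] = _random_seq(rng, hi - lo + 1, no_et)
        if light_motif_family == "ELKR":
            lmotif = "E" + rng.choice(["L", "I", "V"]) + "KR"
        else:
            lmotif = "TVL" + rng.choice(["G", "S", "A"])
        light[light_motif_pos - 1:light_motif_pos - 1 + len(lmotif)] = list(lmotif)

        pairs.append((
            DomainSequence(f"synfab{i:03d}_H", "".join(heavy)),
            DomainSequence(f"synfab{i:03d}_L", "".join(light)),
        ))
    return pairs


# ---------------------------------------------------------------------------
# toy structures

_SITE_RESNAME = {"Asp": "ASP", "Glu": "GLU", "Lys": "LYS", "Arg": "ARG",
                 "His": "HIS", "Tyr": "TYR", "Cys": "CYS", "Ala": "ALA"}
#: charged-group atoms written for each site type, as offsets from the
#: requested centroid (pairs straddle it symmetrically).
_GROUP_ATOMS = {
    "Asp": (("OD1", "O", (0.5, 0.0, 0.0)), ("OD2", "O", (-0.5, 0.0, 0.0))),
    "Glu": (("OE1", "O", (0.5, 0.0, 0.0)), ("OE2", "O", (-0.5, 0.0, 0.0))),
    "Lys": (("NZ", "N", (0.0, 0.0, 0.0)),),
    "Arg": (("CZ", "C", (0.0, 0.0, 0.0)),),
    "His": (("ND1", "N", (0.5, 0.0, 0.0)), ("NE2", "N", (-0.5, 0.0, 0.0))),
    "Tyr": (("OH", "O", (0.0, 0.0, 0.0)),),
    "Cys": (("SG", "S", (0.0, 0.0, 0.0)),),
    "Ala": (),
}


def _pdb_atom_line(serial, name, resname, chain, resseq, xyz, element):
    x, y, z = xyz
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (f"ATOM  {serial:5d} {name_field}{'':1s}{resname:>3s} {chain}"
            f"{resseq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
            f"          {element:>2s}")


def toy_structure_pdb(sites: Sequence[tuple[str, Sequence[float]]],
                      chain_id: str = "A") -> str:
    """PDB-format text for a toy chain with charged groups at given centroids.

    ``sites`` is a list of (site_type, xyz) with site_type one of Asp, Glu,
    Lys, Arg, His, Tyr, Cys or Ala (Ala contributes backbone only). Backbone
    N/CA/C/O atoms are placed near each centroid so that parsing, terminus
    detection and SASA all work; charged-group atoms land exactly on the
    requested centroid.
    """
    coords = [np.asarray(xyz, dtype=float) for _, xyz in sites]
    if not all(np.all(np.isfinite(c)) for c in coords):
        raise ValueError("coordinates must be finite")
    for i in range(len(coords)):
        for j in range(i + 1, len(coords)):
            if np.linalg.norm(coords[i] - coords[j]) == 0.0:
                raise ValueError(f"coincident sites {i} and {j}")
    lines = []
    serial = 1
    for resseq, ((stype, _), centre) in enumerate(zip(sites, coords), start=1):
        resname = _SITE_RESNAME[stype]
        backbone = (("N", "N", (-0.8, -1.6, 0.0)), ("CA", "C", (0.0, -2.4, 0.0)),
                    ("C", "C", (0.8, -1.6, 0.0)), ("O", "O", (1.6, -2.2, 0.0)))
        for name, element, off in backbone + _GROUP_ATOMS[stype]:
            xyz = centre + np.asarray(off)
            lines.append(_pdb_atom_line(serial, name, resname, chain_id,
                                        resseq, xyz, element))
            serial += 1
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def generate_toy_structure(sites, path, chain_id: str = "A") -> None:
    """Write a toy structure to a PDB-format file."""
    with open(path, "w") as fh:
        fh.write(toy_structure_pdb(sites, chain_id))


def toy_dimer_pdbs(sites_a, sites_b) -> tuple[str, str, str]:
    """PDB text for subunit A (chain A), subunit B (chain B) and the AB merge."""
    a = toy_structure_pdb(sites_a, "A")
    b = toy_structure_pdb(sites_b, "B")
    merged_lines = [l for l in a.splitlines() if l.startswith("ATOM") or l == "TER"]
    merged_lines += [l for l in b.splitlines() if l.startswith("ATOM") or l == "TER"]
    # renumber serials for cleanliness
    out, serial = [], 1
    for line in merged_lines:
        if line.startswith("ATOM"):
            out.append(line[:6] + f"{serial:5d}" + line[11:])
            serial += 1
        else:
            out.append(line)
    out.append("END")
    return a, b, "\n".join(out) + "\n"


def fab_structure_pdb(heavy: DomainSequence, light: DomainSequence,
                      extra_chains: Mapping[str, str] | None = None,
                      spacing: float = 4.0) -> str:
    """A coarse Fab-like PDB text: chains H and L with one backbone per residue.

    Residues are laid out on parallel lines (no fold geometry); enough for
    parsing, splitting and atom-partition round-trips.
    """
    one_to_three = {v: k for k, v in
                    {"ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
                     "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
                     "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
                     "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y",
                     "VAL": "V"}.items()}
    chains = {"H": heavy.sequence, "L": light.sequence}
    chains.update(extra_chains or {})
    lines = []
    serial = 1
    for k, (cid, seq) in enumerate(chains.items()):
        y = 20.0 * k
        for resseq, aa in enumerate(seq, start=1):
            x = spacing * resseq
            resname = one_to_three[aa]
            for name, element, off in (("N", "N", (-0.8, 0.0, 0.0)),
                                       ("CA", "C", (0.0, 0.8, 0.0)),
                                       ("C", "C", (0.8, 0.0, 0.0)),
                                       ("O", "O", (1.2, 0.0, 1.0))):
                xyz = (x + off[0], y + off[1], off[2])
                lines.append(_pdb_atom_line(serial, name, resname, cid,
                                            resseq, xyz, element))
                serial += 1
        lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# reference populations

BACKGROUND_FREQS = {a: 1.0 / 18 for a in AMINO_ACIDS if a not in "KR"}


def generate_reference_population(n: int = 1000,
                                  k_minus_r_mean: float = 0.0,
                                  k_minus_r_sd: float = 3.0,
                                  length: int = 200,
                                  entropy_target: float | None = None,
                                  seed: int = 0,
                                  ) -> tuple[list[DomainSequence], ReferencePopulation]:
    """A sequence population with a controlled K-R distribution.

    The per-sequence K-R values (percentage points) are drawn from a normal
    distribution and then standardised so the realised sample mean and SD hit
    the targets to within rounding (well inside 5% relative); all other
    properties take the values realised by the random background, and the
    fitted per-property (mean, SD) table is returned alongside the sequences.
    ``entropy_target`` exists only for validation: entropy cannot exceed
    log2(20) = 4.32 bits, and infeasible targets are rejected.
    """
    if n < 30:
        raise ValueError("need n >= 30 for a usable population")
    if k_minus_r_sd <= 0:
        raise ValueError("k_minus_r_sd must be > 0")
    if entropy_target is not None and entropy_target > MAX_ENTROPY_BITS:
        raise ValueError(f"entropy target {entropy_target} exceeds "
                         f"log2(20) = {MAX_ENTROPY_BITS:.2f} bits")
    rng = np.random.default_rng(seed)
    d = rng.normal(k_minus_r_mean, k_minus_r_sd, size=n)
    d = k_minus_r_mean + (d - d.mean()) * (k_minus_r_sd / d.std(ddof=1))

    others = sorted(BACKGROUND_FREQS)
    probs = np.array([BACKGROUND_FREQS[a] for a in others])
    seqs = []
    base = max(4, int(round(0.05 * length)))
    for i, di in enumerate(d):
        dk = int(round(di / 100.0 * length))
        n_k = base + max(dk, 0)
        n_r = base + max(-dk, 0)
        n_rest = length - n_k - n_r
        if n_rest < 0:
            raise ValueError("K-R target infeasible at this length")
        counts = rng.multinomial(n_rest, probs)
        residues = ["K"] * n_k + ["R"] * n_r + [
            a for a, c in zip(others, counts) for _ in range(c)]
        seqs.append(DomainSequence(f"ref{i:04d}",
                                   "".join(rng.permutation(residues))))
    pop = ReferencePopulation.from_sequences(seqs, provenance=f"synthetic(seed={seed})")
    return seqs, pop


# ---------------------------------------------------------------------------
# IgSF cohorts

def _normalise(v: np.ndarray) -> np.ndarray:
    v = np.clip(v, 1e-4, None)
    return v / v.sum()


def cl_like_profile() -> np.ndarray:
    """A near-uniform composition standing in for a CL domain."""
    p = np.ones(20) / 20.0
    # mild, fixed structure so the CL->CH1 direction is well defined
    idx = {a: i for i, a in enumerate(AMINO_ACIDS)}
    for a, w in {"S": 0.012, "T": 0.008, "K": 0.006, "E": 0.006,
                 "W": -0.015, "M": -0.010, "C": -0.010}.items():
        p[idx[a]] += w
    return _normalise(p)


def ch1_like_profile(shift: float = 1.6) -> np.ndarray:
    """The CL profile pushed along a fixed CH1-like direction.

    Enriched in P, S, T, V and G; depleted in D, E, F, I, Q, R and Y — the
    composition signature that separates CH1 from the other Fab domains —
    and sharpened so its entropy sits well below the 3.83-bit threshold.
    """
    p = cl_like_profile().copy()
    idx = {a: i for i, a in enumerate(AMINO_ACIDS)}
    direction = np.zeros(20)
    for a in "PSTVG":
        direction[idx[a]] += 0.055
    for a in "DEFIQRY":
        direction[idx[a]] -= 0.038
    return _normalise(p + shift * direction)


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a synthetic IgSF cohort with planted CH1-like members."""

    n_background: int = 200
    n_planted: int = 5
    n_cl_like: int = 0
    alpha_background: float = 300.0   # Dirichlet concentration around uniform
    alpha_class: float = 200.0        # concentration around class profiles
    length_range: tuple[int, int] = (100, 140)
    seed: int = 0
    ch1_shift: float = 1.6

    def __post_init__(self) -> None:
        if min(self.n_background, self.n_planted, self.n_cl_like) < 0:
            raise ValueError("class sizes must be >= 0")
        if min(self.alpha_background, self.alpha_class) <= 0:
            raise ValueError("Dirichlet concentrations must be > 0")


def generate_igsf_cohort(spec: CohortSpec = CohortSpec()):
    """Synthetic IgSF cohort: sequences, reference compositions, truth table.

    Returns ``(domains, ch1_ref, cl_ref, truth)`` where ``truth`` is a
    DataFrame with columns id, class, planted. Planted members are drawn
    around the CH1-like profile (low entropy, deviating from CL in the
    CH1 direction); background members are near-uniform and fall well above
    the entropy threshold.
    """
    rng = np.random.default_rng(spec.seed)
    p_cl = cl_like_profile()
    p_ch1 = ch1_like_profile(spec.ch1_shift)
    letters = np.array(list(AMINO_ACIDS))

    def draw(profile, concentration, label, count, region="IgSF"):
        out = []
        for i in range(count):
            length = int(rng.integers(spec.length_range[0],
                                      spec.length_range[1] + 1))
            theta = rng.dirichlet(concentration * profile)
            counts = rng.multinomial(length, theta)
            residues = np.repeat(letters, counts)
            seq = "".join(rng.permutation(residues))
            out.append(DomainSequence(f"{label}{i:03d}:1-{length}", seq,
                                      region=region))
        return out

    background = draw(np.ones(20) / 20.0, spec.alpha_background, "BG", spec.n_background)
    cl_like = draw(p_cl, spec.alpha_class, "CLLIKE", spec.n_cl_like)
    planted = draw(p_ch1, spec.alpha_class, "CH1LIKE", spec.n_planted)

    domains = background + cl_like + planted
    truth = pd.DataFrame(
        [{"id": d.id, "class": "background", "planted": False} for d in background]
        + [{"id": d.id, "class": "cl_like", "planted": False} for d in cl_like]
        + [{"id": d.id, "class": "ch1_like", "planted": True} for d in planted])
    nominal = int(np.mean(spec.length_range))
    ch1_ref = CompositionVector(dict(zip(AMINO_ACIDS, p_ch1)), nominal)
    cl_ref = CompositionVector(dict(zip(AMINO_ACIDS, p_cl)), nominal)
    return domains, ch1_ref, cl_ref, truth


def write_fasta(seqs: Sequence[DomainSequence], path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n{s.sequence}\n")
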