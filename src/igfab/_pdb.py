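"""Small shared helpers for PDB-format structures (Biopython Bio.PDB backed)."""

from __future__ import annotations

import warnings
from typing import Iterable

from Bio.PDB import PDBParser
from Bio.PDB.Residue import Residue
from Bio.PDB.PDBExceptions import PDBConstructionWarning

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # common modified residues mapped to their parent amino acid
    "MSE": "M", "SEC": "C", "PYL": "K", "HYP": "P", "SEP": "S",
    "TPO": "T", "PTR": "Y", "CSO": "C", "MLY": "K",
}


def parse_structure(path, structure_id: str = "structure"):
    """Parse a PDB-format file, silencing construction warnings."""
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        return parser.get_structure(structure_id, str(path))


def is_protein_residue(res: Residue) -> bool:
    """ATOM-record amino-acid residue (HETATM water/ligands excluded)."""
    return res.id[0] == " " and res.get_resname().strip() in THREE_TO_ONE


def residues_of(obj) -> list[Residue]:
    """Protein residues of a Bio.PDB entity or of an iterable of residues."""
    if hasattr(obj, "get_residues"):
        residues = obj.get_residues()
    elif isinstance(obj, Residue):
        residues = [obj]
    else:
        residues = obj
    return [r for r in residues if is_protein_residue(r)]


def residue_letter(res: Residue) -> str:
    return THREE_TO_ONE[res.get_resname().strip()]


def chain_sequence(residues: Iterable[Residue]) -> str:
    """One-letter sequence of observed residues, author order."""
    return "".join(residue_letter(r) for r in residues)


def atom_count(obj) -> int:
    return sum(len(r) for r in residues_of(obj))
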