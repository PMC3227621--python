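"""Exhaustive short-peptide library enumeration, heavy-atom counting and
SMILES emission.

Libraries span all sequences over the 20 standard, genetically encoded
amino acids (20^n for length n).  The heavy atom count (HAC) of a linear
peptide follows from residue composition alone: the sum of the free amino
acids' heavy atoms minus one oxygen per peptide bond (condensation).
Emitted SMILES describe the zwitterionic parent at physiological pH:
ammonium amino terminus, carboxylate C-terminus, Asp/Glu deprotonated,
Lys/Arg protonated, His neutral.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

#: The 20 standard amino acids, lexicographic one-letter order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Heavy atoms of each free amino acid (molecular formula without hydrogens).
RESIDUE_HAC = {
    "G": 5, "A": 6, "S": 7, "C": 7, "P": 8, "V": 8, "T": 8,
    "L": 9, "I": 9, "N": 9, "D": 9, "M": 9,
    "Q": 10, "K": 10, "E": 10,
    "H": 11, "F": 12, "R": 12, "Y": 13, "W": 15,
}

# Side-chain SMILES fragments attached at C-alpha, ionised for pH 7.4
# (Asp/Glu carboxylate, Lys ammonium, Arg guanidinium, His neutral tautomer).
# Proline is handled structurally (ring through the backbone nitrogen).
_SIDECHAINS = {
    "A": "C",
    "C": "CS",
    "D": "CC([O-])=O",
    "E": "CCC([O-])=O",
    "F": "Cc1ccccc1",
    "G": None,
    "H": "Cc1c[nH]cn1",
    "I": "C(C)CC",
    "K": "CCCC[NH3+]",
    "L": "CC(C)C",
    "M": "CCSC",
    "N": "CC(N)=O",
    "P": None,
    "Q": "CCC(N)=O",
    "R": "CCCNC(=[NH2+])N",
    "S": "CO",
    "T": "C(O)C",
    "V": "C(C)C",
    "W": "Cc1c[nH]c2ccccc12",
    "Y": "Cc1ccc(O)cc1",
}


@dataclass
class PeptideRecord:
    """One library entry: sequence, heavy atom count, optional SMILES."""

    sequence: str
    hac: int
    smiles: str | None = None
    tautomer_id: str = "parent"


def _check_sequence(sequence: str) -> None:
    if not sequence:
        raise ValueError("empty peptide sequence")
    for ch in sequence:
        if ch not in RESIDUE_HAC:
            raise ValueError(f"unknown amino-acid code {ch!r} in sequence {sequence!r}")


def peptide_hac(sequence: str) -> int:
    """Heavy atom count of a linear peptide from residue composition.

    One oxygen is lost per peptide bond relative to the free amino acids.
    """
    _check_sequence(sequence)
    return sum(RESIDUE_HAC[ch] for ch in sequence) - (len(sequence) - 1)


def peptide_smiles(sequence: str) -> str:
    """Zwitterionic linear-peptide SMILES assembled from residue templates."""
    _check_sequence(sequence)
    n = len(sequence)
    parts: list[str] = []
    for i, aa in enumerate(sequence):
        first, last = i == 0, i == n - 1
        if aa == "P":
            nitrogen = "[NH2+]" if first else "N"
            unit = f"{nitrogen}1CCC[C@@H]1"
        else:
            nitrogen = "[NH3+]" if first else "N"
            side = _SIDECHAINS[aa]
            alpha = "C" if aa == "G" else f"[C@@H]({side})"
            unit = nitrogen + alpha
        unit += "C(=O)[O-]" if last else "C(=O)"
        parts.append(unit)
    return "".join(parts)


def enumerate_library(n: int, with_smiles: bool = False) -> list[PeptideRecord]:
    """All 20^n peptides of length n in lexicographic order, with HAC."""
    if n < 1:
        raise ValueError(f"peptide length must be >= 1, got {n}")
    records = []
    for combo in itertools.product(sorted(AMINO_ACIDS), repeat=n):
        seq = "".join(combo)
        records.append(PeptideRecord(
            sequence=seq,
            hac=peptide_hac(seq),
            smiles=peptide_smiles(seq) if with_smiles else None,
        ))
    return records


def smiles_heavy_atoms(smiles: str) -> int:
    """Heavy atom count of a SMILES string (RDKit-parsed)."""
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    return mol.GetNumHeavyAtoms()


def filter_valid(records: Iterable[PeptideRecord], return_rejected: bool = False):
    """Drop chemically unreasonable peptide structures.

    Four rules, applied as substructure/formal-charge checks on the SMILES:
    protonated carbonyl oxygens, deprotonated (anionic) amines, missing
    formally charged termini (ammonium + carboxylate), and anionic amide
    nitrogens.  Template-generated parents always pass.  Unparsable SMILES
    are rejected with a reason.
    """
    from rdkit import Chem

    protonated_carbonyl = Chem.MolFromSmarts("[OX1+,OX2H1+]=[#6]")
    ammonium_terminus = Chem.MolFromSmarts("[NX4+;H3,H2]")
    carboxylate = Chem.MolFromSmarts("[CX3](=O)[O-]")
    kept: list[PeptideRecord] = []
    rejected: list[tuple[PeptideRecord, str]] = []
    for rec in records:
        if rec.smiles is None:
            rejected.append((rec, "no SMILES attached"))
            continue
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is None:
            rejected.append((rec, "unparsable SMILES"))
            continue
        reason = None
        if mol.HasSubstructMatch(protonated_carbonyl):
            reason = "protonated carbonyl group"
        if reason is None:
            for atom in mol.GetAtoms():
                if atom.GetSymbol() == "N" and atom.GetFormalCharge() < 0:
                    neighbours_carbonyl = any(
                        nb.GetSymbol() == "C" and any(
                            b.GetBondTypeAsDouble() == 2.0 and
                            b.GetOtherAtom(nb).GetSymbol() == "O"
                            for b in nb.GetBonds())
                        for nb in atom.GetNeighbors())
                    reason = "anionic amide" if neighbours_carbonyl else "de-protonated amine"
                    break
        if reason is None and not (mol.HasSubstructMatch(ammonium_terminus)
                                   and mol.HasSubstructMatch(carboxylate)):
            reason = "without formally charged termini"
        if reason is None:
            kept.append(rec)
        else:
            rejected.append((rec, reason))
    return (kept, rejected) if return_rejected else kept


def library_to_frame(records: Sequence[PeptideRecord]) -> pd.DataFrame:
    return pd.DataFrame([
        {"sequence": r.sequence, "hac": r.hac, "smiles": r.smiles or "",
         "tautomer_id": r.tautomer_id}
        for r in records
    ])


def write_library_tsv(records: Sequence[PeptideRecord], path) -> None:
    library_to_frame(records).to_csv(path, sep="\t", index=False)


def write_smiles_file(records: Sequence[PeptideRecord], path) -> None:
    """One 'SMILES<space>name' line per record (ignores entries without SMILES)."""
    with open(path, "w") as fh:
        for r in records:
            if r.smiles:
                fh.write(f"{r.smiles} {r.sequence}\n")
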