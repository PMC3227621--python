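"""Hydrogen-bond interaction fingerprints of docked peptide poses.

A fingerprint records which receptor residues hydrogen-bond to the peptide
(in either donor/acceptor direction) and whether the peptide-side atom is
backbone or side chain.  Side-chain contacts are the "specific" ones: they
depend on peptide sequence rather than on the invariant backbone, so they
gauge binding specificity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .interface import ContactCriteria, detect_contacts
from .structures import Structure

#: Peptide backbone atoms, including the C-terminal carboxylate oxygen.
PEPTIDE_MAINCHAIN = frozenset({"N", "CA", "C", "O", "OXT"})

_CLASS_CODE = {"specific": "S", "mainchain": "M", "both": "B"}


def peptide_atom_class(atom_name: str) -> str:
    """'mainchain' for N/CA/C/O/OXT (terminal N included), else 'sidechain'."""
    return "mainchain" if atom_name in PEPTIDE_MAINCHAIN else "sidechain"


@dataclass
class InteractionFingerprint:
    complex_id: str
    entries: dict[int, str]  # receptor residue seq number -> specific|mainchain|both

    @property
    def n_residues(self) -> int:
        return len(self.entries)

    @property
    def n_specific(self) -> int:
        return sum(1 for v in self.entries.values() if v in ("specific", "both"))

    def to_json(self) -> str:
        return json.dumps({
            "complex_id": self.complex_id,
            "entries": {str(k): v for k, v in sorted(self.entries.items())},
            "n_residues": self.n_residues,
            "n_specific": self.n_specific,
        }, indent=1)


def fingerprint(
    complex_structure: Structure,
    receptor_chain: str,
    peptide_chain: str,
    criteria: ContactCriteria | None = None,
    complex_id: str | None = None,
    hbonds_only: bool = True,
) -> InteractionFingerprint:
    """Interaction fingerprint of one docked complex.

    Every receptor residue hydrogen-bonded (either direction) to any
    peptide atom becomes an entry, classed by the peptide-side atom:
    side-chain -> "specific", backbone -> "mainchain", both kinds ->
    "both" (counted as specific).  ``hbonds_only=False`` extends the
    definition to all non-bonded contacts.
    """
    receptor = complex_structure.chain(receptor_chain)
    try:
        peptide = complex_structure.chain(peptide_chain)
    except ValueError as exc:
        raise ValueError(f"fingerprint: missing peptide chain: {exc}") from None
    entries: dict[int, set[str]] = {}
    for c in detect_contacts(receptor, peptide, criteria):
        if hbonds_only and not c.is_hbond:
            continue
        kind = peptide_atom_class(c.b.atom_name)
        entries.setdefault(c.a.seq_number, set()).add(kind)
    collapsed = {
        seq: ("both" if len(kinds) == 2 else
              "specific" if "sidechain" in kinds else "mainchain")
        for seq, kinds in entries.items()
    }
    return InteractionFingerprint(
        complex_id=complex_id or complex_structure.source_label or "complex",
        entries=collapsed,
    )


def fingerprint_matrix(
    fingerprints: Sequence[InteractionFingerprint],
    residue_range: Iterable[int] | None = None,
) -> pd.DataFrame:
    """Residues x complexes grid of class codes (S/M/B; empty = no contact)."""
    if residue_range is None:
        seqs = sorted({s for fp in fingerprints for s in fp.entries})
    else:
        seqs = list(residue_range)
    data = {
        fp.complex_id: [_CLASS_CODE.get(fp.entries.get(s, ""), "") for s in seqs]
        for fp in fingerprints
    }
    matrix = pd.DataFrame(data, index=seqs)
    matrix.index.name = "residue"
    return matrix


def summary_table(fingerprints: Sequence[InteractionFingerprint]) -> pd.DataFrame:
    """Per-complex residue and specific-contact counts."""
    return pd.DataFrame([
        {"complex_id": fp.complex_id, "n_residues": fp.n_residues, "n_specific": fp.n_specific}
        for fp in fingerprints
    ])


def write_matrix_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t")


def read_matrix_tsv(path) -> pd.DataFrame:
    matrix = pd.read_csv(path, sep="\t", index_col="residue", keep_default_na=False)
    return matrix
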