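#!/usr/bin/env python
"""H-bond interaction fingerprints for a batch of 12 toy docked complexes.

Each complex pairs a receptor conformation with a top-ranked peptide pose.
Without the study's docked poses the geometry is synthetic: every complex
gets a different mix of peptide side-chain (specific) and backbone
(non-specific) hydrogen bonds to receptor residues in the interface
region.  The driver produces the per-complex residue/specific counts and
the residues x complexes class matrix.
"""

from pathlib import Path

import numpy as np

from etspep.fingerprints import fingerprint, fingerprint_matrix, summary_table, write_matrix_tsv
from etspep.structures import Atom, Residue, Structure

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

# receptor residues available for bonding (interface region 13-49) and the
# donor/acceptor atom used on each
RECEPTOR_SITES = [
    (13, "GLN", "NE2"), (16, "ARG", "NH1"), (17, "GLU", "OE1"), (18, "GLN", "OE1"),
    (20, "ASN", "OD1"), (45, "LEU", "O"), (48, "LEU", "O"), (49, "ARG", "NH2"),
]
# peptide-side atoms: (atom, residue) pairs; non-backbone names are specific
PEPTIDE_ATOMS = [("NZ", "LYS"), ("OG", "SER"), ("N", "GLY"), ("O", "GLY"), ("OH", "TYR")]

rng = np.random.default_rng(7)
fps = []
for c in range(12):
    n_bonds = rng.integers(2, 6)
    sites = rng.choice(len(RECEPTOR_SITES), size=n_bonds, replace=False)
    residues = []
    for slot, site in enumerate(sites):
        seq, res_name, atom_name = RECEPTOR_SITES[site]
        y = 20.0 * slot
        residues.append(Residue("A", seq, res_name, atoms=[
            Atom(atom_name, atom_name[0], np.array([0.0, y, 0.0]))]))
        pep_atom, pep_res = PEPTIDE_ATOMS[rng.integers(len(PEPTIDE_ATOMS))]
        distance = rng.uniform(2.75, 3.30)
        residues.append(Residue("B", slot + 1, pep_res, atoms=[
            Atom(pep_atom, pep_atom[0], np.array([distance, y, 0.0]))]))
    complex_s = Structure(residues=residues, source_label=f"ETS{c + 1}_pose")
    fps.append(fingerprint(complex_s, "A", "B", complex_id=f"ETS{c + 1}"))

summary = summary_table(fps)
summary.to_csv(OUT / "fingerprint_summary.tsv", sep="\t", index=False)
matrix = fingerprint_matrix(fps, residue_range=[s[0] for s in RECEPTOR_SITES])
write_matrix_tsv(matrix, OUT / "fingerprint_matrix.tsv")

print("per-complex H-bonded receptor residues and specific contacts:")
print(summary.to_string(index=False))
assert (summary["n_specific"] <= summary["n_residues"]).all()
print(f"\nresidues x complexes matrix ({matrix.shape[0]} x {matrix.shape[1]}; "
      "S = specific, M = peptide main chain, B = both):")
print(matrix.to_string())
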