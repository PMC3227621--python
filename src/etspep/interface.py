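"""Protein-protein interface characterisation.

Non-bonded contacts and hydrogen bonds are detected purely geometrically
from donor/acceptor heavy-atom distances, using the distance windows of a
LIGPLOT-style analysis: non-bonded contacts between 2.90 and 3.90 Angstrom,
hydrogen bonds between 2.70 and 3.35 Angstrom (donor/acceptor-typed pairs
only; no angular term by default).  Accessible surface area is computed by
Shrake-Rupley sphere quadrature with a NACCESS-like (Chothia) radii table,
and per-residue interface contributions as the surface buried upon
complexation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structures import Atom, Residue, Structure

# Chothia-style radii as used by NACCESS-type ASA programs (Angstrom).
DEFAULT_RADII = {"C": 1.87, "N": 1.65, "O": 1.40, "S": 1.85, "P": 1.90, "SE": 1.90}

# Donor/acceptor typing over the 20 standard residues.  Backbone amide N is
# a donor (except proline, whose ring nitrogen carries no H in a peptide
# bond); backbone carbonyl O and the C-terminal OXT are acceptors.  His and
# the hydroxyls (Ser/Thr/Tyr) act as both.
SIDECHAIN_DONORS = {
    "ARG": {"NE", "NH1", "NH2"},
    "ASN": {"ND2"},
    "GLN": {"NE2"},
    "HIS": {"ND1", "NE2"},
    "LYS": {"NZ"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TRP": {"NE1"},
    "TYR": {"OH"},
    "CYS": {"SG"},
}
SIDECHAIN_ACCEPTORS = {
    "ASN": {"OD1"},
    "ASP": {"OD1", "OD2"},
    "GLN": {"OE1"},
    "GLU": {"OE1", "OE2"},
    "HIS": {"ND1", "NE2"},
    "MET": {"SD"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "CYS": {"SG"},
}


def is_donor(res_name: str, atom_name: str) -> bool:
    if atom_name == "N":
        return res_name != "PRO"
    return atom_name in SIDECHAIN_DONORS.get(res_name, ())


def is_acceptor(res_name: str, atom_name: str) -> bool:
    if atom_name in ("O", "OXT"):
        return True
    return atom_name in SIDECHAIN_ACCEPTORS.get(res_name, ())


@dataclass(frozen=True)
class ContactCriteria:
    """Distance windows (Angstrom) for contacts and hydrogen bonds."""

    nb_min: float = 2.90
    nb_max: float = 3.90
    hb_min: float = 2.70
    hb_max: float = 3.35

    def __post_init__(self) -> None:
        for lo, hi, label in ((self.nb_min, self.nb_max, "non-bonded"),
                              (self.hb_min, self.hb_max, "hydrogen-bond")):
            if not 0 < lo < hi:
                raise ValueError(f"{label} window must satisfy 0 < min < max, got [{lo}, {hi}]")


@dataclass(frozen=True)
class AtomRef:
    chain_id: str
    seq_number: int
    res_name: str
    atom_name: str

    def __str__(self) -> str:
        return f"{self.chain_id}/{self.res_name}{self.seq_number}/{self.atom_name}"


@dataclass(frozen=True)
class Contact:
    a: AtomRef
    b: AtomRef
    distance: float
    is_hbond: bool
    is_nonbonded: bool


@dataclass(frozen=True)
class HBond:
    donor: AtomRef
    acceptor: AtomRef
    distance: float


def _flat_atoms(structure: Structure) -> tuple[list[AtomRef], np.ndarray]:
    refs, coords = [], []
    for r, a in structure.iter_atoms():
        refs.append(AtomRef(r.chain_id, r.seq_number, r.res_name, a.name))
        coords.append(a.coords)
    return refs, np.asarray(coords)


def detect_contacts(a: Structure, b: Structure, criteria: ContactCriteria | None = None) -> list[Contact]:
    """All inter-chain heavy-atom pairs inside the contact/H-bond windows.

    A pair is a non-bonded contact when nb_min <= d <= nb_max and a hydrogen
    bond when it is donor/acceptor typed (in either direction) with
    hb_min <= d <= hb_max.  Pairs satisfying neither (e.g. below both
    minima) are not reported.
    """
    criteria = criteria or ContactCriteria()
    refs_a, xyz_a = _flat_atoms(a)
    refs_b, xyz_b = _flat_atoms(b)
    if len(refs_a) == 0 or len(refs_b) == 0:
        raise ValueError("detect_contacts: empty chain")
    tree = cKDTree(xyz_b)
    upper = max(criteria.nb_max, criteria.hb_max)
    out: list[Contact] = []
    for i, neighbours in enumerate(tree.query_ball_point(xyz_a, r=upper)):
        for j in neighbours:
            d = float(np.linalg.norm(xyz_a[i] - xyz_b[j]))
            ra, rb = refs_a[i], refs_b[j]
            typed = (is_donor(ra.res_name, ra.atom_name) and is_acceptor(rb.res_name, rb.atom_name)) or \
                    (is_donor(rb.res_name, rb.atom_name) and is_acceptor(ra.res_name, ra.atom_name))
            hb = typed and criteria.hb_min <= d <= criteria.hb_max
            nb = criteria.nb_min <= d <= criteria.nb_max
            if hb or nb:
                out.append(Contact(ra, rb, round(d, 6), hb, nb))
    out.sort(key=lambda c: (c.a.chain_id, c.a.seq_number, c.a.atom_name, c.b.seq_number, c.b.atom_name))
    return out


def hydrogen_bonds(a: Structure, b: Structure, criteria: ContactCriteria | None = None) -> list[HBond]:
    """Donor/acceptor-oriented hydrogen bonds between two chains."""
    bonds = []
    for c in detect_contacts(a, b, criteria):
        if not c.is_hbond:
            continue
        if is_donor(c.a.res_name, c.a.atom_name) and is_acceptor(c.b.res_name, c.b.atom_name):
            bonds.append(HBond(c.a, c.b, c.distance))
        elif is_donor(c.b.res_name, c.b.atom_name) and is_acceptor(c.a.res_name, c.a.atom_name):
            bonds.append(HBond(c.b, c.a, c.distance))
    return bonds


def contacts_to_frame(contacts: Iterable[Contact]) -> pd.DataFrame:
    rows = [
        {
            "chain_a": c.a.chain_id, "res_a": c.a.seq_number, "resname_a": c.a.res_name,
            "atom_a": c.a.atom_name,
            "chain_b": c.b.chain_id, "res_b": c.b.seq_number, "resname_b": c.b.res_name,
            "atom_b": c.b.atom_name,
            "distance": c.distance, "hbond": c.is_hbond, "nonbonded": c.is_nonbonded,
        }
        for c in contacts
    ]
    return pd.DataFrame(rows, columns=["chain_a", "res_a", "resname_a", "atom_a",
                                       "chain_b", "res_b", "resname_b", "atom_b",
                                       "distance", "hbond", "nonbonded"])


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic, nearly uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    theta = math.pi * (3.0 - math.sqrt(5.0)) * i
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def shrake_rupley_asa(
    structure: Structure,
    probe: float = 1.4,
    n_points: int = 960,
    radii: dict[str, float] | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Solvent-accessible surface area by Shrake-Rupley quadrature.

    Returns (per-atom ASA array in input atom order, per-residue DataFrame
    with columns chain, seq_number, res_name, asa), all in Angstrom^2.
    """
    radii = radii if radii is not None else DEFAULT_RADII
    refs, coords = [], []
    for r, a in structure.iter_atoms():
        if a.element not in radii:
            raise ValueError(
                f"shrake_rupley_asa: no radius for element {a.element!r} "
                f"(atom {a.name} of {r.label}, chain {r.chain_id})"
            )
        refs.append((r, a))
        coords.append(a.coords)
    xyz = np.asarray(coords)
    rad = np.array([radii[a.element] for _, a in refs]) + probe
    unit = _sphere_points(n_points)
    tree = cKDTree(xyz)
    asa = np.zeros(len(refs))
    max_r = rad.max()
    for i in range(len(refs)):
        pts = xyz[i] + rad[i] * unit
        neighbours = [j for j in tree.query_ball_point(xyz[i], r=rad[i] + max_r) if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbours:
            d2 = np.sum((pts - xyz[j]) ** 2, axis=1)
            accessible &= d2 >= rad[j] ** 2
            if not accessible.any():
                break
        asa[i] = 4.0 * math.pi * rad[i] ** 2 * accessible.sum() / n_points

    per_res: dict[tuple[str, int], dict] = {}
    for (r, _), area in zip(refs, asa):
        key = (r.chain_id, r.seq_number)
        row = per_res.setdefault(key, {"chain": r.chain_id, "seq_number": r.seq_number,
                                       "res_name": r.res_name, "asa": 0.0})
        row["asa"] += float(area)
    frame = pd.DataFrame(list(per_res.values()), columns=["chain", "seq_number", "res_name", "asa"])
    return asa, frame


@dataclass
class InterfaceTable:
    """Per-residue buried surface on complexation and its share of the interface."""

    rows: pd.DataFrame  # chain, seq_number, res_name, delta_asa, percent

    def to_tsv(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index=False, float_format="%.4f")

    def to_json(self) -> str:
        return json.dumps(self.rows.to_dict(orient="records"), indent=1)


def interface_contributions(
    complex_structure: Structure,
    chain: str | None = None,
    probe: float = 1.4,
    n_points: int = 960,
    radii: dict[str, float] | None = None,
    average_chains: bool = False,
) -> InterfaceTable:
    """Residue contributions to the buried interface surface of a dimer.

    For each residue of `chain`, delta_asa = ASA(chain isolated) - ASA(chain
    in complex); percent = 100 * delta_asa / total buried area of that chain
    (residues with delta_asa > 0 only).  With ``average_chains`` the percent
    column is averaged over both chains by residue number (homodimers).
    """
    chains = complex_structure.chains
    if len(chains) < 2:
        raise ValueError("interface_contributions: need a complex with at least two chains")
    chain = chain or chains[0]

    def one_chain(cid: str) -> pd.DataFrame:
        alone = complex_structure.chain(cid)
        _, asa_alone = shrake_rupley_asa(alone, probe, n_points, radii)
        _, asa_complex = shrake_rupley_asa(complex_structure, probe, n_points, radii)
        asa_complex = asa_complex[asa_complex["chain"] == cid]
        merged = asa_alone.merge(asa_complex, on=["chain", "seq_number", "res_name"],
                                 suffixes=("_alone", "_complex"))
        delta = (merged["asa_alone"] - merged["asa_complex"]).clip(lower=0.0)
        merged["delta_asa"] = delta
        total = delta[delta > 0].sum()
        merged["percent"] = np.where(delta > 0, 100.0 * delta / total, 0.0) if total > 0 else 0.0
        out = merged[["chain", "seq_number", "res_name", "delta_asa", "percent"]]
        return out[out["delta_asa"] > 0].sort_values("seq_number").reset_index(drop=True)

    table = one_chain(chain)
    if average_chains:
        tables = [one_chain(c) for c in chains[:2]]
        merged = tables[0].merge(tables[1], on="seq_number", how="outer", suffixes=("", "_partner"))
        merged["percent"] = merged[["percent", "percent_partner"]].fillna(0.0).mean(axis=1)
        merged["delta_asa"] = merged[["delta_asa", "delta_asa_partner"]].fillna(0.0).mean(axis=1)
        merged["chain"] = merged["chain"].fillna(chains[0])
        merged["res_name"] = merged["res_name"].fillna(merged.get("res_name_partner"))
        table = merged[["chain", "seq_number", "res_name", "delta_asa", "percent"]].sort_values(
            "seq_number").reset_index(drop=True)
    return InterfaceTable(rows=table)
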