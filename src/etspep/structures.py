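"""PDB reading, atom selection and core geometry.

A deliberately small hierarchical model (chains -> residues -> atoms) backs
all downstream analyses: least-squares superposition, RMSD, radius of
gyration and backbone torsions.  Only heavy-atom ATOM records are read;
hydrogens, waters and HETATM groups are discarded on input because every
operation here is defined on protein heavy atoms and crystal structures
rarely carry hydrogens anyway.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

MAINCHAIN_ATOMS = frozenset({"N", "CA", "C", "O"})

# Standard atomic masses for mass-weighted radius of gyration.
ATOMIC_MASS = {
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "SE": 78.971,
    "H": 1.008,
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


@dataclass
class Atom:
    """A heavy atom with coordinates in Angstrom."""

    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")

    @property
    def is_mainchain(self) -> bool:
        return self.name in MAINCHAIN_ATOMS

    @property
    def mass(self) -> float:
        try:
            return ATOMIC_MASS[self.element]
        except KeyError:
            raise KeyError(f"no atomic mass for element {self.element!r} (atom {self.name})") from None


@dataclass
class Residue:
    chain_id: str
    seq_number: int
    res_name: str
    atoms: list[Atom] = field(default_factory=list)
    insertion_code: str = ""

    @property
    def aa_code(self) -> str:
        """One-letter code; 'X' for non-standard residues."""
        return THREE_TO_ONE.get(self.res_name, "X")

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(
            f"atom {name} missing from residue {self.res_name}{self.seq_number} (chain {self.chain_id})"
        )

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    @property
    def label(self) -> str:
        return f"{self.res_name}{self.seq_number}"


@dataclass
class Structure:
    """A protein model: ordered residues grouped by chain."""

    residues: list[Residue] = field(default_factory=list)
    source_label: str = ""

    @property
    def chains(self) -> list[str]:
        seen: list[str] = []
        for r in self.residues:
            if r.chain_id not in seen:
                seen.append(r.chain_id)
        return seen

    def chain(self, chain_id: str) -> "Structure":
        res = [r for r in self.residues if r.chain_id == chain_id]
        if not res:
            raise ValueError(
                f"chain {chain_id!r} not present in {self.source_label or 'structure'}; "
                f"available chains: {', '.join(self.chains) or '(none)'}"
            )
        return Structure(residues=res, source_label=f"{self.source_label}:{chain_id}")

    def residue(self, chain_id: str, seq_number: int) -> Residue:
        for r in self.residues:
            if r.chain_id == chain_id and r.seq_number == seq_number:
                return r
        raise KeyError(f"residue {seq_number} of chain {chain_id} not found")

    def iter_atoms(self) -> Iterator[tuple[Residue, Atom]]:
        for r in self.residues:
            for a in r.atoms:
                yield r, a

    def select_coords(
        self,
        atom_names: Iterable[str] | None = None,
        chain_id: str | None = None,
        predicate: Callable[[Residue, Atom], bool] | None = None,
    ) -> np.ndarray:
        names = frozenset(atom_names) if atom_names is not None else None
        pts = [
            a.coords
            for r, a in self.iter_atoms()
            if (chain_id is None or r.chain_id == chain_id)
            and (names is None or a.name in names)
            and (predicate is None or predicate(r, a))
        ]
        if not pts:
            raise ValueError("atom selection is empty")
        return np.asarray(pts)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a rigidly transformed copy (x -> R x + t)."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        new_res = []
        for r in self.residues:
            atoms = [replace(a, coords=rotation @ a.coords + translation) for a in r.atoms]
            new_res.append(replace(r, atoms=atoms))
        return Structure(residues=new_res, source_label=self.source_label)


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid fit x -> R x + t of a mobile onto a reference point set."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation

    def apply_structure(self, structure: Structure) -> Structure:
        return structure.transformed(self.rotation, self.translation)


def _element_from_name(name: str, field77: str) -> str:
    if field77:
        return field77.upper()
    stripped = name.strip().lstrip("0123456789")
    return stripped[:1].upper() if stripped else ""


def parse_pdb(text: str, chain: str | None = None, source_label: str = "") -> Structure:
    """Parse ATOM records of a PDB file into a :class:`Structure`.

    Hydrogens, waters and HETATM groups are dropped.  When a residue carries
    alternative locations, only the conformer with the highest occupancy is
    kept; on a tie altloc ``'A'`` wins, then the lexicographically smallest.

    Parameters
    ----------
    text : full PDB text (a single model; use :func:`parse_pdb_models` for
        multi-model trajectories).
    chain : optional chain id; restrict to this chain and raise a
        ``ValueError`` naming the available chains if absent.
    """
    structure, chains_seen = _parse_atom_lines(text.splitlines(), source_label)
    if chain is not None:
        if chain not in chains_seen:
            raise ValueError(
                f"chain {chain!r} not found; available chains: {', '.join(sorted(chains_seen)) or '(none)'}"
            )
        structure = structure.chain(chain)
    return structure


def parse_pdb_models(text: str, chain: str | None = None, source_label: str = "") -> list[Structure]:
    """Parse a multi-model PDB (MODEL/ENDMDL) into one Structure per model."""
    blocks: list[list[str]] = []
    current: list[str] = []
    in_model = False
    for line in text.splitlines():
        rec = line[:6].strip()
        if rec == "MODEL":
            if current:
                blocks.append(current)
            current = []
            in_model = True
        elif rec == "ENDMDL":
            blocks.append(current)
            current = []
            in_model = False
        else:
            current.append(line)
    if current and any(l[:6].strip() in ("ATOM", "HETATM") for l in current):
        blocks.append(current)
    if not blocks:
        blocks = [text.splitlines()]
    frames = []
    for i, block in enumerate(blocks):
        s, chains_seen = _parse_atom_lines(block, f"{source_label}#model{i + 1}")
        if chain is not None:
            if chain not in chains_seen:
                raise ValueError(
                    f"model {i + 1}: chain {chain!r} not found; available: {', '.join(sorted(chains_seen))}"
                )
            s = s.chain(chain)
        if s.residues:
            frames.append(s)
    return frames


def _parse_atom_lines(lines: Sequence[str], source_label: str) -> tuple[Structure, set[str]]:
    chains_seen: set[str] = set()
    # keyed by (chain, resseq, icode, atom name): list of candidate atoms
    order: list[tuple[str, int, str]] = []
    residues: dict[tuple[str, int, str], Residue] = {}
    candidates: dict[tuple[str, int, str, str], list[Atom]] = {}
    for lineno, line in enumerate(lines, start=1):
        rec = line[:6].strip()
        if rec != "ATOM":
            continue
        try:
            name = line[12:16].strip()
            altloc = line[16:17].strip()
            res_name = line[17:20].strip()
            chain_id = line[21:22].strip()
            seq_number = int(line[22:26])
            icode = line[26:27].strip()
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
            occ_field = line[54:60].strip()
            occupancy = float(occ_field) if occ_field else 1.0
            element = _element_from_name(name, line[76:78].strip() if len(line) >= 77 else "")
        except (ValueError, IndexError) as exc:
            raise ValueError(f"malformed ATOM record at line {lineno}: {exc}") from None
        if res_name in _WATER_NAMES or element in ("H", "D"):
            continue
        chains_seen.add(chain_id)
        rkey = (chain_id, seq_number, icode)
        if rkey not in residues:
            residues[rkey] = Residue(chain_id, seq_number, res_name, insertion_code=icode)
            order.append(rkey)
        akey = (chain_id, seq_number, icode, name)
        atom = Atom(name=name, element=element, coords=np.array([x, y, z]),
                    occupancy=min(max(occupancy, 0.0), 1.0), altloc=altloc)
        candidates.setdefault(akey, []).append(atom)
        if len(candidates[akey]) == 1:
            residues[rkey].atoms.append(atom)

    # altloc resolution: highest occupancy; tie -> 'A', then lexicographic
    for akey, atoms in candidates.items():
        if len(atoms) == 1:
            continue
        best = max(atoms, key=lambda a: (a.occupancy, a.altloc == "A", _neg_lex(a.altloc)))
        rkey = akey[:3]
        res = residues[rkey]
        res.atoms = [best if a.name == akey[3] else a for a in res.atoms]
    return Structure(residues=[residues[k] for k in order], source_label=source_label), chains_seen


def _neg_lex(s: str) -> tuple[int, ...]:
    # lexicographically smallest wins under max(): invert character codes
    return tuple(-ord(c) for c in s) if s else (1,)


def write_pdb(structure: Structure) -> str:
    """Serialise a Structure back to standard PDB ATOM records."""
    lines = []
    serial = 0
    for res in structure.residues:
        for a in res.atoms:
            serial += 1
            name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
            lines.append(
                f"ATOM  {serial:5d} {name:<4.4s}{'':1s}{res.res_name:>3s} {res.chain_id:1s}"
                f"{res.seq_number:4d}{res.insertion_code:1s}   "
                f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
                f"{a.occupancy:6.2f}{0.0:6.2f}          {a.element:>2s}"
            )
    lines.append("END")
    return "\n".join(lines) + "\n"


def radius_of_gyration(
    structure: Structure,
    atom_names: Iterable[str] | None = None,
    chain_id: str | None = None,
    mass_weighted: bool = True,
) -> float:
    """Radius of gyration sqrt(sum w_i |r_i - rbar|^2 / sum w_i) in Angstrom.

    Defaults to all protein heavy atoms, mass-weighted; `atom_names` narrows
    the selection (e.g. {"CA"}).
    """
    names = frozenset(atom_names) if atom_names is not None else None
    coords, weights = [], []
    for r, a in structure.iter_atoms():
        if chain_id is not None and r.chain_id != chain_id:
            continue
        if names is not None and a.name not in names:
            continue
        coords.append(a.coords)
        weights.append(a.mass if mass_weighted else 1.0)
    if not coords:
        raise ValueError("radius_of_gyration: empty atom selection")
    xyz = np.asarray(coords)
    w = np.asarray(weights)
    centre = np.average(xyz, axis=0, weights=w)
    return float(np.sqrt(np.average(np.sum((xyz - centre) ** 2, axis=1), weights=w)))


def superpose(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid fit of `mobile` onto `reference` (Kabsch).

    Returns the proper rotation (determinant +1; reflections are corrected)
    and translation minimising the RMSD, together with the minimised RMSD.
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.ndim != 2 or mob.shape[1] != 3 or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("superpose expects (N, 3) coordinate arrays")
    if mob.shape[0] != ref.shape[0]:
        raise ValueError(f"point count mismatch: mobile {mob.shape[0]} vs reference {ref.shape[0]}")
    n = mob.shape[0]
    if n < 3:
        raise ValueError("superpose requires at least 3 points")
    mob_mean = mob.mean(axis=0)
    ref_mean = ref.mean(axis=0)
    mob_c = mob - mob_mean
    ref_c = ref - ref_mean
    for label, arr in (("mobile", mob_c), ("reference", ref_c)):
        s = np.linalg.svd(arr, compute_uv=False)
        if s[1] <= 1e-8 * max(s[0], 1e-30):
            raise ValueError(f"superpose: {label} points are (nearly) collinear; fit is degenerate")
    rot, rssd = Rotation.align_vectors(ref_c, mob_c)
    matrix = rot.as_matrix()
    translation = ref_mean - matrix @ mob_mean
    return SuperpositionResult(rotation=matrix, translation=translation, rmsd=float(rssd / math.sqrt(n)))


def superpose_structures(
    mobile: Structure,
    reference: Structure,
    atom_names: Iterable[str] = ("CA",),
    chain_id: str | None = None,
) -> tuple[Structure, SuperpositionResult]:
    """Fit `mobile` onto `reference` on the named atoms (default C-alpha)."""
    names = tuple(atom_names)
    mob = mobile.select_coords(atom_names=names, chain_id=chain_id)
    ref = reference.select_coords(atom_names=names, chain_id=chain_id)
    result = superpose(mob, ref)
    return result.apply_structure(mobile), result


def per_residue_rmsd(frame: Structure, reference: Structure, chain_id: str, seq_number: int) -> float:
    """Main-chain (N, CA, C, O) RMSD of one residue, without refitting.

    The frame must already be superposed onto the reference (C-alpha fit).
    """
    fr = frame.residue(chain_id, seq_number)
    rr = reference.residue(chain_id, seq_number)
    sq = 0.0
    for name in ("N", "CA", "C", "O"):
        for res, who in ((fr, "frame"), (rr, "reference")):
            if not res.has_atom(name):
                raise ValueError(
                    f"per_residue_rmsd: main-chain atom {name} missing from {who} "
                    f"residue {res.label} (chain {chain_id})"
                )
        d = fr.atom(name).coords - rr.atom(name).coords
        sq += float(d @ d)
    return math.sqrt(sq / 4.0)


def dihedral(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> float:
    """Signed torsion angle a-b-c-d in degrees, in (-180, 180].

    IUPAC convention: cis (eclipsed) is 0 deg, and looking down b->c a
    clockwise rotation of the far bond is positive.
    """
    a, b, c, d = (np.asarray(p, dtype=float) for p in (a, b, c, d))
    b1 = b - a
    b2 = c - b
    b3 = d - c
    nb2 = np.linalg.norm(b2)
    if nb2 < 1e-10:
        raise ValueError("dihedral: central bond b-c has zero length")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise ValueError("dihedral: degenerate geometry (collinear points)")
    m1 = np.cross(n1, b2 / nb2)
    angle = math.degrees(math.atan2(float(m1 @ n2), float(n1 @ n2)))
    if angle <= -180.0:
        angle += 360.0
    return angle
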