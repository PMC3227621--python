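"""Shared fixtures and geometry builders for the test suite.

The backbone builder places atoms from internal coordinates (NeRF-style),
so it constructs chains with *prescribed* torsions independently of the
torsion-measuring code under test.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from etspep.structures import Atom, Residue, Structure

# idealised backbone internal coordinates (Angstrom / degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
OMEGA = 180.0


def place_atom(a, b, c, length: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place point d with |cd| = length, angle(b,c,d) = angle, torsion(a,b,c,d) = torsion."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    theta = math.radians(angle_deg)
    chi = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -length * math.cos(theta),
        length * math.sin(theta) * math.cos(chi),
        -length * math.sin(theta) * math.sin(chi),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(torsions: list[tuple[float, float]], chain_id: str = "A",
                   res_name: str = "ALA", first_seq: int = 1) -> Structure:
    """Backbone-only chain with the given (phi, psi) per residue.

    phi of the first residue is undefined (no preceding carbonyl) and the
    entry is ignored; psi of the last residue still orients its carbonyl.
    """
    n_res = len(torsions)
    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([BOND_N_CA, 0.0, 0.0])]
    theta = math.radians(ANGLE_N_CA_C)
    C = [CA[0] + np.array([-BOND_CA_C * math.cos(theta), BOND_CA_C * math.sin(theta), 0.0])]
    for i in range(n_res - 1):
        psi_i = torsions[i][1]
        N.append(place_atom(N[i], CA[i], C[i], BOND_C_N, ANGLE_CA_C_N, psi_i))
        CA.append(place_atom(CA[i], C[i], N[i + 1], BOND_N_CA, ANGLE_C_N_CA, OMEGA))
        C.append(place_atom(C[i], N[i + 1], CA[i + 1], BOND_CA_C, ANGLE_N_CA_C,
                            torsions[i + 1][0]))
    O = []
    for i in range(n_res):
        psi_i = torsions[i][1]
        O.append(place_atom(N[i], CA[i], C[i], BOND_C_O, ANGLE_CA_C_O, psi_i + 180.0))
    residues = []
    for i in range(n_res):
        residues.append(Residue(chain_id, first_seq + i, res_name, atoms=[
            Atom("N", "N", N[i]),
            Atom("CA", "C", CA[i]),
            Atom("C", "C", C[i]),
            Atom("O", "O", O[i]),
        ]))
    return Structure(residues=residues, source_label="built_backbone")


def random_rigid_transform(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
    return rot, rng.normal(scale=10.0, size=3)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)


@pytest.fixture
def helix_structure() -> Structure:
    """A 10-residue ideal alpha-helical backbone."""
    return build_backbone([(-57.0, -47.0)] * 10)
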