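"""Synthetic inputs emulating the statistical structure of a screening study.

Three generators make every pipeline stage testable without external data:

* score tables with an additive size bias and a known maximal-ligand-
  efficiency envelope exponent (the ground truth the envelope fit must
  recover),
* backbone-dihedral time series as a mixture of metastable angular states
  with von Mises (thermal) noise and known frame labels,
* minimal two-chain complexes with donor/acceptor atom pairs placed at
  exact distances for contact, hydrogen-bond and fingerprint tests.

All generators are pure functions of (config, seed): replays are
byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structures import Atom, Residue, Structure
from .trajectory import DihedralSeries


@dataclass
class ScoreGenConfig:
    """Synthetic docking-score table configuration.

    The maximal ligand efficiency at each heavy-atom count HAC is forced to
    lie exactly on exp(k_true) * HAC^(-x_true); the remaining peptides
    undershoot the envelope multiplicatively (exponential depth, lognormal
    wiggle of sd `noise_sigma`).  Scores are emitted negative (docking
    convention).
    """

    x_true: float = 0.7
    k_true: float = 0.0
    n_per_hac: int = 50
    hac_range: tuple[int, int] = (10, 29)   # inclusive
    noise_sigma: float = 0.05
    seed: int = 0
    n_receptors: int = 1
    undershoot_scale: float = 0.4           # mean log-depth below the envelope

    def __post_init__(self) -> None:
        if not 0.0 < self.x_true < 1.0:
            raise ValueError("x_true must lie in (0, 1)")
        if self.n_per_hac < 1:
            raise ValueError("n_per_hac must be >= 1")
        if self.hac_range[0] < 1 or self.hac_range[1] < self.hac_range[0]:
            raise ValueError("invalid hac_range")


def gen_scores(config: ScoreGenConfig) -> pd.DataFrame:
    """Synthetic DockScoreTable with a known LE_max envelope.

    Returns columns receptor_id, sequence, tautomer_id, score, hac plus the
    seed in DataFrame attrs.  Sequences are synthetic identifiers (the table
    carries an explicit hac column, so downstream ranking never needs to
    re-derive HAC from them).
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.hac_range
    rows = []
    for r in range(config.n_receptors):
        receptor = f"R{r + 1:02d}"
        for hac in range(lo, hi + 1):
            e_max = np.exp(config.k_true) * hac ** (-config.x_true)
            for j in range(config.n_per_hac):
                if j == 0 and r == 0:
                    e = e_max  # forced envelope peptide
                else:
                    depth = rng.exponential(config.undershoot_scale)
                    wiggle = rng.normal(0.0, config.noise_sigma) if config.noise_sigma > 0 else 0.0
                    e = min(e_max, e_max * np.exp(-depth + wiggle))
                rows.append({
                    "receptor_id": receptor,
                    "sequence": f"pep{hac:03d}_{j:03d}",
                    "tautomer_id": "parent",
                    "score": -e * hac,
                    "hac": hac,
                })
    df = pd.DataFrame(rows)
    df.attrs["seed"] = config.seed
    df.attrs["x_true"] = config.x_true
    df.attrs["k_true"] = config.k_true
    return df


@dataclass
class DihedralGenConfig:
    """Mixture of metastable angular states with von Mises noise.

    Each state is (mean angle vector in degrees, concentration kappa,
    weight); weights must sum to 1.  kappa ~ 1/sigma_rad^2, so kappa = 33
    corresponds to roughly 10 degrees of thermal spread.
    """

    states: list[tuple[list[float], float, float]] = field(default_factory=list)
    n_frames: int = 1000
    seed: int = 0
    residues: list[int] | None = None

    def __post_init__(self) -> None:
        if not self.states:
            raise ValueError("need at least one state")
        widths = {len(m) for m, _, _ in self.states}
        if len(widths) != 1:
            raise ValueError("all state mean vectors must have the same length")
        (width,) = widths
        if width % 2 != 0:
            raise ValueError("mean vectors hold (phi, psi) pairs; length must be even")
        if any(k <= 0 for _, k, _ in self.states):
            raise ValueError("concentrations must be positive")
        total = sum(w for _, _, w in self.states)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"state weights must sum to 1 (got {total})")


def gen_dihedrals(config: DihedralGenConfig) -> tuple[DihedralSeries, np.ndarray]:
    """Draw a dihedral time series plus the planted per-frame state labels."""
    rng = np.random.default_rng(config.seed)
    n_angles = len(config.states[0][0])
    weights = np.array([w for _, _, w in config.states])
    labels = rng.choice(len(config.states), size=config.n_frames, p=weights)
    angles = np.empty((config.n_frames, n_angles))
    for si, (mean, kappa, _) in enumerate(config.states):
        members = np.flatnonzero(labels == si)
        if members.size == 0:
            continue
        draws = rng.vonmises(np.deg2rad(mean), kappa, size=(members.size, n_angles))
        angles[members] = np.rad2deg(draws)
    residues = config.residues or list(range(20, 20 + n_angles // 2))
    series = DihedralSeries(angles=angles.reshape(config.n_frames, n_angles // 2, 2),
                            residues=residues)
    return series, labels


def gen_toy_complex(placements, chain_a: str = "A", chain_b: str = "B") -> Structure:
    """Minimal two-chain structure with atom pairs at exact distances.

    Each placement is a tuple (res_name_a, atom_name_a, res_name_b,
    atom_name_b, distance); pair i is laid out along +x at y = 20 * i so
    pairs never interfere.  Elements are inferred from atom names.
    """
    if not placements:
        raise ValueError("gen_toy_complex: need at least one placement")
    res_a, res_b = [], []
    for i, (rna, ana, rnb, anb, dist) in enumerate(placements):
        if not np.isfinite(dist) or dist <= 0:
            raise ValueError(f"placement {i}: infeasible distance {dist}")
        y = 20.0 * i
        res_a.append(Residue(chain_a, i + 1, rna, atoms=[
            Atom(name=ana, element=_element(ana), coords=np.array([0.0, y, 0.0]))]))
        res_b.append(Residue(chain_b, i + 1, rnb, atoms=[
            Atom(name=anb, element=_element(anb), coords=np.array([float(dist), y, 0.0]))]))
    return Structure(residues=res_a + res_b, source_label="toy_complex")


def _element(atom_name: str) -> str:
    stripped = atom_name.strip().lstrip("0123456789")
    return stripped[:1].upper()
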