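"""Ligand-efficiency and size-independent ligand-efficiency (SILE) ranking.

Docking scores are conventionally more-negative-is-better; affinity is
their magnitude.  Ligand efficiency LE = affinity / HAC falls off with
heavy-atom count, and the maximal-LE envelope across a screen follows a
power law, fitted on logs:

    ln(LE_max) = k - x * ln(HAC)

The SILE score, affinity / HAC^(1 - x), removes the additive size bias of
docking scoring functions so peptides of different lengths compete fairly.
The generic literature exponent x = 0.7 serves as a fallback when no fit is
wanted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .peptides import AMINO_ACIDS, peptide_hac

#: Generic envelope exponent used when a screen-specific fit is not available.
GENERIC_EXPONENT = 0.7

SCORE_COLUMNS = ["receptor_id", "sequence", "tautomer_id", "score"]


def ligand_efficiency(affinity: float, hac: int) -> float:
    """LE = affinity / heavy atom count."""
    if hac < 1:
        raise ValueError(f"heavy atom count must be >= 1, got {hac}")
    return affinity / hac


def sile(affinity: float, hac: int, x: float) -> float:
    """Size-independent ligand efficiency: affinity / HAC^(1 - x)."""
    if np.any(np.asarray(hac) < 1):
        raise ValueError("heavy atom count must be >= 1")
    return affinity / np.power(hac, 1.0 - x)


def load_scores(path) -> pd.DataFrame:
    """Read a (receptor_id, sequence, tautomer_id, score[, hac]) table.

    Accepts TSV or CSV (sniffed from the header line).  Schema violations
    are reported with row numbers.
    """
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, dtype={"receptor_id": str, "sequence": str, "tautomer_id": str})
    missing = [c for c in SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"score table missing columns: {', '.join(missing)}")
    bad = df.index[pd.to_numeric(df["score"], errors="coerce").isna()].tolist()
    if bad:
        raise ValueError(f"non-numeric score at rows {[i + 2 for i in bad[:10]]} (1-based incl. header)")
    return prepare_scores(df)


def prepare_scores(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a score table and derive affinity/hac columns."""
    df = df.copy()
    dup = df.duplicated(subset=["receptor_id", "sequence", "tautomer_id"])
    if dup.any():
        raise ValueError(f"duplicate (receptor, sequence, tautomer) rows at index {list(df.index[dup])[:10]}")
    df["affinity"] = df["score"].abs()
    if "hac" not in df.columns:
        df["hac"] = df["sequence"].map(peptide_hac)
    return df


@dataclass
class LeMaxFit:
    """Log-log fit of the maximal-LE envelope: ln(LE_max) = k - x ln(HAC)."""

    x: float
    k: float
    points: pd.DataFrame  # columns hac, le_max

    def predict(self, hac) -> np.ndarray:
        return np.exp(self.k - self.x * np.log(np.asarray(hac, dtype=float)))


def lemax_envelope(table: pd.DataFrame, pooled: bool = True) -> pd.DataFrame:
    """Maximum LE at each distinct HAC (across all receptors when pooled).

    Returns a DataFrame (hac, le_max) sorted by hac; with ``pooled=False``
    an extra receptor_id column gives one envelope per receptor.
    """
    if table.empty:
        raise ValueError("lemax_envelope: empty score table")
    df = table.copy()
    if "affinity" not in df.columns:
        df = prepare_scores(df)
    df["le"] = df["affinity"] / df["hac"]
    if pooled:
        env = df.groupby("hac", as_index=False)["le"].max().rename(columns={"le": "le_max"})
        return env.sort_values("hac").reset_index(drop=True)
    env = df.groupby(["receptor_id", "hac"], as_index=False)["le"].max().rename(columns={"le": "le_max"})
    return env.sort_values(["receptor_id", "hac"]).reset_index(drop=True)


def fit_lemax(envelope: pd.DataFrame) -> LeMaxFit:
    """Ordinary least squares of ln(le_max) on ln(hac); x = -slope, k = intercept."""
    env = envelope.drop_duplicates(subset="hac")
    if len(env) < 2:
        raise ValueError("fit_lemax needs at least 2 distinct HAC values")
    if (env["le_max"] <= 0).any():
        raise ValueError("fit_lemax requires strictly positive le_max values")
    slope, intercept = np.polyfit(np.log(env["hac"].astype(float)), np.log(env["le_max"]), 1)
    x = -float(slope)
    if not 0.0 <= x <= 1.0:
        warnings.warn(f"fitted envelope exponent x = {x:.3f} lies outside [0, 1]", stacklevel=2)
    return LeMaxFit(x=x, k=float(intercept), points=env.reset_index(drop=True))


def rank_peptides(table: pd.DataFrame, x: float) -> pd.DataFrame:
    """Collapse tautomers and rank peptides per receptor by score and SILE.

    Per (receptor, sequence) the tautomer with the best (most negative)
    score is retained (tie -> lexicographically smallest tautomer_id); ranks
    are assigned by descending affinity (score_rank) and descending SILE
    (sile_rank), 1 = best, ties broken by lexicographic sequence.
    """
    df = table.copy()
    if "affinity" not in df.columns:
        df = prepare_scores(df)
    df = df.sort_values(["receptor_id", "sequence", "score", "tautomer_id"],
                        kind="mergesort")
    best = df.groupby(["receptor_id", "sequence"], as_index=False).first()
    best["le"] = best["affinity"] / best["hac"]
    best["sile"] = sile(best["affinity"].to_numpy(), best["hac"].to_numpy(), x)
    parts = []
    for _, grp in best.groupby("receptor_id", sort=True):
        grp = grp.copy()
        for col, rank_col in (("affinity", "score_rank"), ("sile", "sile_rank")):
            order = grp.sort_values([col, "sequence"], ascending=[False, True],
                                    kind="mergesort").index
            ranks = pd.Series(np.arange(1, len(grp) + 1), index=order)
            grp[rank_col] = ranks
        parts.append(grp)
    out = pd.concat(parts, ignore_index=True)
    return out[["receptor_id", "sequence", "tautomer_id", "score", "affinity", "hac",
                "le", "sile", "score_rank", "sile_rank"]]


def rank_matrix(ranked: pd.DataFrame, n: int = 2, rank_col: str = "sile_rank") -> pd.DataFrame:
    """20 x 20 grid of di-peptide ranks: rows = position 1, columns = position 2."""
    if n != 2:
        raise ValueError("rank_matrix is defined for di-peptide libraries (n = 2)")
    receptors = ranked["receptor_id"].unique()
    if len(receptors) != 1:
        raise ValueError("rank_matrix expects the ranked table of a single receptor")
    by_seq = dict(zip(ranked["sequence"], ranked[rank_col]))
    missing = [a + b for a in AMINO_ACIDS for b in AMINO_ACIDS if a + b not in by_seq]
    if missing:
        shown = ", ".join(missing[:10]) + ("..." if len(missing) > 10 else "")
        raise ValueError(f"rank_matrix: {len(missing)} missing di-peptides: {shown}")
    grid = pd.DataFrame(
        [[int(by_seq[a + b]) for b in AMINO_ACIDS] for a in AMINO_ACIDS],
        index=list(AMINO_ACIDS), columns=list(AMINO_ACIDS),
    )
    return grid


def query_rank(ranked: pd.DataFrame, sequence: str,
               rank_col: str = "sile_rank") -> tuple[dict[str, int], float]:
    """Per-receptor rank of one sequence and the arithmetic mean rank."""
    rows = ranked[ranked["sequence"] == sequence]
    if rows.empty:
        raise ValueError(f"sequence {sequence!r} not present in ranked table")
    per_receptor = {str(r): int(v) for r, v in zip(rows["receptor_id"], rows[rank_col])}
    return per_receptor, float(np.mean(list(per_receptor.values())))
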