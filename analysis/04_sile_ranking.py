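#!/usr/bin/env python
"""SILE-rank a simulated 12-receptor di-peptide screen.

Docking scoring functions are additive, so raw scores favour large
ligands.  This driver simulates that bias over the real 400-sequence
di-peptide library screened against 12 receptor conformations: affinity
scales like HAC^(1-x_true) with multiplicative undershoot, x_true = 0.7.
The pipeline then pools the maximal-LE envelope across receptors, fits the
exponent, rescales with SILE, and contrasts score- and SILE-ranked top
peptides (score rank 1 goes to heavy aromatic sequences; SILE rank 1 does
not have to) plus a 20 x 20 rank matrix.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from etspep.peptides import enumerate_library
from etspep.ranking import (fit_lemax, lemax_envelope, prepare_scores, query_rank,
                            rank_matrix, rank_peptides)

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

X_TRUE = 0.7
rng = np.random.default_rng(2026)
records = enumerate_library(2)

rows = []
for r in range(12):
    receptor = f"ETS{r + 1}"
    for rec in records:
        # size-biased affinity: LE envelope ~ HAC^(-x_true), so affinity
        # grows ~ HAC^(1-x_true); undershoot varies per peptide and receptor
        envelope = rec.hac ** (1.0 - X_TRUE)
        affinity = envelope * np.exp(-rng.exponential(0.4) + rng.normal(0, 0.05))
        rows.append({"receptor_id": receptor, "sequence": rec.sequence,
                     "tautomer_id": "parent", "score": -affinity, "hac": rec.hac})
table = prepare_scores(pd.DataFrame(rows))

fit = fit_lemax(lemax_envelope(table, pooled=True))
print(f"pooled LE_max envelope over 12 screens: x = {fit.x:.3f} "
      f"(simulated ground truth {X_TRUE}), k = {fit.k:.3f}")

ranked = rank_peptides(table, fit.x)
ranked.groupby("receptor_id", sort=False).apply(
    lambda g: g.nsmallest(20, "sile_rank"), include_groups=False).reset_index(
    level=0).to_csv(OUT / "dipeptide_ranked_top20.tsv", sep="\t",
                    index=False, float_format="%.6g")

top = []
for rid, grp in ranked.groupby("receptor_id", sort=False):
    srow = grp.loc[grp["score_rank"] == 1].iloc[0]
    qrow = grp.loc[grp["sile_rank"] == 1].iloc[0]
    top.append({"receptor": rid,
                "score_rank1": srow["sequence"], "score_rank1_hac": srow["hac"],
                "sile_rank1": qrow["sequence"], "sile_rank1_hac": qrow["hac"]})
top = pd.DataFrame(top)
top.to_csv(OUT / "top_ranked_dipeptides.tsv", sep="\t", index=False)
print("\nbest peptide per receptor (raw score vs SILE):")
print(top.to_string(index=False))
print(f"mean HAC of score-rank-1 peptides: {top['score_rank1_hac'].mean():.1f}; "
      f"of SILE-rank-1 peptides: {top['sile_rank1_hac'].mean():.1f} "
      "(SILE removes the size preference)")

grid = rank_matrix(ranked[ranked["receptor_id"] == "ETS9"], rank_col="sile_rank")
grid.to_csv(OUT / "rank_matrix_ETS9.tsv", sep="\t")

# the interface's own contiguous di-peptide, as a Table-7-style query
per_receptor, mean_rank = query_rank(ranked, "EQ")
pd.DataFrame([{"receptor": k, "sile_rank": v} for k, v in per_receptor.items()]).to_csv(
    OUT / "EQ_query_ranks.tsv", sep="\t", index=False)
print(f"\nGlu-Gln (EQ) SILE rank per receptor: {per_receptor}")
print(f"mean rank over the 12 screens: {mean_rank:.0f} of 400")
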