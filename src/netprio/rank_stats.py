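"""Ranking, top-k pooling and cross-measure Spearman correlation.

Each centrality measure ranks the network's genes; the analysis pools
the top-k (k = 50) genes of every measure into one high-score list and
quantifies how differently the measures order the nodes with Spearman's
rank correlation coefficient,

    rho = 1 - 6 * sum(d_i^2) / (n (n^2 - 1)),

where d_i is the rank difference of gene i under the two measures.  With
ties present the ranks are averaged within tied blocks and rho is
computed as the Pearson correlation of the average ranks, which reduces
to the formula above in the tie-free case.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .centrality import ScoreTable

logger = logging.getLogger(__name__)

TIE_POLICIES = ("average", "competition")


@dataclass
class RankTable:
    """Gene -> rank (1 = highest score) for one measure."""

    measure: str
    ranks: dict[str, float]
    tie_policy: str = "average"


def rank_scores(scores: ScoreTable, tie_policy: str = "average") -> RankTable:
    """Rank genes by descending score.

    ``average`` assigns tied blocks their mean rank (used for correlation);
    ``competition`` assigns tied blocks the best rank in the block ("1224"
    ranking, used for top-k selection).
    """
    if tie_policy not in TIE_POLICIES:
        raise ValueError(f"tie_policy must be one of {TIE_POLICIES}")
    if not scores.scores:
        raise ValueError("cannot rank an empty score table")
    genes = sorted(scores.scores)
    vals = -np.array([scores.scores[g] for g in genes])
    method = "average" if tie_policy == "average" else "min"
    r = stats.rankdata(vals, method=method)
    return RankTable(scores.measure, dict(zip(genes, r.tolist())), tie_policy)


def top_k_genes(scores: ScoreTable, k: int) -> set[str]:
    """Genes scoring at least the k-th highest score (boundary ties kept)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    vals = sorted(scores.scores.values(), reverse=True)
    if k > len(vals):
        logger.warning(
            "top_k_genes: k=%d exceeds the %d scored genes; returning all",
            k, len(vals),
        )
        return set(scores.scores)
    threshold = vals[k - 1]
    return {g for g, s in scores.scores.items() if s >= threshold}


def pool_top_genes(per_measure_sets) -> set[str]:
    """Union of the per-measure top-k gene sets."""
    sets = list(per_measure_sets)
    if not sets:
        raise ValueError("no gene sets to pool")
    out: set[str] = set()
    for s in sets:
        out |= set(s)
    return out


def spearman_rho(ranks_x: RankTable, ranks_y: RankTable) -> float:
    """Spearman correlation of two rankings over the same gene universe."""
    gx, gy = set(ranks_x.ranks), set(ranks_y.ranks)
    if gx != gy:
        raise ValueError(
            f"rank tables cover different gene universes "
            f"({len(gx - gy)} only in x, {len(gy - gx)} only in y)"
        )
    genes = sorted(gx)
    if len(genes) < 2:
        raise ValueError("need at least two genes")
    x = np.array([ranks_x.ranks[g] for g in genes])
    y = np.array([ranks_y.ranks[g] for g in genes])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant ranking has undefined correlation")
    return float(np.corrcoef(x, y)[0, 1])


def correlation_matrix(rank_tables: dict[str, RankTable]) -> pd.DataFrame:
    """Symmetric unit-diagonal Spearman matrix over all measure pairs."""
    names = list(rank_tables)
    if len(names) < 2:
        raise ValueError("need at least two measures")
    m = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            rho = spearman_rho(rank_tables[a], rank_tables[b])
            m.loc[a, b] = rho
            m.loc[b, a] = rho
    return m
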