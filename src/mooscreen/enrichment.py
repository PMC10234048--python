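"""Hypergeometric over-representation analysis with Benjamini-Hochberg FDR.

For a query of n genes drawn from a universe of N genes, a term with K
members and k query hits gets the upper-tail probability
P[X >= k] with X ~ Hypergeom(N, K, n); terms with BH-adjusted
p (FDR) <= 0.05 are called significantly enriched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneSetCollection

logger = logging.getLogger("mooscreen")

FDR_ALPHA = 0.05


@dataclass
class EnrichmentResult:
    """Term-level enrichment statistics, sorted by p ascending (ties by term_id).

    Columns: term_id, term_name, k (query ∩ set), K (set size in universe),
    n (query size), N (universe size), p, fdr, significant.
    """

    table: pd.DataFrame

    def __len__(self) -> int:
        return len(self.table)


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P[X >= k] for X ~ Hypergeom(N, K, n); k = 0 gives 1 by convention."""
    if k <= 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(
    query: set[str] | frozenset[str],
    sets: GeneSetCollection,
    universe: set[str] | frozenset[str],
    fdr_alpha: float = FDR_ALPHA,
) -> EnrichmentResult:
    """Over-representation of ``query`` in each gene set, against ``universe``.

    Query genes outside the universe are dropped with a warning; set
    members outside the universe do not count toward K. Raises if nothing
    of the query survives the intersection.
    """
    universe = frozenset(g.upper() for g in universe)
    q = frozenset(g.upper() for g in query)
    outside = q - universe
    if outside:
        logger.warning("enrich: %d query gene(s) outside the universe dropped", len(outside))
    q &= universe
    if not q:
        raise ValueError("enrich: empty query after intersecting with the universe")

    N, n = len(universe), len(q)
    rows = []
    for term_id in sorted(sets.sets):
        name, members = sets.sets[term_id]
        members_u = members & universe
        K = len(members_u)
        if K == 0:
            continue
        k = len(q & members_u)
        rows.append(
            {
                "term_id": term_id,
                "term_name": name,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p": hypergeom_upper_tail(N, K, n, k),
            }
        )
    df = pd.DataFrame(rows, columns=["term_id", "term_name", "k", "K", "n", "N", "p"])
    if len(df):
        df["fdr"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
        df["significant"] = df["fdr"] <= fdr_alpha
        df = df.sort_values(["p", "term_id"], kind="mergesort").reset_index(drop=True)
    else:
        df["fdr"] = []
        df["significant"] = []
    return EnrichmentResult(table=df)


def top_terms(results: EnrichmentResult, top_n: int) -> list[str]:
    """The first ``top_n`` term ids of a sorted enrichment result (fewer if fewer)."""
    if top_n < 0:
        raise ValueError("top_n must be >= 0")
    return list(results.table["term_id"].iloc[:top_n])
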