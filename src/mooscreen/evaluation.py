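"""Model-comparison metrics and the pathway-importance statistic.

The multiobjective optimizer is compared with degree, closeness and
betweenness baselines on five aspects of the networks they keep:

1. ECP overlap — essential common proteins retained;
2. overlap of the top 100 enriched KEGG pathways with an ECP-derived
   reference list;
3. overlap of the top 1000 enriched GO biological processes with the
   ECP-derived reference;
4. average regulating intensity — mean |Pearson r| over gene-gene edges of
   the optimized network;
5. cumulative differential expression — sum of |log2 FC| over retained ECPs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .ctp_network import CTPNetwork, reconstruct
from .enrichment import EnrichmentResult, enrich, top_terms
from .expression_stats import CorrelationProvider, DETable
from .io_formats import GeneSetCollection
from .moo_scoring import (
    CENTRALITY_METHODS,
    ScoreTable,
    centrality_score,
    moo_score,
    select_targets,
)

logger = logging.getLogger("mooscreen")

METRICS = (
    "ecp_overlap",
    "kegg_top100_overlap",
    "gobp_top1000_overlap",
    "avg_regulating_intensity",
    "cumulative_diffexp",
)


def ecp_overlap(optimized: CTPNetwork, ecps: set[str] | frozenset[str]) -> int:
    """Number of original-network ECPs present among the optimized network's genes."""
    return len(optimized.genes & frozenset(ecps))


def enriched_overlap(model_terms: list[str], reference_terms: list[str]) -> int:
    """Size of the intersection of two top-term lists."""
    return len(set(model_terms) & set(reference_terms))


def avg_regulating_intensity(
    optimized: CTPNetwork, cor: CorrelationProvider, signed: bool = False
) -> tuple[float, int]:
    """Mean Pearson correlation over the optimized network's gene-gene edges.

    Default takes |r| (an intensity); ``signed=True`` averages raw r.
    Returns (mean, n_undefined_pairs); raises when no edge has a defined
    correlation.
    """
    vals = []
    undefined = 0
    for a, b in optimized.gg_edges:
        r = cor.get(a, b)
        if r is None:
            undefined += 1
            continue
        vals.append(r if signed else abs(r))
    if not vals:
        raise ValueError("avg_regulating_intensity: no gene-gene edge with a defined correlation")
    return sum(vals) / len(vals), undefined


def cumulative_diffexp(
    optimized: CTPNetwork, ecps: set[str] | frozenset[str], de: DETable
) -> tuple[float, int]:
    """Sum of |log2 FC| over ECPs retained in the optimized network.

    ECPs missing from the DE table contribute 0; their count is returned.
    """
    total = 0.0
    missing = 0
    for g in frozenset(ecps) & optimized.genes:
        lfc = de.logfc(g)
        if lfc is None:
            missing += 1
            continue
        total += abs(lfc)
    return total, missing


@dataclass
class ModelComparison:
    """Tidy per-model metric table plus the intermediate objects for reuse."""

    table: pd.DataFrame  # one row per model, columns METRICS
    score_tables: dict[str, ScoreTable] = field(default_factory=dict)
    optimized: dict[str, CTPNetwork] = field(default_factory=dict)
    reference_kegg: list[str] = field(default_factory=list)
    reference_gobp: list[str] = field(default_factory=list)


def compare_models(
    net: CTPNetwork,
    de: DETable,
    cor: CorrelationProvider,
    kegg_sets: GeneSetCollection,
    methods: tuple[str, ...] = ("moo", *CENTRALITY_METHODS),
    gobp_sets: GeneSetCollection | None = None,
    fraction: float = 0.5,
    universe: frozenset[str] | None = None,
    kegg_top: int = 100,
    gobp_top: int = 1000,
) -> ModelComparison:
    """Optimize the network with each method at the same kept fraction and score it.

    Reference KEGG/GOBP term lists are enriched from the original
    network's ECPs; each model's lists from the genes of its optimized
    network. When ``gobp_sets`` is omitted the KEGG collection doubles for
    the GOBP-style metric.
    """
    gobp_sets = gobp_sets or kegg_sets
    if universe is None:
        universe = kegg_sets.all_genes() | gobp_sets.all_genes() | net.genes
    ecps = net.ecps

    def _top(query: frozenset[str], sets: GeneSetCollection, n: int) -> list[str]:
        if not query & universe:
            return []
        return top_terms(enrich(query, sets, universe), n)

    ref_kegg = _top(ecps, kegg_sets, kegg_top)
    ref_gobp = _top(ecps, gobp_sets, gobp_top)

    rows = []
    score_tables: dict[str, ScoreTable] = {}
    optimized: dict[str, CTPNetwork] = {}
    for method in methods:
        if method == "moo":
            scores = moo_score(net, de, cor, kegg_sets)
        else:
            scores = centrality_score(net, method)
        kept = select_targets(scores, fraction)
        opt = reconstruct(net, kept)
        score_tables[method] = scores
        optimized[method] = opt
        intensity, n_undef = avg_regulating_intensity(opt, cor)
        cumdiff, n_missing = cumulative_diffexp(opt, ecps, de)
        rows.append(
            {
                "model": method,
                "ecp_overlap": ecp_overlap(opt, ecps),
                "kegg_top100_overlap": enriched_overlap(_top(opt.genes, kegg_sets, kegg_top), ref_kegg),
                "gobp_top1000_overlap": enriched_overlap(_top(opt.genes, gobp_sets, gobp_top), ref_gobp),
                "avg_regulating_intensity": intensity,
                "cumulative_diffexp": cumdiff,
                "n_targets_kept": len(kept),
                "n_undefined_correlations": n_undef,
                "n_ecps_missing_logfc": n_missing,
            }
        )
    table = pd.DataFrame(rows).set_index("model")
    return ModelComparison(
        table=table,
        score_tables=score_tables,
        optimized=optimized,
        reference_kegg=ref_kegg,
        reference_gobp=ref_gobp,
    )


@dataclass
class PathwayImportance:
    """Per-pathway normalized cumulative importance of its scored targets."""

    table: pd.DataFrame  # term_id, term_name, m, importance, rank


def pathway_importance(
    scores: ScoreTable,
    sets: GeneSetCollection,
    mode: str = "mean",
) -> PathwayImportance:
    """Importance of each pathway from the Score_t of its member targets.

    Default ``mean`` mode computes (1/m) * Σ Score_t over the m member
    targets present in the score table; ``sum`` mode drops the 1/m factor.
    Pathways with no scored target are excluded; raises if none remains.
    """
    if mode not in ("mean", "sum"):
        raise ValueError(f"unknown mode {mode!r}")
    scored = scores.table["score_t"]
    rows = []
    for term_id in sorted(sets.sets):
        name, members = sets.sets[term_id]
        present = [t for t in members if t in scored.index]
        if not present:
            continue
        total = float(scored.loc[present].sum())
        m = len(present)
        rows.append(
            {
                "term_id": term_id,
                "term_name": name,
                "m": m,
                "importance": total / m if mode == "mean" else total,
            }
        )
    if not rows:
        raise ValueError("pathway_importance: no pathway contains a scored target")
    df = pd.DataFrame(rows).sort_values(
        ["importance", "term_id"], ascending=[False, True], kind="mergesort"
    )
    df["rank"] = range(1, len(df) + 1)
    return PathwayImportance(table=df.reset_index(drop=True))
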