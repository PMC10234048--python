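"""The multiobjective target score and its centrality baselines.

Each target t receives four raw scores:

* expression — |log2 FC| of t itself when t is pathogenic, otherwise the
  mean |log2 FC| of the pathogenic genes interacting with t;
* correlation — 1 when t is pathogenic, otherwise the mean |Pearson r|
  between t and its interacting pathogenic genes;
* degree — the product of min-max-scaled degrees of t in the
  compound-target view (N_CT) and the gene-gene view (N_TP);
* pathway — the fraction of the targets' pathway universe that contains t.

The four are min-max normalized to [0, 1] and summed into Score_t in
[0, 4]; the top fraction of targets (default 50%) by Score_t is kept.
Degree, closeness and betweenness centrality on the full C-T-P graph act
as single-objective baselines through the same normalize/select path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import igraph as ig
import numpy as np
import pandas as pd

from .ctp_network import CTPNetwork, degree_stats, pathogenic_adjacency
from .expression_stats import CorrelationProvider, DETable
from .io_formats import GeneSetCollection

logger = logging.getLogger("mooscreen")

COMPONENTS = ("exp", "cor", "deg", "path")
CENTRALITY_METHODS = ("degree", "closeness", "betweenness")


@dataclass
class ScoreTable:
    """Per-target raw and normalized scores, their sum, rank and selection flag.

    ``table`` is indexed by target symbol. Raw components sit in
    ``score_<name>`` columns, normalized ones in ``score_<name>_norm``;
    ``score_t`` is the sum of the normalized columns, ``deg_ct`` the N_CT
    degree used for tie-breaking. ``degenerate`` lists components whose
    raw values were constant (mapped to 1 for every target).
    """

    table: pd.DataFrame
    components: tuple[str, ...]
    degenerate: tuple[str, ...] = ()

    @property
    def targets(self) -> list[str]:
        return list(self.table.index)

    def selected_targets(self) -> frozenset[str]:
        return frozenset(self.table.index[self.table["selected"]])


# ---------------------------------------------------------------------------
# Raw component scores
# ---------------------------------------------------------------------------

def score_expression(net: CTPNetwork, de: DETable) -> dict[str, float]:
    """Differential-expression score per target.

    Pathogenic targets score their own |logFC|; others average the |logFC|
    of their interacting pathogenic genes (missing logFC contributes 0 and
    is counted); targets with no pathogenic interactor score 0.
    """
    out: dict[str, float] = {}
    n_missing = 0
    adjacency = pathogenic_adjacency(net)
    for t in sorted(net.targets):
        if t in net.pathogenic:
            lfc = de.logfc(t)
            if lfc is None:
                n_missing += 1
                lfc = 0.0
            out[t] = abs(lfc)
        else:
            neigh = adjacency[t]
            if not neigh:
                out[t] = 0.0
                continue
            total = 0.0
            for p in neigh:
                lfc = de.logfc(p)
                if lfc is None:
                    n_missing += 1
                    continue  # contributes 0 to the sum
                total += abs(lfc)
            out[t] = total / len(neigh)
    if n_missing:
        logger.info("score_expression: %d missing logFC value(s) treated as 0", n_missing)
    return out


def score_correlation(net: CTPNetwork, cor: CorrelationProvider) -> dict[str, float]:
    """Pathogenic-gene correlation score per target.

    Pathogenic targets score 1. Others average |r| over interacting
    pathogenic genes; pairs with undefined correlation are excluded from
    numerator and denominator, and a target with no defined pair scores 0.
    """
    out: dict[str, float] = {}
    n_missing_pairs = 0
    adjacency = pathogenic_adjacency(net)
    for t in sorted(net.targets):
        if t in net.pathogenic:
            out[t] = 1.0
            continue
        rs = []
        for p in adjacency[t]:
            r = cor.get(t, p)
            if r is None:
                n_missing_pairs += 1
                continue
            rs.append(abs(r))
        out[t] = float(np.mean(rs)) if rs else 0.0
    if n_missing_pairs:
        logger.info("score_correlation: %d pair(s) with undefined correlation excluded", n_missing_pairs)
    return out


def score_degree(net: CTPNetwork) -> dict[str, float]:
    """Dual-view degree score: product of min-max-scaled N_CT and N_TP degrees.

    A view whose member targets all share one degree contributes factor 1
    for every member (a constant factor must not veto the product); a
    target absent from N_TP contributes second factor 0.
    """
    ct = degree_stats(net, "N_CT")
    tp = degree_stats(net, "N_TP")

    def factor(stats, t: str) -> float:
        if not stats.member[t]:
            return 0.0
        if stats.span == 0:
            return 1.0
        return (stats.degree[t] - stats.min_degree) / stats.span

    return {t: factor(ct, t) * factor(tp, t) for t in sorted(net.targets)}


def score_pathway(targets: frozenset[str] | set[str], sets: GeneSetCollection) -> dict[str, float]:
    """Pathway participation score per target.

    With P_T(t) the pathways containing t and P_T(T) their union over all
    targets, the score is |P_T(t) ∩ P_T(T)| / |P_T(t) ∪ P_T(T)|; because
    P_T(t) ⊆ P_T(T) this is the fraction of the joint pathway universe
    containing t. Targets in no pathway score 0.
    """
    per_target: dict[str, set[str]] = {t: set() for t in targets}
    for term, (_, members) in sets.sets.items():
        for t in members & set(targets):
            per_target[t].add(term)
    union: set[str] = set()
    for s in per_target.values():
        union |= s
    if not union:
        logger.warning("score_pathway: no target occurs in any gene set")
        return {t: 0.0 for t in sorted(targets)}
    return {
        t: len(per_target[t] & union) / len(per_target[t] | union) if per_target[t] else 0.0
        for t in sorted(targets)
    }


# ---------------------------------------------------------------------------
# Normalization and the combined score
# ---------------------------------------------------------------------------

def normalize(raw: dict[str, float]) -> tuple[dict[str, float], bool]:
    """Min-max scale raw scores to [0, 1]; a constant component maps to all 1.

    Returns (normalized, degenerate_flag).
    """
    if not raw:
        raise ValueError("normalize: empty score vector")
    vals = np.array(list(raw.values()), dtype=float)
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        return {t: 1.0 for t in raw}, True
    return {t: (v - lo) / (hi - lo) for t, v in raw.items()}, False


def _assemble(
    net: CTPNetwork,
    raw_components: dict[str, dict[str, float]],
) -> ScoreTable:
    targets = sorted(net.targets)
    ct_stats = degree_stats(net, "N_CT")
    data: dict[str, list[float]] = {}
    degenerate: list[str] = []
    total = np.zeros(len(targets))
    for name, raw in raw_components.items():
        norm, degen = normalize(raw)
        if degen:
            degenerate.append(name)
        data[f"score_{name}"] = [raw[t] for t in targets]
        col = np.array([norm[t] for t in targets])
        data[f"score_{name}_norm"] = list(col)
        total = total + col
    df = pd.DataFrame(data, index=pd.Index(targets, name="target"))
    df["score_t"] = total
    df["deg_ct"] = [ct_stats.degree[t] for t in targets]
    order = sorted(targets, key=lambda t: (-df.at[t, "score_t"], -df.at[t, "deg_ct"], t))
    df["rank"] = pd.Series({t: i + 1 for i, t in enumerate(order)})
    df["selected"] = False
    return ScoreTable(
        table=df.loc[order],
        components=tuple(raw_components),
        degenerate=tuple(degenerate),
    )


def moo_score(
    net: CTPNetwork,
    de: DETable,
    cor: CorrelationProvider,
    sets: GeneSetCollection,
) -> ScoreTable:
    """Full multiobjective score table: four raw components, normalized, summed."""
    raw = {
        "exp": score_expression(net, de),
        "cor": score_correlation(net, cor),
        "deg": score_degree(net),
        "path": score_pathway(net.targets, sets),
    }
    return _assemble(net, raw)


def select_targets(scores: ScoreTable, fraction: float = 0.5) -> frozenset[str]:
    """Keep the top ``ceil(fraction * |T|)`` targets by Score_t.

    Ties at the cut are broken by (score_t, N_CT degree, lexicographic id),
    all already encoded in the table's rank — the selection is
    deterministic and independent of input row order. Marks ``selected``
    in place and returns the kept set.
    """
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    n = len(scores.table)
    k = int(np.ceil(fraction * n))
    kept = frozenset(scores.table.sort_values("rank").index[:k])
    scores.table["selected"] = scores.table.index.isin(kept)
    return kept


# ---------------------------------------------------------------------------
# Centrality baselines
# ---------------------------------------------------------------------------

def _igraph_of(net: CTPNetwork) -> tuple[ig.Graph, dict[str, int]]:
    nodes = sorted(net.compounds) + sorted(net.genes)
    index = {n: i for i, n in enumerate(nodes)}
    edges = [(index[a], index[b]) for a, b in net.ct_edges | net.gg_edges]
    g = ig.Graph(n=len(nodes), edges=edges, directed=False)
    return g, index


def _closeness_wf(g: ig.Graph, node_ids: list[int]) -> list[float]:
    """Closeness with the reachable-set (Wasserman-Faust) normalization.

    For node u with r reachable nodes (excluding u) at total distance d:
    closeness = (r / (n - 1)) * (r / d); isolated nodes score 0. On a
    connected graph this is ordinary normalized closeness.
    """
    n = g.vcount()
    dist = np.array(g.distances(source=node_ids), dtype=float)
    out = []
    for row in dist:
        finite = row[np.isfinite(row)]
        r = len(finite) - 1  # exclude self (distance 0)
        d = float(finite.sum())
        out.append((r / (n - 1)) * (r / d) if r > 0 and d > 0 else 0.0)
    return out


def centrality_score(net: CTPNetwork, method: str) -> ScoreTable:
    """Single-objective baseline: a centrality on the full undirected C-T-P graph.

    The centrality is computed over all nodes (compounds included) but the
    returned table ranks targets only, through the same normalization and
    selection machinery as the multiobjective score.
    """
    if method not in CENTRALITY_METHODS:
        raise ValueError(f"unknown centrality {method!r}; choose from {CENTRALITY_METHODS}")
    g, index = _igraph_of(net)
    targets = sorted(net.targets)
    ids = [index[t] for t in targets]
    if method == "degree":
        vals = [float(d) for d in g.degree(ids)]
    elif method == "betweenness":
        vals = [float(b) for b in g.betweenness(vertices=ids, directed=False)]
    else:
        vals = _closeness_wf(g, ids)
    raw = dict(zip(targets, vals))
    return _assemble(net, {method: raw})
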