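"""Assembly, views and pruning of the compound-target-pathogenic-gene (C-T-P) network.

The network is tripartite: compounds connect to their predicted protein
targets (bipartite view ``N_CT``), and targets/pathogenic genes connect
through protein-protein interactions (gene-gene view ``N_TP``). Genes that
are both targets and pathogenic are the essential common proteins (ECPs).
Graphs are simple and undirected; multi-edges are collapsed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .io_formats import EdgeList, make_edge_list

logger = logging.getLogger("mooscreen")


class ConstructionError(ValueError):
    """The network cannot be built from the given inputs."""


@dataclass(frozen=True)
class CTPNetwork:
    """A C-T-P network: node sets plus the two edge sets.

    ``ct_edges`` are (compound_id, target) pairs; ``gg_edges`` are
    undirected gene pairs stored in lexicographic canonical order with both
    endpoints in ``targets | pathogenic``. Every compound has at least one
    target.
    """

    compounds: frozenset[str]
    targets: frozenset[str]
    pathogenic: frozenset[str]
    ct_edges: frozenset[tuple[str, str]]
    gg_edges: frozenset[tuple[str, str]]

    @property
    def ecps(self) -> frozenset[str]:
        """Essential common proteins: targets that are also pathogenic genes."""
        return self.targets & self.pathogenic

    @property
    def genes(self) -> frozenset[str]:
        return self.targets | self.pathogenic

    def n_ct(self) -> nx.Graph:
        """Bipartite compound-target view."""
        g = nx.Graph()
        g.add_nodes_from(self.compounds, kind="compound")
        g.add_nodes_from(self.targets, kind="target")
        g.add_edges_from(self.ct_edges)
        return g

    def n_tp(self) -> nx.Graph:
        """Gene-gene view restricted to targets/pathogenic genes that carry >= 1 edge."""
        g = nx.Graph()
        g.add_edges_from(self.gg_edges)
        return g

    def full_graph(self) -> nx.Graph:
        """The whole undirected C-T-P graph (compound, target and pathogenic nodes)."""
        g = nx.Graph()
        g.add_nodes_from(self.compounds, kind="compound")
        g.add_nodes_from(self.genes)
        g.add_edges_from(self.ct_edges)
        g.add_edges_from(self.gg_edges)
        return g

    def targets_of(self, compound_id: str) -> frozenset[str]:
        """T_c: the predicted targets of one compound."""
        return frozenset(t for c, t in self.ct_edges if c == compound_id)

    def pathogenic_neighbors(self, target: str) -> frozenset[str]:
        """P_t: pathogenic genes interacting with a target in the gene-gene view."""
        return pathogenic_adjacency(self).get(target, frozenset())


def pathogenic_adjacency(net: "CTPNetwork") -> dict[str, frozenset[str]]:
    """target -> interacting pathogenic genes (P_t), for every target, in one pass."""
    adj: dict[str, set[str]] = {t: set() for t in net.targets}
    for a, b in net.gg_edges:
        if a in adj and b in net.pathogenic:
            adj[a].add(b)
        if b in adj and a in net.pathogenic:
            adj[b].add(a)
    return {t: frozenset(s) for t, s in adj.items()}


def build_ctp(ct: EdgeList, gg: EdgeList, pathogenic: list[str]) -> CTPNetwork:
    """Construct the C-T-P network from raw edge lists and a pathogenic-gene list.

    The target set is every gene appearing on the target side of ``ct``.
    Gene-gene edges are retained only when both endpoints are targets or
    listed pathogenic genes. A listed pathogenic gene becomes part of the
    network only with interaction evidence (>= 1 retained edge) or by also
    being a target; the rest are dropped (and counted).
    """
    if ct.kind != "compound-target" or gg.kind != "gene-gene":
        raise ValueError("edge list kinds must be compound-target and gene-gene")
    if not ct.edges:
        raise ConstructionError("compound-target edge list is empty")
    compounds = frozenset(c for c, _ in ct.edges)
    targets = frozenset(t.upper() for _, t in ct.edges)
    listed = frozenset(p.upper() for p in pathogenic)
    if not listed:
        raise ConstructionError("pathogenic gene list is empty")

    candidates = targets | listed
    kept_gg = frozenset(e for e in gg.edges if e[0] in candidates and e[1] in candidates)
    dropped = len(gg.edges) - len(kept_gg)
    if dropped:
        logger.info("build_ctp: dropped %d gene-gene edge(s) outside T ∪ P", dropped)

    with_edges = {g for e in kept_gg for g in e}
    path_final = frozenset(p for p in listed if p in with_edges or p in targets)
    n_excluded = len(listed) - len(path_final)
    if n_excluded:
        logger.info("build_ctp: %d listed pathogenic gene(s) without interaction evidence excluded", n_excluded)

    ct_norm = frozenset((c, t.upper()) for c, t in ct.edges)
    return CTPNetwork(
        compounds=compounds,
        targets=targets,
        pathogenic=path_final,
        ct_edges=ct_norm,
        gg_edges=kept_gg,
    )


def essential_common_proteins(net: CTPNetwork) -> frozenset[str]:
    """ECPs: the intersection of the target set and the pathogenic-gene set."""
    return net.ecps


@dataclass(frozen=True)
class DegreeStats:
    """Per-node degree in a named view, with the min/max/span over member targets.

    ``member`` flags whether each requested node actually occurs in the
    view; non-members report degree 0 and are excluded from min/max/span.
    ``degenerate`` is set when the view holds < 2 member targets (span 0).
    """

    view: str
    degree: dict[str, int]
    member: dict[str, bool]
    min_degree: int
    max_degree: int
    degenerate: bool = False

    @property
    def span(self) -> int:
        return self.max_degree - self.min_degree


def degree_stats(net: CTPNetwork, view: str, nodes: set[str] | frozenset[str] | None = None) -> DegreeStats:
    """Degrees of target nodes in ``N_CT`` or ``N_TP``.

    A target absent from the requested view (possible in ``N_TP``) gets
    degree 0 with ``member`` False.
    """
    if view == "N_CT":
        g = net.n_ct()
    elif view == "N_TP":
        g = net.n_tp()
    else:
        raise ValueError(f"unknown view {view!r}")
    nodes = frozenset(nodes) if nodes is not None else net.targets
    degree = {n: (g.degree(n) if n in g else 0) for n in nodes}
    member = {n: n in g for n in nodes}
    present = [degree[n] for n in nodes if member[n]]
    if not present:
        return DegreeStats(view=view, degree=degree, member=member, min_degree=0, max_degree=0, degenerate=True)
    lo, hi = min(present), max(present)
    return DegreeStats(
        view=view, degree=degree, member=member,
        min_degree=lo, max_degree=hi, degenerate=(hi == lo),
    )


class ReconstructionError(ValueError):
    """Pruning produced an invalid network."""


def reconstruct(net: CTPNetwork, kept_targets: set[str] | frozenset[str]) -> CTPNetwork:
    """Rebuild the network around a kept target subset (the optimization prune).

    Compound-target edges are restricted to kept targets and compounds left
    without targets are dropped. An ECP that was pruned from the target set
    leaves the network entirely — its pathogenic identity does not retain
    it — whereas an ECP kept as a target always remains a network gene.
    Other pathogenic genes persist only while they still carry >= 1
    gene-gene edge.
    """
    kept = frozenset(kept_targets)
    if not kept:
        raise ReconstructionError("kept_targets is empty")
    if not kept <= net.targets:
        raise ReconstructionError(f"kept targets outside T: {sorted(kept - net.targets)[:5]}")
    ct = frozenset((c, t) for c, t in net.ct_edges if t in kept)
    compounds = frozenset(c for c, _ in ct)
    dropped_ecps = net.ecps - kept
    eligible = kept | (net.pathogenic - dropped_ecps)
    gg = frozenset(e for e in net.gg_edges if e[0] in eligible and e[1] in eligible)
    with_edges = {g for e in gg for g in e}
    pathogenic = frozenset(
        p for p in net.pathogenic - dropped_ecps if p in with_edges or p in kept
    )
    return CTPNetwork(
        compounds=compounds,
        targets=kept,
        pathogenic=pathogenic,
        ct_edges=ct,
        gg_edges=gg,
    )


# ---------------------------------------------------------------------------
# Serialization (Gephi-importable layout: two edge tables + node attributes)
# ---------------------------------------------------------------------------

def network_tables(net: CTPNetwork) -> dict[str, pd.DataFrame]:
    """The network as three tidy frames: ct_edges, gg_edges, nodes (with roles)."""
    ct = pd.DataFrame(sorted(net.ct_edges), columns=["compound_id", "target"])
    gg = pd.DataFrame(sorted(net.gg_edges), columns=["gene_a", "gene_b"])
    rows = []
    for c in sorted(net.compounds):
        rows.append({"node": c, "role": "compound"})
    for g in sorted(net.genes):
        if g in net.ecps:
            role = "ECP"
        elif g in net.targets:
            role = "target"
        else:
            role = "pathogenic"
        rows.append({"node": g, "role": role})
    nodes = pd.DataFrame(rows, columns=["node", "role"])
    return {"ct_edges": ct, "gg_edges": gg, "nodes": nodes}


def write_network(net: CTPNetwork, out_dir: str | Path, prefix: str = "network") -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, frame in network_tables(net).items():
        p = out_dir / f"{prefix}_{name}.tsv"
        frame.to_csv(p, sep="\t", index=False)
        paths.append(p)
    return paths


def read_network(out_dir: str | Path, prefix: str = "network") -> CTPNetwork:
    out_dir = Path(out_dir)
    ct = pd.read_csv(out_dir / f"{prefix}_ct_edges.tsv", sep="\t", dtype=str)
    gg = pd.read_csv(out_dir / f"{prefix}_gg_edges.tsv", sep="\t", dtype=str)
    nodes = pd.read_csv(out_dir / f"{prefix}_nodes.tsv", sep="\t", dtype=str)
    compounds = frozenset(nodes.loc[nodes.role == "compound", "node"])
    targets = frozenset(nodes.loc[nodes.role.isin(["target", "ECP"]), "node"])
    pathogenic = frozenset(nodes.loc[nodes.role.isin(["pathogenic", "ECP"]), "node"])
    gg_edges, _ = make_edge_list(list(gg.itertuples(index=False, name=None)), "gene-gene")
    return CTPNetwork(
        compounds=compounds,
        targets=targets,
        pathogenic=pathogenic,
        ct_edges=frozenset(ct.itertuples(index=False, name=None)),
        gg_edges=frozenset(gg_edges.edges),
    )
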