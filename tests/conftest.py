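"""Shared fixtures: tiny hand-built networks and score scenarios."""

import pandas as pd
import pytest

from mooscreen.ctp_network import build_ctp
from mooscreen.expression_stats import CorrelationProvider, DETable
from mooscreen.io_formats import EdgeList, GeneSetCollection, make_edge_list


def edge_list(pairs, kind):
    return make_edge_list(pairs, kind)[0]


@pytest.fixture
def toy_net():
    """The three-compound / two-target construction example.

    ct: c1-t1, c1-t2, c2-t2; gg: t1-p1, t2-p1, p1-p2, x-y; pathogenic
    {p1, p2, p3}. Expected: T={T1,T2}, P={P1,P2} (p3 edgeless), 3 gene-gene
    edges retained.
    """
    ct = edge_list([("c1", "t1"), ("c1", "t2"), ("c2", "t2")], "compound-target")
    gg = edge_list([("t1", "p1"), ("t2", "p1"), ("p1", "p2"), ("x", "y")], "gene-gene")
    return build_ctp(ct, gg, ["p1", "p2", "p3"])


def de_from_dict(logfc: dict) -> DETable:
    df = pd.DataFrame(
        {"logFC": logfc, "p": 0.01, "fdr": 0.01, "significant": True}
    )
    df.index.name = "gene"
    return DETable(table=df)


def cor_from_dict(values: dict) -> CorrelationProvider:
    canon = {CorrelationProvider._key(a, b): r for (a, b), r in values.items()}
    return CorrelationProvider(values=canon, missing=frozenset(), n_samples=10)


@pytest.fixture
def scored_net():
    """Five-target scenario with every component score computable by hand.

    N_CT degrees: T1:3 T2:2 T3:1 T4:1 T5:1 (min 1, span 2).
    N_TP degrees over member targets: T1:2 T2:3 T3:1 T5:1; T4 absent.
    T1 is an ECP (pathogenic target).
    """
    ct = edge_list(
        [("c1", "T1"), ("c1", "T2"), ("c1", "T3"), ("c1", "T4"), ("c1", "T5"),
         ("c2", "T1"), ("c2", "T2"), ("c3", "T1")],
        "compound-target",
    )
    gg = edge_list(
        [("T1", "P1"), ("T1", "P2"), ("T2", "P1"), ("T2", "P2"), ("T2", "P3"),
         ("T3", "P2"), ("P3", "P4"), ("T5", "P4")],
        "gene-gene",
    )
    net = build_ctp(ct, gg, ["T1", "P1", "P2", "P3", "P4"])
    de = de_from_dict({"T1": -1.5, "P1": 1.0, "P2": -2.0, "P3": 0.5, "P4": 2.0, "T5": 0.3})
    cor = cor_from_dict({("T2", "P1"): 0.8, ("T2", "P2"): -0.4, ("T3", "P2"): 0.5})
    sets = GeneSetCollection(
        sets={
            f"S{i:02d}": (f"set {i}", frozenset(members))
            for i, members in enumerate(
                [
                    {"T1", "T2", "P1"},     # S00
                    {"T1", "T2", "P2"},     # S01
                    {"T1", "T3", "P3"},     # S02
                    {"T1", "T5", "P4"},     # S03
                    {"T1", "P1", "P2"},     # S04
                    {"T1", "P2", "P3"},     # S05
                    {"T1", "P3", "P4"},     # S06
                    {"T1", "P1", "P4"},     # S07
                    {"T1", "P1", "P3"},     # S08
                    {"T1", "P2", "P4"},     # S09
                ]
            )
        },
        namespace="KEGG",
    )
    return net, de, cor, sets
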