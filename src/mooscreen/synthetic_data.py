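"""Seeded synthetic inputs with the statistical structure the method assumes.

The generator emits every input the pipeline reads — compound property
table, compound-target and gene-gene edge lists, pathogenic-gene list,
log2 expression matrix with a two-group design, and KEGG/GOBP-style gene
set collections — together with the ground truth it planted:

* a designated ECP subset of the targets (targets that are also
  pathogenic) carrying large planted |log2 FC|;
* shared latent structure tying each target to a designated pathogenic
  interactor at a configurable Pearson correlation;
* a handful of planted "key" compounds preferentially wired to ECPs;
* gene sets enriched around the ECP neighborhood.

All randomness flows through one seeded NumPy generator; identical config
and seed reproduce byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    CompoundRecord,
    CompoundTable,
    EdgeList,
    ExpressionMatrix,
    GeneSetCollection,
    make_edge_list,
    write_compound_table,
    write_edge_list,
    write_expression_matrix,
    write_gene_list,
    write_gmt,
)

HERBS = ("HERB_A", "HERB_B", "HERB_C", "HERB_D", "HERB_E", "HERB_F")

# Sub-threshold sampling ranges for passing compounds, and violation ranges.
_PASS_RANGES = {
    "MW": (150.0, 500.0),
    "nHD": (0, 5),
    "nHA": (0, 10),
    "logP": (-2.0, 5.0),
    "nRot": (0, 10),
    "F20": (0.0, 0.7),
    "BBB": (0.0, 0.7),
    "hERG": (0.0, 0.7),
    "HHT": (0.0, 0.7),
    "TPSA": (20.0, 140.0),
}
_FAIL_RANGES = {
    "MW": (501.0, 900.0),
    "nHD": (6, 12),
    "nHA": (11, 20),
    "logP": (5.1, 9.0),
    "nRot": (11, 25),
    "F20": (0.71, 1.0),
    "BBB": (0.71, 1.0),
    "hERG": (0.71, 1.0),
    "HHT": (0.71, 1.0),
    "TPSA": (141.0, 250.0),
}
_INT_PROPS = {"nHD", "nHA", "nRot"}


class ConfigError(ValueError):
    """The generator configuration is internally inconsistent."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic study, with defaults forming a scaled-down cohort.

    Scale: 30 compounds x 120 targets x 160 pathogenic genes (a quarter of
    the targets doubling as pathogenic, i.e. ECPs). Signal: ECPs carry
    |log2 FC| around ``ecp_logfc_mean`` over unit within-group noise,
    other pathogenic genes around ``pathogenic_logfc_mean``, background
    genes N(0, ``background_logfc_sd``); each target is tied to one
    pathogenic interactor at Pearson ``ecp_cor_strength``. Compound-target
    degrees follow a truncated power law (``ct_exponent``, minimum
    ``ct_min_degree``, cap ``ct_max_degree_frac`` x n_targets).
    """

    n_compounds: int = 30
    n_targets: int = 120
    n_pathogenic: int = 160
    ecp_fraction: float = 0.25
    ct_exponent: float = 2.0
    ct_min_degree: int = 3
    ct_max_degree_frac: float = 0.15
    gg_density: float = 0.02
    n_samples_per_group: int = 20
    ecp_logfc_mean: float = 2.0
    pathogenic_logfc_mean: float = 1.0
    background_logfc_sd: float = 0.4
    noise_sd: float = 1.0
    ecp_cor_strength: float = 0.6
    n_pathways: int = 60
    pathway_size_range: tuple[int, int] = (10, 40)
    n_gobp_sets: int = 80
    n_background_genes: int = 100
    planted_key_compounds: int = 3
    admet_pass_rate: float = 0.6
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_compounds, self.n_targets, self.n_pathogenic, self.n_samples_per_group) <= 0:
            raise ConfigError("counts must be positive")
        if not (0 < self.ecp_fraction < 1):
            raise ConfigError("ecp_fraction must be in (0, 1)")
        if self.n_ecp > self.n_pathogenic:
            raise ConfigError("ecp_fraction * n_targets exceeds n_pathogenic")
        lo, hi = self.pathway_size_range
        if lo < 10 or hi < lo:
            raise ConfigError("pathway sizes must be >= 10 and ordered")
        if hi > self.n_targets + (self.n_pathogenic - self.n_ecp) + self.n_background_genes:
            raise ConfigError("pathway size exceeds gene count")
        if not (0.0 <= self.ecp_cor_strength <= 1.0):
            raise ConfigError("ecp_cor_strength must be in [0, 1]")
        if not (0.0 < self.admet_pass_rate <= 1.0):
            raise ConfigError("admet_pass_rate must be in (0, 1]")
        if self.planted_key_compounds > self.n_compounds:
            raise ConfigError("more planted key compounds than compounds")
        if self.ct_min_degree < 1 or self.ct_min_degree > self.n_targets:
            raise ConfigError("ct_min_degree outside 1..n_targets")

    @property
    def n_ecp(self) -> int:
        return int(round(self.ecp_fraction * self.n_targets))


@dataclass
class GroundTruth:
    """What the generator planted, for recovery tests and audits."""

    ecps: frozenset[str]
    key_compounds: frozenset[str]
    logfc: dict[str, float]
    planted_pairs: list[tuple[str, str, float]]  # (target, pathogenic partner, target r)
    seed: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "ecps": sorted(self.ecps),
                "key_compounds": sorted(self.key_compounds),
                "logfc": {g: self.logfc[g] for g in sorted(self.logfc)},
                "planted_pairs": [list(p) for p in sorted(self.planted_pairs)],
                "seed": self.seed,
            },
            indent=2,
        )


@dataclass
class SyntheticDataset:
    """The full bundle of generated inputs plus ground truth."""

    compounds: CompoundTable
    ct: EdgeList
    gg: EdgeList
    pathogenic: list[str]
    expression: ExpressionMatrix
    kegg_sets: GeneSetCollection
    gobp_sets: GeneSetCollection
    truth: GroundTruth
    config: GeneratorConfig


def _sample_properties(rng: np.random.Generator, passes: bool) -> dict[str, float]:
    props: dict[str, float] = {}
    for p, (lo, hi) in _PASS_RANGES.items():
        if p in _INT_PROPS:
            props[p] = float(rng.integers(lo, hi + 1))
        else:
            props[p] = float(np.round(rng.uniform(lo, hi), 3))
    if not passes:
        n_viol = int(rng.integers(1, 4))
        for p in rng.choice(list(_FAIL_RANGES), size=n_viol, replace=False):
            lo, hi = _FAIL_RANGES[p]
            if p in _INT_PROPS:
                props[p] = float(rng.integers(lo, hi + 1))
            else:
                props[p] = float(np.round(rng.uniform(lo, hi), 3))
    return props


def _ct_degree(rng: np.random.Generator, cfg: GeneratorConfig) -> int:
    cap = max(cfg.ct_min_degree, int(round(cfg.ct_max_degree_frac * cfg.n_targets)))
    # discrete truncated power law: P(d) ∝ d^(-exponent) on [min_degree, cap]
    d = cfg.ct_min_degree * (1.0 - rng.random()) ** (-1.0 / (cfg.ct_exponent - 1.0))
    return int(min(cap, max(cfg.ct_min_degree, np.floor(d))))


def generate(config: GeneratorConfig) -> SyntheticDataset:
    """Generate one synthetic study from a validated config (deterministic in seed)."""
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    width = max(4, len(str(cfg.n_targets)))
    targets = [f"TG{i:0{width}d}" for i in range(1, cfg.n_targets + 1)]
    ecp_idx = np.sort(rng.choice(cfg.n_targets, size=cfg.n_ecp, replace=False))
    ecps = frozenset(targets[i] for i in ecp_idx)
    n_path_only = cfg.n_pathogenic - cfg.n_ecp
    path_only = [f"PG{i:0{width}d}" for i in range(1, n_path_only + 1)]
    background = [f"BG{i:0{width}d}" for i in range(1, cfg.n_background_genes + 1)]
    pathogenic = sorted(ecps) + path_only
    genes = targets + path_only + background
    network_genes = targets + path_only

    # --- compounds: properties straddle the screen at the configured pass rate
    key_ids = [f"C{i:04d}" for i in range(1, cfg.planted_key_compounds + 1)]
    records = []
    passing: list[str] = []
    for i in range(1, cfg.n_compounds + 1):
        cid = f"C{i:04d}"
        passes = cid in key_ids or bool(rng.random() < cfg.admet_pass_rate)
        herbs = frozenset(rng.choice(HERBS, size=int(rng.integers(1, 3)), replace=False))
        records.append(
            CompoundRecord(
                compound_id=cid,
                name=f"compound-{i}",
                herbs=herbs,
                smiles="C" * int(rng.integers(3, 12)),  # placeholder chemistry
                properties=_sample_properties(rng, passes),
            )
        )
        if passes:
            passing.append(cid)
    compounds = CompoundTable(records)

    # --- compound-target edges (targets are predicted for screened compounds)
    ecp_list = sorted(ecps)
    ct_pairs: list[tuple[str, str]] = []
    cap = max(cfg.ct_min_degree, int(round(cfg.ct_max_degree_frac * cfg.n_targets)))
    for cid in passing:
        if cid in key_ids:
            # key compounds are wired preferentially to ECPs
            n_ecp_hits = min(len(ecp_list), max(1, int(round(0.6 * cap))))
            hits = list(rng.choice(ecp_list, size=n_ecp_hits, replace=False))
            n_rest = cap - n_ecp_hits
            if n_rest > 0:
                rest_pool = [t for t in targets if t not in set(hits)]
                hits += list(rng.choice(rest_pool, size=n_rest, replace=False))
        else:
            d = _ct_degree(rng, cfg)
            hits = list(rng.choice(targets, size=d, replace=False))
        ct_pairs.extend((cid, t) for t in hits)
    ct, _ = make_edge_list(ct_pairs, "compound-target")

    # --- gene-gene interactions: Erdos-Renyi over targets ∪ pathogenic genes
    n_net = len(network_genes)
    iu, ju = np.triu_indices(n_net, k=1)
    mask = rng.random(iu.shape[0]) < cfg.gg_density
    gg_pairs = [(network_genes[a], network_genes[b]) for a, b in zip(iu[mask], ju[mask])]
    gg, _ = make_edge_list(gg_pairs, "gene-gene")

    # --- planted differential expression
    logfc: dict[str, float] = {}
    for g in genes:
        if g in ecps:
            mag = abs(rng.normal(cfg.ecp_logfc_mean, 0.3))
        elif g in set(path_only):
            mag = abs(rng.normal(cfg.pathogenic_logfc_mean, 0.3))
        else:
            logfc[g] = float(rng.normal(0.0, cfg.background_logfc_sd))
            continue
        logfc[g] = float(mag if rng.random() < 0.5 else -mag)

    # --- expression with shared latent structure between targets and their
    #     designated pathogenic interactor
    n_per = cfg.n_samples_per_group
    samples = [f"CASE{i:03d}" for i in range(1, n_per + 1)] + [
        f"CTRL{i:03d}" for i in range(1, n_per + 1)
    ]
    groups = {s: ("case" if s.startswith("CASE") else "control") for s in samples}
    gvec = np.array([0.5 if groups[s] == "case" else -0.5 for s in samples])

    path_only_set = set(path_only)
    neighbors: dict[str, list[str]] = {t: [] for t in targets}
    for a, b in gg.edges:
        if a in neighbors and b in path_only_set:
            neighbors[a].append(b)
        if b in neighbors and a in path_only_set:
            neighbors[b].append(a)

    values = np.empty((len(genes), len(samples)))
    gene_row = {g: i for i, g in enumerate(genes)}
    baseline = rng.normal(7.0, 1.0, size=len(genes))
    # non-target genes first: independent noise + planted shift
    for g in path_only + background:
        i = gene_row[g]
        values[i] = baseline[i] + cfg.noise_sd * rng.standard_normal(len(samples)) + logfc[g] * gvec

    rho = cfg.ecp_cor_strength
    planted_pairs: list[tuple[str, str, float]] = []
    for t in targets:
        i = gene_row[t]
        partner = None
        if neighbors[t]:
            partner = sorted(neighbors[t])[int(rng.integers(0, len(neighbors[t])))]
        if partner is not None and rho > 0:
            src = values[gene_row[partner]]
            z = (src - src.mean()) / src.std()
            core = rho * z + np.sqrt(1.0 - rho**2) * rng.standard_normal(len(samples))
            if t not in ecps:
                planted_pairs.append((t, partner, rho))
        else:
            core = rng.standard_normal(len(samples))
        values[i] = baseline[i] + cfg.noise_sd * core + logfc[t] * gvec
    expression = ExpressionMatrix(
        values=pd.DataFrame(np.round(values, 6), index=genes, columns=samples),
        groups=groups,
    )

    # --- gene sets: half "disease" sets enriched around ECPs and pathogenic
    #     genes, half background sets sampled uniformly
    def _collection(n_sets: int, prefix: str, namespace: str) -> GeneSetCollection:
        sets: dict[str, tuple[str, frozenset[str]]] = {}
        lo, hi = cfg.pathway_size_range
        disease_pool = sorted(ecps) + path_only
        for j in range(1, n_sets + 1):
            size = int(rng.integers(lo, hi + 1))
            if rng.random() < 0.5 and disease_pool:
                n_dis = min(len(disease_pool), max(1, size // 2))
                members = set(rng.choice(disease_pool, size=n_dis, replace=False))
                pool = [g for g in genes if g not in members]
                members |= set(rng.choice(pool, size=size - n_dis, replace=False))
            else:
                members = set(rng.choice(genes, size=size, replace=False))
            term = f"{prefix}{j:05d}"
            sets[term] = (f"{namespace.lower()} set {j}", frozenset(members))
        return GeneSetCollection(sets=sets, namespace=namespace)

    kegg_sets = _collection(cfg.n_pathways, "KEGG", "KEGG")
    gobp_sets = _collection(cfg.n_gobp_sets, "GOBP", "GOBP")

    truth = GroundTruth(
        ecps=ecps,
        key_compounds=frozenset(key_ids),
        logfc=logfc,
        planted_pairs=planted_pairs,
        seed=cfg.seed,
    )
    return SyntheticDataset(
        compounds=compounds,
        ct=ct,
        gg=gg,
        pathogenic=pathogenic,
        expression=expression,
        kegg_sets=kegg_sets,
        gobp_sets=gobp_sets,
        truth=truth,
        config=cfg,
    )


def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Serialize a dataset in exactly the formats the readers consume."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "compounds": write_compound_table(ds.compounds, out / "compounds.tsv"),
        "ct_edges": write_edge_list(ds.ct, out / "ct_edges.tsv"),
        "gg_edges": write_edge_list(ds.gg, out / "gg_edges.tsv"),
        "pathogenic": write_gene_list(ds.pathogenic, out / "pathogenic_genes.txt"),
        "kegg": write_gmt(ds.kegg_sets, out / "kegg.gmt"),
        "gobp": write_gmt(ds.gobp_sets, out / "gobp.gmt"),
    }
    write_expression_matrix(ds.expression, out / "expression.tsv", out / "samples.tsv")
    paths["expression"] = out / "expression.tsv"
    paths["samples"] = out / "samples.tsv"
    truth_path = out / "ground_truth.json"
    truth_path.write_text(ds.truth.to_json() + "\n", encoding="utf-8")
    paths["ground_truth"] = truth_path
    cfg_path = out / "generator_config.json"
    cfg_path.write_text(json.dumps(asdict(ds.config), indent=2) + "\n", encoding="utf-8")
    paths["config"] = cfg_path
    return paths


def tiny_profile(seed: int = 0) -> GeneratorConfig:
    """A few-second profile for smoke tests and examples (<= 10 compounds)."""
    return GeneratorConfig(
        n_compounds=10,
        n_targets=40,
        n_pathogenic=50,
        ecp_fraction=0.25,
        ct_min_degree=2,
        ct_max_degree_frac=0.25,
        gg_density=0.05,
        n_samples_per_group=10,
        n_pathways=20,
        pathway_size_range=(10, 20),
        n_gobp_sets=20,
        n_background_genes=30,
        planted_key_compounds=2,
        seed=seed,
    )


def paper_scale_profile(seed: int = 0) -> GeneratorConfig:
    """A profile at the scale of the published optimized network.

    167 compounds (all past the screen), 1,467 targets, 1,758 pathogenic
    genes with 534 ECPs, compound degrees spanning roughly 10-160 and a
    gene-gene density giving ~45k interactions.
    """
    return GeneratorConfig(
        n_compounds=167,
        n_targets=1467,
        n_pathogenic=1758,
        ecp_fraction=534 / 1467,
        ct_exponent=1.6,
        ct_min_degree=10,
        ct_max_degree_frac=160 / 1467,
        gg_density=0.0125,
        n_samples_per_group=25,
        n_pathways=300,
        pathway_size_range=(10, 80),
        n_gobp_sets=1000,
        n_background_genes=500,
        planted_key_compounds=5,
        admet_pass_rate=1.0,
        seed=seed,
    )
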