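"""Readers, writers and in-memory containers for every external format the pipeline touches.

All tabular I/O is UTF-8, tab- (or comma-) delimited with header rows.
Gene identifiers are uppercased symbols throughout; mapping from other
namespaces (Entrez, Ensembl, UniProt) is the caller's responsibility.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("mooscreen")

#: The ten screened ADMET / physicochemical properties, in canonical order.
PROPERTY_COLUMNS = ("MW", "nHD", "nHA", "logP", "nRot", "F20", "BBB", "hERG", "HHT", "TPSA")


class FormatError(ValueError):
    """A file does not conform to its expected layout."""


class ValidationError(ValueError):
    """A file parsed, but its content violates an invariant."""


# ---------------------------------------------------------------------------
# Compound tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompoundRecord:
    """One formula ingredient with herb provenance and screened properties.

    ``properties`` maps property name -> value; units: MW g/mol, TPSA A^2,
    counts for nHD/nHA/nRot, unitless logP, and model probabilities in
    [0, 1] for F20/BBB/hERG/HHT.
    """

    compound_id: str
    name: str
    herbs: frozenset[str]
    smiles: str | None = None
    properties: Mapping[str, float] = field(default_factory=dict)


@dataclass
class CompoundTable:
    """An ordered collection of :class:`CompoundRecord` with unique ids."""

    records: list[CompoundRecord]

    def __post_init__(self) -> None:
        ids = [r.compound_id for r in self.records]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValidationError(f"duplicate compound_id: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def ids(self) -> list[str]:
        return [r.compound_id for r in self.records]

    def get(self, compound_id: str) -> CompoundRecord:
        for r in self.records:
            if r.compound_id == compound_id:
                return r
        raise KeyError(compound_id)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "compound_id": r.compound_id,
                "name": r.name,
                "herbs": ";".join(sorted(r.herbs)),
                "smiles": r.smiles or "",
            }
            for p in PROPERTY_COLUMNS:
                row[p] = r.properties.get(p, np.nan)
            rows.append(row)
        cols = ["compound_id", "name", "herbs", "smiles", *PROPERTY_COLUMNS]
        return pd.DataFrame(rows, columns=cols)


def read_compound_table(
    path: str | Path,
    dialect: str = "tsv",
    aliases: Mapping[str, str] | None = None,
) -> CompoundTable:
    """Read a compound property table from CSV/TSV.

    Parameters
    ----------
    path:
        File with columns ``compound_id``, ``name``, ``herbs``
        (``;``-separated), optional ``smiles``, and the ten property columns.
    dialect:
        ``"tsv"`` or ``"csv"``.
    aliases:
        Optional map from column names as found in the file to canonical
        names, e.g. ``{"MolWeight": "MW"}``.
    """
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if aliases:
        df = df.rename(columns=dict(aliases))
    if "compound_id" not in df.columns:
        raise FormatError(f"{path}: missing mandatory column 'compound_id'")
    missing = [p for p in PROPERTY_COLUMNS if p not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing property columns {missing}")

    records: list[CompoundRecord] = []
    bad_lines: list[int] = []
    for i, row in df.iterrows():
        cid = str(row["compound_id"]).strip()
        if not cid:
            bad_lines.append(int(i) + 2)  # +2: header + 1-based
            continue
        props: dict[str, float] = {}
        for p in PROPERTY_COLUMNS:
            raw = str(row[p]).strip()
            if raw in ("", "NA", "nan", "NaN"):
                continue
            try:
                v = float(raw)
            except ValueError as exc:
                raise FormatError(f"{path}: line {int(i) + 2}: bad value {raw!r} for {p}") from exc
            if not np.isfinite(v):
                raise ValidationError(f"{path}: non-finite {p} for compound {cid}")
            props[p] = v
        herbs = frozenset(h for h in str(row.get("herbs", "")).split(";") if h)
        records.append(
            CompoundRecord(
                compound_id=cid,
                name=str(row.get("name", cid)),
                herbs=herbs,
                smiles=str(row["smiles"]) or None if "smiles" in df.columns else None,
                properties=props,
            )
        )
    if bad_lines:
        logger.warning("%s: rejected %d rows with unparseable ids (lines %s)", path, len(bad_lines), bad_lines)
    return CompoundTable(records)


def write_compound_table(table: CompoundTable, path: str | Path) -> Path:
    path = Path(path)
    table.to_frame().to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# Edge lists
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EdgeList:
    """A deduplicated list of edges.

    ``kind`` is ``"compound-target"`` (directed compound -> target, though
    treated as bipartite/undirected downstream) or ``"gene-gene"``
    (undirected; pairs stored in lexicographic canonical order, self-loops
    forbidden).
    """

    kind: str
    edges: tuple[tuple[str, str], ...]

    def __len__(self) -> int:
        return len(self.edges)


def make_edge_list(pairs: Iterable[tuple[str, str]], kind: str) -> tuple[EdgeList, int]:
    """Canonicalise and deduplicate raw pairs; returns (edge list, n dropped self-loops)."""
    if kind not in ("compound-target", "gene-gene"):
        raise ValueError(f"unknown edge kind {kind!r}")
    seen: dict[tuple[str, str], None] = {}
    dropped = 0
    for a, b in pairs:
        a, b = str(a).strip(), str(b).strip()
        if kind == "gene-gene":
            a, b = a.upper(), b.upper()
            if a == b:
                dropped += 1
                continue
            if b < a:
                a, b = b, a
        seen.setdefault((a, b), None)
    return EdgeList(kind=kind, edges=tuple(seen)), dropped


def read_edge_list(path: str | Path, kind: str) -> EdgeList:
    """Read a two-column delimited edge list (optional header)."""
    pairs: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t") if "\t" in line else line.split(",")
            if len(fields) != 2:
                raise FormatError(f"{path}: line {lineno}: expected 2 fields, got {len(fields)}")
            if lineno == 1 and _looks_like_header(fields, kind):
                continue
            pairs.append((fields[0], fields[1]))
    edges, dropped = make_edge_list(pairs, kind)
    if dropped:
        logger.warning("%s: dropped %d self-loop(s)", path, dropped)
    return edges


def _looks_like_header(fields: Sequence[str], kind: str) -> bool:
    header_words = {"source", "target", "compound", "compound_id", "gene", "gene_a", "gene_b", "symbol_a", "symbol_b"}
    return any(f.strip().lower() in header_words for f in fields)


def write_edge_list(edges: EdgeList, path: str | Path) -> Path:
    path = Path(path)
    header = {"compound-target": "compound_id\ttarget", "gene-gene": "gene_a\tgene_b"}[edges.kind]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header + "\n")
        for a, b in edges.edges:
            fh.write(f"{a}\t{b}\n")
    return path


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """term_id -> (term_name, member symbols); symbols are uppercased."""

    sets: dict[str, tuple[str, frozenset[str]]]
    namespace: str = "KEGG"

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, term_id: str) -> frozenset[str]:
        return self.sets[term_id][1]

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for _, members in self.sets.values():
            out |= members
        return frozenset(out)

    def filtered(self, min_size: int) -> "GeneSetCollection":
        kept = {t: v for t, v in self.sets.items() if len(v[1]) >= min_size}
        return GeneSetCollection(sets=kept, namespace=self.namespace)


def read_gmt(path: str | Path, min_size: int = 10, namespace: str = "KEGG") -> GeneSetCollection:
    """Read a GMT v1 file (term, description, members...), dropping sets below ``min_size``.

    Sets smaller than ``min_size`` members (default 10) are removed; the
    removal count is logged.
    """
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    removed = 0
    n_lines = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            n_lines += 1
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: GMT needs >= 3 fields")
            term, desc = fields[0], fields[1]
            members = frozenset(g.strip().upper() for g in fields[2:] if g.strip())
            if len(members) < min_size:
                removed += 1
                continue
            sets[term] = (desc, members)
    if removed:
        logger.info("%s: removed %d gene set(s) below size %d", path, removed, min_size)
    if n_lines == 0:
        warnings.warn(f"{path}: empty GMT file", stacklevel=2)
    return GeneSetCollection(sets=sets, namespace=namespace)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for term, (desc, members) in collection.sets.items():
            fh.write("\t".join([term, desc, *sorted(members)]) + "\n")
    return path


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Log-scale expression, genes x samples, with a two-group design.

    ``values`` is a DataFrame indexed by uppercased gene symbol with sample
    ids as columns; ``groups`` maps each sample id to ``"case"`` or
    ``"control"``.
    """

    values: pd.DataFrame
    groups: dict[str, str]

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = sorted(set(self.values.index[self.values.index.duplicated()]))
            raise ValidationError(f"duplicate gene symbols: {dupes[:5]}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValidationError("expression values must be finite")
        labels = set(self.groups.values())
        if not labels <= {"case", "control"}:
            raise ValidationError(f"unknown group labels: {labels - {'case', 'control'}}")
        for g in ("case", "control"):
            if sum(1 for v in self.groups.values() if v == g) < 2:
                raise ValidationError(f"group {g!r} needs >= 2 samples")
        missing = [s for s in self.values.columns if s not in self.groups]
        if missing:
            raise ValidationError(f"samples without group labels: {missing}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def samples_for(self, policy: str) -> list[str]:
        """Sample ids under a policy: all | case-only | control-only."""
        if policy == "all":
            return self.samples
        if policy == "case-only":
            return [s for s in self.samples if self.groups[s] == "case"]
        if policy == "control-only":
            return [s for s in self.samples if self.groups[s] == "control"]
        raise ValueError(f"unknown sample policy {policy!r}")


def read_expression_matrix(path: str | Path, groups_path: str | Path) -> ExpressionMatrix:
    """Read genes x samples TSV plus a two-column sample sheet (sample, group)."""
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index = values.index.astype(str).str.upper()
    sheet = pd.read_csv(groups_path, sep="\t", dtype=str)
    if sheet.shape[1] < 2:
        raise FormatError(f"{groups_path}: sample sheet needs 2 columns (sample, group)")
    groups = dict(zip(sheet.iloc[:, 0], sheet.iloc[:, 1]))
    return ExpressionMatrix(values=values, groups=groups)


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path, groups_path: str | Path) -> None:
    expr.values.to_csv(path, sep="\t", float_format="%.6g")
    with open(groups_path, "w", encoding="utf-8") as fh:
        fh.write("sample\tgroup\n")
        for s in expr.samples:
            fh.write(f"{s}\t{expr.groups[s]}\n")


def read_gene_list(path: str | Path) -> list[str]:
    """One uppercased symbol per line (as exported from disease-gene databases)."""
    out: list[str] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            g = line.strip().upper()
            if g and g not in seen:
                seen.add(g)
                out.append(g)
    return out


def write_gene_list(genes: Iterable[str], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for g in genes:
            fh.write(f"{g}\n")
    return path


# ---------------------------------------------------------------------------
# Run reports
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_run_report(
    artifacts: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    config: Mapping | None = None,
    seed: int | None = None,
) -> Path:
    """Write each artifact DataFrame as a TSV and a JSON manifest describing the run.

    The manifest records file checksums, the resolved config, the seed and
    the tool version, so identical inputs and seed reproduce byte-identical
    tables.
    """
    from mooscreen import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = {}
    for name, frame in artifacts.items():
        fpath = out_dir / f"{name}.tsv"
        frame.to_csv(fpath, sep="\t", index=False, float_format="%.10g")
        entries[name] = {"path": fpath.name, "sha256": _sha256(fpath), "rows": int(len(frame))}
    manifest = {
        "tool": "mooscreen",
        "version": __version__,
        "seed": seed,
        "config": dict(config) if config else {},
        "artifacts": entries,
    }
    mpath = out_dir / "manifest.json"
    with open(mpath, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return mpath
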