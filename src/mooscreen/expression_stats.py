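"""Differential expression and pairwise gene-gene correlation.

A precomputed differential-expression table (gene, logFC, FDR) takes
precedence when available; otherwise a Welch two-sample t-test with
Benjamini-Hochberg correction supplies logFC and FDR from a log-scale
expression matrix. Significance follows |log2 FC| > 1 and FDR < 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix

logger = logging.getLogger("mooscreen")

LOGFC_THRESHOLD = 1.0
FDR_THRESHOLD = 0.05


@dataclass
class DETable:
    """Per-gene logFC (log2 case/control), raw p, BH FDR and significance flag.

    Genes whose test is undefined (zero variance in both groups) carry
    NaN p/fdr and are flagged in ``undefined``.
    """

    table: pd.DataFrame  # index: gene; columns: logFC, p, fdr, significant
    undefined: frozenset[str] = frozenset()

    def logfc(self, gene: str) -> float | None:
        """logFC for a gene, or None when the gene is absent (never silently 0)."""
        try:
            return float(self.table.at[gene, "logFC"])
        except KeyError:
            return None

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.table.index)


def differential_expression(expr: ExpressionMatrix) -> DETable:
    """Welch-test differential expression between case and control samples.

    logFC is mean(case) - mean(control) on the (already log2) input scale.
    """
    case = expr.samples_for("case-only")
    ctrl = expr.samples_for("control-only")
    x = expr.values[case].to_numpy(dtype=float)
    y = expr.values[ctrl].to_numpy(dtype=float)
    logfc = x.mean(axis=1) - y.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(x, y, axis=1, equal_var=False)
    undefined = frozenset(np.asarray(expr.genes)[~np.isfinite(p)])
    if undefined:
        logger.warning("differential_expression: %d gene(s) with undefined test (zero variance)", len(undefined))
    ok = np.isfinite(p)
    fdr = np.full_like(logfc, np.nan)
    if ok.any():
        fdr[ok] = multipletests(p[ok], method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "logFC": logfc,
            "p": np.where(ok, p, np.nan),
            "fdr": fdr,
            "significant": (np.abs(logfc) > LOGFC_THRESHOLD) & (fdr < FDR_THRESHOLD),
        },
        index=pd.Index(expr.genes, name="gene"),
    )
    return DETable(table=table, undefined=undefined)


def read_de_table(path: str | Path) -> DETable:
    """Read a precomputed DE table (gene, logFC, and p and/or fdr columns)."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.strip() for c in df.columns]
    if "gene" not in df.columns or "logFC" not in df.columns:
        raise ValueError(f"{path}: DE table needs 'gene' and 'logFC' columns")
    df["gene"] = df["gene"].astype(str).str.upper()
    df = df.set_index("gene")
    if "fdr" not in df.columns:
        if "p" not in df.columns:
            raise ValueError(f"{path}: DE table needs a 'p' or 'fdr' column")
        df["fdr"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    if "p" not in df.columns:
        df["p"] = np.nan
    df["significant"] = (df["logFC"].abs() > LOGFC_THRESHOLD) & (df["fdr"] < FDR_THRESHOLD)
    return DETable(table=df[["logFC", "p", "fdr", "significant"]])


def write_de_table(de: DETable, path: str | Path) -> Path:
    path = Path(path)
    de.table.to_csv(path, sep="\t", float_format="%.10g")
    return path


@dataclass
class CorrelationProvider:
    """Pairwise Pearson correlations over a declared sample set.

    Pairs whose correlation is undefined (zero variance, or a gene missing
    from the expression matrix) are reported as missing — ``get`` returns
    None, never a silent 0. Correlations are symmetric and cor(x, x) = 1.
    """

    values: dict[tuple[str, str], float]
    missing: frozenset[tuple[str, str]]
    n_samples: int
    sample_policy: str = "all"

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def get(self, a: str, b: str) -> float | None:
        if a == b:
            return 1.0
        return self.values.get(self._key(a, b))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene_a": a, "gene_b": b, "r": r, "n_samples": self.n_samples}
            for (a, b), r in sorted(self.values.items())
        ]
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "r", "n_samples"])


def correlation(
    expr: ExpressionMatrix,
    pairs: list[tuple[str, str]],
    policy: str = "all",
) -> CorrelationProvider:
    """Pearson r for each requested gene pair over the policy's samples.

    Raises when fewer than 3 samples fall under the policy (the
    coefficient is too unstable to report).
    """
    samples = expr.samples_for(policy)
    if len(samples) < 3:
        raise ValueError(f"policy {policy!r} leaves {len(samples)} sample(s); need >= 3")
    sub = expr.values[samples]
    mat = sub.to_numpy(dtype=float)
    index = {g: i for i, g in enumerate(sub.index)}
    centered = mat - mat.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))

    values: dict[tuple[str, str], float] = {}
    missing: set[tuple[str, str]] = set()
    for a, b in pairs:
        key = CorrelationProvider._key(a, b)
        if key in values or key in missing:
            continue
        ia, ib = index.get(a), index.get(b)
        if ia is None or ib is None or norms[ia] == 0.0 or norms[ib] == 0.0:
            missing.add(key)
            continue
        r = float(np.dot(centered[ia], centered[ib]) / (norms[ia] * norms[ib]))
        values[key] = max(-1.0, min(1.0, r))
    if missing:
        logger.info("correlation: %d pair(s) undefined or absent", len(missing))
    return CorrelationProvider(
        values=values, missing=frozenset(missing), n_samples=len(samples), sample_policy=policy
    )


def read_correlation_cache(path: str | Path) -> CorrelationProvider:
    df = pd.read_csv(path, sep="\t")
    values = {
        CorrelationProvider._key(str(r.gene_a), str(r.gene_b)): float(r.r)
        for r in df.itertuples()
    }
    n = int(df["n_samples"].iloc[0]) if len(df) else 0
    return CorrelationProvider(values=values, missing=frozenset(), n_samples=n)
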