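"""Target-coverage scoring of compounds and minimal 90%-coverage combinations.

A compound's coverage score is the sum of the multiobjective scores of its
retained targets, Score_c = Σ Score_t over T_c. For combinations the
default "union" mode sums Score_t over the union of the member compounds'
targets (a weighted maximum-coverage objective — shared targets count
once); "additive" mode sums the per-compound scores instead. The selected
key components are the smallest combination whose optimal coverage reaches
a threshold fraction (default 90%) of the coverage of all candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import pandas as pd

from .ctp_network import CTPNetwork
from .moo_scoring import ScoreTable

logger = logging.getLogger("mooscreen")

#: Exact enumeration refuses above this many size-k combinations.
EXACT_GUARD = 2_000_000


@dataclass
class CompoundCoverage:
    """Per-compound retained-target sets and coverage scores."""

    targets: dict[str, frozenset[str]]  # compound -> T_c in the optimized network
    scores: dict[str, float]  # compound -> Score_c
    flagged_empty: frozenset[str] = frozenset()  # compounds with no retained target

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "compound_id": c,
                "n_targets": len(self.targets[c]),
                "score_c": self.scores[c],
            }
            for c in sorted(self.scores, key=lambda c: (-self.scores[c], c))
        ]
        return pd.DataFrame(rows, columns=["compound_id", "n_targets", "score_c"])


def compound_score(net: CTPNetwork, scores: ScoreTable) -> CompoundCoverage:
    """Score_c = Σ Score_t over each compound's targets in the (optimized) network."""
    score_t = scores.table["score_t"]
    targets: dict[str, frozenset[str]] = {}
    vals: dict[str, float] = {}
    empty = set()
    by_compound: dict[str, set[str]] = {c: set() for c in net.compounds}
    for c, t in net.ct_edges:
        by_compound[c].add(t)
    for c in sorted(net.compounds):
        tc = frozenset(t for t in by_compound[c] if t in score_t.index)
        targets[c] = tc
        vals[c] = float(score_t.loc[list(tc)].sum()) if tc else 0.0
        if not tc:
            empty.add(c)
    if empty:
        logger.info("compound_score: %d compound(s) with no retained target", len(empty))
    return CompoundCoverage(targets=targets, scores=vals, flagged_empty=frozenset(empty))


def combination_coverage(
    combo: set[str] | frozenset[str] | tuple[str, ...],
    coverage: CompoundCoverage,
    scores: ScoreTable,
    mode: str = "union",
) -> float:
    """Coverage of a compound combination.

    union mode: Σ Score_t over the union of the members' target sets
    (shared targets count once); additive mode: Σ Score_c (shared targets
    count once per compound).
    """
    combo = frozenset(combo)
    if not combo:
        raise ValueError("combination_coverage: empty combination")
    if mode == "additive":
        return sum(coverage.scores[c] for c in combo)
    if mode != "union":
        raise ValueError(f"unknown mode {mode!r}")
    union: set[str] = set()
    for c in combo:
        union |= coverage.targets[c]
    score_map = scores.table["score_t"].to_dict()
    return float(sum(score_map[t] for t in union))


def _greedy_order(
    candidates: list[str], coverage: CompoundCoverage, scores: ScoreTable, mode: str
) -> list[str]:
    """Nested greedy chain by maximal marginal gain.

    Ties break by (gain, Score_c, compound id) — deterministic regardless
    of candidate order.
    """
    score_t = scores.table["score_t"].to_dict()
    remaining = sorted(candidates)
    chain: list[str] = []
    covered: set[str] = set()
    while remaining:
        best = None
        best_key = None
        for c in remaining:
            if mode == "union":
                gain = sum(score_t[t] for t in coverage.targets[c] - covered)
            else:
                gain = coverage.scores[c]
            key = (-gain, -coverage.scores[c], c)
            if best_key is None or key < best_key:
                best, best_key = c, key
        chain.append(best)
        covered |= coverage.targets[best]
        remaining.remove(best)
    return chain


def optimal_combination(
    k: int,
    candidates: list[str],
    coverage: CompoundCoverage,
    scores: ScoreTable,
    mode: str = "union",
    solver: str = "greedy",
) -> tuple[frozenset[str], float]:
    """Best size-k combination by coverage.

    ``exact`` enumerates all C(n, k) combinations (guarded; intended for
    n <= ~20) with deterministic lexicographic tie-breaking; ``greedy``
    returns the size-k prefix of the nested greedy chain, which for the
    union (submodular) objective is within (1 - 1/e) of the optimum.
    """
    candidates = sorted(set(candidates))
    n = len(candidates)
    if not (1 <= k <= n):
        raise ValueError(f"k={k} outside 1..{n}")
    if solver == "greedy":
        combo = frozenset(_greedy_order(candidates, coverage, scores, mode)[:k])
        return combo, combination_coverage(combo, coverage, scores, mode)
    if solver != "exact":
        raise ValueError(f"unknown solver {solver!r}")
    if comb(n, k) > EXACT_GUARD:
        raise ValueError(
            f"exact enumeration of C({n},{k}) combinations exceeds the guard; use solver='greedy'"
        )
    if mode == "additive":
        # Σ Score_c is modular: the top-k compounds by score are optimal.
        top = sorted(candidates, key=lambda c: (-coverage.scores[c], c))[:k]
        combo = frozenset(top)
        return combo, combination_coverage(combo, coverage, scores, mode)
    score_map = scores.table["score_t"].to_dict()
    tsets = coverage.targets
    best_combo: tuple[str, ...] | None = None
    best_val = float("-inf")
    for combo in combinations(candidates, k):
        union: set[str] = set()
        for c in combo:
            union |= tsets[c]
        val = sum(score_map[t] for t in union)
        if val > best_val:
            best_combo, best_val = combo, val
    return frozenset(best_combo), float(best_val)


@dataclass
class CompoundSelection:
    """Per-size optimal combinations, the cumulative coverage curve and the
    smallest combination reaching the threshold fraction of total coverage."""

    mode: str
    solver: str
    threshold: float
    total_coverage: float
    curve: pd.DataFrame  # k, combo, coverage, fraction_of_total
    selected: frozenset[str]
    selected_size: int
    selected_coverage: float

    def to_frame(self) -> pd.DataFrame:
        return self.curve


def select_to_threshold(
    candidates: list[str],
    coverage: CompoundCoverage,
    scores: ScoreTable,
    threshold: float = 0.9,
    mode: str = "union",
    solver: str = "greedy",
) -> CompoundSelection:
    """Smallest combination whose optimal coverage reaches threshold x total.

    ``total`` is the coverage of all candidates together (union of every
    target set in union mode; sum of all Score_c in additive mode). The
    full per-size curve is retained for coverage plots.
    """
    if not (0 < threshold <= 1):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    candidates = sorted(set(candidates))
    if not candidates:
        raise ValueError("no candidate compounds")
    total = combination_coverage(candidates, coverage, scores, mode)
    if total <= 0:
        raise ValueError("total coverage is zero; nothing to select")

    rows = []
    selected: frozenset[str] | None = None
    sel_cov = 0.0
    if solver == "greedy":
        chain = _greedy_order(candidates, coverage, scores, mode)
        running: set[str] = set()
        for k, c in enumerate(chain, start=1):
            running.add(c)
            cov = combination_coverage(running, coverage, scores, mode)
            rows.append((k, frozenset(running), cov))
    else:
        for k in range(1, len(candidates) + 1):
            combo, cov = optimal_combination(k, candidates, coverage, scores, mode, solver)
            rows.append((k, combo, cov))
    for k, combo, cov in rows:
        if selected is None and cov >= threshold * total - 1e-12:
            selected, sel_cov = combo, cov
            break
    if selected is None:  # numerically defensive; the full set reaches total
        k, selected, sel_cov = rows[-1]

    curve = pd.DataFrame(
        [
            {
                "k": k,
                "combo": ";".join(sorted(combo)),
                "coverage": cov,
                "fraction_of_total": cov / total,
            }
            for k, combo, cov in rows
        ],
        columns=["k", "combo", "coverage", "fraction_of_total"],
    )
    return CompoundSelection(
        mode=mode,
        solver=solver,
        threshold=threshold,
        total_coverage=total,
        curve=curve,
        selected=selected,
        selected_size=len(selected),
        selected_coverage=sel_cov,
    )
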