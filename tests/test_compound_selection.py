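from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from mooscreen.compound_selection import (
    CompoundCoverage,
    combination_coverage,
    compound_score,
    optimal_combination,
    select_to_threshold,
)
from mooscreen.ctp_network import build_ctp
from mooscreen.moo_scoring import ScoreTable
from tests.conftest import edge_list


def score_table(score_t: dict) -> ScoreTable:
    df = pd.DataFrame({"score_t": score_t})
    df.index.name = "target"
    return ScoreTable(table=df, components=("exp",))


def coverage_of(targets: dict, scores: ScoreTable) -> CompoundCoverage:
    return CompoundCoverage(
        targets={c: frozenset(ts) for c, ts in targets.items()},
        scores={
            c: float(scores.table["score_t"].loc[list(ts)].sum()) if ts else 0.0
            for c, ts in targets.items()
        },
    )


@pytest.fixture
def toy():
    """c1 -> {t1, t2}, c2 -> {t1, t3}; scores t1:1, t2:2, t3:3."""
    scores = score_table({"t1": 1.0, "t2": 2.0, "t3": 3.0})
    cov = coverage_of({"c1": {"t1", "t2"}, "c2": {"t1", "t3"}}, scores)
    return cov, scores


def random_instance(rng, n_compounds=None):
    n_c = n_compounds or int(rng.integers(3, 13))
    n_t = int(rng.integers(4, 11))
    targets = [f"t{i}" for i in range(n_t)]
    scores = score_table({t: float(np.round(rng.uniform(0, 4), 3)) for t in targets})
    mapping = {
        f"c{i}": set(rng.choice(targets, size=int(rng.integers(1, n_t + 1)), replace=False))
        for i in range(n_c)
    }
    return coverage_of(mapping, scores), scores


class TestCompoundScore:
    def test_per_compound_target_sum(self):
        ct = edge_list([("c1", "t1"), ("c1", "t2"), ("c2", "t1")], "compound-target")
        net = build_ctp(ct, edge_list([("t1", "p1")], "gene-gene"), ["p1"])
        scores = score_table({"T1": 1.5, "T2": 2.5})
        cov = compound_score(net, scores)
        assert cov.scores["c1"] == pytest.approx(4.0)
        assert cov.scores["c2"] == pytest.approx(1.5)  # shared target counts per compound

    def test_compound_with_no_retained_targets_flagged(self):
        ct = edge_list([("c1", "t1"), ("c2", "t2")], "compound-target")
        net = build_ctp(ct, edge_list([("t1", "p1")], "gene-gene"), ["p1"])
        cov = compound_score(net, score_table({"T1": 1.0}))  # t2 unscored (pruned)
        assert cov.scores["c2"] == 0.0 and cov.flagged_empty == {"c2"}


class TestCombinationCoverage:
    def test_union_counts_shared_targets_once(self, toy):
        cov, scores = toy
        assert combination_coverage({"c1", "c2"}, cov, scores, "union") == pytest.approx(6.0)

    def test_additive_counts_per_compound(self, toy):
        cov, scores = toy
        assert combination_coverage({"c1", "c2"}, cov, scores, "additive") == pytest.approx(7.0)

    def test_singleton_equals_compound_score(self, toy):
        cov, scores = toy
        for mode in ("union", "additive"):
            assert combination_coverage({"c1"}, cov, scores, mode) == pytest.approx(cov.scores["c1"])


class TestOptimalCombination:
    def test_toy_size_one_enumeration(self, toy):
        cov, scores = toy
        combo, val = optimal_combination(1, ["c1", "c2"], cov, scores, "union", "exact")
        assert combo == {"c2"} and val == pytest.approx(4.0)

    def test_full_size_is_total(self, toy):
        cov, scores = toy
        combo, val = optimal_combination(2, ["c1", "c2"], cov, scores, "union", "exact")
        assert combo == {"c1", "c2"} and val == pytest.approx(6.0)

    def test_guard_refuses_huge_enumeration(self):
        rng = np.random.default_rng(0)
        cov, scores = random_instance(rng, n_compounds=60)
        with pytest.raises(ValueError, match="greedy"):
            optimal_combination(25, sorted(cov.scores), cov, scores, "union", "exact")

    def test_greedy_bound_against_exact_on_random_instances(self):
        rng = np.random.default_rng(10)
        bound = 1 - 1 / np.e
        for _ in range(25):
            cov, scores = random_instance(rng)
            cands = sorted(cov.scores)
            for k in range(1, len(cands) + 1):
                _, exact_val = optimal_combination(k, cands, cov, scores, "union", "exact")
                _, greedy_val = optimal_combination(k, cands, cov, scores, "union", "greedy")
                assert greedy_val >= bound * exact_val - 1e-9

    def test_greedy_equals_exact_on_modular_instances(self):
        # disjoint target sets: the union objective is modular, greedy is optimal
        rng = np.random.default_rng(4)
        for _ in range(10):
            n_c = int(rng.integers(3, 8))
            scores = score_table({f"t{i}": float(rng.uniform(0, 4)) for i in range(3 * n_c)})
            mapping = {f"c{i}": {f"t{3*i}", f"t{3*i+1}", f"t{3*i+2}"} for i in range(n_c)}
            cov = coverage_of(mapping, scores)
            for k in range(1, n_c + 1):
                _, ev = optimal_combination(k, sorted(mapping), cov, scores, "union", "exact")
                _, gv = optimal_combination(k, sorted(mapping), cov, scores, "union", "greedy")
                assert gv == pytest.approx(ev, abs=1e-9)

    def test_additive_mode_equals_top_k_sorting(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            cov, scores = random_instance(rng)
            cands = sorted(cov.scores)
            for k in range(1, len(cands) + 1):
                combo, val = optimal_combination(k, cands, cov, scores, "additive", "exact")
                top_k = sorted(cands, key=lambda c: (-cov.scores[c], c))[:k]
                assert combo == frozenset(top_k)
                assert val == pytest.approx(sum(cov.scores[c] for c in top_k))


class TestMonotoneSubmodular:
    def test_union_coverage_monotone_and_submodular(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            cov, scores = random_instance(rng)
            cands = sorted(cov.scores)
            for _ in range(10):
                size_b = int(rng.integers(1, len(cands)))
                b = set(rng.choice(cands, size=size_b, replace=False))
                a = set(rng.choice(sorted(b), size=int(rng.integers(1, len(b) + 1)), replace=False))
                rest = [c for c in cands if c not in b]
                if not rest:
                    continue
                c = rest[int(rng.integers(len(rest)))]
                f = lambda s: combination_coverage(s, cov, scores, "union")
                assert f(b) >= f(a) - 1e-9  # monotone
                assert f(a | {c}) - f(a) >= f(b | {c}) - f(b) - 1e-9  # diminishing gains


class TestSelectToThreshold:
    def test_toy_needs_two_compounds(self, toy):
        cov, scores = toy
        sel = select_to_threshold(["c1", "c2"], cov, scores, threshold=0.9, solver="exact")
        assert sel.selected == {"c1", "c2"} and sel.selected_size == 2
        assert sel.total_coverage == pytest.approx(6.0)

    def test_threshold_one_saturates(self, toy):
        cov, scores = toy
        sel = select_to_threshold(["c1", "c2"], cov, scores, threshold=1.0)
        assert sel.selected_coverage == pytest.approx(sel.total_coverage)

    def test_curve_is_nondecreasing(self):
        rng = np.random.default_rng(13)
        cov, scores = random_instance(rng)
        sel = select_to_threshold(sorted(cov.scores), cov, scores, threshold=1.0)
        assert (np.diff(sel.curve["coverage"].to_numpy()) >= -1e-9).all()

    def test_invalid_threshold(self, toy):
        cov, scores = toy
        with pytest.raises(ValueError):
            select_to_threshold(["c1"], cov, scores, threshold=1.5)

    def test_selected_meets_threshold(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            cov, scores = random_instance(rng)
            sel = select_to_threshold(sorted(cov.scores), cov, scores, threshold=0.9)
            assert sel.selected_coverage >= 0.9 * sel.total_coverage - 1e-9
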