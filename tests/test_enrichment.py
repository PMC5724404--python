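import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ygate.enrichment import bh_adjust, enrich, hypergeom_upper_tail
from ygate.io import GeneSet


def enumeration_upper_tail(k, K, n, N):
    """Count draws directly: of all C(N, n) subsets of an urn with K marked
    elements, the fraction containing >= k marked ones."""
    hits = total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        hits += sum(1 for e in draw if e < K) >= k
    return hits / total


class TestHypergeomUpperTail:
    def test_worked_small_case(self):
        # 4 query genes all inside a 5-gene set, background 10:
        # P(X >= 4) = C(5,4)C(5,0)/C(10,4) = 5/210
        assert hypergeom_upper_tail(4, 5, 4, 10) == pytest.approx(5 / 210)

    def test_k_zero_is_one(self):
        assert hypergeom_upper_tail(0, 5, 4, 10) == 1.0

    def test_k_above_set_size_is_zero(self):
        assert hypergeom_upper_tail(4, 3, 5, 10) == 0.0

    @settings(max_examples=120, deadline=None, derandomize=True)
    @given(
        N=st.integers(2, 12),
        data=st.data(),
    )
    def test_matches_enumeration_oracle(self, N, data):
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(1, N))
        k = data.draw(st.integers(0, n))
        assert hypergeom_upper_tail(k, K, n, N) == pytest.approx(
            enumeration_upper_tail(k, K, n, N), abs=1e-12
        )

    def test_deep_tail_matches_scipy_in_relative_terms(self):
        # a tail around 1e-60: log-space summation must keep accuracy
        p = hypergeom_upper_tail(61, 90, 1539, 20000)
        sp = stats.hypergeom.sf(60, 20000, 90, 1539)
        assert p == pytest.approx(sp, rel=1e-9)
        assert p < 1e-40

    def test_pmf_kernel_normalizes(self):
        # successive upper tails difference to the pmf; the pmf must sum to 1
        K, n, N = 7, 5, 12
        pmf = [
            hypergeom_upper_tail(k, K, n, N) - hypergeom_upper_tail(k + 1, K, n, N)
            for k in range(0, n)
        ] + [hypergeom_upper_tail(n, K, n, N)]
        assert sum(pmf) == pytest.approx(1.0, abs=1e-12)
        for k, value in enumerate(pmf):
            assert value == pytest.approx(
                stats.hypergeom.pmf(k, N, K, n), abs=1e-12
            )

    def test_inconsistent_counts_are_error(self):
        with pytest.raises(ValueError):
            hypergeom_upper_tail(5, 3, 4, 10)  # k > n


def hand_step_up(p):
    """BH oracle: sort, multiply by m/rank, enforce monotonicity from the
    largest rank down, cap at 1, restore input order."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [None] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adjusted[i] = min(running, 1.0)
    return adjusted


class TestBhAdjust:
    def test_hand_worked_example(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert list(out) == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_matches_step_up_oracle_and_dominates_raw(self, p):
        out = bh_adjust(p)
        assert list(out) == pytest.approx(hand_step_up(p), abs=1e-12)
        assert all(a >= r for a, r in zip(out, p))
        ranked = sorted(zip(p, out))
        assert all(
            ranked[i][1] <= ranked[i + 1][1] for i in range(len(ranked) - 1)
        )

    def test_out_of_range_is_error(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestEnrich:
    def _two_set_collection(self):
        return {
            "target": GeneSet("query lives here", tuple(f"T{i}" for i in range(8))),
            "decoy": GeneSet("disjoint", tuple(f"D{i}" for i in range(8))),
        }

    def test_full_set_query_is_most_enriched(self):
        sets = self._two_set_collection()
        background = list(sets["target"].genes) + list(sets["decoy"].genes)
        table = enrich(list(sets["target"].genes), sets, background, cutoff=0.05)
        assert table.iloc[0]["set_name"] == "target"
        assert table.iloc[0]["p_raw"] < table.iloc[1]["p_raw"]
        assert bool(table.iloc[0]["enriched"])

    def test_records_self_consistent_with_kernel(self, rng):
        background = [f"G{i}" for i in range(300)]
        sets = {
            f"S{j}": GeneSet("rand", tuple(rng.choice(background, 25, replace=False)))
            for j in range(12)
        }
        query = list(rng.choice(background, 60, replace=False))
        table = enrich(query, sets, background)
        for _, row in table.iterrows():
            assert row["p_raw"] == pytest.approx(
                hypergeom_upper_tail(row["k"], row["K"], row["n"], row["N"])
            )
            assert row["k"] <= min(row["K"], row["n"])
            assert row["p_adjusted"] >= row["p_raw"] - 1e-15

    def test_nested_query_monotonicity(self):
        sets = self._two_set_collection()
        background = list(sets["target"].genes) + list(sets["decoy"].genes)
        q1 = list(sets["target"].genes[:4])
        q2 = list(sets["target"].genes[:7])
        p1 = enrich(q1, sets, background).set_index("set_name").loc["target", "p_raw"]
        p2 = enrich(q2, sets, background).set_index("set_name").loc["target", "p_raw"]
        assert p2 <= p1

    def test_query_outside_background_dropped_with_warning(self):
        sets = self._two_set_collection()
        background = list(sets["target"].genes) + list(sets["decoy"].genes)
        with pytest.warns(UserWarning, match="dropped"):
            table = enrich(
                ["NOT_IN_BG"] + list(sets["target"].genes[:3]), sets, background
            )
        assert (table["n"] == 3).all()

    def test_empty_query_after_filtering_is_error(self):
        sets = self._two_set_collection()
        with pytest.raises(ValueError, match="no query genes"):
            with pytest.warns(UserWarning):
                enrich(["X"], sets, list(sets["target"].genes))

    def test_degenerate_sets_skipped(self):
        sets = {
            "tiny": GeneSet("one gene in background", ("A", "ZZZ")),
            "ok": GeneSet("fine", ("A", "B", "C")),
        }
        table = enrich(["A"], sets, ["A", "B", "C", "D"])
        assert list(table["set_name"]) == ["ok"]
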