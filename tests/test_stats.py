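import itertools
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trajex.dataio import AnnotationSet
from trajex.stats import (
    benjamini_hochberg,
    enrich,
    hypergeom_point,
    hypergeom_tail,
    linear_trend,
    pathway_intersection,
    precision_recall,
    rank_by_volatility,
    volatility,
)

from conftest import make_agg, make_dset


def enumerate_point(N, D, n, k):
    """Exact oracle: enumerate every size-n draw from an N-item urn."""
    items = list(range(N))
    inset = set(range(D))
    hits = sum(
        1 for draw in itertools.combinations(items, n) if len(inset & set(draw)) == k
    )
    total = sum(1 for _ in itertools.combinations(items, n))
    return Fraction(hits, total)


class TestHypergeomPoint:
    def test_worked_example_10_5_4_2(self):
        # enumeration over all C(10,4)=210 draws gives 100 with exactly 2 hits
        assert enumerate_point(10, 5, 4, 2) == Fraction(100, 210)
        assert hypergeom_point(10, 5, 4, 2) == pytest.approx(100 / 210, abs=1e-15)

    def test_worked_example_4_2_2_2(self):
        assert enumerate_point(4, 2, 2, 2) == Fraction(1, 6)
        assert hypergeom_point(4, 2, 2, 2) == pytest.approx(1 / 6, abs=1e-15)

    def test_empty_draw(self):
        assert hypergeom_point(10, 5, 0, 0) == 1.0

    @pytest.mark.parametrize(
        "N,D,n,k,msg",
        [
            (10, 11, 4, 2, "exceed"),
            (10, 5, 4, 5, "exceeds min"),
            (10, 9, 4, 0, "N-D"),
            (10, 5, -1, 0, "non-negative"),
        ],
    )
    def test_bounds_checked(self, N, D, n, k, msg):
        with pytest.raises(ValueError, match=msg):
            hypergeom_point(N, D, n, k)

    def test_log_space_path_matches_exact(self):
        # force both code paths on the same moderate input
        from trajex import stats as stats_mod

        exact = hypergeom_point(500, 40, 60, 10)
        old = stats_mod._EXACT_N_LIMIT
        try:
            stats_mod._EXACT_N_LIMIT = 0
            approx = hypergeom_point(500, 40, 60, 10)
        finally:
            stats_mod._EXACT_N_LIMIT = old
        assert approx == pytest.approx(exact, rel=1e-10)


class TestHypergeomTail:
    def test_k_zero_is_one(self):
        assert hypergeom_tail(10, 5, 4, 0) == 1.0

    def test_tail_at_maximum_equals_point(self):
        assert hypergeom_tail(10, 5, 4, 4) == pytest.approx(5 / 210, abs=1e-15)
        assert hypergeom_tail(10, 5, 4, 4) == hypergeom_point(10, 5, 4, 4)

    def test_tail_dominates_point(self, rng):
        for _ in range(50):
            N = int(rng.integers(2, 40))
            D = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            lo = max(0, n - (N - D))
            k = int(rng.integers(lo, min(n, D) + 1))
            assert hypergeom_tail(N, D, n, k) >= hypergeom_point(N, D, n, k) - 1e-15

    def test_tail_is_sum_of_points(self):
        N, D, n = 12, 5, 6
        for k in range(0, min(n, D) + 1):
            expected = sum(
                hypergeom_point(N, D, n, j)
                for j in range(k, min(n, D) + 1)
                if n - j <= N - D
            )
            assert hypergeom_tail(N, D, n, k) == pytest.approx(expected, abs=1e-14)


def test_normalization_small_cases():
    for N in range(1, 13):
        for D in range(N + 1):
            for n in range(N + 1):
                total = sum(
                    hypergeom_point(N, D, n, k)
                    for k in range(max(0, n - (N - D)), min(n, D) + 1)
                )
                assert total == pytest.approx(1.0, abs=1e-12)


class TestEnrich:
    def make_annotation(self):
        return AnnotationSet(
            pathways={
                "PLANTED": frozenset(f"P{i}" for i in range(10)),
                "DECOY": frozenset(f"P{i}" for i in range(500, 520)),
                "GHOST": frozenset({"ZZZ"}),
            }
        )

    def test_planted_pathway_ranks_first(self):
        universe = {f"P{i}" for i in range(1000)}
        selected = {f"P{i}" for i in range(10)}
        results, notes = enrich(selected, self.make_annotation(), universe)
        assert results[0].set_name == "PLANTED"
        oracle = Fraction(1, 1)  # k = n = D = 10: only one maximal draw term
        import math

        oracle = Fraction(math.comb(990, 0) * math.comb(10, 10), math.comb(1000, 10))
        assert results[0].p_tail == pytest.approx(float(oracle), rel=1e-12)
        assert any("GHOST" in n for n in notes)

    def test_selected_equals_universe_forces_full_overlap(self):
        universe = {f"P{i}" for i in range(30)}
        ann = AnnotationSet(pathways={"PW": frozenset(list(universe)[:7])})
        results, _ = enrich(universe, ann, universe)
        r = results[0]
        assert r.k == r.D
        assert r.p_tail == pytest.approx(1.0)

    def test_selected_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            enrich({"X"}, self.make_annotation(), {"P1"})

    def test_invariants_on_results(self):
        universe = {f"P{i}" for i in range(100)}
        selected = {f"P{i}" for i in range(15)}
        results, _ = enrich(selected, self.make_annotation(), universe)
        for r in results:
            assert 0 <= r.k <= min(r.n, r.D)
            assert r.D <= r.N and r.n <= r.N
            assert 0.0 <= r.p_point <= 1.0
            assert r.p_tail >= r.p_point - 1e-15

    def test_bh_adjustment(self):
        universe = {f"P{i}" for i in range(1000)}
        selected = {f"P{i}" for i in range(10)}
        results, _ = enrich(selected, self.make_annotation(), universe, adjust="BH")
        qs = [r.q for r in results]
        assert all(q is not None for q in qs)
        assert qs == sorted(qs)  # monotone in rank order

    def test_point_mode_sorts_by_point(self):
        universe = {f"P{i}" for i in range(100)}
        selected = {f"P{i}" for i in range(5)}
        results, _ = enrich(selected, self.make_annotation(), universe, mode="point")
        ps = [r.p_point for r in results]
        assert ps == sorted(ps)


class TestPrecisionRecall:
    def test_worked_example(self):
        S = {f"s{i}" for i in range(2)} | {"c1", "c2"}
        R = {f"r{i}" for i in range(6)} | {"c1", "c2"}
        assert precision_recall(S, R) == (0.5, 0.25)

    def test_identical_nonempty(self):
        assert precision_recall({"a", "b"}, {"a", "b"}) == (1.0, 1.0)

    def test_disjoint_nonempty(self):
        assert precision_recall({"a"}, {"b"}) == (0.0, 0.0)

    def test_empty_sides_not_applicable(self):
        p, r = precision_recall(set(), {"a"})
        assert p is None and r == 0.0
        p, r = precision_recall({"a"}, set())
        assert p == 0.0 and r is None

    def test_symmetry(self, rng):
        pool = [f"x{i}" for i in range(20)]
        for _ in range(20):
            S = set(rng.choice(pool, size=rng.integers(1, 10), replace=False))
            R = set(rng.choice(pool, size=rng.integers(1, 10), replace=False))
            assert precision_recall(S, R)[0] == precision_recall(R, S)[1]


class TestVolatilityAndTrend:
    def test_constant_is_zero(self):
        assert volatility([2, 2, 2, 2]) == 0.0

    def test_oscillator(self):
        assert volatility([0, 1, 0, 1]) == 3.0
        assert linear_trend([0, 1, 0, 1]) == 1.0

    def test_fractional(self):
        assert volatility([1.0, 2.5, 2.0]) == pytest.approx(2.0)

    def test_trend_examples(self):
        assert linear_trend([2, 2, 2]) == 0.0
        assert linear_trend([3, 1, -2]) == -5.0

    def test_too_short(self):
        with pytest.raises(ValueError):
            volatility([1.0])
        with pytest.raises(ValueError):
            linear_trend([1.0])


@settings(max_examples=200, deadline=None)
@given(
    values=st.lists(
        st.floats(min_value=-100, max_value=100, allow_nan=False),
        min_size=2,
        max_size=12,
    )
)
def test_telescoping_and_dominance_property(values):
    L = linear_trend(values)
    V = volatility(values)
    assert L == pytest.approx(values[-1] - values[0], abs=1e-9)
    assert abs(L) <= V + 1e-9
    # exact rational oracle for the equality-iff-monotone claim
    diffs = [Fraction(b) - Fraction(a) for a, b in zip(values, values[1:])]
    exact_V = sum(abs(d) for d in diffs)
    exact_L = sum(diffs)
    monotone = all(d >= 0 for d in diffs) or all(d <= 0 for d in diffs)
    assert (abs(exact_L) == exact_V) == monotone
    assert V == pytest.approx(float(exact_V), rel=1e-9, abs=1e-9)


class TestRanking:
    def test_constant_probes_sort_last_descending(self):
        agg = make_agg([[0, 5, 0], [1, 1, 1], [2, 2.5, 2]], probe_ids=["hot", "flat", "mild"])
        rows = rank_by_volatility(agg)
        assert [r.probe for r in rows] == ["hot", "mild", "flat"]
        assert rows[0].volatility == 10.0

    def test_scores_match_direct_evaluation(self, rng):
        values = rng.normal(size=(15, 6))
        agg = make_agg(values)
        rows = {r.probe: r for r in rank_by_volatility(agg)}
        for probe, row in zip(agg.probe_ids, values):
            assert rows[probe].volatility == pytest.approx(volatility(row))
            assert rows[probe].linear_trend == pytest.approx(linear_trend(row))

    def test_ordering_is_permutation_with_tiebreak(self):
        dset = make_dset([[0, 1], [0, 1], [2, 3]], probe_ids=["B", "A", "C"])
        rows = rank_by_volatility(dset)
        assert sorted(r.probe for r in rows) == ["A", "B", "C"]
        assert [r.probe for r in rows] == ["A", "B", "C"]  # all V=1, id ascending
        assert rows[0].units == "bins"


def test_pathway_intersection_triples():
    ann = AnnotationSet(
        pathways={"PW1": frozenset({"P1", "P2"}), "PW2": frozenset({"P9"})}
    )
    context = {"P1", "P2", "P3"}
    triples = pathway_intersection(context, ann)
    assert triples["PW1"] == (3, 2, 2)  # context ⊇ PW1
    assert triples["PW2"] == (3, 1, 0)  # disjoint
    # consistency with enrich's n, D, k
    results, _ = enrich(context, ann, context | {"P9", "P10"})
    for r in results:
        n_ctx, D, k = triples[r.set_name]
        assert (r.n, r.k) == (n_ctx, k)


def test_benjamini_hochberg_known_values():
    ps = [0.01, 0.02, 0.03, 0.04]
    qs = benjamini_hochberg(ps)
    assert qs == pytest.approx([0.04, 0.04, 0.04, 0.04])
    qs = benjamini_hochberg([0.005, 0.5])
    assert qs == pytest.approx([0.01, 0.5])
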