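"""Richness and rank-abundance change metrics against brute-force oracles."""

import math

import numpy as np
import pytest

from betachron import (
    UndefinedComparisonError,
    ValidationError,
    median_richness,
    rac_series,
    rank_difference,
    richness_difference,
    summarize_rac,
)
from conftest import random_species_sets


def naive_rank_difference(census_a, census_b):
    """Brute-force rank assigner kept independent of the implementation.

    Ranks are assigned by sorting; tied abundances get the average of the
    positions they occupy, and absent species all share the rank below the
    present block.
    """
    union = sorted(
        {s for s, v in census_a.items() if v > 0}
        | {s for s, v in census_b.items() if v > 0}
    )
    s_union = len(union)

    def ranks(census):
        present = sorted(
            (s for s in union if census.get(s, 0) > 0),
            key=lambda s: -census[s],
        )
        out = {}
        i = 0
        while i < len(present):
            j = i
            while j < len(present) and census[present[j]] == census[present[i]]:
                j += 1
            avg = (i + 1 + j) / 2  # average of positions i+1 .. j
            for k in range(i, j):
                out[present[k]] = avg
            i = j
        absent_rank = len(present) + (s_union - len(present) + 1) / 2
        for s in union:
            out.setdefault(s, absent_rank)
        return out

    ra, rb = ranks(census_a), ranks(census_b)
    return sum(abs(ra[s] - rb[s]) for s in union) / (s_union * s_union)


class TestRichnessDifference:
    def test_subset_loss(self):
        a = frozenset("wxyz")
        b = frozenset("wx")
        assert richness_difference(a, b) == pytest.approx(-0.5)

    def test_identical_sets_give_zero(self):
        assert richness_difference(frozenset("abc"), frozenset("abc")) == 0.0

    def test_disjoint_gain(self):
        assert richness_difference(frozenset("a"), frozenset("bcd")) == pytest.approx(0.5)

    def test_shared_denominator_mode(self):
        # the "shared" variant violates the [-1, 1] bound: (1-3)/1 = -2
        a, b = frozenset("abc"), frozenset("a")
        assert richness_difference(a, b, denominator="shared") == pytest.approx(-2.0)
        assert math.isnan(
            richness_difference(frozenset("a"), frozenset("b"), denominator="shared")
        )

    def test_bounded_and_antisymmetric_on_random_pairs(self):
        rng = np.random.default_rng(99)
        for a, b in random_species_sets(rng, pool=25, n_pairs=1000, allow_empty=True):
            d = richness_difference(a, b)
            assert -1.0 <= d <= 1.0
            assert richness_difference(b, a) == pytest.approx(-d)
            if len(a) == len(b):
                assert d == 0.0

    def test_both_empty_is_undefined(self):
        with pytest.raises(UndefinedComparisonError):
            richness_difference(frozenset(), frozenset())


class TestRankDifference:
    def test_identical_censuses_zero(self):
        c = {"x": 10.0, "y": 3.0, "z": 1.0}
        assert rank_difference(c, c) == 0.0

    def test_full_swap_of_two_species(self):
        # ranks swap: mean |delta relative rank| = ((1/2) + (1/2)) / 2 = 0.5
        assert rank_difference({"x": 10, "y": 1}, {"x": 1, "y": 10}) == pytest.approx(0.5)

    def test_species_absent_from_both_contributes_nothing(self):
        assert rank_difference({"x": 5}, {"x": 5}) == 0.0
        assert rank_difference({"x": 5, "y": 0}, {"x": 5}) == 0.0

    def test_symmetry_and_scale_invariance(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            n = int(rng.integers(1, 12))
            names = [f"sp{i}" for i in range(n + 3)]
            a = {s: float(rng.integers(0, 8)) for s in rng.choice(names, n, replace=False)}
            b = {s: float(rng.integers(0, 8)) for s in rng.choice(names, n, replace=False)}
            if not any(v > 0 for v in (*a.values(), *b.values())):
                continue
            d = rank_difference(a, b)
            assert rank_difference(b, a) == pytest.approx(d, abs=1e-12)
            scaled = {s: 7.5 * v for s, v in a.items()}
            assert rank_difference(scaled, b) == pytest.approx(d, abs=1e-12)

    def test_matches_naive_rank_assigner(self):
        rng = np.random.default_rng(17)
        for _ in range(300):
            n = int(rng.integers(1, 10))
            names = [f"sp{i}" for i in range(12)]
            a = {s: float(rng.integers(1, 6)) for s in rng.choice(names, n, replace=False)}
            b = {s: float(rng.integers(1, 6)) for s in rng.choice(names, n, replace=False)}
            assert rank_difference(a, b) == pytest.approx(
                naive_rank_difference(a, b), abs=1e-12
            )

    def test_negative_abundance_rejected(self):
        with pytest.raises(ValidationError):
            rank_difference({"x": -1.0}, {"x": 1.0})


class TestSeriesSummaries:
    def test_median_richness_examples(self, make_series):
        rows = []
        for year, n in [(2000, 10), (2001, 12), (2002, 20)]:
            rows += [(year, "p1", f"sp{i}", 1) for i in range(n)]
        assert median_richness(make_series(rows)) == 12
        rows = []
        for year, n in [(2000, 10), (2001, 20)]:
            rows += [(year, "p1", f"sp{i}", 1) for i in range(n)]
        assert median_richness(make_series(rows)) == 15

    def test_rac_series_and_medians(self, three_year_series):
        pairs = rac_series(three_year_series)
        assert len(pairs) == 2
        assert [(p.year_from, p.year_to) for p in pairs] == [(2000, 2005), (2005, 2010)]
        med = summarize_rac(pairs)
        expected = sorted(p.richness_diff for p in pairs)
        assert med["median_richness_diff"] == pytest.approx(sum(expected) / 2)

    def test_single_pair_medians_equal_pair(self, make_series):
        rows = [(2000, "p1", "a", 3), (2000, "p1", "b", 1), (2001, "p1", "a", 1)]
        pairs = rac_series(make_series(rows))
        med = summarize_rac(pairs)
        assert med["median_richness_diff"] == pytest.approx(pairs[0].richness_diff)
        assert med["median_rank_diff"] == pytest.approx(pairs[0].rank_diff)
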