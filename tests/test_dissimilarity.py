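"""Jaccard partition: closed forms, oracle equivalence and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from betachron import (
    UndefinedComparisonError,
    ValidationError,
    abc_counts,
    beta_partition,
    beta_series,
    census_species_set,
    consecutive_pairs,
    summarize_median,
)
from conftest import random_species_sets


def jaccard_by_enumeration(a, b):
    """Independent oracle: 1 - |A∩B| / |A∪B| by explicit set enumeration."""
    union = a | b
    shared = sum(1 for s in union if s in a and s in b)
    return 1.0 - shared / len(union)


class TestAbcCounts:
    def test_set_arithmetic(self):
        assert abc_counts({"x", "y", "z"}, {"y", "z", "w"}) == (2, 1, 1)

    def test_identity_and_disjoint(self):
        assert abc_counts({"x", "y"}, {"x", "y"}) == (2, 0, 0)
        assert abc_counts({"x"}, {"y", "z"}) == (0, 1, 2)

    def test_both_empty_is_undefined(self):
        with pytest.raises(UndefinedComparisonError):
            abc_counts(frozenset(), frozenset())


class TestBetaPartition:
    @pytest.mark.parametrize(
        "abc, expected",
        [
            ((2, 1, 1), (0.5, 0.5, 0.0)),       # balanced replacement
            ((2, 2, 0), (0.5, 0.0, 0.5)),       # poorer census nested in richer
            ((4, 0, 0), (0.0, 0.0, 0.0)),       # identical censuses
            ((0, 3, 2), (1.0, 1.0, 0.0)),       # complete replacement
        ],
    )
    def test_closed_forms(self, abc, expected):
        assert beta_partition(*abc) == pytest.approx(expected, abs=1e-15)

    def test_all_zero_undefined(self):
        with pytest.raises(UndefinedComparisonError):
            beta_partition(0, 0, 0)

    def test_jaccard_matches_enumeration_oracle(self):
        rng = np.random.default_rng(2024)
        for a, b in random_species_sets(rng, pool=30, n_pairs=1000, allow_empty=True):
            jac, jtu, jne = beta_partition(*abc_counts(a, b))
            assert jac == pytest.approx(jaccard_by_enumeration(a, b), abs=1e-12)
            assert abs(jac - (jtu + jne)) < 1e-12

    @given(
        a=st.integers(min_value=0, max_value=50),
        b=st.integers(min_value=0, max_value=50),
        c=st.integers(min_value=0, max_value=50),
    )
    @settings(max_examples=300, derandomize=True)
    def test_partition_identity_bounds_and_symmetry(self, a, b, c):
        if a + b + c == 0:
            return
        jac, jtu, jne = beta_partition(a, b, c)
        assert abs(jac - (jtu + jne)) < 1e-12
        assert 0.0 <= jtu <= jac <= 1.0
        assert jne >= 0.0
        # all three components invariant under swapping the censuses
        assert beta_partition(a, c, b) == pytest.approx((jac, jtu, jne), abs=1e-15)

    def test_nestedness_monotone_when_no_replacement(self):
        for a in (1, 3, 10):
            jnes = [beta_partition(a, b, 0)[2] for b in range(0, 15)]
            jtus = [beta_partition(a, b, 0)[1] for b in range(0, 15)]
            assert all(t == 0.0 for t in jtus)
            assert all(x < y for x, y in zip(jnes, jnes[1:]))


class TestSeriesLevel:
    def test_census_species_set_semantics(self, make_series):
        s = make_series(
            [(2000, "p1", "sp1", 2), (2000, "p2", "sp1", 1), (2000, "p1", "sp2", 1)]
        )
        assert census_species_set(s, 2000) == {"sp1", "sp2"}
        with pytest.raises(ValidationError):
            census_species_set(s, 1999)

    def test_consecutive_pairs_span_calendar_gaps(self, three_year_series):
        assert consecutive_pairs(three_year_series) == [(2000, 2005), (2005, 2010)]

    def test_n_minus_one_pairs(self, make_series):
        s = make_series([(y, "p1", f"sp{y}", 1) for y in range(2000, 2005)])
        assert len(consecutive_pairs(s)) == 4
        assert len(beta_series(s).pairs) == 4

    def test_single_year_is_error(self, make_series):
        s = make_series([(2000, "p1", "sp1", 1)])
        with pytest.raises(ValidationError):
            consecutive_pairs(s)

    def test_pair_values_and_gap(self, three_year_series):
        bs = beta_series(three_year_series)
        p0 = bs.pairs[0]
        # {sp1,sp2,sp3} vs {sp2,sp3,sp4}: a=2, b=1, c=1
        assert (p0.a, p0.b, p0.c) == (2, 1, 1)
        assert p0.gap == 5
        assert p0.beta_jac == pytest.approx(0.5)

    def test_median_summaries(self, make_series):
        # construct series of pairwise values via known compositions
        bs = beta_series(
            make_series(
                [
                    (2000, "p1", "a", 1), (2000, "p1", "b", 1),
                    (2001, "p1", "a", 1), (2001, "p1", "b", 1),  # identical: 0.0
                    (2002, "p1", "c", 1), (2002, "p1", "d", 1),  # disjoint: 1.0
                    (2003, "p1", "c", 1), (2003, "p1", "e", 1),  # (1,1,1): 2/3
                ]
            )
        )
        med = summarize_median(bs)
        vals = sorted(p.beta_jac for p in bs.pairs)
        assert vals == pytest.approx([0.0, 2 / 3, 1.0])
        assert med["median_beta_jac"] == pytest.approx(2 / 3)

    def test_even_count_median_is_midpoint(self, make_series):
        rows = [(2000, "p1", sp, 1) for sp in "abcde"]
        rows += [(2001, "p1", sp, 1) for sp in "abcd"]   # (4,1,0) -> 0.2
        rows += [(2002, "p1", sp, 1) for sp in "abce"]   # (3,1,1) -> 0.4
        med = summarize_median(beta_series(make_series(rows)))
        assert med["median_beta_jac"] == pytest.approx(0.3)

    def test_single_pair_median_equals_pair(self, make_series):
        rows = [(2000, "p1", sp, 1) for sp in "abc"]
        rows += [(2001, "p1", sp, 1) for sp in "bcd"]
        bs = beta_series(make_series(rows))
        med = summarize_median(bs)
        assert med["median_beta_jac"] == pytest.approx(bs.pairs[0].beta_jac)
        assert med["median_beta_jtu"] == pytest.approx(bs.pairs[0].beta_jtu)
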