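"""Temporal alpha diversity and rank-abundance-curve (RAC) change metrics.

Two complementary views of how an assemblage changes between consecutive
censuses without invoking composition directly:

* **richness difference** — later richness minus earlier richness, scaled by
  the size of the union of the two censuses, so the value is bounded in
  [-1, 1] with 0 meaning no richness change;
* **rank difference** — mean absolute change in species' relative abundance
  ranks: within each census, present species are ranked by descending
  abundance (ties receive the average rank) and species absent from a census
  share the tied bottom rank; ranks are divided by the union size so the
  metric is scale-free and symmetric.

Rank difference is sensitive to the shuffling of species abundances even
when richness and composition are static, which makes it informative for
invasion dynamics where alien species change their abundances over time.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Mapping

import numpy as np
from scipy.stats import rankdata

from .core import AssemblageTimeSeries, UndefinedComparisonError, ValidationError
from .dissimilarity import consecutive_pairs

__all__ = [
    "RacDifference",
    "median_richness",
    "richness_difference",
    "rank_difference",
    "rac_series",
    "summarize_rac",
]


@dataclass(frozen=True)
class RacDifference:
    """Richness and rank change across one consecutive-census pair."""

    year_from: int
    year_to: int
    richness_diff: float
    rank_diff: float


def median_richness(series: AssemblageTimeSeries) -> float:
    """Median over census years of per-census species richness."""
    richness = series.richness_by_year()
    if not richness:
        raise ValidationError(f"study {series.study_id!r}: no censuses")
    return float(median(richness.values()))


def richness_difference(
    set_a: frozenset | set,
    set_b: frozenset | set,
    denominator: str = "union",
) -> float:
    """(S_B - S_A) / denominator; positive means richness gain.

    ``denominator="union"`` (default) divides by |A ∪ B|, which guarantees a
    value in [-1, 1] that is 0 for equal-richness pairs and antisymmetric
    under swapping the censuses.  ``denominator="shared"`` divides by |A ∩ B|
    instead; that variant is unbounded and undefined for disjoint pairs, and
    is provided only for comparison.
    """
    if not set_a and not set_b:
        raise UndefinedComparisonError("both censuses empty: richness difference undefined")
    diff = len(set_b) - len(set_a)
    if denominator == "union":
        return diff / len(set_a | set_b)
    if denominator == "shared":
        shared = len(set_a & set_b)
        if shared == 0:
            return float("nan")
        return diff / shared
    raise ValueError(f"unknown denominator mode {denominator!r}")


def _relative_ranks(census: Mapping[str, float], union: list[str]) -> np.ndarray:
    """Relative rank (rank / union size) for every species in ``union``.

    Present species are ranked 1..S_present by descending abundance with
    average ranks for ties; absent species share the tied rank
    S_present + (S_union - S_present + 1) / 2.
    """
    s_union = len(union)
    present = [s for s in union if census.get(s, 0) > 0]
    ranks = np.empty(s_union)
    absent_rank = len(present) + (s_union - len(present) + 1) / 2
    present_rank = dict(
        zip(present, rankdata([-census[s] for s in present], method="average"))
    )
    for i, s in enumerate(union):
        ranks[i] = present_rank.get(s, absent_rank)
    return ranks / s_union


def rank_difference(
    census_a: Mapping[str, float], census_b: Mapping[str, float]
) -> float:
    """Mean absolute change in relative abundance rank over the union.

    Symmetric in its arguments; zero iff the censuses share the same species
    and the same rank order; invariant to rescaling either census's
    abundances by a positive constant.
    """
    for census in (census_a, census_b):
        if any(v < 0 for v in census.values()):
            raise ValidationError("negative abundance in census")
    union = sorted(
        {s for s, v in census_a.items() if v > 0} | {s for s, v in census_b.items() if v > 0}
    )
    if not union:
        raise UndefinedComparisonError("both censuses empty: rank difference undefined")
    ra = _relative_ranks(census_a, union)
    rb = _relative_ranks(census_b, union)
    return float(np.mean(np.abs(ra - rb)))


def rac_from_censuses(abund_by_year: Mapping[int, Mapping[str, float]]) -> list[RacDifference]:
    """Richness/rank differences from a year -> {species: abundance} mapping."""
    years = sorted(abund_by_year)
    out = []
    for y0, y1 in zip(years[:-1], years[1:]):
        a, b = abund_by_year[y0], abund_by_year[y1]
        sa = frozenset(s for s, v in a.items() if v > 0)
        sb = frozenset(s for s, v in b.items() if v > 0)
        out.append(
            RacDifference(
                year_from=y0,
                year_to=y1,
                richness_diff=richness_difference(sa, sb),
                rank_diff=rank_difference(a, b),
            )
        )
    return out


def rac_series(series: AssemblageTimeSeries) -> list[RacDifference]:
    """Richness/rank differences for every consecutive-census pair."""
    consecutive_pairs(series)  # validates >= 2 censuses with the study id
    abund = {y: series.abundance_in_year(y) for y in series.years}
    return rac_from_censuses(abund)


def summarize_rac(pairs: list[RacDifference]) -> dict[str, float]:
    """Median richness difference and rank difference over consecutive pairs."""
    if not pairs:
        raise ValidationError("no pairs to summarize")
    return {
        "median_richness_diff": float(median(p.richness_diff for p in pairs)),
        "median_rank_diff": float(median(p.rank_diff for p in pairs)),
    }
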