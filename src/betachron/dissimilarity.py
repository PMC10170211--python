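"""Jaccard temporal beta diversity, partitioned into turnover and nestedness.

For two presence/absence censuses with ``a`` shared species, ``b`` unique to
the earlier census and ``c`` unique to the later one, the pairwise Jaccard
family decomposes as

    beta_jac = (b + c) / (a + b + c)
    beta_jtu = 2 * min(b, c) / (a + 2 * min(b, c))        (turnover)
    beta_jne = beta_jac - beta_jtu                         (nestedness)

Turnover quantifies species replacement independent of richness change;
nestedness captures dissimilarity due to richness difference when the poorer
census is a subset of the richer one.  Comparisons are made between
consecutive censuses (adjacent entries of the observed year sequence, which
may span calendar gaps), and each assemblage is summarized by the median of
each component over its pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from .core import AssemblageTimeSeries, UndefinedComparisonError, ValidationError

__all__ = [
    "PairwiseBeta",
    "BetaSeries",
    "census_species_set",
    "abc_counts",
    "beta_partition",
    "consecutive_pairs",
    "beta_series",
    "summarize_median",
]


@dataclass(frozen=True)
class PairwiseBeta:
    """One consecutive-census comparison."""

    year_from: int
    year_to: int
    gap: int
    a: int
    b: int
    c: int
    beta_jac: float
    beta_jtu: float
    beta_jne: float


@dataclass(frozen=True)
class BetaSeries:
    study_id: str
    pairs: tuple[PairwiseBeta, ...]


def census_species_set(series: AssemblageTimeSeries, year: int) -> frozenset:
    """Distinct species with abundance > 0 in one census (post-rarefaction)."""
    return series.species_in_year(year)


def abc_counts(set_a: frozenset | set, set_b: frozenset | set) -> tuple[int, int, int]:
    """Incidence bookkeeping: shared count and the two unique counts."""
    if not set_a and not set_b:
        raise UndefinedComparisonError("both censuses empty: comparison undefined")
    a = len(set_a & set_b)
    return a, len(set_a) - a, len(set_b) - a


def beta_partition(a: int, b: int, c: int) -> tuple[float, float, float]:
    """(beta_jac, beta_jtu, beta_jne) from incidence counts.

    The partition identity beta_jac = beta_jtu + beta_jne holds exactly in
    exact arithmetic; when ``min(b, c) = 0`` the turnover component is zero
    by definition (no replacement — one census is a subset of the other).
    """
    if a < 0 or b < 0 or c < 0:
        raise ValidationError("incidence counts must be non-negative")
    total = a + b + c
    if total == 0:
        raise UndefinedComparisonError("a = b = c = 0: comparison undefined")
    beta_jac = (b + c) / total
    m = min(b, c)
    beta_jtu = 0.0 if m == 0 else 2 * m / (a + 2 * m)
    return beta_jac, beta_jtu, beta_jac - beta_jtu


def consecutive_pairs(series: AssemblageTimeSeries) -> list[tuple[int, int]]:
    """Adjacent pairs of the sorted distinct census years.

    "Consecutive" means adjacent censuses, not adjacent calendar years: a
    study censused in 1990, 1995 and 2000 yields (1990, 1995), (1995, 2000).
    """
    years = series.years
    if len(years) < 2:
        raise ValidationError(
            f"study {series.study_id!r}: need >= 2 census years, have {len(years)}"
        )
    return list(zip(years[:-1], years[1:]))


def beta_series_from_censuses(
    study_id: str, censuses: dict[int, frozenset]
) -> BetaSeries:
    """BetaSeries from a year -> species-set mapping (adjacent-pair order).

    Pairs in which both censuses are empty (possible only on degenerate
    input) raise :class:`UndefinedComparisonError`.
    """
    years = sorted(censuses)
    if len(years) < 2:
        raise ValidationError(
            f"study {study_id!r}: need >= 2 census years, have {len(years)}"
        )
    pairs = []
    for y0, y1 in zip(years[:-1], years[1:]):
        a, b, c = abc_counts(censuses[y0], censuses[y1])
        jac, jtu, jne = beta_partition(a, b, c)
        pairs.append(
            PairwiseBeta(
                year_from=y0, year_to=y1, gap=y1 - y0,
                a=a, b=b, c=c, beta_jac=jac, beta_jtu=jtu, beta_jne=jne,
            )
        )
    return BetaSeries(study_id=study_id, pairs=tuple(pairs))


def beta_series(series: AssemblageTimeSeries) -> BetaSeries:
    """All consecutive-census comparisons for one assemblage."""
    grouped = series.records.groupby("year")["species"]
    censuses = {int(y): frozenset(sp) for y, sp in grouped.unique().items()}
    return beta_series_from_censuses(series.study_id, censuses)


def summarize_median(bs: BetaSeries) -> dict[str, float]:
    """Component-wise medians over pairs: one summary value per assemblage.

    Even pair counts use the midpoint of the two central values.
    """
    if not bs.pairs:
        raise ValidationError(f"study {bs.study_id!r}: no pairs to summarize")
    return {
        "median_beta_jac": float(median(p.beta_jac for p in bs.pairs)),
        "median_beta_jtu": float(median(p.beta_jtu for p in bs.pairs)),
        "median_beta_jne": float(median(p.beta_jne for p in bs.pairs)),
    }
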