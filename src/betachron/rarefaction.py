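"""Sample-based rarefaction: equalize sampling effort across census years.

Diversity metrics are only comparable over time when each census rests on
the same number of sampling units.  The sampling unit here is the plot: for
each year we keep a uniform random subset of plots of fixed size (the
minimum effort observed in any year) and drop all records from unchosen
plots.  Studies whose effort is already constant pass through untouched.
"""

from __future__ import annotations

import zlib

import numpy as np

from .core import AssemblageTimeSeries, ValidationError

__all__ = ["min_effort", "rarefy", "rarefy_to_min"]


def min_effort(series: AssemblageTimeSeries) -> int:
    """Minimum over years of the number of distinct plots sampled."""
    effort = series.effort_by_year
    if not effort:
        raise ValidationError(f"study {series.study_id!r}: no records")
    return min(effort.values())


def _series_rng(series: AssemblageTimeSeries, seed: int) -> np.random.Generator:
    # study-keyed stream: the draw for one study does not depend on how many
    # other studies were processed before it
    return np.random.default_rng([int(seed), zlib.crc32(str(series.study_id).encode())])


def rarefy(
    series: AssemblageTimeSeries, n_samples: int, seed: int
) -> AssemblageTimeSeries:
    """Keep exactly ``n_samples`` uniformly chosen plots in every year.

    Deterministic given (series, n_samples, seed).  Years that already have
    exactly ``n_samples`` plots keep all of them regardless of the seed.

    Raises
    ------
    ValidationError
        If ``n_samples`` exceeds the effort of any year (the error names the
        year) or is < 1.
    """
    if n_samples < 1:
        raise ValidationError("n_samples must be >= 1")
    effort = series.effort_by_year
    for year in sorted(effort):
        if effort[year] < n_samples:
            raise ValidationError(
                f"study {series.study_id!r}: year {year} has {effort[year]} plot(s), "
                f"fewer than n_samples={n_samples}"
            )
    rng = _series_rng(series, seed)
    rec = series.records
    keep_mask = np.zeros(len(rec), dtype=bool)
    years = rec["year"].to_numpy()
    plots = rec["plot_id"].to_numpy()
    for year in sorted(effort):
        in_year = years == year
        year_plots = np.unique(plots[in_year])
        if len(year_plots) == n_samples:
            chosen = year_plots
        else:
            chosen = rng.choice(year_plots, size=n_samples, replace=False)
        keep_mask |= in_year & np.isin(plots, chosen)
    return series.with_records(rec.loc[keep_mask])


def rarefy_to_min(series: AssemblageTimeSeries, seed: int) -> AssemblageTimeSeries:
    """Rarefy a study to its minimum yearly effort.

    Applied only where effort varies among years; constant-effort studies
    are returned unchanged (no randomness consumed).
    """
    effort = series.effort_by_year
    values = set(effort.values())
    if len(values) <= 1:
        return series
    return rarefy(series, min(values), seed)
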