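import numpy as np
import pandas as pd
import pytest

from betachron.core import AssemblageTimeSeries


def build_series(
    rows,
    study_id="study1",
    latitude=10.0,
    longitude=20.0,
    region="Testland",
):
    """Series from (year, plot, species, abundance) tuples."""
    records = pd.DataFrame(rows, columns=["year", "plot_id", "species", "abundance"])
    return AssemblageTimeSeries(
        study_id=study_id,
        records=records,
        latitude=latitude,
        longitude=longitude,
        region=region,
    )


@pytest.fixture
def make_series():
    return build_series


@pytest.fixture
def three_year_series():
    """One plot per year, three censuses, gradual species replacement."""
    rows = [
        (2000, "p1", "sp1", 3), (2000, "p1", "sp2", 1), (2000, "p1", "sp3", 2),
        (2005, "p1", "sp2", 2), (2005, "p1", "sp3", 1), (2005, "p1", "sp4", 4),
        (2010, "p1", "sp3", 5), (2010, "p1", "sp4", 1), (2010, "p1", "sp5", 2),
    ]
    return build_series(rows)


@pytest.fixture
def uneven_effort_series():
    """Effort 5 / 3 / 4 plots across three years; species spread over plots."""
    rng = np.random.default_rng(7)
    rows = []
    for year, n_plots in [(2000, 5), (2001, 3), (2002, 4)]:
        for j in range(n_plots):
            for sp in range(1 + (j % 3), 6):
                rows.append((year, f"p{j + 1}", f"sp{sp}", int(rng.integers(1, 9))))
    return build_series(rows)


def random_species_sets(rng, pool=30, n_pairs=1000, allow_empty=False):
    """Random census-set pairs over a small pool, skipping empty-empty."""
    pool_names = [f"sp{i}" for i in range(pool)]
    pairs = []
    while len(pairs) < n_pairs:
        pa, pb = rng.uniform(0.05, 0.9, size=2)
        a = frozenset(s for s in pool_names if rng.random() < pa)
        b = frozenset(s for s in pool_names if rng.random() < pb)
        if not a and not b:
            continue
        if not allow_empty and (not a or not b):
            continue
        pairs.append((a, b))
    return pairs
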