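"""Monte-Carlo evaluation of the pipeline on simulated corpora.

Used to answer calibration questions about the whole analysis chain
(simulate -> flag aliens -> filter -> rarefy -> metrics -> group model):
with what power does the group contrast detect a known elevated-turnover
scenario, and does it hold its nominal type-I rate when both groups share
the same generating parameters?  Each replicate simulates a full study set
under a scenario config, runs the standard summary pipeline and fits the
group model; replicates differ only in their seed.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import pandas as pd

from .curation import assign_alien_status, filter_studies
from .inference import TermResult, fit_group_model
from .pipeline import analyze_series
from .simulate import SimulationConfig, simulate_study_set

__all__ = ["simulate_and_summarize", "alien_term_tests", "monte_carlo_alien"]


def simulate_and_summarize(config: SimulationConfig) -> pd.DataFrame:
    """One replicate: simulated corpus -> per-assemblage summary table."""
    ss = simulate_study_set(config)
    flagged = [assign_alien_status(s, ss.checklist) for s in ss.series]
    kept, _ = filter_studies(flagged)
    return analyze_series(kept, seed=config.seed)["summaries"]


def alien_term_tests(
    config: SimulationConfig, responses: Sequence[str]
) -> dict[str, TermResult]:
    """Alien-term coefficient and test for each response, one replicate."""
    summaries = simulate_and_summarize(config)
    return {r: fit_group_model(summaries, r).alien for r in responses}


def monte_carlo_alien(
    config_factory: Callable[[int], SimulationConfig],
    seeds: Iterable[int],
    responses: Sequence[str],
) -> pd.DataFrame:
    """Alien-term results over a seed grid: one row per (seed, response)."""
    rows = []
    for seed in seeds:
        for response, term in alien_term_tests(config_factory(seed), responses).items():
            rows.append(
                {"seed": seed, "response": response, "coef": term.coef, "p": term.p}
            )
    return pd.DataFrame(rows)
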