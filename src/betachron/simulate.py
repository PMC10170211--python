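"""Synthetic assemblage time series with controlled change channels.

The generator emulates the structure of multi-plot vegetation monitoring
data: each study is a community assembled from a regional species pool with
lognormal abundances, censused annually with a varying number of plots, and
written in the same long-format dialect the readers ingest.  Three channels
of temporal change are controlled independently:

* **composition** — each census, every resident species goes locally extinct
  with a per-group probability and new species immigrate from the pool
  (immigration/extinction balance in the island-biogeography sense), so the
  expected richness stays at its starting value while the *rate* of species
  replacement scales with the extinction rate;
* **rank shuffling** — within a census, species are ranked by a noisy score
  and the (fixed) abundance multiset is dealt out in that order, so rank
  order churns from census to census without altering the abundance
  distribution itself (and hence without altering detectability);
* **alien presence** — every study carries a few rare "injected" species
  persisting through the series at a small total relative abundance; in
  invaded studies they are drawn from the alien pool (aliens are typically
  rare in invaded assemblages), in uninvaded studies from the native pool.
  Both groups therefore share the same community structure — same expected
  richness, same abundance distribution, same dynamics — and differ only in
  whether the rare members carry the alien label, so the label itself is
  metric-neutral when the dynamic rates are matched.

Everything is reproducible from a single integer seed; each study gets its
own RNG stream derived from (seed, study index).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import AlienChecklist, AssemblageTimeSeries, ValidationError
from .io import write_checklist, write_occurrence_table

__all__ = [
    "SimulationConfig",
    "StudySet",
    "simulate_assemblage",
    "simulate_study_set",
    "write_study_set",
    "headline_config",
    "rank_channel_config",
    "null_config",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of the synthetic community generator.

    Defaults define the reference scenario: 20 invaded + 20 uninvaded
    studies, 10 annual censuses, richness held near 30 species, invaded
    assemblages turning over twice as fast (extinction 0.30 vs 0.15 per
    species per census).
    """

    n_invaded: int = 20
    n_uninvaded: int = 20
    pool_size: int = 200
    s0: int = 30
    years: int = 10
    start_year: int = 2000
    extinction_rate_base: float = 0.15
    extinction_rate_invaded: float = 0.30
    #: expected immigrants per census; None balances immigration against the
    #: group's extinction rate (Poisson(rate * target richness)) so richness
    #: is mean-reverting to s0 in both groups
    immigration_rate: float | None = None
    #: SD of the rank-score noise (on the log-abundance scale) per census
    rank_noise: float = 0.25
    #: rank-score noise for invaded studies; None = same as rank_noise
    rank_noise_invaded: float | None = None
    #: minimum baseline abundance for a species to take part in rank
    #: reassignment; species this abundant are effectively never lost by
    #: plot subsampling, which keeps the rank channel orthogonal to the
    #: presence/absence (beta) channel
    rank_shuffle_floor: int = 8
    alien_pool_fraction: float = 0.10
    #: target total relative abundance of aliens in invaded assemblages
    alien_rel_abundance: float = 0.03
    n_aliens: int = 2
    plots_per_year: tuple[int, int] = (3, 6)
    coords_box: tuple[tuple[float, float], tuple[float, float]] = (
        (-40.0, 60.0),
        (-120.0, 150.0),
    )
    region: str = "Simulia"
    abundance_logmean: float = 2.0
    abundance_logsd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("extinction_rate_base", "extinction_rate_invaded", "alien_pool_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} must be a probability in [0, 1]")
        if not 0.0 <= self.alien_rel_abundance < 1.0:
            raise ValidationError("alien_rel_abundance must be in [0, 1)")
        if self.years < 3:
            raise ValidationError("years must be >= 3 so generated studies pass the study filter")
        if self.s0 > self.pool_size:
            raise ValidationError("s0 cannot exceed pool_size")
        n_alien_pool = self._n_alien_pool
        if self.n_aliens > n_alien_pool:
            raise ValidationError(
                f"n_aliens={self.n_aliens} exceeds the alien pool "
                f"({n_alien_pool} = alien_pool_fraction * pool_size)"
            )
        if self.s0 - self.n_aliens < 1:
            raise ValidationError("s0 must exceed n_aliens")
        lo, hi = self.plots_per_year
        if not 1 <= lo <= hi:
            raise ValidationError(f"plots_per_year range {self.plots_per_year} invalid")
        (lat_lo, lat_hi), (lon_lo, lon_hi) = self.coords_box
        if not (-90 <= lat_lo <= lat_hi <= 90 and -180 <= lon_lo <= lon_hi <= 180):
            raise ValidationError(f"coords_box {self.coords_box} outside valid degrees")

    @property
    def _n_alien_pool(self) -> int:
        return int(round(self.alien_pool_fraction * self.pool_size))

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown simulation option(s): {sorted(unknown)}")
        d = dict(d)
        for key in ("plots_per_year",):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if "coords_box" in d and d["coords_box"] is not None:
            d["coords_box"] = tuple(tuple(box) for box in d["coords_box"])
        return cls(**d)


def _pool_names(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(all names, alien indices, native indices) for the regional pool."""
    n_alien = config._n_alien_pool
    names = np.array(
        [f"Alienia simulata{i + 1:04d}" for i in range(n_alien)]
        + [f"Nativa communis{i + 1:04d}" for i in range(config.pool_size - n_alien)]
    )
    return names, np.arange(n_alien), np.arange(n_alien, config.pool_size)


def simulate_assemblage(
    config: SimulationConfig,
    invaded: bool,
    rng: np.random.Generator,
    study_id: str = "sim000",
) -> AssemblageTimeSeries:
    """Generate one study's assemblage time series.

    With extinction, immigration and rank noise all zero the community is
    frozen: every census records the identical species set and rank order.
    """
    names, alien_idx, native_idx = _pool_names(config)
    e_rate = config.extinction_rate_invaded if invaded else config.extinction_rate_base
    sigma = (
        config.rank_noise_invaded
        if (invaded and config.rank_noise_invaded is not None)
        else config.rank_noise
    )
    native_target = config.s0 - config.n_aliens

    mu = rng.normal(config.abundance_logmean, config.abundance_logsd, config.pool_size)
    # rare injected members: alien-pool species in invaded studies, native
    # species in uninvaded ones — identical structure, different label
    if invaded:
        injected = rng.choice(alien_idx, size=config.n_aliens, replace=False)
        resident_pool = native_idx
    else:
        injected = rng.choice(native_idx, size=config.n_aliens, replace=False)
        resident_pool = np.setdiff1d(native_idx, injected)
    current = rng.choice(resident_pool, size=native_target, replace=False)
    # persistent relative weights of the injected rare members
    injected_w = np.exp(rng.normal(0.0, 0.5, len(injected)))
    injected_w /= injected_w.sum()
    lo, hi = config.plots_per_year
    plot_names = np.array([f"plot{j + 1:02d}" for j in range(hi)])

    years_col, plots_col, species_col, abund_col = [], [], [], []
    for t in range(config.years):
        year = config.start_year + t
        if t > 0:
            survived = rng.random(len(current)) >= e_rate
            current = current[survived]
            lam = (
                config.immigration_rate
                if config.immigration_rate is not None
                else e_rate * native_target
            )
            n_imm = rng.poisson(lam)
            candidates = np.setdiff1d(resident_pool, current, assume_unique=False)
            n_imm = min(int(n_imm), len(candidates))
            if n_imm:
                current = np.concatenate(
                    [current, rng.choice(candidates, size=n_imm, replace=False)]
                )
        species_idx = current
        counts = np.empty(0, dtype=np.int64)
        if len(current):
            base = np.maximum(1, np.round(np.exp(mu[current]))).astype(np.int64)
            # deal the fixed abundance multiset out by noisy-score rank:
            # shuffles ranks without changing the abundance distribution.
            # Only comfortably-detectable species take part, so rank churn
            # cannot masquerade as composition change after plot subsampling
            counts = base.copy()
            mask = base >= config.rank_shuffle_floor
            n_shuffle = int(mask.sum())
            if n_shuffle > 1:
                scores = mu[current][mask] + rng.normal(0.0, sigma, n_shuffle)
                order = np.argsort(-scores)
                dealt = np.empty(n_shuffle, dtype=np.int64)
                dealt[order] = np.sort(base[mask])[::-1]
                counts[mask] = dealt
        if len(injected):
            resident_total = int(counts.sum()) if len(counts) else 0
            target = config.alien_rel_abundance / (1.0 - config.alien_rel_abundance)
            injected_total = max(len(injected), int(round(target * resident_total)))
            injected_counts = np.maximum(
                1, np.round(injected_total * injected_w)
            ).astype(np.int64)
            species_idx = np.concatenate([species_idx, injected])
            counts = np.concatenate([counts, injected_counts])
        if len(species_idx) == 0:
            continue
        k = int(rng.integers(lo, hi + 1))
        plate = rng.multinomial(counts, np.full(k, 1.0 / k))
        si, pj = np.nonzero(plate)
        years_col.append(np.full(len(si), year))
        plots_col.append(plot_names[pj])
        species_col.append(names[species_idx[si]])
        abund_col.append(plate[si, pj])

    records = pd.DataFrame(
        {
            "year": np.concatenate(years_col) if years_col else np.empty(0, dtype=int),
            "plot_id": np.concatenate(plots_col) if plots_col else np.empty(0, dtype=object),
            "species": np.concatenate(species_col) if species_col else np.empty(0, dtype=object),
            "abundance": np.concatenate(abund_col) if abund_col else np.empty(0, dtype=int),
        }
    )
    (lat_lo, lat_hi), (lon_lo, lon_hi) = config.coords_box
    return AssemblageTimeSeries(
        study_id=study_id,
        records=records,
        latitude=float(rng.uniform(lat_lo, lat_hi)),
        longitude=float(rng.uniform(lon_lo, lon_hi)),
        region=config.region,
    )


@dataclass
class StudySet:
    """A simulated corpus: series, the matching checklist, and ground truth."""

    series: list[AssemblageTimeSeries]
    checklist: AlienChecklist
    truth: pd.DataFrame
    config: SimulationConfig


def simulate_study_set(config: SimulationConfig) -> StudySet:
    """Generate ``n_invaded + n_uninvaded`` studies plus checklist and truth.

    Invaded studies come first in the id order.  The checklist lists every
    alien-pool species for the configured region, so downstream alien-status
    assignment recovers the generating labels exactly.
    """
    names, alien_idx, _ = _pool_names(config)
    series: list[AssemblageTimeSeries] = []
    truth_rows = []
    n_total = config.n_invaded + config.n_uninvaded
    for i in range(n_total):
        invaded = i < config.n_invaded
        rng = np.random.default_rng([int(config.seed), i])
        sid = f"sim{i + 1:03d}"
        s = simulate_assemblage(config, invaded, rng, study_id=sid)
        series.append(s)
        truth_rows.append(
            {
                "study_id": sid,
                "invaded": invaded,
                "extinction_rate": (
                    config.extinction_rate_invaded if invaded else config.extinction_rate_base
                ),
                "rank_noise": (
                    config.rank_noise_invaded
                    if (invaded and config.rank_noise_invaded is not None)
                    else config.rank_noise
                ),
                "latitude": s.latitude,
                "longitude": s.longitude,
                "n_censuses": s.n_censuses,
            }
        )
    checklist = AlienChecklist.from_pairs(
        (config.region, names[i]) for i in alien_idx
    )
    return StudySet(
        series=series,
        checklist=checklist,
        truth=pd.DataFrame(truth_rows),
        config=config,
    )


def write_study_set(study_set: StudySet, out_dir: str | Path) -> dict[str, Path]:
    """Write occurrence.csv, checklist.csv and truth.csv; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "occurrence": out / "occurrence.csv",
        "checklist": out / "checklist.csv",
        "truth": out / "truth.csv",
    }
    write_occurrence_table(study_set.series, paths["occurrence"])
    write_checklist(study_set.checklist, paths["checklist"])
    study_set.truth.to_csv(paths["truth"], index=False)
    return paths


# ------------------------------------------------------------- scenarios


def headline_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Reference scenario: invaded assemblages turn over faster (0.30 vs 0.15)."""
    return SimulationConfig(seed=seed, **overrides)


def rank_channel_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Rank-shuffling channel only: matched turnover, elevated rank noise in
    the invaded group."""
    defaults = dict(
        extinction_rate_invaded=SimulationConfig.extinction_rate_base,
        rank_noise_invaded=1.5,
    )
    defaults.update(overrides)
    return SimulationConfig(seed=seed, **defaults)


def null_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Null scenario: identical generating parameters in both groups (aliens
    still present in the invaded group, but dynamically neutral)."""
    defaults = dict(extinction_rate_invaded=SimulationConfig.extinction_rate_base)
    defaults.update(overrides)
    return SimulationConfig(seed=seed, **defaults)
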