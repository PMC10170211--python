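"""Generate a synthetic monitoring corpus and look at its structure.

Builds 4 invaded + 4 uninvaded assemblages (8 annual censuses each) from
the generator's reference scenario and writes them as the three CSVs the
pipeline ingests: a long-format occurrence table, a region-keyed alien
checklist, and a ground-truth table of generating parameters.
"""

from betachron import SimulationConfig, simulate_study_set, write_study_set

config = SimulationConfig(n_invaded=4, n_uninvaded=4, years=8, seed=42)
study_set = simulate_study_set(config)
paths = write_study_set(study_set, "scratch/example_corpus")

s = study_set.series[0]
print(f"{len(study_set.series)} studies written to: {sorted(p.name for p in paths.values())}")
print(f"checklist lists {len(study_set.checklist)} alien (region, species) pairs")
print(f"\nfirst study {s.study_id}: {s.n_censuses} censuses at "
      f"({s.latitude:.1f}, {s.longitude:.1f}) in region {s.region!r}")
print("plots per year (sampling effort):", s.effort_by_year)
print("species richness per year:", s.richness_by_year())

# Effort varies among years, richness hovers around s0 = 30: the community
# is at immigration/extinction balance, so composition churns while the
# species count stays roughly level.
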