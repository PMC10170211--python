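"""Full in-memory analysis: do invaded assemblages change faster?

Simulates the reference scenario (20 invaded studies with per-census
extinction 0.30 vs 0.15 in the 20 uninvaded ones, immigration balanced so
richness is stationary in both), runs the complete pipeline and fits the
group contrast metric ~ alien + latitude + longitude for each summary
metric.
"""

from betachron import headline_config
from betachron.inference import fit_group_model
from betachron.montecarlo import simulate_and_summarize

summaries = simulate_and_summarize(headline_config(seed=1))
flags = summaries["alien_flag"].astype(bool)

print(f"{len(summaries)} assemblages ({int(flags.sum())} invaded)\n")
print(f"{'metric':22s} {'invaded':>8} {'uninvaded':>10} {'alien coef':>11} {'p':>9}")
for metric in ("median_beta_jac", "median_beta_jtu", "median_beta_jne",
               "median_richness", "median_rank_diff"):
    inv = summaries.loc[flags, metric].median()
    uninv = summaries.loc[~flags, metric].median()
    term = fit_group_model(summaries, metric).alien
    print(f"{metric:22s} {inv:8.3f} {uninv:10.3f} {term.coef:11.4f} {term.p:9.2g}")

# Expected pattern: strongly positive, significant alien coefficients for
# total Jaccard and its turnover component; nestedness and richness
# indistinguishable between groups — elevated compositional change without
# an alpha-diversity signal.
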