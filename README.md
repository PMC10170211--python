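# betachron

Temporal beta diversity of ecological assemblages, stratified by alien
species presence.

`betachron` is a Python library for a question community ecologists keep
returning to: are assemblages that contain naturalized alien species
reshaped faster than assemblages without them?  It takes long-format
assemblage time series (study × year × plot × species × abundance, the
shape of large biodiversity time-series exports), curates them against a
synonym table and a region-keyed alien checklist, equalizes sampling
effort by sample-based rarefaction, measures between-census change, and
tests the invaded/uninvaded contrast at the assemblage level.  A built-in
community simulator generates corpora with known change rates so every
stage — and the whole chain — can be validated without external data.

## The metrics

For each pair of consecutive censuses (adjacent censuses of the observed
year sequence), with `a` shared species, `b` unique to the earlier and `c`
unique to the later census, Jaccard dissimilarity is partitioned into
species replacement and richness-driven change:

```
beta_jac = (b + c) / (a + b + c)                 total dissimilarity
beta_jtu = 2 min(b,c) / (a + 2 min(b,c))         turnover (replacement)
beta_jne = beta_jac - beta_jtu                   nestedness-resultant
```

Alongside these, richness difference `(S_B − S_A)/S_union` (bounded in
[−1, 1], 0 = no change) and a rank difference — the mean absolute change
in species' relative abundance ranks — capture the alpha-diversity and
abundance-reordering channels.  Each assemblage is summarized by the
median of each metric over its pairs, and the group contrast is fitted as

```
metric ~ intercept + alien_flag + latitude + longitude     (Gaussian GLM)
```

with Moran's I (inverse-distance weights, expectation −1/(n−1)),
distance-decay and within-series acceleration tests as spatial and
temporal diagnostics.

## A worked example

`examples/06_group_inference.py` simulates the reference scenario — 20
invaded studies whose species turn over at per-census extinction rate
0.30 versus 0.15 in 20 uninvaded studies, immigration balanced so
richness is stationary in both groups — and fits the contrast:

```
40 assemblages (20 invaded)

metric                  invaded  uninvaded  alien coef         p
median_beta_jac           0.446      0.277      0.1715     1e-15
median_beta_jtu           0.387      0.222      0.1682   4.4e-14
median_beta_jne           0.052      0.050      0.0002      0.98
median_richness          29.500     29.250      0.0125      0.99
median_rank_diff          0.271      0.198      0.0734   5.1e-14
```

Read: invaded assemblages show strongly elevated total Jaccard
dissimilarity, and the elevation is carried almost entirely by the
turnover component — species replacement — while nestedness and median
richness are indistinguishable between groups.  Rank shuffling is also
elevated.  That is the signature of compositional reorganization without
an alpha-diversity signal.

The other scripts in `examples/` each demonstrate one capability:
simulation (01), ingestion and curation (02), rarefaction (03), the
Jaccard partition (04), and rank metrics (05).

## Command line

A thin CLI wraps the pipeline for shell use:

```sh
betachron simulate -c sim.yaml -o corpus/ --seed 1
betachron run -c pipeline.yaml -o results/ [--period 2000 2016] [--plots]
betachron report -i results/
```

`run` writes per-pair tables, per-assemblage summaries, GLM / Moran's I /
distance-decay / acceleration tables, a JSON run manifest (seed, stage
counts, exclusions) and a markdown report.  Identical config + seed gives
byte-identical outputs.

## Layout

```
src/betachron/
  core.py           data types: assemblage series, synonym table, checklist
  io.py             CSV/TSV readers and writers (configurable dialect)
  curation.py       name standardization, alien status, study filters
  rarefaction.py    sample-based effort equalization
  dissimilarity.py  Jaccard turnover/nestedness partition
  rank.py           richness and rank-abundance change metrics
  inference.py      group GLM, Moran's I, distance decay, acceleration
  simulate.py       synthetic community generator
  montecarlo.py     replicate-level power / calibration evaluation
  pipeline.py       end-to-end orchestration and reporting
  cli.py            click front end
```
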