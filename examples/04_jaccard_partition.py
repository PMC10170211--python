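"""Partition consecutive-census Jaccard dissimilarity into its components.

Three archetypal census pairs show how the partition separates species
replacement (turnover) from richness-driven change (nestedness):
balanced replacement is pure turnover, subset loss is pure nestedness,
and the two components always sum to total Jaccard dissimilarity.
"""

from betachron import abc_counts, beta_partition, beta_series
from betachron.dissimilarity import summarize_median
import pandas as pd
from betachron import AssemblageTimeSeries

cases = {
    "balanced replacement": ({"a", "b", "c"}, {"b", "c", "d"}),
    "subset loss (nested)": ({"a", "b", "c", "d"}, {"a", "b"}),
    "complete replacement": ({"a", "b"}, {"x", "y", "z"}),
}
print(f"{'pair':24s} {'a':>2} {'b':>2} {'c':>2}  {'jac':>5} {'jtu':>5} {'jne':>5}")
for label, (early, late) in cases.items():
    a, b, c = abc_counts(early, late)
    jac, jtu, jne = beta_partition(a, b, c)
    print(f"{label:24s} {a:2d} {b:2d} {c:2d}  {jac:5.3f} {jtu:5.3f} {jne:5.3f}")

# Whole-series view: censuses at 2000/2005/2010 (consecutive *censuses*,
# not consecutive calendar years) give one comparison per adjacent pair,
# summarized by the median.
rows = [
    (2000, "p1", sp, 1) for sp in ("a", "b", "c")
] + [
    (2005, "p1", sp, 1) for sp in ("b", "c", "d")
] + [
    (2010, "p1", sp, 1) for sp in ("b", "d")
]
series = AssemblageTimeSeries(
    study_id="demo",
    records=pd.DataFrame(rows, columns=["year", "plot_id", "species", "abundance"]),
    latitude=0.0, longitude=0.0, region="XX",
)
bs = beta_series(series)
for p in bs.pairs:
    print(f"{p.year_from}->{p.year_to} (gap {p.gap}): "
          f"jac={p.beta_jac:.3f} jtu={p.beta_jtu:.3f} jne={p.beta_jne:.3f}")
print("assemblage medians:", summarize_median(bs))
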