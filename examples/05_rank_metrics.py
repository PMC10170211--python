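"""Richness-difference and rank-difference between censuses.

Rank difference is sensitive to abundance reordering even when the species
list is unchanged — the channel through which invasions can reshape a
community without changing its richness.
"""

from betachron import rank_difference, richness_difference

early = {"grass": 120, "herb": 40, "shrub": 12, "fern": 3}
same_species_reordered = {"grass": 15, "herb": 130, "shrub": 2, "fern": 44}
after_loss = {"grass": 110, "herb": 35}

print("same species, shuffled abundances:")
print("  richness_difference:",
      richness_difference(frozenset(early), frozenset(same_species_reordered)))
print("  rank_difference:    ",
      round(rank_difference(early, same_species_reordered), 4))

print("two species lost, ranks of the rest kept:")
print("  richness_difference:",
      richness_difference(frozenset(early), frozenset(after_loss)))
print("  rank_difference:    ", round(rank_difference(early, after_loss), 4))

# The first comparison changes ranks but not richness (richness_diff = 0,
# rank_diff > 0); the second changes richness (negative: species lost,
# scaled by the union size) and drags rank_diff up only through the two
# now-absent species sharing the tied bottom rank.
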