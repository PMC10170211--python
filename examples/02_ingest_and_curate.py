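"""Ingest a small occurrence table and curate it step by step.

Shows the curation chain on a hand-built table: reading the long-format
CSV, standardizing raw names through a synonym table, assigning alien
status from a region-keyed checklist, and applying the study-selection
filter (at least three census years, numerical abundance).
"""

import pathlib
import tempfile

from betachron import (
    AlienChecklist,
    SynonymTable,
    assign_alien_status,
    filter_studies,
    read_occurrence_table,
    standardize_names,
)

csv_text = """STUDY_ID,YEAR,PLOT,GENUS_SPECIES,ABUNDANCE,LATITUDE,LONGITUDE,REGION
cerrado1,2001,p1,Melinis minutiflora Beauv.,4,-21.9,-47.9,BR
cerrado1,2001,p1,Andropogon bicornis,11,-21.9,-47.9,BR
cerrado1,2004,p1,Andropogon bicornis,9,-21.9,-47.9,BR
cerrado1,2008,p1,Melinis minutiflora Beauv.,7,-21.9,-47.9,BR
cerrado1,2008,p1,Andropogon bicornis,6,-21.9,-47.9,BR
shortone,2001,p1,Andropogon bicornis,3,-20.0,-45.0,BR
shortone,2002,p1,Andropogon bicornis,2,-20.0,-45.0,BR
"""

with tempfile.TemporaryDirectory() as tmp:
    path = pathlib.Path(tmp) / "occ.csv"
    path.write_text(csv_text, encoding="utf-8")
    series = read_occurrence_table(path)

synonyms = SynonymTable({"Melinis minutiflora Beauv.": "Melinis minutiflora"})
checklist = AlienChecklist.from_pairs([("BR", "Melinis minutiflora")])

curated = []
for s in series:
    s, rep = standardize_names(s, synonyms)
    print(f"{s.study_id}: {rep.n_replaced} names standardized, "
          f"{len(rep.unmatched)} unmatched ({rep.unmatched})")
    curated.append(assign_alien_status(s, checklist))

kept, excluded = filter_studies(curated)
for s in kept:
    label = "with aliens" if s.alien_flag else "no aliens"
    print(f"retained {s.study_id}: years {s.years} -> {label} "
          f"(alien species: {sorted(s.alien_species)})")
for sid, reason in excluded.items():
    print(f"excluded {sid}: {reason}")

# cerrado1 is flagged invaded because Melinis minutiflora — alien in region
# BR — appears in at least one census; shortone fails the 3-year filter.
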