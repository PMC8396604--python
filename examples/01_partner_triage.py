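"""Triage the bundled cross-structure peptide-count table.

Applies the three partner rules (unique >=3 peptides, selected >50%
relative peptide difference, unique small <=25 kDa) to the 14 candidate
OTX2 partners detected in SVZ, RMS and visual cortex, then asks which of
the proteins shared by those three structures also pass in the choroid
plexus.
"""
from collections import defaultdict

from chptools import datasets, triage

by_structure = defaultdict(list)
for record in datasets.load_coip_records():
    by_structure[record.structure].append(record)

sets = {s: triage.high_confidence_set(recs) for s, recs in by_structure.items()}
report = triage.cross_structure(sets, require=["SVZ", "RMS", "VCx"], also=["ChP"])

print("high-confidence per structure:",
      {s: len(m) for s, m in sorted(sets.items())})
print(f"shared by SVZ+RMS+VCx: {len(report.common)} proteins")
shared_chp = sorted(report.also_common["ChP"])
print(f"of those, also in ChP: {len(shared_chp)} -> {', '.join(shared_chp)}")
# The 14 shared proteins are candidate ubiquitous partners of the bait; the
# 5 that also pass in the choroid plexus are candidate cell-autonomous ones.
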