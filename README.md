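# chptools

Analysis toolkit for studies of transcription-factor function in the adult
choroid plexus (ChP), built around the OTX2 knockdown/interactome design:
a bait protein is immunoprecipitated against an IgG control in several
brain structures, its gene is knocked down in conditional and constitutive
mouse models, and the resulting peptide-count, RNA-seq and qPCR tables are
mined for protein partners, concordant expression changes, enriched
functional terms and isoform switches.

`chptools` provides each of those desk-scale computations as a tested,
importable Python API, plus seeded synthetic-data generators that plant a
known ground truth for every stage.

## What it computes

**Partner triage** (`chptools.triage`). For each protein with `O` peptides
in the bait co-IP and `I` in the IgG control, the relative peptide
difference is rel∆ = (O − I)/O (exclusive detection scores 1; the
(O − I)/I variant is selectable). A protein is a putative partner when it
is *unique* (I = 0, O ≥ 3), *selected* (O ≥ 3, I ≥ 1 and rel∆ > 0.5), or a
*unique small* protein (I = 0, O ≥ 1, mass ≤ 25 kDa). Partner sets are
intersected across replicates and compared across structures.

**DE concordance** (`chptools.de`). Signed fold changes
(+kd/ctrl up, −ctrl/kd down, ±∞ sentinels for zero means), knockdown
percentages 100·(1 − kd/ctrl), strict p-adj < α significance filtering,
direction-consistent consensus across knockdown comparisons, Venn region
counts and external-list overlap.

**Enrichment** (`chptools.enrichment`). Upper-tail hypergeometric
over-representation P[X ≥ k] of a query set against term annotations over
a background, Benjamini–Hochberg adjusted.

**Isoform usage** (`chptools.isoforms`). Isoform fractions
IF = isoform count / gene total per condition, usage differences
dIF = IF_kd − IF_control, and switch calls (|dIF| ≥ 0.15 and BH-adjusted
p < 0.05 from a two-proportion test on pooled counts).

**qPCR** (`chptools.qpcr`). 2^−ΔΔCt relative quantification with a
reference gene and calibrator group, group means ± SEM and a t-test.

**Synthetic data** (`chptools.synthetic`). Pure-function generators
(Poisson peptide counts, log-normal mean reads, multinomial isoform
counts) with planted partners, consensus DE genes and isoform switches.

Small published measurement tables (cross-structure peptide counts for 14
candidate partners, top knockdown-regulated genes, secreted-factor
expression) ship with the package under `chptools.datasets`.

## Worked example

```python
from collections import defaultdict
from chptools import datasets, triage

by_structure = defaultdict(list)
for record in datasets.load_coip_records():
    by_structure[record.structure].append(record)
sets = {s: triage.high_confidence_set(recs) for s, recs in by_structure.items()}
report = triage.cross_structure(sets, require=["SVZ", "RMS", "VCx"], also=["ChP"])
print(len(report.common), sorted(report.also_common["ChP"]))
```

prints

```
14 ['ACOT11', 'FIG4', 'KCND3', 'PIKFYVE', 'VAC14']
```

— all 14 bundled candidates clear the high-confidence criterion (≥3 bait
peptides, rel∆ > 0.5) in each of the three non-cell-autonomous structures,
and exactly 5 of them also clear it in the choroid plexus, marking them as
candidate ubiquitous partners. Likewise

```python
from chptools import de
de.round_sig(de.signed_fold(444, 83), 2)    # -> -5.3  (5.3-fold decrease)
round(de.percent_knockdown(7924, 4143))     # -> 48    (48% knockdown)
```

The `examples/` directory holds one short script per capability
(`01_partner_triage.py` … `05_qpcr_ddct.py`); each builds or loads a small
input, runs the method and explains the numbers it prints. A thin CLI
mirrors the API: `chptools triage compare --counts counts.tsv
--require SVZ,RMS,VCx --also ChP --out membership.tsv`, and
`chptools simulate coip|de|isoforms --seed N --out DIR` writes synthetic
tables with their truth files.

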