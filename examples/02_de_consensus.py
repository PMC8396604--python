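"""Fold changes and cross-model consensus on simulated knockdown tables.

First recomputes signed fold changes and knockdown percentages from the
bundled published mean reads, then simulates three knockdown comparisons
with a planted consensus signature (42 genes up, 34 down) and recovers it.
"""
from chptools import datasets, de
from chptools.synthetic import DESimSpec, simulate_de

top = datasets.load_top_de_genes()
for gene in ("Slc1a6", "Gpx3", "Ngfr"):
    row = top[(top.gene_id == gene) & (top.comparison == "LV_cond")].iloc[0]
    fold = de.round_sig(de.signed_fold(row.mean_control, row.mean_kd), 2)
    print(f"{gene}: {row.mean_control:g} -> {row.mean_kd:g} mean reads, fold {fold:g}")
print("Otx2 exon-2 knockdown: "
      f"{round(de.percent_knockdown(7924, 4143))}% (LV ChP conditional)")

tables, truth = simulate_de(DESimSpec(seed=42))
sets = {c: de.significant(t, alpha=0.05) for c, t in tables.items()}
res = de.consensus_genes(sets, list(tables))
print(f"consensus across 3 comparisons: {len(res.up)} up, {len(res.down)} down "
      f"(planted 42 up, 34 down)")
# Positive folds are increases in the knockdown; negative folds use the
# reciprocal convention, so -5.3 means a 5.3-fold decrease.
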