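"""Relative quantification of a qPCR experiment by 2^-ddCt.

Builds a small Ct table for a target gene and the Hprt reference across
control and knockdown animals and reports per-group fold changes relative
to the control (calibrator) group.
"""
import pandas as pd

from chptools.qpcr import ddct_fold

rows = []
# control animals: target ~5 cycles after the reference
for i, (t, r) in enumerate([(25.1, 20.0), (25.4, 20.2), (24.9, 19.9),
                            (25.2, 20.1), (25.0, 20.0)]):
    rows += [(f"ctl{i}", "control", "Gpx3", t), (f"ctl{i}", "control", "Hprt", r)]
# knockdown animals: target ~3 cycles earlier => ~4-fold induction
for i, (t, r) in enumerate([(22.2, 20.1), (22.0, 19.8), (22.4, 20.2),
                            (21.9, 20.0), (22.1, 20.1)]):
    rows += [(f"kd{i}", "treated", "Gpx3", t), (f"kd{i}", "treated", "Hprt", r)]
table = pd.DataFrame(rows, columns=["sample_id", "group", "gene_id", "ct"])

res = ddct_fold(table, target_gene="Gpx3", reference_gene="Hprt",
                calibrator_group="control")
for row in res.group_stats.itertuples(index=False):
    print(f"{row.group}: mean fold {row.mean_fold:.2f} +/- {row.sem_fold:.2f} "
          f"(n={row.n})")
print(f"t-test p = {res.t_pvalue:.2e}")
# Folds are 2^-ddCt relative to the mean of the control group, whose
# geometric mean fold is exactly 1 by construction.
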