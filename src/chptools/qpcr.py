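"""Relative quantification of qPCR data by the 2^-ddCt method.

For every sample, the target gene's cycle threshold (Ct) is normalized to a
reference gene measured on the same plate (dCt = Ct_target - Ct_reference),
then to the mean dCt of a calibrator group (ddCt), and expressed as a fold
change 2^-ddCt.  Because the calibrator normalization subtracts the
calibrator mean on the log2 scale, the geometric mean of calibrator-group
folds is exactly 1.  Technical replicates are averaged on the Ct scale
before any normalization.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["DdctResult", "ddct_fold"]

REQUIRED_COLUMNS = ("sample_id", "group", "gene_id", "ct")


@dataclass(frozen=True)
class DdctResult:
    """Per-sample fold changes plus per-group summary statistics.

    ``per_sample`` has one row per sample (sample_id, group, dct, ddct,
    fold); ``group_stats`` holds mean fold, SEM and n per group;
    ``t_pvalue`` is the two-sample t-test on fold values when exactly two
    groups are present (NaN otherwise).
    """

    target_gene: str
    reference_gene: str
    calibrator_group: str
    per_sample: pd.DataFrame
    group_stats: pd.DataFrame
    t_pvalue: float


def ddct_fold(
    records: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    calibrator_group: str,
) -> DdctResult:
    """Relative expression of one target gene by 2^-ddCt.

    ``records`` is a long table ``sample_id, group, gene_id, ct``.  Samples
    missing either the target or the reference measurement are excluded
    with a warning.
    """
    missing = set(REQUIRED_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if not np.isfinite(records["ct"]).all():
        raise ValueError("all Ct values must be finite")

    sub = records[records["gene_id"].isin([target_gene, reference_gene])]
    # technical replicates collapse on the Ct scale
    ct = (
        sub.groupby(["sample_id", "group", "gene_id"], as_index=False)["ct"].mean()
    )
    wide = ct.pivot_table(
        index=["sample_id", "group"], columns="gene_id", values="ct"
    ).reset_index()
    for gene in (target_gene, reference_gene):
        if gene not in wide.columns:
            wide[gene] = math.nan
    incomplete = wide[wide[[target_gene, reference_gene]].isna().any(axis=1)]
    if not incomplete.empty:
        warnings.warn(
            f"{len(incomplete)} sample(s) missing target or reference Ct; excluded",
            stacklevel=2,
        )
        wide = wide.dropna(subset=[target_gene, reference_gene])

    wide = wide.copy()
    wide["dct"] = wide[target_gene] - wide[reference_gene]
    calibrator = wide[wide["group"] == calibrator_group]
    if calibrator.empty:
        raise ValueError(f"no samples in calibrator group {calibrator_group!r}")
    wide["ddct"] = wide["dct"] - calibrator["dct"].mean()
    wide["fold"] = 2.0 ** (-wide["ddct"])

    per_sample = wide[["sample_id", "group", "dct", "ddct", "fold"]].reset_index(
        drop=True
    )
    group_stats = (
        per_sample.groupby("group")["fold"]
        .agg(mean_fold="mean", sem_fold="sem", n="count")
        .reset_index()
    )
    groups = list(group_stats["group"])
    if len(groups) == 2 and (group_stats["n"] >= 2).all():
        a = per_sample.loc[per_sample["group"] == groups[0], "fold"]
        b = per_sample.loc[per_sample["group"] == groups[1], "fold"]
        t_pvalue = float(stats.ttest_ind(a, b).pvalue)
    else:
        t_pvalue = math.nan
    return DdctResult(
        target_gene, reference_gene, calibrator_group, per_sample, group_stats, t_pvalue
    )
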