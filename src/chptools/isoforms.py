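"""Isoform-usage fractions and switch detection from transcript counts.

An isoform's usage (isoform fraction, IF) is its share of the total
expression of its gene within one condition.  The difference in usage
between knockdown and control, dIF = IF_kd - IF_control, flags isoform
switches: an isoform switches when |dIF| clears a usage cutoff (0.15 by
default) *and* the change is statistically supported.  Statistical support
comes from a two-proportion z-test comparing the isoform's share of the
pooled gene counts between conditions, with a Fisher exact fallback when
expected counts are small, and Benjamini-Hochberg adjustment over all
tested isoforms.

This is a deliberately simple count-level test; it does not model
per-replicate dispersion the way GLM-based differential-transcript-usage
tools do.
"""
from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, norm

from .enrichment import bh_adjust

__all__ = ["isoform_fractions", "detect_switches"]

REQUIRED_COLUMNS = ("gene_id", "isoform_id", "condition", "replicate", "count")


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(REQUIRED_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"isoform table missing columns: {sorted(missing)}")
    if (table["count"] < 0).any():
        raise ValueError("isoform counts must be non-negative")
    genes_per_isoform = table.groupby("isoform_id")["gene_id"].nunique()
    shared = genes_per_isoform[genes_per_isoform > 1]
    if not shared.empty:
        raise ValueError(
            f"isoform(s) assigned to more than one gene: {list(shared.index)[:5]}"
        )
    return table


def _pooled_counts(table: pd.DataFrame, method: str) -> pd.DataFrame:
    """Collapse replicates to one count per gene/isoform/condition."""
    if method not in ("pooled", "mean"):
        raise ValueError(f"unknown pooling method {method!r}")
    agg = "sum" if method == "pooled" else "mean"
    return (
        table.groupby(["gene_id", "isoform_id", "condition"], as_index=False)["count"]
        .agg(agg)
    )


def isoform_fractions(table: pd.DataFrame, method: str = "pooled") -> pd.DataFrame:
    """Per-isoform usage fraction by condition.

    Replicates are pooled by summing counts (``method="pooled"``, the
    default reading of "% of total isoforms") or averaged per replicate
    (``method="mean"``).  IF = isoform count / gene total within each
    condition; gene/condition groups with zero total are excluded.

    Returns a long table ``gene_id, isoform_id, condition, IF``.
    """
    pooled = _pooled_counts(_validate(table), method)
    totals = pooled.groupby(["gene_id", "condition"])["count"].transform("sum")
    pooled = pooled[totals > 0].copy()
    pooled["IF"] = pooled["count"] / totals[totals > 0]
    return pooled[["gene_id", "isoform_id", "condition", "IF"]].reset_index(drop=True)


def _two_proportion_p(x1: float, n1: float, x2: float, n2: float) -> float:
    """Two-sided p-value for equal isoform share in two pooled samples.

    Pooled-variance z-test; Fisher's exact test on the rounded 2x2 table
    when any expected count falls below 5.
    """
    hits = x1 + x2
    if hits == 0 or hits == n1 + n2:
        return 1.0
    phat = hits / (n1 + n2)
    expected = min(phat * n1, phat * n2, (1 - phat) * n1, (1 - phat) * n2)
    if expected < 5:
        table = np.rint([[x1, n1 - x1], [x2, n2 - x2]]).astype(int)
        table = np.clip(table, 0, None)
        return float(fisher_exact(table)[1])
    se = math.sqrt(phat * (1 - phat) * (1 / n1 + 1 / n2))
    z = (x1 / n1 - x2 / n2) / se
    return float(2 * norm.sf(abs(z)))


def detect_switches(
    table: pd.DataFrame,
    dif_cutoff: float = 0.15,
    alpha: float = 0.05,
    method: str = "pooled",
    control: str = "control",
    knockdown: str = "knockdown",
) -> pd.DataFrame:
    """Flag isoform switches between two conditions.

    For every gene present in both conditions with at least two isoforms,
    computes per-isoform IF_control, IF_kd and dIF = IF_kd - IF_control,
    tests each isoform's share of the pooled gene counts with a
    two-proportion test, adjusts with Benjamini-Hochberg over all tested
    isoforms, and calls a switch when ``|dIF| >= dif_cutoff`` and
    ``p_bh < alpha``.

    Genes missing from one condition are excluded with a warning.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    pooled = _pooled_counts(_validate(table), "pooled")
    usage = _pooled_counts(table, method)

    rows = []
    for gene, sub in pooled.groupby("gene_id"):
        conditions = set(sub["condition"])
        if not {control, knockdown} <= conditions:
            warnings.warn(
                f"gene {gene!r} missing one condition; excluded", stacklevel=2
            )
            continue
        isoforms = sorted(sub["isoform_id"].unique())
        if len(isoforms) < 2:
            continue
        counts = sub.pivot_table(
            index="isoform_id", columns="condition", values="count", fill_value=0.0
        ).reindex(isoforms, fill_value=0.0)
        n1 = float(counts[control].sum())
        n2 = float(counts[knockdown].sum())
        if n1 <= 0 or n2 <= 0:
            warnings.warn(
                f"gene {gene!r} has zero total counts in one condition; excluded",
                stacklevel=2,
            )
            continue
        us = usage[usage["gene_id"] == gene].pivot_table(
            index="isoform_id", columns="condition", values="count", fill_value=0.0
        ).reindex(isoforms, fill_value=0.0)
        if_control = us[control] / us[control].sum()
        if_kd = us[knockdown] / us[knockdown].sum()
        for iso in isoforms:
            x1 = float(counts.at[iso, control])
            x2 = float(counts.at[iso, knockdown])
            rows.append(
                {
                    "gene_id": gene,
                    "isoform_id": iso,
                    "IF_control": float(if_control[iso]),
                    "IF_kd": float(if_kd[iso]),
                    "dIF": float(if_kd[iso] - if_control[iso]),
                    "p": _two_proportion_p(x1, n1, x2, n2),
                }
            )
    frame = pd.DataFrame(
        rows, columns=["gene_id", "isoform_id", "IF_control", "IF_kd", "dIF", "p"]
    )
    if frame.empty:
        frame["p_bh"] = pd.Series(dtype=float)
        frame["is_switch"] = pd.Series(dtype=bool)
        return frame
    frame["p_bh"] = bh_adjust(frame["p"])
    frame["is_switch"] = (frame["dIF"].abs() >= dif_cutoff) & (frame["p_bh"] < alpha)
    return frame.reset_index(drop=True)
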