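"""Differential-expression concordance across knockdown comparisons.

Works on per-gene mean read counts for a control and a knockdown condition
plus an adjusted p-value produced upstream (the DE test itself is consumed,
never recomputed here).  Fold changes use the signed convention common in
expression tables: upregulation is reported as ``+mean_kd/mean_control``,
downregulation as ``-mean_control/mean_kd``, so the magnitude is always a
ratio >= 1 and the sign carries the direction.  A gene detected only in the
knockdown gets a +inf sentinel ("infinite" fold); a gene silenced to zero
gets -inf.

Consensus across comparisons (e.g. conditional knockdown in lateral- and
fourth-ventricle choroid plexus plus a constitutive heterozygote) keeps a
gene only if it is significant with a consistent direction in every
required comparison; significant but direction-discordant genes are
reported separately.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import AbstractSet, Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "COMPARISONS",
    "signed_fold",
    "round_sig",
    "percent_knockdown",
    "significant",
    "ConsensusGeneList",
    "consensus_genes",
    "VennReport",
    "venn_counts",
    "overlap_with_external",
    "expression_floor",
]

#: The three knockdown comparisons in the reporting preset.
COMPARISONS = ("LV_cond", "FourV_cond", "FourV_GFP")


def signed_fold(mean_control: float, mean_kd: float) -> float:
    """Signed fold change between two mean read counts.

    Returns ``+mean_kd/mean_control`` when expression rises (including +1
    for no change), ``-mean_control/mean_kd`` when it falls, ``+inf`` when
    the gene appears only in the knockdown, ``-inf`` when it disappears,
    and NaN when both means are zero.
    """
    if mean_control < 0 or mean_kd < 0:
        raise ValueError("mean reads must be non-negative")
    if mean_control == 0 and mean_kd == 0:
        return math.nan
    if mean_control == 0:
        return math.inf
    if mean_kd == 0:
        return -math.inf
    if mean_kd >= mean_control:
        return mean_kd / mean_control
    return -(mean_control / mean_kd)


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures; passes through 0, NaN and inf."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def percent_knockdown(mean_control: float, mean_kd: float) -> float:
    """Percentage decrease from control to knockdown, ``100*(1 - kd/ctrl)``.

    Negative values mean an increase.  NaN when the control mean is zero
    (the decrease is undefined).  Round to the nearest integer for
    reporting.
    """
    if mean_control < 0 or mean_kd < 0:
        raise ValueError("mean reads must be non-negative")
    if mean_control == 0:
        return math.nan
    return 100.0 * (1.0 - mean_kd / mean_control)


def _check_de_frame(frame: pd.DataFrame) -> None:
    required = {"gene_id", "mean_control", "mean_kd", "p_adj"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")


def significant(
    records: pd.DataFrame, alpha: float = 0.05
) -> tuple[frozenset[str], frozenset[str]]:
    """Split one comparison's table into up- and down-regulated gene sets.

    A gene is kept iff ``p_adj < alpha`` (strict); its direction comes from
    the sign of the fold change.  Genes with missing p-values or with no
    direction (equal means, or zero in both conditions) are excluded.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    _check_de_frame(records)
    up: set[str] = set()
    down: set[str] = set()
    for row in records.itertuples(index=False):
        p = row.p_adj
        if p is None or (isinstance(p, float) and math.isnan(p)) or not p < alpha:
            continue
        fold = signed_fold(float(row.mean_control), float(row.mean_kd))
        if math.isnan(fold):
            continue
        if fold > 1:
            up.add(str(row.gene_id))
        elif fold < 1:
            down.add(str(row.gene_id))
    return frozenset(up), frozenset(down)


@dataclass(frozen=True)
class ConsensusGeneList:
    """Genes significant and direction-consistent in all required comparisons.

    ``discordant`` holds genes significant everywhere but with mixed
    direction; they belong to neither list.  ``membership`` is a gene x
    comparison matrix with +1 (up), -1 (down), 0 (not significant).
    """

    up: frozenset[str]
    down: frozenset[str]
    discordant: frozenset[str]
    membership: pd.DataFrame


def consensus_genes(
    sets_by_comparison: Mapping[str, tuple[AbstractSet[str], AbstractSet[str]]],
    require: Sequence[str] | None = None,
) -> ConsensusGeneList:
    """Intersect per-comparison up/down sets with direction consistency."""
    require = list(require) if require is not None else list(sets_by_comparison)
    if len(require) < 2:
        raise ValueError("consensus needs at least two comparisons")
    for name in require:
        if name not in sets_by_comparison:
            raise ValueError(f"unknown comparison {name!r}")

    ups = [frozenset(sets_by_comparison[n][0]) for n in require]
    downs = [frozenset(sets_by_comparison[n][1]) for n in require]
    up = frozenset.intersection(*ups)
    down = frozenset.intersection(*downs)
    sig_everywhere = frozenset.intersection(*(u | d for u, d in zip(ups, downs)))
    discordant = sig_everywhere - up - down

    genes = sorted(set().union(*(u | d for u, d in zip(ups, downs))))
    membership = pd.DataFrame(
        0, index=pd.Index(genes, name="gene_id"), columns=list(sets_by_comparison)
    )
    for name, (u, d) in sets_by_comparison.items():
        membership.loc[membership.index.isin(list(u)), name] = 1
        membership.loc[membership.index.isin(list(d)), name] = -1
    return ConsensusGeneList(up, down, discordant, membership)


@dataclass(frozen=True)
class VennReport:
    """Exclusive region counts and memberships for 2-3 sets.

    Region keys are tuples of the set names the region belongs to; counts
    over all regions sum to the size of the union.
    """

    regions: Mapping[tuple[str, ...], int]
    memberships: Mapping[tuple[str, ...], frozenset[str]]


def venn_counts(sets: Mapping[str, AbstractSet[str]]) -> VennReport:
    """Exclusive Venn region counts for two or three named sets."""
    names = list(sets)
    if not 2 <= len(names) <= 3:
        raise ValueError("venn_counts supports 2 or 3 sets")
    regions: dict[tuple[str, ...], int] = {}
    memberships: dict[tuple[str, ...], frozenset[str]] = {}
    n = len(names)
    for mask in range(1, 2**n):
        inside = [names[i] for i in range(n) if mask >> i & 1]
        outside = [names[i] for i in range(n) if not mask >> i & 1]
        region = frozenset.intersection(*(frozenset(sets[x]) for x in inside))
        for x in outside:
            region -= frozenset(sets[x])
        key = tuple(inside)
        regions[key] = len(region)
        memberships[key] = region
    return VennReport(regions, memberships)


def overlap_with_external(
    genes: AbstractSet[str], external: AbstractSet[str]
) -> tuple[int, float]:
    """Overlap of a gene set with an external list: count and fraction of
    the external list covered."""
    if not external:
        raise ValueError("external list must be non-empty")
    inter = frozenset(genes) & frozenset(external)
    return len(inter), len(inter) / len(external)


def expression_floor(
    records: pd.DataFrame | Iterable[pd.DataFrame], min_mean: float = 10.0
) -> frozenset[str]:
    """Genes expressed above a mean-read floor in at least one sample.

    The standard filter applied before term-enrichment analysis: keep genes
    with more than ``min_mean`` mean reads in at least one condition of at
    least one comparison table.
    """
    frames = [records] if isinstance(records, pd.DataFrame) else list(records)
    keep: set[str] = set()
    for frame in frames:
        _check_de_frame(frame)
        mask = (frame["mean_control"] > min_mean) | (frame["mean_kd"] > min_mean)
        keep.update(frame.loc[mask, "gene_id"].astype(str))
    return frozenset(keep)
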