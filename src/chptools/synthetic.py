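"""Seeded generators for every input the analysis modules consume.

Each generator plants a known ground truth (true bait partners, consensus
differentially expressed genes, isoform switches) and emits both the data
table in the exact dialect the corresponding analysis module reads and a
truth table keyed by the same identifiers, so every pipeline stage supports
parameter-recovery testing without any external download.

Noise models are standard count models: Poisson peptide counts, log-normal
baseline mean reads, multinomial isoform counts with optional Dirichlet
overdispersion.  Every generator is a pure function of its spec (including
the seed): the same spec yields byte-identical output.
"""
from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TriageSimSpec",
    "DESimSpec",
    "IsoformSimSpec",
    "simulate_coip",
    "simulate_de",
    "simulate_isoforms",
    "load_spec",
]


def _rng(seed: int | None) -> np.random.Generator:
    return np.random.default_rng(seed)


def _from_yaml(cls, path):
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} fields: {sorted(unknown)}")
    return cls(**data)


def load_spec(cls, path):
    """Load a simulation spec dataclass from a YAML mapping file."""
    return _from_yaml(cls, path)


# ---------------------------------------------------------------------------
# co-IP peptide counts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TriageSimSpec:
    """Planted AP-MS experiment: partners, background, small exclusives.

    True partners are exclusive to the bait with a Poisson bait-count mean
    high enough to clear the 3-peptide rule; contaminants appear in both
    co-IPs with symmetric means (relative difference ~0); small exclusives
    are bait-only proteins below the 25 kDa rule with too few peptides for
    the unique rule.  In ``noise_free`` mode counts sit exactly at the
    rounded class means, so triage must recover the planted classes
    perfectly.
    """

    n_true_partners: int = 60
    n_contaminants: int = 300
    n_small_exclusive: int = 30
    partner_bait_mean: float = 8.0
    small_bait_mean: float = 1.5
    contaminant_mean: float = 6.0
    #: control mean = symmetry * bait mean for contaminants (1.0 = symmetric)
    contaminant_symmetry: float = 1.0
    n_replicates: int = 3
    structure: str = "ChP"
    #: log-normal molecular-mass model for non-small proteins (kDa)
    mw_log_mean: float = np.log(45.0)
    mw_log_sd: float = 0.5
    #: small exclusives draw mass uniformly on [mw_small_low, mw_small_high]
    mw_small_low: float = 8.0
    mw_small_high: float = 24.0
    noise_free: bool = False
    seed: int | None = None

    @classmethod
    def from_yaml(cls, path) -> "TriageSimSpec":
        return _from_yaml(cls, path)


def simulate_coip(
    spec: TriageSimSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a bait/control peptide-count experiment.

    Returns ``(counts, annotations, truth)``: the peptide-count table for
    every replicate, the per-protein molecular-mass table, and the truth
    table with the planted class (``partner``, ``small_partner``,
    ``contaminant``) and the expected partner verdict.
    """
    rng = _rng(spec.seed)
    classes = (
        [("TP%04d" % i, "partner") for i in range(1, spec.n_true_partners + 1)]
        + [("SM%04d" % i, "small_partner") for i in range(1, spec.n_small_exclusive + 1)]
        + [("BG%04d" % i, "contaminant") for i in range(1, spec.n_contaminants + 1)]
    )

    ann_rows = []
    for pid, cls in classes:
        if cls == "small_partner":
            mw = rng.uniform(spec.mw_small_low, spec.mw_small_high)
        else:
            mw = float(np.exp(rng.normal(spec.mw_log_mean, spec.mw_log_sd)))
        ann_rows.append({"protein_id": pid, "mw_kda": mw})
    annotations = pd.DataFrame(ann_rows)

    rows = []
    for rep in range(1, spec.n_replicates + 1):
        for pid, cls in classes:
            if cls == "partner":
                o_mean, i_mean = spec.partner_bait_mean, 0.0
            elif cls == "small_partner":
                o_mean, i_mean = spec.small_bait_mean, 0.0
            else:
                o_mean = spec.contaminant_mean
                i_mean = spec.contaminant_symmetry * spec.contaminant_mean
            if spec.noise_free:
                o = int(round(o_mean))
                i = int(round(i_mean))
            else:
                o = int(rng.poisson(o_mean))
                i = int(rng.poisson(i_mean))
            rows.append(
                {
                    "protein_id": pid,
                    "structure": spec.structure,
                    "replicate": rep,
                    "otx2_peptides": o,
                    "igg_peptides": i,
                }
            )
    counts = pd.DataFrame(rows)
    truth = pd.DataFrame(
        {
            "protein_id": [pid for pid, _ in classes],
            "cls": [cls for _, cls in classes],
            "is_partner": [cls != "contaminant" for _, cls in classes],
        }
    )
    return counts, annotations, truth


# ---------------------------------------------------------------------------
# differential-expression tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DESimSpec:
    """Planted three-comparison differential-expression experiment.

    Consensus genes are significant with a consistent direction in all
    three comparisons (default 42 up / 34 down, the scale of the global
    knockdown signature the toolkit targets); per-comparison extras are
    significant in exactly one comparison; optional discordant genes are
    significant everywhere but flip direction in the last comparison.
    Baseline mean reads are log-normal; adjusted p-values are assigned
    directly (below alpha for planted DE genes, at or above alpha for
    nulls) because the upstream DE test is outside this toolkit's scope.
    """

    n_genes: int = 2000
    n_consensus_up: int = 42
    n_consensus_down: int = 34
    extra_per_comparison: int = 100
    n_discordant: int = 0
    comparisons: tuple[str, ...] = ("LV_cond", "FourV_cond", "FourV_GFP")
    baseline_log_mean: float = 5.0
    baseline_log_sd: float = 1.5
    #: |log2 fold| of planted effects ~ Normal(effect_log2_mean, effect_log2_sd),
    #: truncated below at 0.5 so planted effects are never degenerate
    effect_log2_mean: float = 1.5
    effect_log2_sd: float = 0.5
    alpha: float = 0.05
    seed: int | None = None

    @classmethod
    def from_yaml(cls, path) -> "DESimSpec":
        return _from_yaml(cls, path)


def simulate_de(
    spec: DESimSpec,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Simulate the three knockdown DE tables with planted consensus genes.

    Returns ``(tables, truth)`` where ``tables`` maps comparison name to a
    ``gene_id, comparison, mean_control, mean_kd, p_adj`` table and
    ``truth`` labels each gene (``consensus_up``, ``consensus_down``,
    ``extra_<comparison>``, ``discordant``, ``null``).
    """
    planted = (
        spec.n_consensus_up
        + spec.n_consensus_down
        + spec.n_discordant
        + spec.extra_per_comparison * len(spec.comparisons)
    )
    if planted > spec.n_genes:
        raise ValueError("more planted genes than n_genes")
    rng = _rng(spec.seed)

    gene_ids = ["G%05d" % i for i in range(1, spec.n_genes + 1)]
    labels = (
        ["consensus_up"] * spec.n_consensus_up
        + ["consensus_down"] * spec.n_consensus_down
        + ["discordant"] * spec.n_discordant
        + sum(
            ([f"extra_{c}"] * spec.extra_per_comparison for c in spec.comparisons),
            [],
        )
    )
    labels += ["null"] * (spec.n_genes - len(labels))
    truth = pd.DataFrame({"gene_id": gene_ids, "cls": labels})

    def effect(direction: int) -> float:
        mag = max(0.5, rng.normal(spec.effect_log2_mean, spec.effect_log2_sd))
        return float(2.0 ** (direction * mag))

    last = spec.comparisons[-1]
    tables: dict[str, pd.DataFrame] = {}
    for comp in spec.comparisons:
        rows = []
        for gid, label in zip(gene_ids, labels):
            base = float(np.exp(rng.normal(spec.baseline_log_mean, spec.baseline_log_sd)))
            de_here = False
            direction = 0
            if label == "consensus_up":
                de_here, direction = True, +1
            elif label == "consensus_down":
                de_here, direction = True, -1
            elif label == "discordant":
                de_here = True
                direction = -1 if comp == last else +1
            elif label == f"extra_{comp}":
                de_here = True
                direction = int(rng.choice([-1, +1]))
            kd = base * effect(direction) if de_here else base * float(
                2.0 ** rng.normal(0.0, 0.05)
            )
            p = (
                float(rng.uniform(1e-8, 0.9 * spec.alpha))
                if de_here
                else float(rng.uniform(spec.alpha, 1.0))
            )
            rows.append(
                {
                    "gene_id": gid,
                    "comparison": comp,
                    "mean_control": base,
                    "mean_kd": kd,
                    "p_adj": p,
                }
            )
        tables[comp] = pd.DataFrame(rows)
    return tables, truth


# ---------------------------------------------------------------------------
# isoform counts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IsoformSimSpec:
    """Planted isoform-switch experiment.

    Switch genes move usage mass ``target_dif`` from the rest of the gene
    onto the first isoform between control and knockdown (control IF =
    0.5 - dIF/2, knockdown IF = 0.5 + dIF/2 for that isoform); non-switch
    genes keep a Dirichlet-drawn usage vector in both conditions.  Counts
    are multinomial per replicate at ``reads_per_gene / n_replicates``
    depth, with optional Dirichlet overdispersion of the per-replicate
    usage vector.  ``deterministic`` mode emits expected (real-valued)
    counts, so observed usage equals planted usage exactly.
    """

    n_genes: int = 20
    n_switch_genes: int = 4
    isoforms_per_gene: int = 2
    #: total reads per gene per condition (split evenly across replicates)
    reads_per_gene: float = 1000.0
    n_replicates: int = 2
    target_dif: float = 0.30
    #: Dirichlet concentration for per-replicate usage noise; None = none
    dirichlet_concentration: float | None = None
    deterministic: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.target_dif <= 0.9:
            raise ValueError("target_dif must be in [0, 0.9]")
        if self.n_switch_genes > self.n_genes:
            raise ValueError("more switch genes than genes")
        if self.isoforms_per_gene < 2:
            raise ValueError("need at least two isoforms per gene")

    @classmethod
    def from_yaml(cls, path) -> "IsoformSimSpec":
        return _from_yaml(cls, path)


def simulate_isoforms(
    spec: IsoformSimSpec,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate transcript-level counts with planted isoform switches.

    Returns ``(table, truth)``: the long count table the switch detector
    reads and a truth table with the planted switch flag, the switching
    isoform, and the planted dIF per gene.
    """
    rng = _rng(spec.seed)
    k = spec.isoforms_per_gene
    depth = spec.reads_per_gene / spec.n_replicates

    rows = []
    truth_rows = []
    for g in range(1, spec.n_genes + 1):
        gene = "G%04d" % g
        is_switch = g <= spec.n_switch_genes
        if is_switch:
            lo = 0.5 - spec.target_dif / 2.0
            hi = 0.5 + spec.target_dif / 2.0
            rest_ctrl = (1.0 - lo) / (k - 1)
            rest_kd = (1.0 - hi) / (k - 1)
            p_control = np.array([lo] + [rest_ctrl] * (k - 1))
            p_kd = np.array([hi] + [rest_kd] * (k - 1))
        else:
            p_control = rng.dirichlet([5.0] * k)
            p_kd = p_control.copy()
        truth_rows.append(
            {
                "gene_id": gene,
                "is_switch": is_switch,
                "switch_isoform": f"{gene}.1" if is_switch else "",
                "target_dif": spec.target_dif if is_switch else 0.0,
            }
        )
        for condition, p in (("control", p_control), ("knockdown", p_kd)):
            for rep in range(1, spec.n_replicates + 1):
                if spec.deterministic:
                    counts = depth * p
                else:
                    p_rep = p
                    if spec.dirichlet_concentration is not None:
                        p_rep = rng.dirichlet(spec.dirichlet_concentration * p)
                    counts = rng.multinomial(int(round(depth)), p_rep).astype(float)
                for j in range(k):
                    rows.append(
                        {
                            "gene_id": gene,
                            "isoform_id": f"{gene}.{j + 1}",
                            "condition": condition,
                            "replicate": rep,
                            "count": float(counts[j]),
                        }
                    )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)
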