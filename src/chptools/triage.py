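"""Bait-versus-control triage of AP-MS peptide counts.

Affinity-purification mass spectrometry (AP-MS) of a bait transcription
factor (here OTX2) against a nonspecific IgG control yields, for each
detected protein, a pair of peptide counts: ``O`` peptides in the bait
co-immunoprecipitation and ``I`` peptides in the IgG control.  A protein is
called a putative bait partner when it satisfies any of three rules:

1. **unique** — at least 3 peptides, detected exclusively in the bait co-IP
   (``I = 0``);
2. **selected** — at least 3 bait peptides and a relative peptide difference
   greater than 50% versus the control;
3. **unique_small** — any small protein (molecular mass at or below 25 kDa)
   detected exclusively in the bait co-IP, regardless of peptide number,
   because small proteins yield few identifiable peptides.

The relative peptide difference is ``(O - I) / O`` by default (negative
differences clamp to 0, exclusive detection scores 1), with ``(O - I) / I``
selectable.  ``unique`` and ``selected`` are disjoint: ``selected`` requires
the protein to be detected in the control at all (``I >= 1``).

Per-replicate partner sets are intersected across replicates of one
structure (:func:`consensus`) and the resulting high-confidence sets are
compared across brain structures (:func:`cross_structure`), e.g. requiring
detection in all of SVZ, RMS and visual cortex and reporting which of those
partners also appear in the choroid plexus.
"""
from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.SeqUtils import molecular_weight

__all__ = [
    "KNOWN_STRUCTURES",
    "FLAG_UNIQUE",
    "FLAG_SELECTED",
    "FLAG_UNIQUE_SMALL",
    "CoIPRecord",
    "ProteinAnnotation",
    "TriageCall",
    "PartnerSet",
    "CrossStructureReport",
    "rel_delta",
    "classify",
    "partner_set",
    "consensus",
    "high_confidence_set",
    "cross_structure",
    "mw_from_sequence",
    "triage_report",
    "records_from_frame",
    "annotations_from_frame",
]

#: Brain structures assayed in the study design this toolkit mirrors.
KNOWN_STRUCTURES = ("ChP", "SVZ", "RMS", "VCx")

FLAG_UNIQUE = "unique"
FLAG_SELECTED = "selected"
FLAG_UNIQUE_SMALL = "unique_small"
ALL_FLAGS = (FLAG_UNIQUE, FLAG_SELECTED, FLAG_UNIQUE_SMALL)

_WATER_KDA = 0.0180153
_STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


def mw_from_sequence(sequence: str) -> float:
    """Average molecular mass of a protein sequence, in kilodaltons.

    Computed as the sum of average residue masses plus one water, i.e. the
    mass of the intact unmodified chain.  Only the 20 standard one-letter
    residue codes are accepted; ambiguity codes and gaps are rejected.

    >>> round(mw_from_sequence("G"), 5)
    0.07507
    """
    sequence = str(sequence).upper()
    for pos, ch in enumerate(sequence):
        if ch not in _STANDARD_RESIDUES:
            raise ValueError(
                f"non-standard residue {ch!r} at position {pos}; "
                "only the 20 standard amino acids are supported"
            )
    if not sequence:
        return _WATER_KDA
    return molecular_weight(sequence, seq_type="protein", monoisotopic=False) / 1000.0


@dataclass(frozen=True)
class CoIPRecord:
    """Peptide counts for one protein in one bait/control co-IP pair.

    A protein absent from one of the two co-IPs carries count 0 there; once
    the pair is formed there are no missing counts.
    """

    protein_id: str
    structure: str
    replicate: int
    bait_peptides: int
    control_peptides: int

    def __post_init__(self) -> None:
        if self.bait_peptides < 0 or self.control_peptides < 0:
            raise ValueError(
                f"{self.protein_id}: peptide counts must be non-negative"
            )
        if self.replicate < 1:
            raise ValueError(f"{self.protein_id}: replicate must be >= 1")


@dataclass(frozen=True)
class ProteinAnnotation:
    """Molecular-mass annotation for one protein.

    Either an explicit mass in kDa or an amino-acid sequence from which the
    mass is computed; an explicit ``mw_kda`` takes precedence over the
    sequence.
    """

    protein_id: str
    mw_kda: float | None = None
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.mw_kda is not None and not self.mw_kda > 0:
            raise ValueError(f"{self.protein_id}: mw_kda must be positive")

    @property
    def mass_kda(self) -> float | None:
        if self.mw_kda is not None:
            return self.mw_kda
        if self.sequence is not None:
            return mw_from_sequence(self.sequence)
        return None


@dataclass(frozen=True)
class TriageCall:
    """Triage verdict for one protein: category flags plus the score."""

    protein_id: str
    flags: frozenset[str]
    rel_delta: float | None

    @property
    def is_partner(self) -> bool:
        return bool(self.flags)


@dataclass(frozen=True)
class PartnerSet:
    """Partner proteins for one structure and replicate (or consensus).

    ``flags_by_protein`` records, for each member, which triage categories
    it satisfied; ``category_counts`` tallies members per flag.  Note a
    protein can carry both ``unique`` and ``unique_small``, so category
    counts may sum to more than ``total``.
    """

    structure: str | None
    replicate: int | str | None
    members: frozenset[str]
    category_counts: Mapping[str, int]
    flags_by_protein: Mapping[str, frozenset[str]] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return len(self.members)


def rel_delta(
    bait_peptides: float, control_peptides: float, mode: str = "bait"
) -> float | None:
    """Relative peptide difference between bait and control co-IPs.

    ``mode="bait"`` (default): ``(O - I) / O``, clamped to [0, 1]; exclusive
    detection (``I = 0``) scores 1.  ``mode="control"``: ``(O - I) / I``,
    clamped below at 0, with ``I = 0`` scoring +inf.  Undefined (``None``)
    when the protein was not seen in the bait co-IP at all (``O = 0``).
    """
    if bait_peptides < 0 or control_peptides < 0:
        raise ValueError("peptide counts must be non-negative")
    if mode not in ("bait", "control"):
        raise ValueError(f"unknown rel_delta mode {mode!r}")
    o = float(bait_peptides)
    i = float(control_peptides)
    if o == 0:
        return None
    if mode == "bait":
        return max(0.0, (o - i) / o)
    if i == 0:
        return math.inf
    return max(0.0, (o - i) / i)


def classify(
    record: CoIPRecord,
    annotation: ProteinAnnotation | None = None,
    *,
    mode: str = "bait",
    rel_delta_threshold: float = 0.5,
    min_peptides: int = 3,
    small_mw_kda: float = 25.0,
) -> TriageCall:
    """Apply the three partner rules to one bait/control count pair.

    Without an annotation (unknown mass) the ``unique_small`` rule can never
    fire.  The rel-delta threshold is strict (``> 0.5``), so a protein at
    exactly 50% relative difference is not selected.
    """
    o = record.bait_peptides
    i = record.control_peptides
    rd = rel_delta(o, i, mode=mode)
    mass = annotation.mass_kda if annotation is not None else None

    flags: set[str] = set()
    if i == 0 and o >= min_peptides:
        flags.add(FLAG_UNIQUE)
    if i == 0 and o >= 1 and mass is not None and mass <= small_mw_kda:
        flags.add(FLAG_UNIQUE_SMALL)
    if i >= 1 and o >= min_peptides and rd is not None and rd > rel_delta_threshold:
        flags.add(FLAG_SELECTED)
    return TriageCall(record.protein_id, frozenset(flags), rd)


def partner_set(
    records: Iterable[CoIPRecord],
    annotations: Mapping[str, ProteinAnnotation] | None = None,
    **classify_kwargs,
) -> PartnerSet:
    """Build the partner set for one structure and replicate.

    Raises on duplicate protein identifiers within the replicate and on
    records mixing structures or replicates.
    """
    records = list(records)
    annotations = annotations or {}
    if not records:
        return PartnerSet(None, None, frozenset(), {f: 0 for f in ALL_FLAGS}, {})

    keys = {(r.structure, r.replicate) for r in records}
    if len(keys) > 1:
        raise ValueError(f"records mix structures/replicates: {sorted(keys)}")
    seen: set[str] = set()
    for r in records:
        if r.protein_id in seen:
            raise ValueError(f"duplicate protein_id {r.protein_id!r} in one replicate")
        seen.add(r.protein_id)

    flags_by_protein: dict[str, frozenset[str]] = {}
    counts: Counter[str] = Counter({f: 0 for f in ALL_FLAGS})
    for r in records:
        call = classify(r, annotations.get(r.protein_id), **classify_kwargs)
        if call.is_partner:
            flags_by_protein[r.protein_id] = call.flags
            counts.update(call.flags)
    (structure, replicate), = keys
    return PartnerSet(
        structure, replicate, frozenset(flags_by_protein), dict(counts), flags_by_protein
    )


def consensus(partner_sets: Sequence[PartnerSet]) -> PartnerSet:
    """Strict intersection of partner sets across replicates of one structure.

    The consensus member set is the intersection of the input member sets.
    For reporting, each surviving member carries the union of the flags it
    earned across replicates, and category counts tally those unions.
    """
    partner_sets = list(partner_sets)
    if not partner_sets:
        raise ValueError("at least one partner set is required")
    structures = {s.structure for s in partner_sets if s.structure is not None}
    if len(structures) > 1:
        raise ValueError(f"cannot form consensus across structures: {sorted(structures)}")

    members = frozenset.intersection(*(s.members for s in partner_sets))
    flags_by_protein: dict[str, frozenset[str]] = {}
    for pid in members:
        union: frozenset[str] = frozenset()
        for s in partner_sets:
            union |= s.flags_by_protein.get(pid, frozenset())
        flags_by_protein[pid] = union
    counts: Counter[str] = Counter({f: 0 for f in ALL_FLAGS})
    for fl in flags_by_protein.values():
        counts.update(fl)
    structure = next(iter(structures), None)
    return PartnerSet(structure, "consensus", members, dict(counts), flags_by_protein)


def high_confidence_set(
    records: Iterable[CoIPRecord],
    *,
    min_peptides: int = 3,
    rel_delta_threshold: float = 0.5,
    mode: str = "bait",
) -> frozenset[str]:
    """Proteins with >= 3 bait peptides and rel. difference above threshold.

    Exclusive detection counts as a relative difference of 100%, so bait-only
    proteins with enough peptides always qualify.  This is the filter used
    to rank partners when comparing structures.
    """
    out = set()
    for r in records:
        rd = rel_delta(r.bait_peptides, r.control_peptides, mode=mode)
        if r.bait_peptides >= min_peptides and rd is not None and rd > rel_delta_threshold:
            out.add(r.protein_id)
    return frozenset(out)


@dataclass(frozen=True)
class CrossStructureReport:
    """Per-protein structure membership plus the requested intersections."""

    membership: pd.DataFrame  # bool, proteins x structures
    required: tuple[str, ...]
    common: frozenset[str]  # proteins passing in every required structure
    also_common: Mapping[str, frozenset[str]]  # overlap of `common` with each extra structure


def cross_structure(
    sets_by_structure: Mapping[str, PartnerSet | Iterable[str]],
    require: Sequence[str],
    also: Sequence[str] = (),
) -> CrossStructureReport:
    """Compare per-structure partner sets and report shared membership.

    ``require`` names the structures whose intersection defines the shared
    set (e.g. the three non-cell-autonomous structures SVZ, RMS, VCx);
    ``also`` names further structures whose overlap with that shared set is
    reported (e.g. ChP).
    """
    members: dict[str, frozenset[str]] = {}
    for name, s in sets_by_structure.items():
        members[name] = s.members if isinstance(s, PartnerSet) else frozenset(s)
    if len(members) < 2:
        raise ValueError("cross-structure comparison needs at least two structures")
    for name in list(require) + list(also):
        if name not in members:
            raise ValueError(f"unknown structure {name!r}; have {sorted(members)}")

    universe = sorted(set().union(*members.values()))
    membership = pd.DataFrame(
        {name: [pid in s for pid in universe] for name, s in members.items()},
        index=pd.Index(universe, name="protein_id"),
    )
    common = frozenset.intersection(*(members[n] for n in require))
    also_common = {n: common & members[n] for n in also}
    return CrossStructureReport(membership, tuple(require), common, also_common)


def records_from_frame(frame: pd.DataFrame) -> list[CoIPRecord]:
    """Build records from a table with the peptide-count column layout."""
    required = {"protein_id", "structure", "replicate", "otx2_peptides", "igg_peptides"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"peptide-count table missing columns: {sorted(missing)}")
    return [
        CoIPRecord(
            str(row.protein_id),
            str(row.structure),
            int(row.replicate),
            int(row.otx2_peptides),
            int(row.igg_peptides),
        )
        for row in frame.itertuples(index=False)
    ]


def annotations_from_frame(frame: pd.DataFrame) -> dict[str, ProteinAnnotation]:
    """Build an annotation mapping from a ``protein_id``/``mw_kda`` table."""
    if not {"protein_id", "mw_kda"} <= set(frame.columns):
        raise ValueError("annotation table needs protein_id and mw_kda columns")
    return {
        str(row.protein_id): ProteinAnnotation(str(row.protein_id), float(row.mw_kda))
        for row in frame.itertuples(index=False)
    }


def triage_report(
    records: Iterable[CoIPRecord],
    annotations: Mapping[str, ProteinAnnotation] | None = None,
    **classify_kwargs,
) -> pd.DataFrame:
    """Tabular triage verdicts, one row per record.

    Ordered by descending bait peptide count, then protein identifier.
    """
    annotations = annotations or {}
    rows = []
    for r in records:
        call = classify(r, annotations.get(r.protein_id), **classify_kwargs)
        rows.append(
            {
                "protein_id": r.protein_id,
                "structure": r.structure,
                "replicate": r.replicate,
                "otx2_peptides": r.bait_peptides,
                "igg_peptides": r.control_peptides,
                "flags": ",".join(sorted(call.flags)),
                "rel_delta": call.rel_delta,
                "is_partner": call.is_partner,
            }
        )
    frame = pd.DataFrame(rows)
    if not frame.empty:
        frame = frame.sort_values(
            ["otx2_peptides", "protein_id"], ascending=[False, True]
        ).reset_index(drop=True)
    return frame
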