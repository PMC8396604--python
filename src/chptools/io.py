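"""Readers and writers for the toolkit's tab-separated dialects."""
from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

from .triage import (
    CoIPRecord,
    ProteinAnnotation,
    annotations_from_frame,
    mw_from_sequence,
    records_from_frame,
)

__all__ = [
    "read_peptide_counts",
    "read_annotations",
    "read_de_table",
    "read_isoform_table",
    "read_ct_table",
    "read_gene_list",
    "read_annotation_map_frame",
    "write_tsv",
]


def read_peptide_counts(path) -> list[CoIPRecord]:
    """Read a ``protein_id structure replicate otx2_peptides igg_peptides``
    TSV into co-IP records."""
    return records_from_frame(pd.read_csv(path, sep="\t"))


def read_annotations(path) -> dict[str, ProteinAnnotation]:
    """Read protein annotations from a ``protein_id/mw_kda`` TSV or a FASTA
    file (masses computed from the sequences)."""
    path = Path(path)
    if path.suffix.lower() in (".fa", ".fasta", ".faa"):
        out = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            out[rec.id] = ProteinAnnotation(
                rec.id, mw_from_sequence(str(rec.seq))
            )
        return out
    return annotations_from_frame(pd.read_csv(path, sep="\t"))


def read_de_table(path) -> pd.DataFrame:
    """Read a ``gene_id comparison mean_control mean_kd p_adj`` TSV."""
    frame = pd.read_csv(path, sep="\t")
    required = {"gene_id", "mean_control", "mean_kd", "p_adj"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    return frame


def read_isoform_table(path) -> pd.DataFrame:
    """Read a ``gene_id isoform_id condition replicate count`` TSV."""
    return pd.read_csv(path, sep="\t")


def read_ct_table(path) -> pd.DataFrame:
    """Read a ``sample_id group gene_id ct`` TSV."""
    return pd.read_csv(path, sep="\t")


def read_gene_list(path) -> frozenset[str]:
    """Read a one-identifier-per-line text file into a set."""
    lines = Path(path).read_text().splitlines()
    return frozenset(line.strip() for line in lines if line.strip())


def read_annotation_map_frame(path) -> pd.DataFrame:
    """Read a two-column ``term_id gene_id`` TSV (GMT files are handled by
    :meth:`chptools.enrichment.AnnotationMap.from_gmt`)."""
    return pd.read_csv(path, sep="\t")


def write_tsv(frame: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False)
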