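"""Bundled example datasets (small published measurement tables).

Three tables transcribed from a published OTX2 choroid-plexus knockdown
study ship with the package so the worked examples and acceptance checks
run without any download:

* peptide counts for the 14 candidate OTX2 partner proteins recurrently
  detected in the three non-cell-autonomous structures (SVZ, RMS, visual
  cortex), with choroid-plexus counts for the five proteins that were also
  detected there (the others carry 0/0 in ChP);
* the top-10 up- and down-regulated genes of the conditional knockdown in
  lateral- and fourth-ventricle choroid plexus, with mean reads, the fold
  change as printed, and adjusted p-values;
* expression of candidate secreted factors across all three knockdown
  comparisons.
"""
from __future__ import annotations

from importlib.resources import files

import pandas as pd

from .triage import CoIPRecord, records_from_frame

__all__ = [
    "load_coip_peptide_counts",
    "load_coip_records",
    "load_top_de_genes",
    "load_secreted_factor_de",
]

_DATA = files("chptools") / "data"


def _read(name: str) -> pd.DataFrame:
    with (_DATA / name).open() as handle:
        return pd.read_csv(handle, sep="\t")


def load_coip_peptide_counts() -> pd.DataFrame:
    """Peptide-count table for the 14 cross-structure candidate partners."""
    return _read("coip_peptide_counts.tsv")


def load_coip_records() -> list[CoIPRecord]:
    """The same table as :class:`~chptools.triage.CoIPRecord` objects."""
    return records_from_frame(load_coip_peptide_counts())


def load_top_de_genes() -> pd.DataFrame:
    """Top differentially expressed genes of the conditional knockdown."""
    return _read("de_top_genes.tsv")


def load_secreted_factor_de() -> pd.DataFrame:
    """Secreted-factor expression across the three knockdown comparisons."""
    return _read("de_secreted_factors.tsv")
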