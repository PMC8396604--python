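"""Over-representation analysis by the hypergeometric test.

Given a query gene set, a background universe, and a term -> genes
annotation map, each term is scored with the upper-tail hypergeometric
probability P[X >= k] of drawing at least the observed number of annotated
genes when sampling the query size from the background without replacement
(equivalently, a one-sided Fisher exact test).  P-values are adjusted with
Benjamini-Hochberg across all tested terms and exported together with
-log10(p) for plotting.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import AbstractSet, Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = ["AnnotationMap", "hypergeom_enrich", "bh_adjust"]


@dataclass(frozen=True)
class AnnotationMap:
    """Term -> gene-set annotations over a fixed background universe.

    Annotated genes outside the background are dropped at construction, as
    are terms left with no annotated genes, so every stored annotation is a
    subset of the background.
    """

    terms: Mapping[str, frozenset[str]]
    background: frozenset[str]

    @classmethod
    def build(
        cls,
        terms: Mapping[str, AbstractSet[str]],
        background: AbstractSet[str],
    ) -> "AnnotationMap":
        background = frozenset(str(g) for g in background)
        if not background:
            raise ValueError("background must be non-empty")
        kept = {}
        for term, genes in terms.items():
            genes = frozenset(str(g) for g in genes) & background
            if genes:
                kept[str(term)] = genes
        return cls(kept, background)

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, background: AbstractSet[str] | None = None
    ) -> "AnnotationMap":
        """From a two-column ``term_id``/``gene_id`` table.  Without an
        explicit background, the union of annotated genes is used."""
        if not {"term_id", "gene_id"} <= set(frame.columns):
            raise ValueError("annotation table needs term_id and gene_id columns")
        terms: dict[str, set[str]] = {}
        for row in frame.itertuples(index=False):
            terms.setdefault(str(row.term_id), set()).add(str(row.gene_id))
        if background is None:
            background = set().union(*terms.values()) if terms else set()
        return cls.build(terms, background)

    @classmethod
    def from_gmt(
        cls, lines: Iterable[str], background: AbstractSet[str] | None = None
    ) -> "AnnotationMap":
        """From GMT lines (``term<TAB>description<TAB>gene...``)."""
        terms: dict[str, set[str]] = {}
        for line in lines:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            terms[parts[0]] = set(parts[2:])
        if background is None:
            background = set().union(*terms.values()) if terms else set()
        return cls.build(terms, background)


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_enrich(
    query: AbstractSet[str],
    annotations: AnnotationMap,
    min_term_size: int = 2,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query set per term.

    Query genes outside the background are dropped with a warning.  Returns
    one row per tested term with the 2x2 counts (k = query hits, K = term
    size, n = query size, N = background size), the upper-tail p-value,
    its BH adjustment, and -log10(p), sorted by ascending p.
    """
    if not annotations.background:
        raise ValueError("background must be non-empty")
    query = frozenset(str(g) for g in query)
    outside = query - annotations.background
    if outside:
        warnings.warn(
            f"{len(outside)} query gene(s) outside the background were dropped",
            stacklevel=2,
        )
    query &= annotations.background

    n = len(query)
    N = len(annotations.background)
    rows = []
    for term, genes in annotations.terms.items():
        K = len(genes)
        if K < min_term_size:
            continue
        k = len(query & genes)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append({"term_id": term, "k": k, "K": K, "n": n, "N": N, "p": p})
    frame = pd.DataFrame(rows, columns=["term_id", "k", "K", "n", "N", "p"])
    if frame.empty:
        frame["p_bh"] = pd.Series(dtype=float)
        frame["neg_log10_p"] = pd.Series(dtype=float)
        return frame
    frame["p_bh"] = bh_adjust(frame["p"])
    frame["neg_log10_p"] = -np.log10(frame["p"])
    return frame.sort_values(["p", "term_id"], kind="stable").reset_index(drop=True)
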