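"""Hypergeometric over-representation of gene sets in term annotations.

A query gene set (here: consensus targets of differential miRNAs) is tested
against term -> gene annotation maps in the style of GO categories or KEGG
pathways.  For a background of N genes of which K belong to a term, and a
query of n genes of which k hit the term, the enrichment p-value is the
hypergeometric upper tail P(X >= k).  Benjamini-Hochberg q-values are
reported across all tested terms; only over-representation is tested.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Iterable

import pandas as pd
from scipy.stats import hypergeom

from .diffexpr import bh_adjust

__all__ = [
    "AnnotationMap",
    "EnrichmentResult",
    "read_annotations",
    "hypergeom_pvalue",
    "enrich",
]


@dataclasses.dataclass(frozen=True)
class TermAnnotation:
    term_id: str
    term_name: str
    category: str
    genes: frozenset[str]


@dataclasses.dataclass
class AnnotationMap:
    """term_id -> annotation plus the background gene universe.

    By default the background is the union of all annotated genes (standing
    in for a genome-wide background); it may be overridden, e.g. with the
    consensus-target universe, but must cover every annotated gene.
    """

    terms: dict[str, TermAnnotation]
    background: frozenset[str]

    def __post_init__(self) -> None:
        for term in self.terms.values():
            if not term.genes:
                raise ValueError(f"term {term.term_id!r} has no genes")
            extra = term.genes - self.background
            if extra:
                raise ValueError(
                    f"term {term.term_id!r} has genes outside the background: "
                    f"{sorted(extra)[:5]}"
                )

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, background: Iterable[str] | None = None
    ) -> "AnnotationMap":
        """Build from a long-form table.

        Accepts the four-column dialect (term_id, term_name, category, gene)
        or the minimal two-column one (term_id, gene).
        """
        cols = list(frame.columns)
        if cols == ["term_id", "gene"]:
            frame = frame.assign(term_name=frame["term_id"], category="NA")[
                ["term_id", "term_name", "category", "gene"]
            ]
        elif cols != ["term_id", "term_name", "category", "gene"]:
            raise ValueError(
                "annotation table must have columns (term_id, term_name, "
                f"category, gene) or (term_id, gene); found {cols}"
            )
        terms: dict[str, TermAnnotation] = {}
        for term_id, sub in frame.groupby("term_id", sort=True):
            terms[str(term_id)] = TermAnnotation(
                term_id=str(term_id),
                term_name=str(sub["term_name"].iloc[0]),
                category=str(sub["category"].iloc[0]),
                genes=frozenset(str(g) for g in sub["gene"]),
            )
        if background is None:
            bg = frozenset(str(g) for g in frame["gene"])
        else:
            bg = frozenset(str(g) for g in background)
        return cls(terms=terms, background=bg)


def read_annotations(
    path: str | Path, background: Iterable[str] | None = None
) -> AnnotationMap:
    return AnnotationMap.from_frame(
        pd.read_csv(path, sep="\t", dtype=str), background=background
    )


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("need 0 <= K <= N and 0 <= n <= N")
    if not (0 <= k <= min(K, n)):
        raise ValueError("need 0 <= k <= min(K, n)")
    return float(hypergeom.sf(k - 1, N, K, n))


@dataclasses.dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    category: str
    k: int
    K: int
    n: int
    N: int
    p: float
    q: float


def enrich(
    query: Iterable[str],
    annot: AnnotationMap,
    min_term_size: int = 1,
) -> pd.DataFrame:
    """Over-representation of a query gene set across all annotated terms.

    Query genes outside the background are dropped with a warning.  One row
    per term with K >= min_term_size, sorted by p ascending (ties by
    term_id); q is BH-adjusted across the tested terms.
    """
    if not annot.background:
        raise ValueError("empty background")
    query_set = {str(g) for g in query}
    outside = query_set - annot.background
    if outside:
        warnings.warn(
            f"{len(outside)} query gene(s) outside the background were dropped",
            stacklevel=2,
        )
        query_set -= outside
    N = len(annot.background)
    n = len(query_set)
    rows = []
    for term_id in sorted(annot.terms):
        term = annot.terms[term_id]
        K = len(term.genes)
        if K < min_term_size:
            continue
        k = len(term.genes & query_set)
        rows.append(
            {
                "term_id": term.term_id,
                "term_name": term.term_name,
                "category": term.category,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p": hypergeom_pvalue(k, K, n, N),
            }
        )
    frame = pd.DataFrame(
        rows, columns=["term_id", "term_name", "category", "k", "K", "n", "N", "p"]
    )
    if len(frame):
        frame["q_bh"] = bh_adjust(frame["p"].to_numpy())
    else:
        frame["q_bh"] = pd.Series(dtype=float)
    return frame.sort_values(["p", "term_id"], kind="mergesort").reset_index(
        drop=True
    )
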