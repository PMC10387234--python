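"""Consensus of miRNA target predictions and the miRNA-mRNA network.

Target genes predicted for each differential miRNA by several tools
(typically RNAhybrid, PITA, Miranda and TargetScan) are combined by
intersection: a gene is retained when at least ``min_sources`` sources
predict it, with the default being all of them, on the premise that genes
predicted by every tool are the more reliable calls.  The surviving edges
form a bipartite regulatory network in which each miRNA node carries its
differential direction (up or down).
"""

from __future__ import annotations

import dataclasses
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "TargetPredictionSet",
    "RegulatoryNetwork",
    "read_target_lists",
    "write_target_list",
    "consensus_targets",
    "venn_counts",
    "build_network",
]


@dataclasses.dataclass
class TargetPredictionSet:
    """Per-source miRNA -> gene-set predictions.

    ``sources`` fixes the source order; ``predictions`` maps
    (source, mirna_id) to a set of gene symbols.
    """

    sources: list[str]
    predictions: dict[tuple[str, str], set[str]]

    def __post_init__(self) -> None:
        known = set(self.sources)
        for (source, _mid), genes in self.predictions.items():
            if source not in known:
                raise ValueError(f"prediction for unlisted source {source!r}")
            if any(not g for g in genes):
                raise ValueError("empty gene symbol")

    @property
    def mirnas(self) -> list[str]:
        return sorted({mid for _, mid in self.predictions})

    def genes(self, source: str, mirna_id: str) -> set[str]:
        return self.predictions.get((source, mirna_id), set())


def read_target_lists(paths: Mapping[str, str | Path]) -> TargetPredictionSet:
    """Load per-source TSVs with columns (mirna_id, gene); duplicates within
    a source are collapsed."""
    sources = list(paths)
    predictions: dict[tuple[str, str], set[str]] = {}
    for source, path in paths.items():
        frame = pd.read_csv(path, sep="\t", dtype=str)
        expected = ["mirna_id", "gene"]
        if list(frame.columns) != expected:
            raise ValueError(
                f"{path}: expected columns {expected}, found {list(frame.columns)}"
            )
        for mid, gene in frame.itertuples(index=False):
            predictions.setdefault((source, str(mid)), set()).add(str(gene))
    return TargetPredictionSet(sources=sources, predictions=predictions)


def write_target_list(
    predictions: Mapping[str, Iterable[str]], path: str | Path
) -> Path:
    """Write one source's miRNA -> genes mapping as a (mirna_id, gene) TSV."""
    path = Path(path)
    rows = [
        {"mirna_id": mid, "gene": gene}
        for mid in sorted(predictions)
        for gene in sorted(predictions[mid])
    ]
    pd.DataFrame(rows, columns=["mirna_id", "gene"]).to_csv(
        path, sep="\t", index=False
    )
    return path


def consensus_targets(
    preds: TargetPredictionSet, min_sources: int | None = None
) -> dict[str, set[str]]:
    """Genes predicted for each miRNA by at least ``min_sources`` sources
    (default: all of them, i.e. the strict intersection)."""
    k = len(preds.sources) if min_sources is None else min_sources
    if not 1 <= k <= len(preds.sources):
        raise ValueError(
            f"min_sources must be within [1, {len(preds.sources)}], got {k}"
        )
    out: dict[str, set[str]] = {}
    for mid in preds.mirnas:
        votes: dict[str, int] = {}
        for source in preds.sources:
            for gene in preds.genes(source, mid):
                votes[gene] = votes.get(gene, 0) + 1
        out[mid] = {g for g, v in votes.items() if v >= k}
    return out


def venn_counts(preds: TargetPredictionSet) -> dict[frozenset[str], int]:
    """Exclusive Venn-region sizes over the per-source gene universes.

    Genes are pooled across miRNAs within each source; each gene in the
    union is assigned to the exact subset of sources predicting it.  Region
    counts over all non-empty subsets sum to the union size.
    """
    if len(preds.sources) > 6:
        raise ValueError("Venn regions only supported for up to 6 sources")
    per_source: dict[str, set[str]] = {s: set() for s in preds.sources}
    for (source, _mid), genes in preds.predictions.items():
        per_source[source] |= genes
    regions: dict[frozenset[str], int] = {
        frozenset(sub): 0
        for r in range(1, len(preds.sources) + 1)
        for sub in combinations(preds.sources, r)
    }
    union = set().union(*per_source.values()) if per_source else set()
    for gene in union:
        member = frozenset(s for s in preds.sources if gene in per_source[s])
        regions[member] += 1
    return regions


@dataclasses.dataclass
class RegulatoryNetwork:
    """Bipartite miRNA -> gene edge set; each miRNA carries its direction."""

    edges: set[tuple[str, str, str]]  # (mirna_id, gene, direction)
    mirna_direction: dict[str, str]

    @property
    def genes(self) -> set[str]:
        return {gene for _, gene, _ in self.edges}

    def to_edge_frame(self) -> pd.DataFrame:
        rows = sorted(self.edges)
        return pd.DataFrame(
            rows, columns=["source_node", "target_node", "mirna_direction"]
        )

    def write_edge_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_edge_frame().to_csv(path, sep="\t", index=False)
        return path

    def write_sif(self, path: str | Path) -> Path:
        """Simple interaction format: mirna <direction-tagged relation> gene."""
        path = Path(path)
        with open(path, "w") as fh:
            for mid, gene, direction in sorted(self.edges):
                fh.write(f"{mid}\ttargets_{direction}\t{gene}\n")
        return path


def build_network(
    de_records: pd.DataFrame | Iterable, consensus: Mapping[str, Iterable[str]]
) -> RegulatoryNetwork:
    """Network over differential miRNAs and their consensus targets.

    ``de_records`` is a differential table (or records) providing
    ``mirna_id`` and ``direction``; every record must be a real call
    (direction 'up' or 'down').
    """
    if isinstance(de_records, pd.DataFrame):
        pairs = list(zip(de_records["mirna_id"], de_records["direction"]))
    else:
        pairs = [(r.mirna_id, r.direction) for r in de_records]
    directions: dict[str, str] = {}
    for mid, direction in pairs:
        if direction not in ("up", "down"):
            raise ValueError(
                f"non-differential record in network input: {mid!r} ({direction!r})"
            )
        directions[mid] = direction
    edges = {
        (mid, gene, directions[mid])
        for mid in directions
        for gene in consensus.get(mid, ())
    }
    return RegulatoryNetwork(edges=edges, mirna_direction=directions)
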