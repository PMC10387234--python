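"""From raw small-RNA FASTQ to a miRNA count matrix and TPM values.

The stages mirror a standard serum small-RNA workflow: quality filtering of
raw reads (poly-N and low-Phred rules), 3' adapter trimming, 18-30 nt length
selection, collapsing identical tags, annotation against a mature-miRNA
reference with contaminant precedence (rRNA/scRNA/snoRNA/snRNA/tRNA first),
and TPM normalisation where the denominator is the total number of clean
tags per library:

    TPM = miRNA tag count / total clean tags * 10^6

Group-level TPM pools counts and clean totals across the group's libraries;
a group value of exactly zero is floored at 0.01 so fold changes stay
finite.  Positive values below the floor are reported as-is.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from pathlib import Path
from typing import Iterable, Iterator, Mapping, TYPE_CHECKING

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

if TYPE_CHECKING:  # pragma: no cover - type-only import
    from .synthetic_data import MiRNAReference

__all__ = [
    "TPM_FLOOR",
    "FastqRecord",
    "ReadTag",
    "QCReport",
    "SampleQuant",
    "MiRNACountMatrix",
    "read_fastq",
    "filter_reads",
    "trim_adapter",
    "select_length",
    "collapse_tags",
    "annotate_tags",
    "quantify_sample",
    "count_matrix",
    "tpm_normalize",
    "group_tpm",
    "zscore_matrix",
]

#: Floor substituted for group TPM values that are exactly zero.
TPM_FLOOR = 0.01

PHRED_OFFSET = 33


@dataclasses.dataclass(frozen=True)
class FastqRecord:
    name: str
    seq: str
    qual: str


@dataclasses.dataclass(frozen=True)
class ReadTag:
    """A collapsed read: one distinct sequence and its multiplicity."""

    seq: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("tag count must be >= 1")


@dataclasses.dataclass
class QCReport:
    """Per-sample accounting of the QC funnel; removals plus survivors
    reconcile with the input at every stage."""

    n_input: int = 0
    n_polyN_removed: int = 0
    n_lowqual_removed: int = 0
    n_length_removed: int = 0
    n_contaminant_removed: int = 0
    n_clean: int = 0

    def validate(self) -> None:
        fields = dataclasses.asdict(self)
        if any(v < 0 for v in fields.values()):
            raise ValueError("negative QC counter")
        expected = (
            self.n_polyN_removed
            + self.n_lowqual_removed
            + self.n_length_removed
            + self.n_clean
        )
        if expected != self.n_input:
            raise ValueError(
                f"QC counters do not reconcile: {expected} != {self.n_input}"
            )
        if self.n_contaminant_removed > self.n_clean:
            raise ValueError("contaminant tags exceed clean tags")


def read_fastq(path: str | Path) -> Iterator[FastqRecord]:
    """Stream Phred+33 FASTQ records; parse errors name the record index."""
    idx = 0
    with open(path) as fh:
        it = FastqGeneralIterator(fh)
        while True:
            try:
                name, seq, qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise ValueError(
                    f"malformed FASTQ record {idx} in {path}: {exc}"
                ) from exc
            if len(seq) != len(qual):
                raise ValueError(
                    f"malformed FASTQ record {idx} in {path}: "
                    "sequence/quality length mismatch"
                )
            yield FastqRecord(name, seq.upper(), qual)
            idx += 1


def _phred(qual: str) -> np.ndarray:
    return np.frombuffer(qual.encode("ascii"), dtype=np.uint8) - PHRED_OFFSET


def filter_reads(
    reads: Iterable[FastqRecord],
    max_n_frac: float = 0.10,
    min_phred: int = 5,
    max_lowqual_frac: float = 0.10,
) -> tuple[list[FastqRecord], QCReport]:
    """Drop low-quality raw reads by two independent rules.

    A read is discarded iff its fraction of ``N`` bases exceeds
    ``max_n_frac`` (strict >) or the fraction of bases with Phred quality
    below ``min_phred`` exceeds ``max_lowqual_frac``.  A read failing both
    rules is attributed to the poly-N counter.
    """
    for name, value in (
        ("max_n_frac", max_n_frac),
        ("max_lowqual_frac", max_lowqual_frac),
    ):
        if not 0 <= value <= 1:
            raise ValueError(f"{name} must be within [0, 1]")
    report = QCReport()
    kept: list[FastqRecord] = []
    for rec in reads:
        report.n_input += 1
        n = len(rec.seq)
        if n and rec.seq.count("N") / n > max_n_frac:
            report.n_polyN_removed += 1
            continue
        if n and np.mean(_phred(rec.qual) < min_phred) > max_lowqual_frac:
            report.n_lowqual_removed += 1
            continue
        kept.append(rec)
    return kept, report


def trim_adapter(seq: str, adapter3: str, min_overlap: int = 6) -> str | None:
    """Remove the 3' adapter; ``None`` means no adapter was found.

    The longest suffix of ``seq`` that exactly matches a prefix of
    ``adapter3`` with at least ``min_overlap`` bases is removed.  Reads that
    run past the insert into the adapter (the normal small-RNA case) are
    thereby trimmed back to the insert.
    """
    if not seq:
        raise ValueError("empty sequence")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    limit = len(seq) - min_overlap
    for start in range(0, limit + 1):
        tail_len = len(seq) - start
        if seq[start:] == adapter3[:tail_len]:
            return seq[:start]
    return None


def select_length(
    seqs: Iterable[str], min_len: int = 18, max_len: int = 30
) -> list[str]:
    """Keep sequences with min_len <= length <= max_len (inclusive)."""
    if min_len < 1 or max_len < min_len:
        raise ValueError("invalid length window")
    return [s for s in seqs if min_len <= len(s) <= max_len]


def collapse_tags(seqs: Iterable[str]) -> list[ReadTag]:
    """Collapse identical sequences into tags; counts conserve read number."""
    counter = Counter(seqs)
    return [ReadTag(seq=s, count=c) for s, c in sorted(counter.items())]


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def annotate_tags(
    tags: Iterable[ReadTag], reference: "MiRNAReference"
) -> dict[str, tuple[str, str | None]]:
    """Classify each tag as contaminant, known miRNA or unannotated.

    Contaminant classes take precedence over miRNA identity, emulating the
    removal of rRNA/scRNA/snoRNA/snRNA/tRNA before miRNA identification.
    Comparison is alphabet-normalised (U -> T), exact-match only.
    """
    contam: dict[str, str] = {}
    for label, seq in reference.contaminants:
        contam.setdefault(_normalize(seq), label)
    mirna: dict[str, str] = {}
    for mid, seq in reference.records:
        key = _normalize(seq)
        if key in mirna:
            raise ValueError(
                f"reference integrity: {mid!r} and {mirna[key]!r} share a "
                "mature sequence"
            )
        mirna[key] = mid
    out: dict[str, tuple[str, str | None]] = {}
    for tag in tags:
        key = _normalize(tag.seq)
        if key in contam:
            out[tag.seq] = (contam[key], None)
        elif key in mirna:
            out[tag.seq] = ("miRNA", mirna[key])
        else:
            out[tag.seq] = ("unannotated", None)
    return out


@dataclasses.dataclass
class SampleQuant:
    """Per-sample quantification: miRNA counts, the clean-tag total
    (the TPM denominator, all annotation classes included) and the QC log."""

    mirna_counts: dict[str, int]
    clean_total: int
    qc: QCReport


def quantify_sample(
    reads: Iterable[FastqRecord],
    reference: "MiRNAReference",
    adapter3: str,
    max_n_frac: float = 0.10,
    min_phred: int = 5,
    max_lowqual_frac: float = 0.10,
    min_len: int = 18,
    max_len: int = 30,
    min_overlap: int = 6,
) -> SampleQuant:
    """Run the full per-library pipeline: QC, trim, select, collapse,
    annotate, count.

    Reads in which no adapter is found are kept untrimmed (the insert is
    assumed to run past the read end) and are then subject to the length
    window like any other sequence.
    """
    kept, report = filter_reads(
        reads,
        max_n_frac=max_n_frac,
        min_phred=min_phred,
        max_lowqual_frac=max_lowqual_frac,
    )
    trimmed: list[str] = []
    for rec in kept:
        t = trim_adapter(rec.seq, adapter3, min_overlap=min_overlap)
        trimmed.append(rec.seq if t is None else t)
    selected = select_length(trimmed, min_len=min_len, max_len=max_len)
    report.n_length_removed = len(trimmed) - len(selected)
    report.n_clean = len(selected)

    tags = collapse_tags(selected)
    annotations = annotate_tags(tags, reference)
    mirna_counts: dict[str, int] = {}
    n_contaminant = 0
    for tag in tags:
        cls, mid = annotations[tag.seq]
        if cls == "miRNA":
            mirna_counts[mid] = mirna_counts.get(mid, 0) + tag.count
        elif cls != "unannotated":
            n_contaminant += tag.count
    report.n_contaminant_removed = n_contaminant
    report.validate()
    return SampleQuant(
        mirna_counts=mirna_counts, clean_total=report.n_clean, qc=report
    )


@dataclasses.dataclass
class MiRNACountMatrix:
    """Integer miRNA x sample read counts plus per-sample clean-tag totals.

    ``clean_totals`` are the TPM denominators: every clean tag in the
    library, miRNA or not, so per-sample miRNA counts never exceed them.
    """

    mirna_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    clean_totals: dict[str, int]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.mirna_ids), len(self.sample_ids)):
            raise ValueError("count matrix shape mismatch")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.mirna_ids)) != len(self.mirna_ids):
            raise ValueError("duplicate miRNA ids")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        for j, sample in enumerate(self.sample_ids):
            total = self.clean_totals.get(sample)
            if total is None or total <= 0:
                raise ValueError(f"missing or non-positive clean total: {sample!r}")
            if self.counts[:, j].sum() > total:
                raise ValueError(
                    f"miRNA counts exceed the clean total for {sample!r}"
                )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.mirna_ids, columns=self.sample_ids
        ).rename_axis("mirna_id")

    def write_tsv(self, counts_path: str | Path, totals_path: str | Path) -> None:
        self.to_frame().to_csv(counts_path, sep="\t")
        pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "clean_total": [self.clean_totals[s] for s in self.sample_ids],
            }
        ).to_csv(totals_path, sep="\t", index=False)

    @classmethod
    def read_tsv(
        cls, counts_path: str | Path, totals_path: str | Path
    ) -> "MiRNACountMatrix":
        frame = pd.read_csv(counts_path, sep="\t", index_col="mirna_id")
        totals = pd.read_csv(totals_path, sep="\t")
        clean_totals = dict(
            zip(totals["sample_id"].astype(str), totals["clean_total"].astype(int))
        )
        return cls(
            mirna_ids=[str(i) for i in frame.index],
            sample_ids=[str(c) for c in frame.columns],
            counts=frame.to_numpy(dtype=np.int64),
            clean_totals=clean_totals,
        )


def count_matrix(
    per_sample: Mapping[str, SampleQuant],
    mirna_ids: list[str] | None = None,
) -> MiRNACountMatrix:
    """Assemble per-sample quantifications into one count matrix.

    ``mirna_ids`` fixes the row order (typically the reference order);
    without it the sorted union of observed ids is used.
    """
    samples = list(per_sample)
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample ids")
    if mirna_ids is None:
        mirna_ids = sorted({m for q in per_sample.values() for m in q.mirna_counts})
    counts = np.zeros((len(mirna_ids), len(samples)), dtype=np.int64)
    row = {m: i for i, m in enumerate(mirna_ids)}
    for j, sample in enumerate(samples):
        for mid, c in per_sample[sample].mirna_counts.items():
            if mid not in row:
                raise ValueError(f"miRNA {mid!r} missing from the id universe")
            counts[row[mid], j] = c
    return MiRNACountMatrix(
        mirna_ids=list(mirna_ids),
        sample_ids=samples,
        counts=counts,
        clean_totals={s: per_sample[s].clean_total for s in samples},
    )


def tpm_normalize(m: MiRNACountMatrix) -> pd.DataFrame:
    """Per-sample TPM: count / clean total * 10^6, without any flooring."""
    totals = np.array([m.clean_totals[s] for s in m.sample_ids], dtype=float)
    if (totals <= 0).any():
        bad = [s for s in m.sample_ids if m.clean_totals[s] <= 0]
        raise ZeroDivisionError(f"zero clean total for samples {bad}")
    return pd.DataFrame(
        m.counts / totals * 1e6, index=m.mirna_ids, columns=m.sample_ids
    ).rename_axis("mirna_id")


def group_tpm(
    m: MiRNACountMatrix,
    design: Mapping[str, str],
    group: str,
    floor: float = TPM_FLOOR,
) -> pd.Series:
    """Group-level TPM from pooled counts and pooled clean totals.

    Values that are exactly zero are replaced by ``floor``; positive values
    below the floor are reported unchanged.
    """
    members = [s for s in m.sample_ids if design.get(s) == group]
    if not members:
        raise ValueError(f"unknown or empty group {group!r}")
    cols = [m.sample_ids.index(s) for s in members]
    pooled = m.counts[:, cols].sum(axis=1)
    total = sum(m.clean_totals[s] for s in members)
    tpm = pooled / total * 1e6
    tpm = np.where(pooled == 0, floor, tpm)
    return pd.Series(tpm, index=m.mirna_ids, name=group).rename_axis("mirna_id")


def zscore_matrix(tpm: pd.DataFrame, pseudo: float = TPM_FLOOR) -> pd.DataFrame:
    """Row-standardise log2(TPM + pseudo) per miRNA (population SD).

    Rows with zero variance map to all zeros; this is the matrix behind the
    blue-to-red expression heat maps.
    """
    if tpm.shape[1] < 2:
        raise ValueError("z-scores need at least two samples")
    logged = np.log2(tpm.to_numpy(dtype=float) + pseudo)
    mean = logged.mean(axis=1, keepdims=True)
    sd = logged.std(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (logged - mean) / sd
    z[np.repeat(sd == 0, tpm.shape[1], axis=1)] = 0.0
    return pd.DataFrame(z, index=tpm.index, columns=tpm.columns)
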