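"""Synthetic data generators for the serum small-RNA profiling pipeline.

Every input the pipeline consumes can be generated here: a miniature
mature-miRNA reference with small-RNA contaminant classes, negative-binomial
count matrices with known spiked fold changes, adapter-ligated FASTQ reads,
per-source miRNA->gene target-prediction lists, term->gene annotation maps,
and qPCR Ct tables referenced to 5sRNA.  Each generator is deterministic for
a fixed seed and emits the simulation truth alongside the data, so recovery
tests never have to re-derive what was injected.

The default study design mirrors a three-group serum biomarker study:
12 seronegative-RA (N-RA), 9 healthy-control (HC) and 9 seropositive-RA
(P-RA) libraries of 18-30 nt small RNAs.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .smallrna_quant import MiRNACountMatrix

__all__ = [
    "CONTAMINANT_CLASSES",
    "TRUSEQ_SMALLRNA_ADAPTER3",
    "DEFAULT_DESIGN",
    "MiRNAReference",
    "Spike",
    "SimulationTruth",
    "make_reference",
    "make_design",
    "simulate_counts",
    "simulate_reads",
    "simulate_qpcr",
    "simulate_target_lists",
    "simulate_annotations",
]

CONTAMINANT_CLASSES = ("rRNA", "scRNA", "snoRNA", "snRNA", "tRNA")

# Illumina TruSeq small-RNA 3' adapter; non-periodic, so longest-suffix
# trimming cannot over-trim into the insert.
TRUSEQ_SMALLRNA_ADAPTER3 = "TGGAATTCTCGGGTGCCAAGGAACTCCAGTCAC"

_ALPHABET = np.array(list("ACGT"))

MIN_MATURE_LEN = 18
MAX_MATURE_LEN = 25


def _default_design() -> dict[str, str]:
    design: dict[str, str] = {}
    for group, n in (("N-RA", 12), ("HC", 9), ("P-RA", 9)):
        for i in range(n):
            design[f"{group}-{i + 1:02d}"] = group
    return design


#: sample -> group map of the emulated study: 12 N-RA, 9 HC, 9 P-RA libraries.
DEFAULT_DESIGN: dict[str, str] = _default_design()


def make_design(group_sizes: Mapping[str, int] | None = None) -> dict[str, str]:
    """Build a sample->group map; defaults to the 12/9/9 three-group layout."""
    if group_sizes is None:
        return dict(DEFAULT_DESIGN)
    design: dict[str, str] = {}
    for group, n in group_sizes.items():
        if n < 1:
            raise ValueError(f"group {group!r} needs at least one sample")
        for i in range(n):
            design[f"{group}-{i + 1:02d}"] = group
    return design


@dataclasses.dataclass(frozen=True)
class MiRNAReference:
    """A miniature mature-miRNA reference plus small-RNA contaminants.

    ``records`` maps unique miRNA ids to mature DNA sequences of 18-25 nt;
    ``contaminants`` holds (class, sequence) pairs for the rRNA/scRNA/snoRNA/
    snRNA/tRNA classes that are removed before miRNA counting.  No mature
    sequence is a substring of another, which makes exact-match annotation
    unambiguous.
    """

    records: tuple[tuple[str, str], ...]
    contaminants: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        ids = [mid for mid, _ in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate miRNA ids in reference")
        for mid, seq in self.records:
            if not seq or set(seq) - set("ACGTUN"):
                raise ValueError(f"invalid sequence for {mid!r}")
            if not (MIN_MATURE_LEN <= len(seq) <= MAX_MATURE_LEN):
                raise ValueError(f"mature length out of [18, 25] for {mid!r}")
        for label, seq in self.contaminants:
            if label not in CONTAMINANT_CLASSES:
                raise ValueError(f"unknown contaminant class {label!r}")
            if not seq:
                raise ValueError("empty contaminant sequence")

    @property
    def mirna_ids(self) -> list[str]:
        return [mid for mid, _ in self.records]

    def write_fasta(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            for mid, seq in self.records:
                fh.write(f">{mid}\n{seq}\n")
            for i, (label, seq) in enumerate(self.contaminants, start=1):
                fh.write(f">contam-{i:03d} class={label}\n{seq}\n")
        return path


@dataclasses.dataclass(frozen=True)
class Spike:
    """A planted differential effect: the elevated group and its fold change."""

    group: str
    fold: float

    def __post_init__(self) -> None:
        if self.fold <= 0:
            raise ValueError("true fold change must be > 0")


@dataclasses.dataclass
class SimulationTruth:
    """What was injected into a simulated dataset.

    ``spiked`` maps miRNA ids to the group whose mean was multiplied by the
    stated fold change; all other group means are at baseline.
    ``library_sizes`` are the total clean-tag counts per sample (the TPM
    denominators).
    """

    spiked: dict[str, Spike]
    library_sizes: dict[str, int]
    seed: int

    def __post_init__(self) -> None:
        for sample, size in self.library_sizes.items():
            if size <= 0:
                raise ValueError(f"library size for {sample!r} must be positive")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"mirna_id": mid, "elevated_group": sp.group, "fold": sp.fold}
            for mid, sp in sorted(self.spiked.items())
        ]
        return pd.DataFrame(rows, columns=["mirna_id", "elevated_group", "fold"])


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_ALPHABET, size=length))


def _substring_free(candidate: str, accepted: Sequence[str]) -> bool:
    return not any(candidate in s or s in candidate for s in accepted)


def make_reference(
    n_mirnas: int, n_contaminants: int = 0, seed: int = 0
) -> MiRNAReference:
    """Generate a random substring-free mature-miRNA reference.

    Mature sequences are uniform random DNA of 18-25 nt, rejection-sampled so
    that no sequence (miRNA or contaminant) is a substring of any other.
    Contaminants cycle through the rRNA/scRNA/snoRNA/snRNA/tRNA classes with
    lengths of 18-28 nt, so they survive the pipeline's length window and
    exercise annotation precedence.
    """
    if n_mirnas < 0 or n_contaminants < 0:
        raise ValueError("sizes must be non-negative")
    rng = np.random.default_rng(seed)
    seqs: list[str] = []
    while len(seqs) < n_mirnas + n_contaminants:
        if len(seqs) < n_mirnas:
            length = int(rng.integers(MIN_MATURE_LEN, MAX_MATURE_LEN + 1))
        else:
            length = int(rng.integers(18, 29))
        cand = _random_seq(rng, length)
        if _substring_free(cand, seqs):
            seqs.append(cand)
    records = tuple(
        (f"syn-miR-{i + 1:03d}", seq) for i, seq in enumerate(seqs[:n_mirnas])
    )
    contaminants = tuple(
        (CONTAMINANT_CLASSES[i % len(CONTAMINANT_CLASSES)], seq)
        for i, seq in enumerate(seqs[n_mirnas:])
    )
    return MiRNAReference(records=records, contaminants=contaminants)


def simulate_counts(
    reference: MiRNAReference,
    design: Mapping[str, str],
    truth: SimulationTruth,
    baseline_mean: float = 100.0,
    dispersion: float = 0.0,
) -> tuple[MiRNACountMatrix, SimulationTruth]:
    """Draw a miRNA x sample count matrix with planted fold changes.

    Each count is negative-binomial with mean
    ``baseline_mean * library_size / mean_library_size * fold`` and variance
    ``mean + dispersion * mean**2``; ``dispersion = 0`` is exact Poisson
    sampling, the model under which the differential test is exact.  The
    clean-tag totals equal the library sizes; the expected miRNA tag total
    must stay below each library size (the remainder stands for non-miRNA
    clean tags).
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    missing = set(sp.group for sp in truth.spiked.values()) - set(design.values())
    if missing:
        raise ValueError(f"spiked groups absent from design: {sorted(missing)}")
    unknown = set(truth.spiked) - set(reference.mirna_ids)
    if unknown:
        raise ValueError(f"spiked ids absent from reference: {sorted(unknown)}")

    samples = list(design)
    mirna_ids = reference.mirna_ids
    sizes = np.array([truth.library_sizes[s] for s in samples], dtype=float)
    size_factor = sizes / sizes.mean()

    mean = np.tile(baseline_mean * size_factor, (len(mirna_ids), 1))
    for mid, spike in truth.spiked.items():
        i = mirna_ids.index(mid)
        in_group = np.array([design[s] == spike.group for s in samples])
        mean[i, in_group] *= spike.fold

    if np.any(mean.sum(axis=0) > 0.9 * sizes):
        raise ValueError(
            "expected miRNA tag total exceeds 90% of a library size; "
            "lower baseline_mean or raise library sizes"
        )

    rng = np.random.default_rng(truth.seed)
    if dispersion == 0:
        counts = rng.poisson(mean)
    else:
        # NB with variance mu + dispersion * mu^2  <=>  shape n = 1/dispersion
        n_shape = 1.0 / dispersion
        p = n_shape / (n_shape + mean)
        counts = rng.negative_binomial(n_shape, p)

    matrix = MiRNACountMatrix(
        mirna_ids=list(mirna_ids),
        sample_ids=samples,
        counts=counts.astype(np.int64),
        clean_totals={s: int(truth.library_sizes[s]) for s in samples},
    )
    return matrix, truth


def _format_read(
    body: str, adapter3: str, read_length: int
) -> str:
    full = body + adapter3
    if len(full) < read_length:
        raise ValueError(
            "adapter shorter than the padding needed to reach the read length"
        )
    return full[:read_length]


def simulate_reads(
    counts: MiRNACountMatrix,
    reference: MiRNAReference,
    out_dir: str | Path,
    adapter3: str = TRUSEQ_SMALLRNA_ADAPTER3,
    frac_polyN: float = 0.0,
    frac_lowqual: float = 0.0,
    seed: int = 0,
    read_length: int = 50,
    fill_to_total: bool = True,
) -> dict[str, Path]:
    """Write one Phred+33 FASTQ per sample realising a count matrix.

    Every counted miRNA molecule becomes one read: the mature sequence
    (DNA alphabet) followed by the 3' adapter, truncated to ``read_length``.
    With ``fill_to_total`` the gap between the miRNA tag total and the
    library's clean total is filled with contaminant-derived reads, so the
    quantifier's clean-tag denominators reproduce the simulated ones exactly.
    Junk reads carrying the two QC failure modes are injected on top at the
    given fractions of the clean total: poly-N bodies (all ``N``) and
    low-quality reads whose every base is below Phred 5.
    """
    if not 0 <= frac_polyN <= 1 or not 0 <= frac_lowqual <= 1:
        raise ValueError("junk fractions must be within [0, 1]")
    min_body = min(
        [len(s) for _, s in reference.records]
        + [len(s) for _, s in reference.contaminants],
        default=MIN_MATURE_LEN,
    )
    if min_body + len(adapter3) < read_length:
        raise ValueError(
            "adapter shorter than the padding needed to reach the read length"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    hi_qual = "I" * read_length  # Phred 40
    lo_qual = "#" * read_length  # Phred 2, below the Phred-5 cutoff
    paths: dict[str, Path] = {}
    seq_by_id = {mid: seq.replace("U", "T") for mid, seq in reference.records}

    for j, sample in enumerate(counts.sample_ids):
        bodies: list[str] = []
        quals: list[str] = []
        for i, mid in enumerate(counts.mirna_ids):
            seq = seq_by_id[mid]
            bodies.extend([seq] * int(counts.counts[i, j]))
        quals.extend([hi_qual] * len(bodies))

        if fill_to_total:
            gap = counts.clean_totals[sample] - len(bodies)
            if gap < 0:
                raise ValueError(
                    f"miRNA tags exceed the clean total for sample {sample!r}"
                )
            if gap:
                if not reference.contaminants:
                    raise ValueError(
                        "fill_to_total requires contaminant sequences in the "
                        "reference"
                    )
                picks = rng.integers(0, len(reference.contaminants), size=gap)
                for k in picks:
                    bodies.append(reference.contaminants[k][1].replace("U", "T"))
                quals.extend([hi_qual] * int(gap))

        n_clean = counts.clean_totals[sample] if fill_to_total else len(bodies)
        n_polyN = int(round(frac_polyN * n_clean))
        n_lowq = int(round(frac_lowqual * n_clean))
        for _ in range(n_polyN):
            bodies.append("N" * int(rng.integers(18, 31)))
            quals.append(hi_qual)
        for _ in range(n_lowq):
            bodies.append(_random_seq(rng, int(rng.integers(18, 31))))
            quals.append(lo_qual)

        order = rng.permutation(len(bodies))
        path = out_dir / f"{sample}.fastq"
        with open(path, "w") as fh:
            for r, k in enumerate(order):
                seq = _format_read(bodies[k], adapter3, read_length)
                fh.write(f"@{sample}:{r + 1}\n{seq}\n+\n{quals[k][:len(seq)]}\n")
        paths[sample] = path
    return paths


def simulate_qpcr(
    groups: Mapping[str, str],
    true_log2fc: Mapping[str, float],
    ct_ref_mean: float = 20.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    base_delta_ct: float = 5.0,
) -> pd.DataFrame:
    """Simulate a qPCR Ct table (target vs a 5sRNA-style reference).

    Per sample the reference Ct is ``ct_ref_mean`` plus Gaussian noise and the
    target Ct is ``ref_ct + base_delta_ct - true_log2fc[group]`` plus noise,
    so with a calibrator group at log2 fold 0 the expected per-sample log2
    relative expression (-ddCt) equals the injected value; at zero noise the
    recovery is exact.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if not groups:
        raise ValueError("empty sample->group map")
    missing = set(groups.values()) - set(true_log2fc)
    if missing:
        raise ValueError(f"groups without a true log2 fold: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    rows = []
    for sample, group in groups.items():
        ref_ct = ct_ref_mean + rng.normal(0.0, noise_sd)
        target_ct = (
            ref_ct
            + base_delta_ct
            - true_log2fc[group]
            + rng.normal(0.0, noise_sd)
        )
        rows.append(
            {
                "sample_id": sample,
                "group": group,
                "target_ct": target_ct,
                "ref_ct": ref_ct,
            }
        )
    return pd.DataFrame(rows)


def simulate_target_lists(
    mirnas: Sequence[str],
    gene_universe: Sequence[str],
    n_sources: int = 4,
    overlap: float = 0.5,
    genes_per_mirna: int = 100,
    seed: int = 0,
) -> tuple[dict[str, dict[str, set[str]]], dict[str, set[str]]]:
    """Generate per-source target predictions with a known consensus core.

    For each miRNA a core of ``round(overlap * genes_per_mirna)`` genes is
    shared by every source; the remaining genes of each source are drawn
    disjointly from the rest of the universe, so the strict intersection
    equals the core by construction.  Returns ``(predictions, core_truth)``
    where predictions maps source -> mirna -> gene set.  The first four
    sources carry the names of the common prediction tools.
    """
    if n_sources < 1:
        raise ValueError("n_sources must be >= 1")
    if not 0 <= overlap <= 1:
        raise ValueError("overlap must be within [0, 1]")
    n_core = int(round(overlap * genes_per_mirna))
    n_extra = genes_per_mirna - n_core
    if n_core + n_sources * n_extra > len(gene_universe):
        raise ValueError("gene universe too small for the requested layout")
    canonical = ["RNAhybrid", "PITA", "Miranda", "TargetScan"]
    sources = [
        canonical[i] if i < len(canonical) else f"source{i + 1}"
        for i in range(n_sources)
    ]
    rng = np.random.default_rng(seed)
    universe = np.array(gene_universe)
    predictions: dict[str, dict[str, set[str]]] = {s: {} for s in sources}
    core_truth: dict[str, set[str]] = {}
    for mid in mirnas:
        picks = rng.choice(
            len(universe), size=n_core + n_sources * n_extra, replace=False
        )
        core = set(universe[picks[:n_core]])
        core_truth[mid] = core
        for si, source in enumerate(sources):
            lo = n_core + si * n_extra
            extra = set(universe[picks[lo : lo + n_extra]])
            predictions[source][mid] = core | extra
    return predictions, core_truth


def simulate_annotations(
    gene_universe: Sequence[str],
    n_terms: int = 20,
    term_size_range: tuple[int, int] = (10, 50),
    category: str = "GO",
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a term->gene annotation table over a gene universe.

    Returns a long-form frame with columns (term_id, term_name, category,
    gene), the four-column annotation dialect the enrichment module reads.
    """
    if n_terms < 0:
        raise ValueError("n_terms must be >= 0")
    lo, hi = term_size_range
    if not 1 <= lo <= hi <= len(gene_universe):
        raise ValueError("invalid term size range for this universe")
    rng = np.random.default_rng(seed)
    universe = np.array(gene_universe)
    rows = []
    for t in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        genes = rng.choice(universe, size=size, replace=False)
        tid = f"{category}:{t + 1:07d}"
        for g in genes:
            rows.append(
                {
                    "term_id": tid,
                    "term_name": f"synthetic term {t + 1}",
                    "category": category,
                    "gene": str(g),
                }
            )
    return pd.DataFrame(rows, columns=["term_id", "term_name", "category", "gene"])
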