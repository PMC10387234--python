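"""End-to-end orchestration: simulate -> quant -> diffexpr -> targets ->
enrichment -> qpcr, plus the printed-table replay mode.

``run`` executes the configured stages into a run directory and writes a
manifest with the parameters and SHA-256 hashes of every output, so a
repeated run with the same configuration and seed is verifiably identical.
``replay_tables`` re-derives the log2 fold change and sign-based direction
from a published table's two group-TPM columns, reporting the per-row
deviation when the table also carries the printed fold-change column.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import diffexpr, enrichment, qpcr, smallrna_quant, synthetic_data, target_consensus
from .diffexpr import log2_fold_change
from .smallrna_quant import MiRNACountMatrix, TPM_FLOOR

__all__ = [
    "RunConfig",
    "StageError",
    "run",
    "replay_tables",
    "load_printed_table",
    "PRINTED_TABLES",
]

#: Packaged published comparison tables: name -> (resource, group_a, group_b).
PRINTED_TABLES: dict[str, tuple[str, str, str]] = {
    "table1": ("table1_nra_vs_hc.tsv", "N-RA", "HC"),
    "table2": ("table2_nra_vs_pra.tsv", "N-RA", "P-RA"),
    "table3": ("table3_pra_vs_hc.tsv", "P-RA", "HC"),
}


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclasses.dataclass
class RunConfig:
    """All knobs of a pipeline run; every threshold appears exactly once.

    The QC fractions, the 18-30 nt window, the 0.01 TPM floor, the
    fold-change threshold 2 and alpha 0.05 are the canonical small-RNA
    profiling settings; the simulation block controls the synthetic study
    (three groups of 12/9/9 libraries by default, with library sizes kept
    modest so an end-to-end run stays interactive).
    """

    out_dir: str = "run"
    seed: int = 0
    # stage toggles
    do_simulate: bool = True
    do_quant: bool = True
    do_diffexpr: bool = True
    do_targets: bool = True
    do_enrichment: bool = True
    do_qpcr: bool = True
    # QC / quantification thresholds
    max_n_frac: float = 0.10
    min_phred: int = 5
    max_lowqual_frac: float = 0.10
    min_len: int = 18
    max_len: int = 30
    tpm_floor: float = TPM_FLOOR
    # differential selection
    fc_threshold: float = 2.0
    alpha: float = 0.05
    tail: str = "two-sided"
    # consensus / enrichment
    min_sources: int | None = None
    min_term_size: int = 1
    # qPCR
    calibrator_group: str = "HC"
    # simulation block
    n_mirnas: int = 60
    n_contaminants: int = 10
    group_sizes: dict[str, int] = dataclasses.field(
        default_factory=lambda: {"N-RA": 12, "HC": 9, "P-RA": 9}
    )
    library_size: int = 20_000
    baseline_mean: float = 100.0
    dispersion: float = 0.0
    n_spiked: int = 6
    spike_fold: float = 8.0
    frac_polyN: float = 0.02
    frac_lowqual: float = 0.02
    read_length: int = 50
    adapter3: str = synthetic_data.TRUSEQ_SMALLRNA_ADAPTER3
    gene_universe_size: int = 2000
    genes_per_mirna: int = 100
    target_overlap: float = 0.5
    n_target_sources: int = 4
    n_terms: int = 25
    qpcr_true_log2fc: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"HC": 0.0, "N-RA": 1.4, "P-RA": 0.1}
    )
    qpcr_noise_sd: float = 0.3

    def validate(self) -> None:
        for name in ("max_n_frac", "max_lowqual_frac", "frac_polyN", "frac_lowqual"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be within [0, 1]")
        if not 1 <= self.min_len <= self.max_len:
            raise ValueError("invalid length window")
        if self.fc_threshold < 1:
            raise ValueError("fc_threshold must be >= 1")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be within (0, 1]")
        if self.tpm_floor <= 0:
            raise ValueError("tpm_floor must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(data) - known
        if extra:
            raise ValueError(f"unknown config keys: {sorted(extra)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)
        return path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _log(stage: str, message: str) -> None:
    print(f"[{stage}] {message}", file=sys.stderr)


def run(config: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest (also written to
    ``<out_dir>/manifest.json``)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}}
    config.to_yaml(out / "config.yaml")

    design = synthetic_data.make_design(config.group_sizes)
    reference = None
    counts: MiRNACountMatrix | None = None
    de_tables: dict[str, pd.DataFrame] = {}
    comparisons = [("N-RA", "HC"), ("N-RA", "P-RA"), ("P-RA", "HC")]
    groups = list(dict.fromkeys(design.values()))
    comparisons = [c for c in comparisons if c[0] in groups and c[1] in groups]
    if not comparisons and len(groups) >= 2:
        comparisons = [(groups[0], groups[1])]

    def record(stage: str, outputs: Mapping[str, Path], **params) -> None:
        manifest["stages"][stage] = {
            "status": "done",
            "params": params,
            "outputs": {name: _sha256(Path(p)) for name, p in outputs.items()},
        }

    def skip(stage: str) -> None:
        manifest["stages"][stage] = {"status": "skipped"}
        _log(stage, "skipped")

    # ---- simulate -------------------------------------------------------
    if config.do_simulate:
        stage = "simulate"
        try:
            _log(stage, f"seed={config.seed}")
            rng = np.random.default_rng(config.seed)
            reference = synthetic_data.make_reference(
                config.n_mirnas, config.n_contaminants, seed=config.seed
            )
            sizes = {
                s: int(rng.integers(
                    int(0.8 * config.library_size), int(1.2 * config.library_size) + 1
                ))
                for s in design
            }
            spiked_ids = rng.choice(
                reference.mirna_ids, size=min(config.n_spiked, config.n_mirnas),
                replace=False,
            )
            truth = synthetic_data.SimulationTruth(
                spiked={
                    str(mid): synthetic_data.Spike(
                        group=groups[i % len(groups)], fold=config.spike_fold
                    )
                    for i, mid in enumerate(spiked_ids)
                },
                library_sizes=sizes,
                seed=config.seed + 1,
            )
            counts, _ = synthetic_data.simulate_counts(
                reference, design, truth,
                baseline_mean=config.baseline_mean, dispersion=config.dispersion,
            )
            fastq_dir = out / "fastq"
            fastq_paths = synthetic_data.simulate_reads(
                counts, reference, fastq_dir,
                adapter3=config.adapter3, frac_polyN=config.frac_polyN,
                frac_lowqual=config.frac_lowqual, seed=config.seed + 2,
                read_length=config.read_length,
            )
            ct = synthetic_data.simulate_qpcr(
                design, config.qpcr_true_log2fc,
                noise_sd=config.qpcr_noise_sd, seed=config.seed + 3,
            )
            universe = [f"GENE{i + 1:05d}" for i in range(config.gene_universe_size)]
            predictions, _core = synthetic_data.simulate_target_lists(
                reference.mirna_ids, universe,
                n_sources=config.n_target_sources, overlap=config.target_overlap,
                genes_per_mirna=config.genes_per_mirna, seed=config.seed + 4,
            )
            annotations = synthetic_data.simulate_annotations(
                universe, n_terms=config.n_terms, seed=config.seed + 5
            )

            outputs: dict[str, Path] = {}
            outputs["reference.fasta"] = reference.write_fasta(out / "reference.fasta")
            counts.write_tsv(out / "counts_true.tsv", out / "clean_totals_true.tsv")
            outputs["counts_true.tsv"] = out / "counts_true.tsv"
            outputs["clean_totals_true.tsv"] = out / "clean_totals_true.tsv"
            truth.to_frame().to_csv(out / "truth.tsv", sep="\t", index=False)
            outputs["truth.tsv"] = out / "truth.tsv"
            pd.DataFrame(
                {"sample_id": list(design), "group": list(design.values())}
            ).to_csv(out / "design.tsv", sep="\t", index=False)
            outputs["design.tsv"] = out / "design.tsv"
            ct.to_csv(out / "ct_table.tsv", sep="\t", index=False)
            outputs["ct_table.tsv"] = out / "ct_table.tsv"
            for source, mapping in predictions.items():
                p = target_consensus.write_target_list(
                    mapping, out / f"targets_{source}.tsv"
                )
                outputs[p.name] = p
            annotations.to_csv(out / "annotations.tsv", sep="\t", index=False)
            outputs["annotations.tsv"] = out / "annotations.tsv"
            pd.DataFrame({"gene": universe}).to_csv(
                out / "gene_universe.tsv", sep="\t", index=False
            )
            outputs["gene_universe.tsv"] = out / "gene_universe.tsv"
            for sample, p in fastq_paths.items():
                outputs[f"fastq/{p.name}"] = p
            record(stage, outputs, seed=config.seed)
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc
    else:
        skip("simulate")

    # ---- quant ----------------------------------------------------------
    if config.do_quant:
        stage = "quant"
        try:
            if reference is None:
                raise ValueError("quant needs the simulate stage in this run")
            per_sample = {}
            for sample in design:
                reads = smallrna_quant.read_fastq(out / "fastq" / f"{sample}.fastq")
                per_sample[sample] = smallrna_quant.quantify_sample(
                    reads, reference, config.adapter3,
                    max_n_frac=config.max_n_frac, min_phred=config.min_phred,
                    max_lowqual_frac=config.max_lowqual_frac,
                    min_len=config.min_len, max_len=config.max_len,
                )
            counts = smallrna_quant.count_matrix(
                per_sample, mirna_ids=reference.mirna_ids
            )
            tpm = smallrna_quant.tpm_normalize(counts)
            z = smallrna_quant.zscore_matrix(tpm, pseudo=config.tpm_floor)
            qc = pd.DataFrame(
                [
                    {"sample_id": s, **dataclasses.asdict(q.qc)}
                    for s, q in per_sample.items()
                ]
            )
            counts.write_tsv(out / "counts.tsv", out / "clean_totals.tsv")
            tpm.to_csv(out / "tpm.tsv", sep="\t")
            z.to_csv(out / "zscore.tsv", sep="\t")
            qc.to_csv(out / "qc_report.tsv", sep="\t", index=False)
            record(
                stage,
                {
                    "counts.tsv": out / "counts.tsv",
                    "clean_totals.tsv": out / "clean_totals.tsv",
                    "tpm.tsv": out / "tpm.tsv",
                    "zscore.tsv": out / "zscore.tsv",
                    "qc_report.tsv": out / "qc_report.tsv",
                },
                max_n_frac=config.max_n_frac,
                min_phred=config.min_phred,
                max_lowqual_frac=config.max_lowqual_frac,
                length_window=[config.min_len, config.max_len],
            )
            _log(stage, f"{len(per_sample)} libraries quantified")
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc
    else:
        skip("quant")

    # ---- diffexpr -------------------------------------------------------
    if config.do_diffexpr:
        stage = "diffexpr"
        try:
            if counts is None:
                raise ValueError("diffexpr needs counts from quant or simulate")
            outputs = {}
            for a, b in comparisons:
                table = diffexpr.de_table(
                    counts, design, a, b,
                    fc_threshold=config.fc_threshold, alpha=config.alpha,
                    tail=config.tail, floor=config.tpm_floor,
                )
                name = f"de_{a}_vs_{b}.tsv"
                table.to_csv(out / name, sep="\t", index=False)
                outputs[name] = out / name
                de_tables[f"{a}|{b}"] = table
                n_sig = int((table["direction"] != "ns").sum())
                _log(stage, f"{a} vs {b}: {n_sig} differential miRNAs")
            record(
                stage, outputs,
                fc_threshold=config.fc_threshold, alpha=config.alpha,
                tail=config.tail, tpm_floor=config.tpm_floor,
            )
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc
    else:
        skip("diffexpr")

    # ---- targets --------------------------------------------------------
    consensus_union: set[str] = set()
    if config.do_targets:
        stage = "targets"
        try:
            if not de_tables:
                raise ValueError("targets needs differential tables")
            source_paths = {
                p.stem.removeprefix("targets_"): p
                for p in sorted(out.glob("targets_*.tsv"))
            }
            if not source_paths:
                raise ValueError("no target-prediction lists found")
            preds = target_consensus.read_target_lists(source_paths)
            consensus = target_consensus.consensus_targets(
                preds, min_sources=config.min_sources
            )
            directions: dict[str, str] = {}
            for table in de_tables.values():
                sig = table[table["direction"] != "ns"]
                for mid, direction in zip(sig["mirna_id"], sig["direction"]):
                    directions.setdefault(mid, direction)
            sig_records = pd.DataFrame(
                {"mirna_id": list(directions), "direction": list(directions.values())}
            )
            sig_consensus = {m: consensus.get(m, set()) for m in directions}
            network = target_consensus.build_network(sig_records, sig_consensus)
            consensus_union = set().union(*sig_consensus.values()) if sig_consensus else set()

            cons_rows = [
                {"mirna_id": m, "gene": g}
                for m in sorted(sig_consensus)
                for g in sorted(sig_consensus[m])
            ]
            pd.DataFrame(cons_rows, columns=["mirna_id", "gene"]).to_csv(
                out / "consensus_targets.tsv", sep="\t", index=False
            )
            venn = target_consensus.venn_counts(preds)
            pd.DataFrame(
                [
                    {"sources": "&".join(sorted(k)), "n_genes": v}
                    for k, v in sorted(venn.items(), key=lambda kv: sorted(kv[0]))
                ]
            ).to_csv(out / "venn_regions.tsv", sep="\t", index=False)
            network.write_edge_tsv(out / "network_edges.tsv")
            network.write_sif(out / "network.sif")
            record(
                stage,
                {
                    "consensus_targets.tsv": out / "consensus_targets.tsv",
                    "venn_regions.tsv": out / "venn_regions.tsv",
                    "network_edges.tsv": out / "network_edges.tsv",
                    "network.sif": out / "network.sif",
                },
                min_sources=config.min_sources or len(preds.sources),
            )
            _log(stage, f"{len(network.edges)} network edges")
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc
    else:
        skip("targets")

    # ---- enrichment -----------------------------------------------------
    if config.do_enrichment:
        stage = "enrichment"
        try:
            universe_path = out / "gene_universe.tsv"
            background = (
                pd.read_csv(universe_path, sep="\t")["gene"].astype(str).tolist()
                if universe_path.exists()
                else None
            )
            annot = enrichment.read_annotations(
                out / "annotations.tsv", background=background
            )
            result = enrichment.enrich(
                consensus_union, annot, min_term_size=config.min_term_size
            )
            result.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            record(
                stage, {"enrichment.tsv": out / "enrichment.tsv"},
                min_term_size=config.min_term_size, n_query=len(consensus_union),
            )
            _log(stage, f"{len(result)} terms tested")
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc
    else:
        skip("enrichment")

    # ---- qpcr -----------------------------------------------------------
    if config.do_qpcr:
        stage = "qpcr"
        try:
            ct = qpcr.read_ct_table(out / "ct_table.tsv")
            folds = qpcr.delta_delta_ct(ct, calibrator_group=config.calibrator_group)
            summary = qpcr.group_summary(folds)
            f_stat, p_anova = qpcr.group_anova(folds)
            folds.to_csv(out / "qpcr_folds.tsv", sep="\t", index=False)
            summary.to_csv(out / "qpcr_summary.tsv", sep="\t", index=False)
            anova = pd.DataFrame([{"F": f_stat, "p": p_anova}])
            anova.to_csv(out / "qpcr_anova.tsv", sep="\t", index=False)
            record(
                stage,
                {
                    "qpcr_folds.tsv": out / "qpcr_folds.tsv",
                    "qpcr_summary.tsv": out / "qpcr_summary.tsv",
                    "qpcr_anova.tsv": out / "qpcr_anova.tsv",
                },
                calibrator=config.calibrator_group,
            )
            _log(stage, f"ANOVA F={f_stat:.3g} p={p_anova:.3g}")
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc
    else:
        skip("qpcr")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _clean_number(value) -> float:
    # tolerate the typographic minus used in published tables
    return float(str(value).replace("−", "-"))


def load_printed_table(name: str) -> pd.DataFrame:
    """Load a packaged published comparison table (``table1``..``table3``).

    Columns: mirna_id, tpm_a, tpm_b (group TPMs, already floored at 0.01
    where the group had no reads), direction, log2fc; the compared groups
    are recorded in ``DataFrame.attrs``.
    """
    if name not in PRINTED_TABLES:
        raise KeyError(f"unknown table {name!r}; expected {sorted(PRINTED_TABLES)}")
    resource, group_a, group_b = PRINTED_TABLES[name]
    ref = resources.files("mirnapipe.data.tables") / resource
    with resources.as_file(ref) as path:
        frame = pd.read_csv(path, sep="\t")
    frame.attrs["group_a"] = group_a
    frame.attrs["group_b"] = group_b
    return frame


def replay_tables(table: pd.DataFrame | str | Path) -> pd.DataFrame:
    """Recompute log2 fold change and direction from group-TPM columns.

    Input needs columns (mirna_id, tpm_a, tpm_b); TPMs must be positive
    (published tables are pre-floored).  Adds ``log2fc_recomputed`` and
    ``direction_recomputed`` (by sign), and ``abs_delta_log2fc`` when a
    printed ``log2fc`` column is present.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep="\t")
    required = {"mirna_id", "tpm_a", "tpm_b"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"replay table missing columns {sorted(missing)}")
    frame = table.copy()
    frame["tpm_a"] = frame["tpm_a"].map(_clean_number)
    frame["tpm_b"] = frame["tpm_b"].map(_clean_number)
    if (frame["tpm_a"] <= 0).any() or (frame["tpm_b"] <= 0).any():
        raise ValueError("non-positive TPM in replay table (tables are floored)")
    frame["log2fc_recomputed"] = [
        log2_fold_change(a, b) for a, b in zip(frame["tpm_a"], frame["tpm_b"])
    ]
    frame["direction_recomputed"] = np.where(
        frame["log2fc_recomputed"] >= 0, "up", "down"
    )
    if "log2fc" in frame.columns:
        printed = frame["log2fc"].map(_clean_number)
        frame["abs_delta_log2fc"] = (frame["log2fc_recomputed"] - printed).abs()
    return frame
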