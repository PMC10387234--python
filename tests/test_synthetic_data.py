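"""Generators: determinism, invariants, and truth recovery at zero noise."""

import numpy as np
import pandas as pd
import pytest

from mirnapipe import synthetic_data as sd


class TestMakeReference:
    def test_empty(self):
        ref = sd.make_reference(0, 0, seed=1)
        assert ref.records == () and ref.contaminants == ()

    def test_seeded_determinism(self, tmp_path):
        a = sd.make_reference(5, 2, seed=42)
        b = sd.make_reference(5, 2, seed=42)
        fa = a.write_fasta(tmp_path / "a.fasta").read_bytes()
        fb = b.write_fasta(tmp_path / "b.fasta").read_bytes()
        assert fa == fb

    def test_substring_freedom_and_lengths(self):
        ref = sd.make_reference(50, 10, seed=7)
        ids = ref.mirna_ids
        assert len(set(ids)) == 50
        seqs = [s for _, s in ref.records] + [s for _, s in ref.contaminants]
        assert all(18 <= len(s) <= 25 for _, s in ref.records)
        # all-pairs scan: no sequence contained in another
        for i, a in enumerate(seqs):
            for j, b in enumerate(seqs):
                if i != j:
                    assert a not in b

    def test_negative_sizes_rejected(self):
        with pytest.raises(ValueError):
            sd.make_reference(-1, 0, seed=0)


class TestSimulateCounts:
    def _truth(self, design, spiked, lib=1_000_000, seed=9):
        return sd.SimulationTruth(
            spiked=spiked, library_sizes={s: lib for s in design}, seed=seed
        )

    def test_spike_ratio_recovered_at_depth(self):
        ref = sd.make_reference(10, 0, seed=1)
        design = sd.make_design({"A": 1, "B": 1})
        truth = self._truth(
            design, {"syn-miR-001": sd.Spike(group="A", fold=8.0)}
        )
        counts, _ = sd.simulate_counts(
            ref, design, truth, baseline_mean=50_000.0, dispersion=0.0
        )
        i = counts.mirna_ids.index("syn-miR-001")
        ratio = counts.counts[i, 0] / counts.counts[i, 1]
        assert ratio == pytest.approx(8.0, rel=0.10)

    def test_null_log_ratios_center_on_zero(self):
        ref = sd.make_reference(100, 0, seed=2)
        design = sd.make_design({"A": 3, "B": 3})
        truth = self._truth(design, {}, lib=100_000, seed=3)
        counts, _ = sd.simulate_counts(ref, design, truth, baseline_mean=500.0)
        a = counts.counts[:, :3].sum(axis=1)
        b = counts.counts[:, 3:].sum(axis=1)
        log_ratios = np.log2(a / b)
        assert abs(log_ratios.mean()) < 0.05

    def test_seeded_determinism(self, reference, two_group_design):
        truth = self._truth(two_group_design, {}, lib=10_000, seed=4)
        c1, _ = sd.simulate_counts(reference, two_group_design, truth)
        c2, _ = sd.simulate_counts(reference, two_group_design, truth)
        assert np.array_equal(c1.counts, c2.counts)

    def test_negative_dispersion_rejected(self, reference, two_group_design):
        truth = self._truth(two_group_design, {}, lib=10_000)
        with pytest.raises(ValueError):
            sd.simulate_counts(reference, two_group_design, truth, dispersion=-1)

    def test_overdispersed_counts_inflate_variance(self, reference, two_group_design):
        truth = self._truth(two_group_design, {}, lib=50_000, seed=8)
        poisson, _ = sd.simulate_counts(
            reference, two_group_design, truth, baseline_mean=300.0, dispersion=0.0
        )
        nb, _ = sd.simulate_counts(
            reference, two_group_design, truth, baseline_mean=300.0, dispersion=0.5
        )
        assert nb.counts.var() > 3 * poisson.counts.var()


class TestSimulateReads:
    def test_seeded_determinism(self, reference, two_group_design, tmp_path):
        truth = sd.SimulationTruth(
            spiked={}, library_sizes={s: 500 for s in two_group_design}, seed=6
        )
        counts, _ = sd.simulate_counts(reference, two_group_design, truth,
                                       baseline_mean=10.0)
        p1 = sd.simulate_reads(counts, reference, tmp_path / "r1", seed=13,
                               frac_polyN=0.1, frac_lowqual=0.1)
        p2 = sd.simulate_reads(counts, reference, tmp_path / "r2", seed=13,
                               frac_polyN=0.1, frac_lowqual=0.1)
        for s in counts.sample_ids:
            assert p1[s].read_bytes() == p2[s].read_bytes()

    def test_adapter_too_short_rejected(self, reference, two_group_design, tmp_path):
        truth = sd.SimulationTruth(
            spiked={}, library_sizes={s: 1000 for s in two_group_design}, seed=6
        )
        counts, _ = sd.simulate_counts(reference, two_group_design, truth,
                                       baseline_mean=5.0)
        with pytest.raises(ValueError, match="adapter shorter"):
            sd.simulate_reads(counts, reference, tmp_path, adapter3="ACGTACGT")


class TestSimulateQpcr:
    def test_zero_noise_null_gives_fold_one(self):
        groups = {"s1": "HC", "s2": "HC", "s3": "RA", "s4": "RA"}
        ct = sd.simulate_qpcr(groups, {"HC": 0.0, "RA": 0.0}, noise_sd=0.0)
        dct = ct["target_ct"] - ct["ref_ct"]
        assert np.allclose(2 ** -(dct - dct[:2].mean()), 1.0)

    def test_zero_noise_twofold(self):
        groups = {"h1": "HC", "h2": "HC", "r1": "RA", "r2": "RA"}
        ct = sd.simulate_qpcr(groups, {"HC": 0.0, "RA": 1.0}, noise_sd=0.0)
        dct = ct["target_ct"] - ct["ref_ct"]
        ddct = dct - dct[ct["group"] == "HC"].mean()
        folds = 2.0 ** -ddct[ct["group"] == "RA"]
        assert np.allclose(folds, 2.0)

    def test_noisy_recovery_within_three_sem(self):
        n = 10
        groups = {f"h{i}": "HC" for i in range(n)} | {f"r{i}": "RA" for i in range(n)}
        ct = sd.simulate_qpcr(groups, {"HC": 0.0, "RA": 1.0}, noise_sd=0.2, seed=21)
        dct = ct["target_ct"] - ct["ref_ct"]
        ddct = dct - dct[ct["group"] == "HC"].mean()
        ra = -ddct[ct["group"] == "RA"]
        sem = ra.std(ddof=1) / np.sqrt(n)
        assert abs(ra.mean() - 1.0) < 3 * sem

    def test_empty_groups_rejected(self):
        with pytest.raises(ValueError):
            sd.simulate_qpcr({}, {"HC": 0.0})


class TestSimulateTargetLists:
    UNIVERSE = [f"G{i}" for i in range(1000)]

    def test_full_overlap_means_identical_sets(self):
        preds, core = sd.simulate_target_lists(
            ["m1", "m2"], self.UNIVERSE, overlap=1.0, genes_per_mirna=30, seed=1
        )
        for mid in ("m1", "m2"):
            sets = [preds[s][mid] for s in preds]
            assert all(s == core[mid] for s in sets)

    def test_zero_overlap_disjoint_peripheries(self):
        preds, core = sd.simulate_target_lists(
            ["m1"], self.UNIVERSE, overlap=0.0, genes_per_mirna=20, seed=2
        )
        sets = [preds[s]["m1"] for s in preds]
        assert core["m1"] == set()
        inter = set.intersection(*sets)
        assert inter == set()

    def test_half_overlap_core_size(self):
        preds, core = sd.simulate_target_lists(
            ["m1"], self.UNIVERSE, n_sources=4, overlap=0.5,
            genes_per_mirna=100, seed=3,
        )
        sets = [preds[s]["m1"] for s in preds]
        assert set.intersection(*sets) == core["m1"]
        assert len(core["m1"]) == 50

    def test_source_names_and_errors(self):
        preds, _ = sd.simulate_target_lists(["m1"], self.UNIVERSE, seed=4)
        assert list(preds) == ["RNAhybrid", "PITA", "Miranda", "TargetScan"]
        with pytest.raises(ValueError):
            sd.simulate_target_lists(["m1"], self.UNIVERSE, n_sources=0)


def test_simulate_annotations_validity():
    universe = [f"G{i}" for i in range(200)]
    frame = sd.simulate_annotations(universe, n_terms=10, seed=5)
    assert list(frame.columns) == ["term_id", "term_name", "category", "gene"]
    assert set(frame["gene"]) <= set(universe)
    sizes = frame.groupby("term_id")["gene"].nunique()
    assert len(sizes) == 10 and sizes.between(10, 50).all()
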