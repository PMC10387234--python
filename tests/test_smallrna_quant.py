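"""QC filtering, trimming, annotation and TPM normalisation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mirnapipe import smallrna_quant as sq
from mirnapipe import synthetic_data as sd
from mirnapipe.smallrna_quant import FastqRecord, MiRNACountMatrix, ReadTag

ADAPTER = sd.TRUSEQ_SMALLRNA_ADAPTER3
HI = "I"
LO = "#"


def _rec(seq, qual_char=HI, name="r"):
    return FastqRecord(name, seq, qual_char * len(seq))


class TestFilterReads:
    def test_poly_n_strict_threshold(self):
        over = _rec("N" * 6 + "A" * 44)   # 12% N -> removed
        at = _rec("N" * 5 + "A" * 45)     # exactly 10% -> kept
        kept, report = sq.filter_reads([over, at])
        assert [r.seq for r in kept] == [at.seq]
        assert report.n_polyN_removed == 1

    def test_lowqual_rule(self):
        # 6 of 50 bases (12%) below Phred 5 -> removed; 5 of 50 kept
        bad = FastqRecord("b", "A" * 50, LO * 6 + HI * 44)
        ok = FastqRecord("o", "A" * 50, LO * 5 + HI * 45)
        kept, report = sq.filter_reads([bad, ok])
        assert [r.name for r in kept] == ["o"]
        assert report.n_lowqual_removed == 1

    def test_batch_bookkeeping(self):
        reads = [_rec("ACGT" * 10, name=f"g{i}") for i in range(900)]
        reads += [_rec("N" * 40, name=f"n{i}") for i in range(100)]
        kept, report = sq.filter_reads(reads)
        assert report.n_input == 1000
        assert report.n_polyN_removed == 100
        assert len(kept) == 900
        report.n_clean = len(kept)
        report.validate()

    def test_malformed_fastq_names_record(self, tmp_path):
        path = tmp_path / "bad.fastq"
        path.write_text("@r1\nACGT\n+\nIIII\n@r2\nACGT\n+\nII\n")
        with pytest.raises(ValueError, match="record 1"):
            list(sq.read_fastq(path))


class TestTrimAdapter:
    def test_exact_ligation_inverse(self):
        assert sq.trim_adapter("ACGT" + ADAPTER, ADAPTER) == "ACGT"

    def test_no_adapter_gives_sentinel(self):
        assert sq.trim_adapter("ACGTACGTACGTACGTACGT", ADAPTER) is None

    def test_partial_adapter_with_min_overlap(self):
        read = "TTTTTTTTTTTTTTTTTT" + ADAPTER[:8]
        assert sq.trim_adapter(read, ADAPTER) == "T" * 18
        assert sq.trim_adapter("T" * 18 + ADAPTER[:5], ADAPTER) is None


class TestSelectLength:
    @pytest.mark.parametrize(
        "length,kept", [(17, False), (18, True), (30, True), (31, False)]
    )
    def test_boundaries(self, length, kept):
        out = sq.select_length(["A" * length])
        assert (out == ["A" * length]) is kept

    def test_constructed_batch(self):
        lengths = [10, 17, 18, 20, 25, 29, 30, 31, 40, 50]
        out = sq.select_length(["C" * n for n in lengths])
        assert len(out) == sum(18 <= n <= 30 for n in lengths)


class TestCollapseTags:
    def test_multiset_counts(self):
        tags = sq.collapse_tags(["A" * 20, "A" * 20, "C" * 20])
        assert {(t.seq, t.count) for t in tags} == {("A" * 20, 2), ("C" * 20, 1)}

    def test_empty(self):
        assert sq.collapse_tags([]) == []

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.sampled_from(["AC" * 10, "GT" * 10, "AG" * 10])))
    def test_conservation(self, seqs):
        assert sum(t.count for t in sq.collapse_tags(seqs)) == len(seqs)


class TestAnnotateTags:
    def test_contaminant_precedence_and_exact_match(self, reference):
        mirna_seq = reference.records[0][1]
        contam_class, contam_seq = reference.contaminants[0]
        tags = [ReadTag(mirna_seq, 2), ReadTag(contam_seq, 1), ReadTag("A" * 22, 1)]
        ann = sq.annotate_tags(tags, reference)
        assert ann[mirna_seq] == ("miRNA", reference.records[0][0])
        assert ann[contam_seq] == (contam_class, None)
        assert ann["A" * 22] == ("unannotated", None)

    def test_contaminant_wins_over_mirna(self):
        seq = "ACGT" * 5
        ref = sd.MiRNAReference(
            records=(("mir-a", seq),), contaminants=(("tRNA", seq),)
        )
        ann = sq.annotate_tags([ReadTag(seq, 1)], ref)
        assert ann[seq] == ("tRNA", None)

    def test_alphabet_normalised_match(self):
        ref = sd.MiRNAReference(records=(("mir-u", "ACGU" * 5),))
        ann = sq.annotate_tags([ReadTag("ACGT" * 5, 1)], ref)
        assert ann["ACGT" * 5] == ("miRNA", "mir-u")

    def test_duplicate_mature_sequence_is_integrity_error(self):
        ref = sd.MiRNAReference(
            records=(("mir-a", "ACGT" * 5), ("mir-b", "ACGT" * 5))
        )
        with pytest.raises(ValueError, match="integrity"):
            sq.annotate_tags([ReadTag("ACGT" * 5, 1)], ref)

    def test_order_independence(self, reference):
        tags = [ReadTag(s, i + 1) for i, (_, s) in enumerate(reference.records)]
        fwd = sq.annotate_tags(tags, reference)
        rev = sq.annotate_tags(tags[::-1], reference)
        assert fwd == rev


class TestCountMatrix:
    def test_single_sample_sums_and_absence(self):
        qa = sq.SampleQuant({"m1": 5}, clean_total=10, qc=sq.QCReport())
        qb = sq.SampleQuant({}, clean_total=4, qc=sq.QCReport())
        m = sq.count_matrix({"s1": qa, "s2": qb}, mirna_ids=["m1", "m2"])
        frame = m.to_frame()
        assert frame.loc["m1", "s1"] == 5
        assert frame.loc["m2", "s1"] == 0 and frame.loc["m1", "s2"] == 0

    def test_duplicate_sample_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate sample"):
            MiRNACountMatrix(
                mirna_ids=["m1"], sample_ids=["s", "s"],
                counts=np.zeros((1, 2)), clean_totals={"s": 1},
            )

    def test_tsv_round_trip(self, tiny_matrix, tmp_path):
        tiny_matrix.write_tsv(tmp_path / "c.tsv", tmp_path / "t.tsv")
        back = MiRNACountMatrix.read_tsv(tmp_path / "c.tsv", tmp_path / "t.tsv")
        assert np.array_equal(back.counts, tiny_matrix.counts)
        assert back.clean_totals == tiny_matrix.clean_totals


class TestTPM:
    def test_formula_and_zero(self):
        m = MiRNACountMatrix(
            mirna_ids=["m1", "m2"], sample_ids=["s"],
            counts=np.array([[10], [0]]), clean_totals={"s": 1_000_000},
        )
        tpm = sq.tpm_normalize(m)
        assert tpm.loc["m1", "s"] == 10.0 and tpm.loc["m2", "s"] == 0.0

    def test_conservation_identity(self, tiny_matrix):
        tpm = sq.tpm_normalize(tiny_matrix)
        totals = np.array([tiny_matrix.clean_totals[s] for s in tiny_matrix.sample_ids])
        back = tpm.to_numpy() * totals / 1e6
        assert np.allclose(back, tiny_matrix.counts, atol=1e-9)
        # per-sample sum identity
        frac = tiny_matrix.counts.sum(axis=0) / totals
        assert np.allclose(tpm.sum(axis=0), 1e6 * frac)

    def test_zero_total_names_sample(self):
        m = MiRNACountMatrix(
            mirna_ids=["m1"], sample_ids=["s"], counts=np.array([[1]]),
            clean_totals={"s": 5},
        )
        m.clean_totals["s"] = 0
        with pytest.raises(ZeroDivisionError, match="s"):
            sq.tpm_normalize(m)


class TestGroupTPM:
    def _matrix(self, counts, totals):
        samples = [f"s{j}" for j in range(len(totals))]
        return (
            MiRNACountMatrix(
                mirna_ids=[f"m{i}" for i in range(counts.shape[0])],
                sample_ids=samples,
                counts=counts,
                clean_totals=dict(zip(samples, totals)),
            ),
            {s: ("A" if j < len(totals) // 2 else "B") for j, s in enumerate(samples)},
        )

    def test_zero_floor_applied_to_exact_zeros_only(self):
        m, design = self._matrix(
            np.array([[0, 0, 5, 5], [1, 0, 0, 0]]), [10**8] * 4
        )
        a = sq.group_tpm(m, design, "A")
        assert a["m0"] == 0.01                       # exact zero -> floor
        assert a["m1"] == pytest.approx(0.005, rel=1e-12)  # sub-floor kept

    def test_pooled_rates_symmetry(self):
        m, design = self._matrix(np.array([[4, 6, 2, 8]]), [1000, 1000, 500, 1500])
        a = sq.group_tpm(m, design, "A")
        b = sq.group_tpm(m, design, "B")
        assert a["m0"] == b["m0"] == pytest.approx(10 / 2000 * 1e6)

    def test_unknown_group_rejected(self, tiny_matrix):
        with pytest.raises(ValueError):
            sq.group_tpm(tiny_matrix, {s: "A" for s in tiny_matrix.sample_ids}, "Z")


class TestZscore:
    def test_constant_row_maps_to_zeros(self):
        tpm = pd.DataFrame([[5.0, 5.0, 5.0]], index=["m"], columns=list("abc"))
        assert (sq.zscore_matrix(tpm).to_numpy() == 0).all()

    def test_rows_standardised(self):
        rng = np.random.default_rng(1)
        tpm = pd.DataFrame(rng.uniform(0, 100, size=(10, 6)))
        z = sq.zscore_matrix(tpm)
        assert np.allclose(z.mean(axis=1), 0, atol=1e-9)
        assert np.allclose(z.to_numpy().std(axis=1), 1, atol=1e-9)  # population SD

    def test_two_sample_row_is_plus_minus_one(self):
        tpm = pd.DataFrame([[1.0, 9.0]], index=["m"], columns=["a", "b"])
        z = sq.zscore_matrix(tpm)
        assert np.allclose(sorted(z.loc["m"]), [-1.0, 1.0])


class TestRoundTrip:
    def test_zero_noise_reads_reproduce_counts(self, reference, two_group_design,
                                               tmp_path):
        truth = sd.SimulationTruth(
            spiked={}, library_sizes={s: 1500 for s in two_group_design}, seed=17
        )
        counts, _ = sd.simulate_counts(reference, two_group_design, truth,
                                       baseline_mean=40.0)
        paths = sd.simulate_reads(counts, reference, tmp_path, seed=18)
        per_sample = {
            s: sq.quantify_sample(sq.read_fastq(p), reference, ADAPTER)
            for s, p in paths.items()
        }
        quantified = sq.count_matrix(per_sample, mirna_ids=reference.mirna_ids)
        assert np.array_equal(quantified.counts, counts.counts)
        assert quantified.clean_totals == counts.clean_totals

    def test_all_junk_reads_are_filtered(self, reference, two_group_design,
                                         tmp_path):
        truth = sd.SimulationTruth(
            spiked={}, library_sizes={s: 300 for s in two_group_design}, seed=19
        )
        counts, _ = sd.simulate_counts(reference, two_group_design, truth,
                                       baseline_mean=10.0)
        paths = sd.simulate_reads(counts, reference, tmp_path, seed=20,
                                  frac_polyN=1.0, frac_lowqual=0.5)
        sample = counts.sample_ids[0]
        quant = sq.quantify_sample(
            sq.read_fastq(paths[sample]), reference, ADAPTER
        )
        assert quant.qc.n_polyN_removed == counts.clean_totals[sample]
        assert quant.qc.n_lowqual_removed == round(0.5 * counts.clean_totals[sample])
        assert quant.clean_total == counts.clean_totals[sample]
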