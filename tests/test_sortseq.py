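"""Barcode extraction, counting, enrichment and the regularized t-test."""

import gzip

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fretsort import sortseq
from fretsort.sortseq import U1_ADAPTER as U1
from fretsort.sortseq import U2_ADAPTER as U2
from fretsort.sortseq import reverse_complement as rc

BC_A = "ACGTACGTACGTACGTACGT"
BC_B = "TTGGCCAATTGGCCAATTGG"


def write_fastq(path, reads, quals=None):
    """reads: list of sequences; quals: matching list or uniform Q40."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for i, seq in enumerate(reads):
            q = quals[i] if quals else "I" * len(seq)
            fh.write(f"@r{i}\n{seq}\n+\n{q}\n")


def read_for(barcode, pad5="AACC", pad3="GGTTAA"):
    return pad5 + U1 + rc(barcode) + U2 + pad3


class TestExtractBarcodes:
    def test_error_free_reads_all_counted(self, tmp_path):
        construction = [BC_A] * 7 + [BC_B] * 3
        fq = tmp_path / "sample.fastq.gz"
        write_fastq(fq, [read_for(b) for b in construction])
        out = sortseq.extract_barcodes(fq)
        assert out.n_reads_total == 10
        assert out.counts == {BC_A: 7, BC_B: 3}
        assert out.n_discarded_no_adapter == 0
        assert out.n_discarded_short == 0
        assert out.n_discarded_quality == 0

    def test_discard_classes(self, tmp_path):
        reads = [
            read_for(BC_A),                          # counted
            "AACC" + U1 + rc(BC_A)[:19] + U2,        # 19 bp insert -> short
            "AACCGGTTAACCGGTT" + rc(BC_A) + U2,      # no U1 -> no_adapter
            "AACC" + U1 + rc(BC_A) + "GGTTAACCGGTTAACC",  # no U2 -> no_adapter
            "ACGT",                                  # adapter > read: no match
        ]
        fq = tmp_path / "mix.fastq"
        write_fastq(fq, reads)
        out = sortseq.extract_barcodes(fq)
        assert out.counts == {BC_A: 1}
        assert out.n_discarded_short == 1
        assert out.n_discarded_no_adapter == 3
        assert out.n_discarded_quality == 0
        out.check_accounting()

    def test_quality_trimming_drops_bad_tail_but_keeps_barcode(self, tmp_path):
        good = read_for(BC_A)
        seq = good + "ACGTACGT"
        quals = ["I" * len(good) + "#" * 8]  # Q2 tail is trimmed away
        fq = tmp_path / "trim.fastq"
        write_fastq(fq, [seq], quals)
        out = sortseq.extract_barcodes(fq)
        assert out.counts == {BC_A: 1}

    def test_low_quality_read_tallied_separately(self, tmp_path):
        seq = read_for(BC_A)
        quals = ["#" * len(seq)]  # whole read Q2 -> trimmed to nothing
        fq = tmp_path / "bad.fastq"
        write_fastq(fq, [seq], quals)
        out = sortseq.extract_barcodes(fq)
        assert out.n_discarded_quality == 1
        assert out.counts == {}

    def test_adapter_mismatch_tolerance(self, tmp_path):
        # mutate internal positions so shifted alignments cannot rescue them
        u1_one_mm = U1[:5] + "A" + U1[6:]  # 1 mismatch: floor(0.1*18) = 1 allowed
        u1_two_mm = U1[:5] + "A" + U1[6:10] + "C" + U1[11:]
        fq = tmp_path / "mm.fastq"
        write_fastq(
            fq,
            [
                "AACC" + u1_one_mm + rc(BC_A) + U2 + "GG",
                "AACC" + u1_two_mm + rc(BC_A) + U2 + "GG",
            ],
        )
        out = sortseq.extract_barcodes(fq)
        assert out.counts == {BC_A: 1}
        assert out.n_discarded_no_adapter == 1

    def test_invalid_adapter_rejected(self, tmp_path):
        fq = tmp_path / "x.fastq"
        write_fastq(fq, [read_for(BC_A)])
        with pytest.raises(ValueError):
            sortseq.extract_barcodes(fq, u1="ACGTN")


class TestMapToGenes:
    LIB = sortseq.LibraryMap(
        records=pd.DataFrame(
            {
                "barcode": [BC_A, BC_B, "G" * 20],
                "gene": ["geneX", "geneX", "geneY"],
                "insertion_location": ["a", "b", "c"],
                "intergenic": [0, 0, 0],
            }
        )
    )

    def test_per_gene_sum(self):
        counts = sortseq.BarcodeCounts(
            sample_id="s", counts={BC_A: 5, BC_B: 7, "G" * 20: 1}, n_reads_total=13
        )
        col = sortseq.map_to_genes(counts, self.LIB)
        assert col["geneX"] == 12
        assert col["geneY"] == 1

    def test_unmatched_barcode_tallied_not_assigned(self):
        counts = sortseq.BarcodeCounts(
            sample_id="s", counts={"C" * 20: 4, BC_A: 1}, n_reads_total=5
        )
        col = sortseq.map_to_genes(counts, self.LIB)
        assert counts.n_unmatched == 4
        assert col.sum() == 1

    def test_empty_counts_give_zero_column(self):
        col = sortseq.map_to_genes(
            sortseq.BarcodeCounts(sample_id="s"), self.LIB
        )
        assert (col == 0).all()

    def test_duplicate_barcodes_rejected(self):
        with pytest.raises(ValueError):
            sortseq.LibraryMap(
                records=pd.DataFrame(
                    {"barcode": [BC_A, BC_A], "gene": ["x", "y"]}
                )
            )


def make_table(counts: dict, roles: dict) -> sortseq.CountTable:
    samples = pd.DataFrame(
        {
            "role": {s: r[0] for s, r in roles.items()},
            "cycle": {s: r[1] for s, r in roles.items()},
            "replicate": {s: r[2] for s, r in roles.items()},
            "biosensor": "C3",
        }
    )
    return sortseq.CountTable(counts=pd.DataFrame(counts), samples=samples)


class TestEnrichment:
    def test_hand_arithmetic(self):
        table = make_table(
            {"u": [100, 300, 600], "hi": [400, 100, 500]},
            {"u": ("unsorted", 0, 1), "hi": ("high_sorted", 1, 1)},
        )
        et = sortseq.normalize_enrichment(table)
        np.testing.assert_allclose(
            et.enrichment["hi"].values, [4.0, 1 / 3, 5 / 6], rtol=1e-12
        )

    def test_identical_columns_give_unit_enrichment(self):
        table = make_table(
            {"u": [10, 20, 30], "hi": [10, 20, 30]},
            {"u": ("unsorted", 0, 1), "hi": ("high_sorted", 1, 1)},
        )
        et = sortseq.normalize_enrichment(table)
        np.testing.assert_allclose(et.enrichment["hi"].values, 1.0)

    def test_zero_unsorted_reads_undefined(self):
        table = make_table(
            {"u": [0, 100], "hi": [5, 95]},
            {"u": ("unsorted", 0, 1), "hi": ("high_sorted", 1, 1)},
        )
        et = sortseq.normalize_enrichment(table)
        assert np.isnan(et.enrichment["hi"].iloc[0])

    def test_depth_invariance(self):
        table = make_table(
            {"u": [100, 300, 600], "hi": [400, 100, 500]},
            {"u": ("unsorted", 0, 1), "hi": ("high_sorted", 1, 1)},
        )
        scaled = make_table(
            {"u": [100, 300, 600], "hi": [4000, 1000, 5000]},
            {"u": ("unsorted", 0, 1), "hi": ("high_sorted", 1, 1)},
        )
        e1 = sortseq.normalize_enrichment(table).enrichment["hi"]
        e2 = sortseq.normalize_enrichment(scaled).enrichment["hi"]
        np.testing.assert_allclose(e1.values, e2.values, rtol=1e-12)


class TestReadFilter:
    def test_excluded_only_when_below_in_every_sample(self):
        table = make_table(
            {"a": [150, 150], "b": [180, 250], "c": [90, 90]},
            {
                "a": ("unsorted", 0, 1),
                "b": ("high_sorted", 1, 1),
                "c": ("low_sorted", 1, 1),
            },
        )
        keep = sortseq.filter_low_reads(table, threshold=200)
        assert not keep.iloc[0]  # (150, 180, 90): all below
        assert keep.iloc[1]  # (150, 250, 90): one sample above
        assert sortseq.filter_low_reads(table, threshold=0).all()

    def test_any_mode_is_stricter(self):
        table = make_table(
            {"a": [250, 250], "b": [180, 250]},
            {"a": ("unsorted", 0, 1), "b": ("high_sorted", 1, 1)},
        )
        assert sortseq.filter_low_reads(table, 200, mode="any").tolist() == [
            False,
            True,
        ]


class TestLog2FoldChange:
    def test_values_and_antisymmetry(self):
        assert sortseq.log2_fold_change(1.0, 1.0) == 0.0
        assert sortseq.log2_fold_change(4.0, 0.25) == pytest.approx(4.0)
        assert sortseq.log2_fold_change(0.25, 4.0) == pytest.approx(-4.0)
        a = sortseq.log2_fold_change(3.7, 0.9)
        b = sortseq.log2_fold_change(0.9, 3.7)
        assert a == pytest.approx(-b)

    def test_nan_propagates(self):
        assert np.isnan(sortseq.log2_fold_change(np.nan, 2.0))


class TestCyberT:
    def test_identical_groups_give_p_one(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=(300, 2))
        p = sortseq.cybert_test(v, v.copy())
        assert (p == 1.0).all()

    def test_strong_outlier_has_minimal_p(self):
        rng = np.random.default_rng(1)
        vh = rng.normal(size=(500, 2))
        vl = rng.normal(size=(500, 2))
        vh[123] += 10.0
        p = sortseq.cybert_test(vh, vl)
        assert p.idxmin() == 123

    def test_reduces_to_classical_t_as_prior_vanishes(self):
        # at prior 0 the regularized variance keeps a (n-1)/(n-2) factor from
        # the posterior; the difference from Student's t vanishes with n
        rng = np.random.default_rng(2)
        gaps = []
        for n in (6, 12, 30):
            vh = rng.normal(size=(400, n))
            vl = rng.normal(size=(400, n))
            p = sortseq.cybert_test(
                vh, vl, sortseq.CyberTConfig(prior=0.0, window=101)
            )
            t_cls, p_cls = stats.ttest_ind(vh, vl, axis=1)
            gaps.append(np.max(np.abs(p.values - p_cls)))
        assert gaps[2] < gaps[0]
        assert gaps[2] < 0.02

    def test_window_larger_than_gene_count_shrinks_with_warning(self):
        rng = np.random.default_rng(3)
        with pytest.warns(UserWarning, match="shrunk"):
            sortseq.cybert_test(
                rng.normal(size=(51, 2)),
                rng.normal(size=(51, 2)),
                sortseq.CyberTConfig(prior=6.0, window=101),
            )

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            sortseq.cybert_test(np.zeros((10, 1)), np.zeros((10, 2)))


class TestReport:
    def make_enrichment_table(self):
        genes = ["gA", "gB", "gC", "gD"]
        et = sortseq.EnrichmentTable(
            enrichment=pd.DataFrame(index=genes),
            passed_filter=pd.Series([True, True, True, False], index=genes),
            log2fc=pd.DataFrame(
                {
                    "log2FC_x2": [9.2, 1.0, -5.0, 12.0],
                    "log2FC_x3": [8.0, 0.5, -6.0, 11.0],
                },
                index=genes,
            ),
            p_value=pd.DataFrame(
                {"p_x2": [0.01, 0.2, 0.02, 0.001], "p_x3": [0.02, 0.5, 0.01, 0.001]},
                index=genes,
            ),
        )
        return et

    def test_threshold_and_ranking(self):
        rep = sortseq.enrichment_report(
            self.make_enrichment_table(), fc_threshold=3.5, p_threshold=0.05, cycle=2
        )
        assert rep["gene"].tolist() == ["gA", "gC"]  # sorted by log2FC desc
        assert "log2FC_x3" in rep.columns

    def test_infinite_threshold_empty(self):
        rep = sortseq.enrichment_report(
            self.make_enrichment_table(), fc_threshold=np.inf, p_threshold=0.0
        )
        assert rep.empty

    def test_filtered_gene_never_reported(self):
        # gD has the largest fold change but failed the read filter
        rep = sortseq.enrichment_report(
            self.make_enrichment_table(), fc_threshold=3.5, cycle=2
        )
        assert "gD" not in rep["gene"].tolist()
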