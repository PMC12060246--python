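"""Variant normalization, quality-dip thresholding, call-set intersection,
genic partitioning, indel frame analysis and per-class densities."""

import math

import numpy as np
import pandas as pd
import pytest

from asmqc import contig_stats as cs
from asmqc import variant_landscape as vl
from asmqc.annotation import AnnotationIndex, GeneModel
from asmqc.contig_classify import labels_to_frame


def V(contig, pos, ref, alt, qual=30.0, gt="0/1", ps=None):
    return vl.VariantRecord(contig, pos, ref, alt, qual, gt, ps)


def apply_variant(seq: str, pos: int, ref: str, alt: str) -> str:
    assert seq[pos - 1: pos - 1 + len(ref)] == ref
    return seq[: pos - 1] + alt + seq[pos - 1 + len(ref):]


class TestNormalize:
    def test_left_aligns_to_first_repeat_copy(self):
        # deletion of one CT in a CTCTCT run
        seq = "GGGGA" + "CTCTCT" + "AGGGG"
        pos = seq.index("CT") + 3  # a right-side copy, 1-based
        rec = V("c1", pos, "CTC", "C")
        hap = apply_variant(seq, pos, "CTC", "C")
        (out,) = vl.normalize_variants([rec], {"c1": seq})
        assert apply_variant(seq, out.pos, out.ref, out.alt) == hap
        # brute-force shift oracle: no equivalent representation further left
        for p in range(1, out.pos):
            for w in range(1, 4):
                ref = seq[p - 1: p - 1 + w + 1]
                alt = ref[0]
                if len(ref) == w + 1 and apply_variant(seq, p, ref, alt) == hap:
                    pytest.fail(f"representation at {p} is further left than {out.pos}")

    def test_minimal_snv_unchanged_and_idempotent(self):
        seq = "ACGTACGTACGT"
        rec = V("c1", 5, "A", "G")
        once = vl.normalize_variants([rec], {"c1": seq})
        twice = vl.normalize_variants(once, {"c1": seq})
        assert once == twice == [rec]

    def test_idempotence_on_indels(self):
        seq = "GGAAAAATTTTCCGG"
        recs = [V("c1", 3, "AA", "A"), V("c1", 8, "T", "TTT"), V("c1", 13, "C", "G")]
        once = vl.normalize_variants(recs, {"c1": seq})
        assert vl.normalize_variants(once, {"c1": seq}) == once

    def test_shared_prefix_suffix_trimmed(self):
        seq = "TTGCATGCAT"
        rec = V("c1", 3, "GCA", "GTA")  # only middle base differs
        (out,) = vl.normalize_variants([rec], {"c1": seq})
        assert (out.pos, out.ref, out.alt) == (4, "C", "T")

    def test_ref_mismatch_rejected(self):
        with pytest.raises(ValueError, match="REF mismatch"):
            vl.normalize_variants([V("c1", 1, "T", "G")], {"c1": "AAAA"})

    def test_output_sorted(self):
        seq = "ACGTACGTAC"
        recs = [V("c1", 7, "G", "A"), V("c1", 2, "C", "T")]
        out = vl.normalize_variants(recs, {"c1": seq})
        assert [r.pos for r in out] == [2, 7]


class TestQualityDip:
    def test_planted_valley_recovered(self):
        rng = np.random.default_rng(0)
        quals = np.concatenate([
            np.clip(np.round(rng.normal(8, 2, 3_000)), 1, 60),
            np.clip(np.round(rng.normal(30, 6, 9_000)), 1, 60),
        ])
        # brute-force valley of the smoothed histogram between the modes
        hist = np.bincount(quals.astype(int))
        sm = np.convolve(hist, np.ones(3) / 3, mode="same")
        oracle = 8 + int(np.argmin(sm[8:31]))
        assert vl.detect_quality_dip(quals) == oracle

    def test_unimodal_returns_fallback(self):
        rng = np.random.default_rng(1)
        quals = np.clip(np.round(rng.normal(30, 4, 5_000)), 1, 60)
        assert vl.detect_quality_dip(quals, fallback=14) == 14

    def test_flat_valley_takes_leftmost_minimum(self):
        # equal-height peaks at 10 and 22 with an empty stretch in between:
        # the smoothed histogram is 0 on bins 12-13 and 19-20, so the
        # leftmost minimal bin, 12, is the threshold
        quals = [10] * 50 + [15] * 3 + [16] * 3 + [17] * 3 + [22] * 50
        assert vl.detect_quality_dip(quals) == 12

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            vl.detect_quality_dip([])


class TestFilterAndIntersect:
    def test_strictly_above_threshold(self):
        recs = [V("c", 1, "A", "G", q) for q in (14, 14.5, 20)]
        assert len(vl.filter_by_quality(recs, 14)) == 2

    def test_threshold_zero_keeps_all_positive(self):
        recs = [V("c", i + 1, "A", "G", 5) for i in range(4)]
        assert vl.filter_by_quality(recs, 0) == recs

    def test_identical_sets_fully_shared(self):
        recs = sorted([V("c", i + 1, "A", "G") for i in range(5)], key=vl.VariantRecord.key)
        shared, a_only, b_only, counts = vl.intersect_callsets(recs, list(recs))
        assert len(shared) == 5 and not a_only and not b_only
        assert counts.loc["snv", "shared"] == 5

    def test_disjoint_sets_share_nothing(self):
        a = [V("c", 1, "A", "G")]
        b = [V("c", 2, "A", "G")]
        shared, a_only, b_only, _ = vl.intersect_callsets(a, b)
        assert not shared and len(a_only) == 1 and len(b_only) == 1

    def test_commutative_in_counts(self):
        rng = np.random.default_rng(2)
        a = sorted((V("c", int(p), "A", "G") for p in rng.choice(1000, 50, replace=False)),
                   key=vl.VariantRecord.key)
        b = sorted((V("c", int(p), "A", "G") for p in rng.choice(1000, 50, replace=False)),
                   key=vl.VariantRecord.key)
        s1, _, _, _ = vl.intersect_callsets(a, b)
        s2, _, _, _ = vl.intersect_callsets(b, a)
        assert len(s1) == len(s2)

    def test_unsorted_input_rejected(self):
        a = [V("c", 5, "A", "G"), V("c", 1, "A", "G")]
        with pytest.raises(ValueError, match="not sorted"):
            vl.intersect_callsets(a, a)

    def test_shared_set_equals_truth_on_synthetic_callsets(self, default_run):
        truth = default_run["truth"]
        seqs = default_run["sequences"]
        a = vl.normalize_variants(default_run["set_a"], seqs)
        b = vl.normalize_variants(default_run["set_b"], seqs)
        shared, _, _, _ = vl.intersect_callsets(a, b)
        both = truth.variants[truth.variants["membership"] == "both"]
        truth_keys = {
            (r.contig, int(r.pos), r.ref, r.alt) for r in both.itertuples()
        }
        # truth records are already minimal; normalization may shift them
        norm_truth = vl.normalize_variants(
            [V(r.contig, int(r.pos), r.ref, r.alt) for r in both.itertuples()], seqs
        )
        assert {r.key() for r in shared} == {r.key() for r in norm_truth}
        assert len(shared) == len(truth_keys)


@pytest.fixture
def half_exonic_index():
    # one gene covering the left half of a 10 kbp contig, fully exonic
    genes = [GeneModel("g1", "c1", 1, 5_000, [(1, 5_000)])]
    return AnnotationIndex(genes, {"c1": 10_000})


class TestPartition:
    def test_printed_fraction_worked_example(self):
        # genome 0.853% exonic vs 0.245% of indels exonic -> 3.5-fold depletion
        assert round(vl.depletion_fold(0.853, 0.245), 1) == 3.5

    def test_boundary_snv_is_exonic(self, half_exonic_index):
        summary = cs.annotation_summary(half_exonic_index)
        part = vl.partition_by_annotation(
            [V("c1", 5_000, "A", "G")], half_exonic_index, summary
        )
        assert part.counts.loc["snv", "exon"] == 1

    def test_uniform_positions_match_exonic_fraction(self, half_exonic_index):
        rng = np.random.default_rng(3)
        recs = sorted(
            (V("c1", int(p) + 1, "A", "G") for p in rng.choice(10_000, 1_000, replace=False)),
            key=vl.VariantRecord.key,
        )
        summary = cs.annotation_summary(half_exonic_index)
        part = vl.partition_by_annotation(recs, half_exonic_index, summary)
        frac = part.fractions.loc["snv", "exon"]
        se = math.sqrt(0.5 * 0.5 / 1_000)
        assert abs(frac - 0.5) <= 3 * se
        # annotation-blind uniform variants -> depletion fold near 1
        assert abs(part.depletion_fold["snv"] - 1.0) <= 6 * se

    def test_partition_counts_conserved(self, half_exonic_index):
        recs = [V("c1", p, "A", "G") for p in (10, 5_000, 7_000)]
        summary = cs.annotation_summary(half_exonic_index)
        part = vl.partition_by_annotation(recs, half_exonic_index, summary)
        assert int(part.counts.to_numpy().sum()) == 3


class TestFrameSpectrum:
    def test_frame_preserving_counts(self, half_exonic_index):
        recs = [
            V("c1", 10, "AAAA", "A"),      # -3 exonic
            V("c1", 100, "A", "AAAAAAA"),  # +6 exonic
            V("c1", 200, "AAAA", "A"),     # -3 exonic
        ]
        df = vl.indel_frame_spectrum(recs, half_exonic_index)
        assert df.loc["exon", "frame_preserving"] == 3
        assert df.loc["exon", "frame_disrupting"] == 0

    def test_mixed_lengths(self, half_exonic_index):
        recs = [
            V("c1", 6_000, "AA", "A"),    # -1 intergenic
            V("c1", 6_100, "AAA", "A"),   # -2 intergenic
            V("c1", 6_200, "A", "AAAA"),  # +3 intergenic
        ]
        df = vl.indel_frame_spectrum(recs, half_exonic_index)
        assert df.loc["intergenic", "frame_preserving"] == 1
        assert df.loc["intergenic", "frame_disrupting"] == 2


class TestPerGeneIndels:
    def test_rate_arithmetic(self):
        genes = [GeneModel("g1", "c1", 1, 2_000, [(1, 1_000)])]
        index = AnnotationIndex(genes, {"c1": 10_000})
        recs = [V("c1", 10, "AA", "A"), V("c1", 500, "A", "AT")]
        per_gene, _ = vl.per_gene_indel_stats(recs, index)
        row = per_gene.iloc[0]
        assert row["n_indels"] == 2
        assert row["rate_per_kbp"] == pytest.approx(2.0)

    def test_no_indels_zero_rates(self):
        genes = [GeneModel("g1", "c1", 1, 2_000, [(1, 1_000)])]
        index = AnnotationIndex(genes, {"c1": 10_000})
        per_gene, _ = vl.per_gene_indel_stats([], index)
        assert (per_gene["rate_per_kbp"] == 0).all()

    def test_uniform_rate_has_no_length_trend(self):
        rng = np.random.default_rng(11)
        genes, recs = [], []
        cursor = 1
        for i in range(120):
            glen = int(rng.integers(500, 8_000))
            genes.append(GeneModel(f"g{i}", "c1", cursor, cursor + glen - 1,
                                   [(cursor, cursor + glen - 1)]))
            n = rng.poisson(glen * 2e-3)  # uniform per-bp indel rate
            for p in rng.choice(glen - 1, size=min(n, glen - 1), replace=False):
                recs.append(V("c1", cursor + int(p), "AA", "A"))
            cursor += glen + 10
        index = AnnotationIndex(genes, {"c1": cursor + 10})
        per_gene, _ = vl.per_gene_indel_stats(recs, index)
        slope, lo, hi = vl.rate_length_trend(per_gene)
        assert lo <= 0 <= hi


class TestDensityByClass:
    def test_constructed_density(self):
        labels = pd.DataFrame({"contig_id": ["c1"], "label": ["autosomal"]})
        recs = [V("c1", i * 10 + 1, "A", "G") for i in range(24)]
        by_class, per_contig = vl.density_by_contig_class(recs, labels, {"c1": 10_000})
        assert by_class.set_index("label").loc["autosomal", "snv_per_kbp"] == pytest.approx(2.4)

    def test_zero_variants(self):
        labels = pd.DataFrame({"contig_id": ["c1"], "label": ["autosomal"]})
        by_class, _ = vl.density_by_contig_class([], labels, {"c1": 1_000})
        assert (by_class["snv_per_kbp"] == 0).all()

    def test_hom_calls_excluded_when_het_only(self):
        labels = pd.DataFrame({"contig_id": ["c1"], "label": ["autosomal"]})
        recs = [V("c1", 1, "A", "G", gt="1/1"), V("c1", 5, "A", "G", gt="0/1")]
        by_class, _ = vl.density_by_contig_class(recs, labels, {"c1": 1_000})
        assert by_class["total_snvs"].sum() == 1


class TestVcfRoundTrip:
    def test_records_survive_write_and_read(self, tmp_path):
        recs = [
            V("c1", 3, "A", "G", 31, "0|1", 3),
            V("c1", 9, "AT", "A", 22, "0/1", None),
        ]
        path = tmp_path / "out.vcf"
        vl.write_vcf(recs, {"c1": 50}, path)
        back = vl.read_vcf(str(path))
        assert [(r.contig, r.pos, r.ref, r.alt, r.genotype, r.phase_set) for r in back] == [
            ("c1", 3, "A", "G", "0|1", 3),
            ("c1", 9, "AT", "A", "0/1", None),
        ]
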