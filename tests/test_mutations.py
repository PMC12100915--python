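"""Tests of mutation-overlap classification and SBS profiles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cffrag import fragio
from cffrag.mutations import (
    OverlapAnnotation,
    OverlapCategory,
    SBS96_CONTEXTS,
    VariantLocus,
    aggregate_support,
    annotate_pairs,
    call_trinucleotide,
    classify_overlap,
    cosine_similarity,
    do_removed_profile,
    locus_base_support,
    pileup_mismatches,
    read_variant_loci,
    sbs_context,
)

from conftest import make_pair

LOCUS = VariantLocus("chr1", 1100, "C", "T")


class TestClassifyOverlap:
    @pytest.mark.parametrize(
        "support,expected",
        [
            (("T", "T"), OverlapCategory.CO),      # both reads support the variant
            (("T", None), OverlapCategory.SO),     # only one read covers, supports it
            ((None, "T"), OverlapCategory.SO),
            (("T", "C"), OverlapCategory.DO),      # covering reads disagree on the variant
            (("C", "T"), OverlapCategory.DO),
            (("C", "C"), OverlapCategory.REF_ONLY),
            (("C", None), OverlapCategory.REF_ONLY),
            (("C", "G"), OverlapCategory.REF_ONLY),  # disagreement without the alt base
            ((None, None), OverlapCategory.NO_COVER),
        ],
    )
    def test_categories(self, support, expected):
        assert classify_overlap(support, LOCUS) is expected

    @given(
        b1=st.sampled_from(["A", "C", "G", "T", None]),
        b2=st.sampled_from(["A", "C", "G", "T", None]),
    )
    @settings(derandomize=True, max_examples=50)
    def test_totality(self, b1, b2):
        """Every observation maps to exactly one category."""
        assert classify_overlap((b1, b2), LOCUS) in OverlapCategory


class TestLocusBaseSupport:
    def test_both_reads_span(self):
        pair = make_pair(1001, 1150, "+", 1001, 1140, "-")
        pair.r1.bases = "A" * 99 + "T" + "A" * 50
        pair.r2.bases = "A" * 99 + "T" + "A" * 40
        assert locus_base_support(pair, LOCUS, min_base_quality=0) == ("T", "T")

    def test_only_forward_spans(self):
        # 300 bp fragment, 150 bp reads, locus at offset 99 from the start
        pair = make_pair(1001, 1150, "+", 1151, 1300, "-")
        pair.r1.bases = "A" * 99 + "T" + "A" * 50
        assert locus_base_support(pair, LOCUS, min_base_quality=0) == ("T", None)

    def test_deletion_over_locus(self):
        pair = make_pair(1001, 1150, "+", 1001, 1140, "-")
        # r1: 50M then 10D over 1051-1060... place deletion over pos 1100
        pair.r1.cigartuples = [(0, 90), (2, 20), (0, 40)]  # 1001-1090 M, 1091-1110 D
        pair.r1.bases = "A" * 130
        pair.r2.bases = "A" * 99 + "G" + "A" * 40
        assert locus_base_support(pair, LOCUS, min_base_quality=0) == (None, "G")

    def test_low_base_quality_masked(self):
        pair = make_pair(1001, 1150, "+", 1001, 1140, "-")
        pair.r1.bases = "A" * 99 + "T" + "A" * 50
        pair.r1.qualities = [30] * 99 + [5] + [30] * 50
        b1, _ = locus_base_support(pair, LOCUS, min_base_quality=20)
        assert b1 is None


class TestAggregateSupport:
    def _ann(self, cat, i):
        return OverlapAnnotation(f"f{i}", LOCUS, cat)

    def test_do_excluded_from_alt_by_default(self):
        anns = (
            [self._ann(OverlapCategory.CO, i) for i in range(3)]
            + [self._ann(OverlapCategory.SO, i + 3) for i in range(2)]
            + [self._ann(OverlapCategory.DO, 6)]
            + [self._ann(OverlapCategory.REF_ONLY, i + 7) for i in range(4)]
        )
        sup = aggregate_support(anns)[LOCUS.id]
        assert (sup.alt_count, sup.ref_count) == (5, 4)
        assert sup.category_counts["DO"] == 1
        assert sup.total_overlapping == 10

    def test_do_included_with_flag(self):
        anns = [self._ann(OverlapCategory.DO, 0), self._ann(OverlapCategory.CO, 1)]
        sup = aggregate_support(anns, include_discordant_in_alt=True)[LOCUS.id]
        assert sup.alt_count == 2

    def test_empty(self):
        assert aggregate_support([]) == {}


class TestSbsContext:
    def test_pyrimidine_reference(self):
        ref = {"chr1": "TACGT"}
        assert sbs_context(VariantLocus("chr1", 3, "C", "T"), ref) == "A[C>T]G"

    def test_purine_reference_reverse_complemented(self):
        # reference ...TGC..., G>A at the middle: revcomp(TGC)=GCA, G>A == C>T
        ref = {"chr1": "ATGCA"}
        assert sbs_context(VariantLocus("chr1", 3, "G", "A"), ref) == "G[C>T]A"

    def test_ref_mismatch_raises(self):
        ref = {"chr1": "TACGT"}
        with pytest.raises(ValueError, match="chr1:3"):
            sbs_context(VariantLocus("chr1", 3, "G", "A"), ref)

    @given(st.data())
    @settings(derandomize=True, max_examples=100)
    def test_totality(self, data):
        """Any locus with valid flanks maps to one of the 96 contexts."""
        seq = data.draw(st.text(alphabet="ACGT", min_size=3, max_size=3))
        ref_base = seq[1]
        alt = data.draw(st.sampled_from([b for b in "ACGT" if b != ref_base]))
        ctx = sbs_context(VariantLocus("c", 2, ref_base, alt), {"c": seq})
        assert ctx in SBS96_CONTEXTS


class TestCallTrinucleotide:
    REF = {"chr1": "TACGT" + "AATCGG"}  # pos 3: ACG with C; pos 8: TCG... pos 8 is "T"? indexing below

    def _anns(self, cats):
        locus = VariantLocus("chr1", 3, "C", "T")  # A[C>T]G
        return [OverlapAnnotation(f"f{i}", locus, c) for i, c in enumerate(cats)]

    def test_co_stratum_counts_fragments(self):
        profiles = call_trinucleotide(self._anns([OverlapCategory.CO] * 3), self.REF)
        idx = SBS96_CONTEXTS.index("A[C>T]G")
        assert profiles["CO"].counts[idx] == 3
        assert profiles["CO"].counts.sum() == 3

    def test_do_removed_subtraction(self):
        cats = [OverlapCategory.CO] * 3 + [OverlapCategory.DO] * 2
        profiles = call_trinucleotide(self._anns(cats), self.REF)
        removed = do_removed_profile(profiles)
        idx = SBS96_CONTEXTS.index("A[C>T]G")
        assert profiles["ALL"].counts[idx] == 5
        assert removed.counts[idx] == 3

    def test_ref_only_does_not_contribute(self):
        profiles = call_trinucleotide(self._anns([OverlapCategory.REF_ONLY] * 4), self.REF)
        assert profiles["ALL"].empty

    def test_co_plus_so_stratum(self):
        cats = [OverlapCategory.CO, OverlapCategory.SO, OverlapCategory.DO]
        profiles = call_trinucleotide(self._anns(cats), self.REF)
        assert profiles["CO+SO"].counts.sum() == 2


class TestCosineSimilarity:
    def test_identical(self):
        v = np.array([1.0, 2.0, 3.0])
        assert cosine_similarity(v, v) == pytest.approx(1.0)

    def test_disjoint(self):
        assert cosine_similarity(np.array([1, 0, 0]), np.array([0, 1, 1])) == 0.0

    def test_closed_form(self):
        p = np.zeros(96); p[0] = p[1] = 1.0
        q = np.zeros(96); q[0] = 1.0
        assert cosine_similarity(p, q) == pytest.approx(1 / np.sqrt(2))

    def test_zero_vector_nan(self):
        assert np.isnan(cosine_similarity(np.zeros(3), np.ones(3)))


class TestVariantIO:
    def test_tsv_with_header(self, tmp_path):
        p = tmp_path / "muts.tsv"
        p.write_text("chrom\tpos\tref\talt\nchr1\t1100\tC\tT\nchr2\t500\tG\tA\n")
        loci = read_variant_loci(p)
        assert loci == [VariantLocus("chr1", 1100, "C", "T"), VariantLocus("chr2", 500, "G", "A")]

    def test_vcf_convenience(self, tmp_path):
        p = tmp_path / "muts.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t1100\t.\tC\tT\t.\tPASS\t.\n"
            "chr1\t1200\t.\tCA\tC\t.\tPASS\t.\n"  # indel skipped
        )
        assert read_variant_loci(p) == [VariantLocus("chr1", 1100, "C", "T")]

    def test_invalid_locus(self):
        with pytest.raises(ValueError):
            VariantLocus("chr1", 10, "C", "C")


@pytest.fixture(scope="module")
def spiked(tmp_path_factory):
    from cffrag import synthetic as syn

    tmp = tmp_path_factory.mktemp("spiked")
    chroms = [("chr1", 20_000, 0.5)]
    cfg0 = syn.SimulationConfig(seed=21, chromosomes=chroms)
    ref = syn.make_reference(cfg0, tmp / "ref.fa")
    rb = str(ref["chr1"][9_999]).upper()
    alt = "T" if rb != "T" else "A"
    cfg = syn.SimulationConfig(
        seed=21, n_fragments=12_000, chromosomes=chroms,
        variant_spikes=[syn.VariantSpike("chr1", 10_000, alt, 0.5, 0.0)],
    )
    truth = syn.simulate_fragments(cfg, ref)
    bam = syn.emit_alignments(truth, cfg, ref, tmp / "a.bam")
    return cfg, ref, truth, bam, VariantLocus("chr1", 10_000, rb, alt)


class TestPileupAndAnnotation:
    def test_spiked_locus_found_and_unique(self, spiked):
        cfg, ref, _, bam, locus = spiked
        cands = pileup_mismatches(bam, "chr1:9900-10100", ref, min_alt_fragments=5)
        assert [c[0] for c in cands] == [locus]

    def test_no_spike_no_errors_empty(self, clean_sim):
        cfg, ref, _, bam = clean_sim
        assert pileup_mismatches(bam, "chr1:5000-6000", ref, min_alt_fragments=1) == []

    def test_annotation_matches_truth_categories(self, spiked):
        cfg, ref, truth, bam, locus = spiked
        anns = annotate_pairs(fragio.read_pairs(bam), [locus], cfg.contig_lengths)
        called = {}
        for a in anns:
            called[a.fragment_id] = a.category.value
        mapping = {"CO": "CO", "SO": "SO", "DO": "DO", "REF": "REF_ONLY", "UNCOVERED": "NO_COVER"}
        tr = truth.support.set_index("fragment_id")["category"]
        assert len(called) == len(tr)
        for fid, cat in called.items():
            assert mapping[tr[fid]] == cat

    def test_region_outside_reference(self, clean_sim):
        cfg, ref, _, bam = clean_sim
        with pytest.raises(ValueError):
            pileup_mismatches(bam, "chr1:999999999-1000000000", ref)
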