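"""Unit and property tests for QC, curation and fragment I/O."""

from __future__ import annotations

import pysam
import pytest

from cffrag import fragio
from cffrag.fragio import (
    CurationReason,
    QCPolicy,
    QCReason,
    apply_qc,
    curate,
    curated_fragments,
    downsample,
    problematic_length,
    read_frag_tsv,
    read_pairs,
)

from conftest import make_pair, make_record

CONTIGS = {"chr1": 1_000_000, "chr2": 800_000, "chrM": 16_000}


class TestApplyQC:
    def test_clean_pair_passes(self):
        pair = make_pair(1001, 1150, "+", 1001, 1140, "-")
        assert apply_qc(pair) == (True, None)

    def test_low_mapq_on_one_mate_fails(self):
        # mapping quality below 30 on either mate rejects the pair
        pair = make_pair(1001, 1150, "+", 1001, 1140, "-")
        pair.r2.mapq = 29
        assert apply_qc(pair) == (False, QCReason.MAPQ)
        pair.r2.mapq = 30
        assert apply_qc(pair)[0]

    def test_non_proper_pair_passes_by_default(self):
        # proper-pair filtering is off by default: cfDNA lengths are multimodal
        pair = make_pair(1001, 1150, "+", 1001, 1140, "-", is_proper_pair=False)
        assert apply_qc(pair) == (True, None)
        assert apply_qc(pair, QCPolicy(require_proper_pair=True)) == (
            False,
            QCReason.PROPER_PAIR,
        )

    @pytest.mark.parametrize(
        "flags,expected",
        [
            ({"is_duplicate": True}, QCReason.DUPLICATE),
            ({"is_secondary": True}, QCReason.SECONDARY),
            ({"is_supplementary": True}, QCReason.SUPPLEMENTARY),
        ],
    )
    def test_flag_rejections(self, flags, expected):
        pair = make_pair(1001, 1150, "+", 1001, 1140, "-", **flags)
        assert apply_qc(pair) == (False, expected)

    def test_reason_precedence_unmapped_before_mapq(self):
        pair = make_pair(1001, 1150, "+", 1001, 1140, "-", mapq=5)
        pair.r2.is_unmapped = True
        assert apply_qc(pair) == (False, QCReason.UNMAPPED)


class TestCurate:
    def test_sequence_through_with_overhang(self):
        # forward read runs 10 bp past the fragment end (untrimmed adapter);
        # the curated fragment is forward start .. reverse end
        pair = make_pair(1001, 1150, "+", 1001, 1140, "-")
        out = curate(pair, CONTIGS)
        assert out.ok
        assert (out.fragment.start, out.fragment.end, out.fragment.length) == (1001, 1140, 140)

    def test_seqname_discordant(self):
        pair = make_pair(1001, 1150, "+", 1001, 1150, "-", chrom2="chr2")
        assert curate(pair, CONTIGS).reason is CurationReason.SEQNAME_DISCORDANT

    def test_same_strand_rejected(self):
        pair = make_pair(1001, 1150, "+", 1201, 1350, "+")
        assert curate(pair, CONTIGS).reason is CurationReason.NO_STRAND

    def test_outward_pair_rejected(self):
        # plus-strand read entirely right of the minus-strand read
        pair = make_pair(2001, 2150, "+", 1001, 1150, "-")
        assert curate(pair, CONTIGS).reason is CurationReason.NOT_INWARD

    def test_out_of_bound(self):
        pair = make_pair(999_990, 1_000_100, "+", 999_990, 1_000_100, "-")
        assert curate(pair, CONTIGS).reason is CurationReason.OUT_OF_BOUND

    def test_unknown_contig_raises(self):
        pair = make_pair(1001, 1150, "+", 1001, 1140, "-", chrom="chrUn", chrom2="chrUn")
        with pytest.raises(KeyError, match="chrUn"):
            curate(pair, CONTIGS)


class TestProblematicLength:
    @pytest.mark.parametrize(
        "spans,expected",
        [
            # sequence-through with 10 bp overhang: outermost span over-counts
            (((1001, 1150, "+"), (1001, 1140, "-")), 150),
            # non-overlapping inward pair: definitions coincide
            (((1001, 1150, "+"), (1201, 1350, "-")), 350),
            # exact sequence-through, no overhang
            (((1001, 1140, "+"), (1001, 1140, "-")), 140),
        ],
    )
    def test_outermost_boundaries(self, spans, expected):
        (s1, e1, st1), (s2, e2, st2) = spans
        pair = make_pair(s1, e1, st1, s2, e2, st2)
        assert problematic_length(pair) == expected

    def test_different_contigs_error(self):
        pair = make_pair(1001, 1150, "+", 1001, 1150, "-", chrom2="chr2")
        with pytest.raises(ValueError):
            problematic_length(pair)

    def test_agrees_with_curated_beyond_two_read_lengths(self, clean_sim):
        # for fragments longer than 2 x read length the two definitions coincide
        cfg, _, truth, bam = clean_sim
        checked = 0
        for pair in read_pairs(bam):
            out = curate(pair, cfg.contig_lengths)
            if out.ok and out.fragment.length > 2 * cfg.read_length:
                assert problematic_length(pair) == out.fragment.length
                checked += 1
        assert checked > 10


class TestFragTsv:
    def test_conversion_and_filter(self, tmp_path):
        p = tmp_path / "frags.tsv"
        p.write_text(
            "chrom\tstart\tend\tmapq\tstrand\n"
            "chr1\t1000\t1140\t60\t+\n"
            "chr1\t5000\t5167\t10\t-\n"
        )
        frags = list(read_frag_tsv(p))
        assert len(frags) == 1  # mapq-10 row dropped
        assert (frags[0].start, frags[0].end, frags[0].length) == (1001, 1140, 140)

    def test_one_based_override(self, tmp_path):
        p = tmp_path / "frags.tsv"
        p.write_text("chr1\t1001\t1140\t60\t+\n")
        (frag,) = read_frag_tsv(p, zero_based_half_open=False)
        assert (frag.start, frag.end) == (1001, 1140)

    def test_empty_with_header(self, tmp_path):
        p = tmp_path / "frags.tsv"
        p.write_text("chrom\tstart\tend\tmapq\tstrand\n")
        assert list(read_frag_tsv(p)) == []

    def test_bad_row_names_line(self, tmp_path):
        p = tmp_path / "frags.tsv"
        p.write_text("chr1\t1000\t1140\t60\t+\nchr1\tXYZ\t2000\t60\t+\n")
        with pytest.raises(ValueError, match=":2"):
            list(read_frag_tsv(p))


class TestReadPairs:
    def test_clean_file_all_paired(self, clean_sim):
        cfg, _, _, bam = clean_sim
        report = fragio.PairReadReport()
        pairs = list(read_pairs(bam, report=report))
        assert len(pairs) == cfg.n_fragments
        assert report.orphans == 0

    def test_orphans_reported(self, clean_sim, tmp_path):
        cfg, _, _, bam = clean_sim
        # drop read2 of ten templates
        drop = {f"frag{i:07d}" for i in range(10)}
        out = tmp_path / "orphaned.bam"
        with pysam.AlignmentFile(str(bam), "rb") as src:
            with pysam.AlignmentFile(str(out), "wb", template=src) as dst:
                for rec in src.fetch(until_eof=True):
                    if rec.query_name in drop and rec.is_read2:
                        continue
                    dst.write(rec)
        report = fragio.PairReadReport()
        pairs = list(read_pairs(out, report=report))
        assert len(pairs) == cfg.n_fragments - 10
        assert report.orphans == 10
        assert set(report.orphan_names) == drop

    def test_single_end_rejected(self, tmp_path):
        sam = tmp_path / "se.sam"
        sam.write_text(
            "@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:chr1\tLN:10000\n"
            "r1\t0\tchr1\t100\t60\t50M\t*\t0\t0\t" + "A" * 50 + "\t" + "F" * 50 + "\n"
        )
        with pytest.raises(fragio.NotPairedEndError):
            list(read_pairs(sam))

    def test_region_query_matches_brute_force(self, clean_sim):
        cfg, _, truth, bam = clean_sim
        region = "chr1:1-50000"
        got = {p.query_name for p in read_pairs(bam, region=region)}
        # brute force over the truth table: any read of the pair overlaps window
        expect = set()
        L = cfg.read_length
        for row in truth.fragments.itertuples(index=False):
            if row.chrom != "chr1":
                continue
            fe = min(row.true_start + L - 1, row.true_end + row.overhang_len)
            rs = max(row.true_start, row.true_end - L + 1)
            if row.true_start <= 50000 or rs <= 50000:
                assert fe >= 1
                expect.add(row.fragment_id)
        assert got == expect


class TestStreamingOracle:
    def test_matches_in_memory_enumeration(self, artifact_sim):
        """Streaming QC+curation equals a brute-force in-memory pass."""
        cfg, _, _, bam = artifact_sim
        report = fragio.CurationReport()
        streamed = {
            (f.query_name, f.ref_name, f.start, f.end)
            for f in curated_fragments(read_pairs(bam), cfg.contig_lengths, report=report)
        }
        # brute force: slurp every record, group by name, re-apply the rules
        by_name: dict[str, list] = {}
        with pysam.AlignmentFile(str(bam), "rb") as af:
            for rec in af.fetch(until_eof=True):
                by_name.setdefault(rec.query_name, []).append(rec)
        expected = set()
        for name, recs in by_name.items():
            assert len(recs) == 2
            a, b = recs
            if any(
                r.is_unmapped or r.mapping_quality < 30 or r.is_duplicate
                or r.is_secondary or r.is_supplementary
                for r in recs
            ):
                continue
            if a.reference_name != b.reference_name:
                continue
            if a.is_reverse == b.is_reverse:
                continue
            fwd = a if not a.is_reverse else b
            rev = b if fwd is a else a
            start, end = fwd.reference_start + 1, rev.reference_end
            if start > end or start < 1 or end > cfg.contig_lengths[a.reference_name]:
                continue
            expected.add((name, a.reference_name, start, end))
        assert streamed == expected
        # exact accounting
        assert report.pairs_in == report.passing + report.total_rejected()


class TestDownsample:
    def test_identity_at_full_fraction(self, clean_sim, tmp_path):
        _, _, _, bam = clean_sim
        out = tmp_path / "full.bam"
        n = downsample(bam, out, fraction=1.0, seed=1)
        with pysam.AlignmentFile(str(bam), "rb") as af:
            total = sum(1 for _ in af.fetch(until_eof=True))
        assert n == total

    def test_half_fraction_pairs_preserved(self, clean_sim, tmp_path):
        cfg, _, _, bam = clean_sim
        out = tmp_path / "half.bam"
        n = downsample(bam, out, fraction=0.5, seed=7)
        kept_pairs = n / 2
        mean, sd = cfg.n_fragments * 0.5, (cfg.n_fragments * 0.25) ** 0.5
        assert abs(kept_pairs - mean) < 3 * sd
        counts: dict[str, int] = {}
        with pysam.AlignmentFile(str(out), "rb") as af:
            for rec in af.fetch(until_eof=True):
                counts[rec.query_name] = counts.get(rec.query_name, 0) + 1
        assert all(v == 2 for v in counts.values())  # no orphaned mates

    def test_coverage_mode_error_when_above_current(self, clean_sim, tmp_path):
        _, _, _, bam = clean_sim
        with pytest.raises(ValueError, match="exceeds"):
            downsample(bam, tmp_path / "x.bam", target_coverage=1e9)
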