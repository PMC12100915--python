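"""Paired-end alignment input, QC, and fragment curation.

cfDNA molecules are sequenced as paired-end reads.  The curated fragment is
the interval from the forward-strand read's left boundary to the
reverse-strand read's right boundary; this is robust to "sequence-through"
read pairs (fragment shorter than the read length) where untrimmed adapter
can extend a read's aligned span past the true molecule end.  The
"problematic" alternative — outermost boundaries of the two reads — is kept
only as a diagnostic.

All internal coordinates are 1-based inclusive (SAM convention);
``length = end - start + 1``.  BED-like inputs are converted at the boundary.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator

import pysam

logger = logging.getLogger(__name__)


class NotPairedEndError(ValueError):
    """Raised when an alignment file does not contain paired-end reads."""


class QCReason(str, Enum):
    """Reasons a read pair fails quality control, in evaluation order."""

    UNMAPPED = "unmapped"
    MAPQ = "mapq"
    DUPLICATE = "duplicate"
    SECONDARY = "secondary"
    SUPPLEMENTARY = "supplementary"
    PROPER_PAIR = "proper_pair"


class CurationReason(str, Enum):
    """Reasons a QC-passing pair cannot be curated into a fragment."""

    SEQNAME_DISCORDANT = "SEQNAME_DISCORDANT"
    NO_STRAND = "NO_STRAND"
    NOT_INWARD = "NOT_INWARD"
    OUT_OF_BOUND = "OUT_OF_BOUND"


@dataclass
class AlignmentRecord:
    """One mapped (or unmapped) read: the unit of QC.

    ``start``/``end`` are the 1-based inclusive reference span of the
    alignment, computed from reference-consuming CIGAR operations
    (soft-clips excluded).  Unmapped records carry no coordinates.
    """

    query_name: str
    ref_name: str | None
    start: int | None
    end: int | None
    strand: str | None  # "+", "-", or None for unmapped
    mapq: int
    is_paired: bool = True
    is_proper_pair: bool = False
    is_unmapped: bool = False
    is_secondary: bool = False
    is_supplementary: bool = False
    is_duplicate: bool = False
    is_first_in_pair: bool = True
    bases: str = ""
    qualities: list[int] | None = None
    cigartuples: list[tuple[int, int]] | None = None
    edit_distance: int | None = None

    @classmethod
    def from_pysam(cls, rec: pysam.AlignedSegment) -> "AlignmentRecord":
        unmapped = rec.is_unmapped
        nm = rec.get_tag("NM") if rec.has_tag("NM") else None
        return cls(
            query_name=rec.query_name,
            ref_name=None if unmapped else rec.reference_name,
            start=None if unmapped else rec.reference_start + 1,
            end=None if unmapped else rec.reference_end,  # pysam end is exclusive 0-based == inclusive 1-based
            strand=None if unmapped else ("-" if rec.is_reverse else "+"),
            mapq=rec.mapping_quality,
            is_paired=rec.is_paired,
            is_proper_pair=rec.is_proper_pair,
            is_unmapped=unmapped,
            is_secondary=rec.is_secondary,
            is_supplementary=rec.is_supplementary,
            is_duplicate=rec.is_duplicate,
            is_first_in_pair=rec.is_read1,
            bases=rec.query_sequence or "",
            qualities=list(rec.query_qualities) if rec.query_qualities is not None else None,
            cigartuples=list(rec.cigartuples) if rec.cigartuples else None,
            edit_distance=int(nm) if nm is not None else None,
        )

    def query_index_at(self, ref_pos: int) -> int | None:
        """Query-sequence index aligned to 1-based reference position, or None.

        Returns None when the read does not span the position or a deletion /
        reference skip covers it.  Walks the CIGAR: M/=/X consume both, I/S
        consume query only, D/N consume reference only.
        """
        if self.is_unmapped or self.start is None or self.cigartuples is None:
            return None
        rpos = self.start
        qidx = 0
        for op, ln in self.cigartuples:
            if op in (0, 7, 8):  # M, =, X
                if rpos <= ref_pos < rpos + ln:
                    return qidx + (ref_pos - rpos)
                rpos += ln
                qidx += ln
            elif op in (1, 4):  # I, S
                qidx += ln
            elif op in (2, 3):  # D, N
                if rpos <= ref_pos < rpos + ln:
                    return None
                rpos += ln
            # H (5) and P (6) consume neither
        return None

    def base_at(self, ref_pos: int, min_base_quality: int = 0) -> str | None:
        """Read base aligned to a 1-based reference position.

        None if the read does not span the position, a deletion covers it,
        or the base quality is below ``min_base_quality``.
        """
        idx = self.query_index_at(ref_pos)
        if idx is None or idx >= len(self.bases):
            return None
        if min_base_quality and self.qualities is not None and self.qualities[idx] < min_base_quality:
            return None
        return self.bases[idx]


@dataclass
class ReadPair:
    """The two primary records of one paired-end template."""

    r1: AlignmentRecord
    r2: AlignmentRecord

    @property
    def query_name(self) -> str:
        return self.r1.query_name

    @property
    def records(self) -> tuple[AlignmentRecord, AlignmentRecord]:
        return (self.r1, self.r2)

    def forward_reverse(self) -> tuple[AlignmentRecord, AlignmentRecord] | None:
        """(plus-strand read, minus-strand read), or None without exactly one of each."""
        strands = {self.r1.strand, self.r2.strand}
        if strands != {"+", "-"}:
            return None
        fwd = self.r1 if self.r1.strand == "+" else self.r2
        rev = self.r2 if fwd is self.r1 else self.r1
        return fwd, rev


@dataclass
class QCPolicy:
    """Read-pair quality control policy.

    Defaults: minimum mapping quality 30; reads must be paired; duplicates,
    secondary, supplementary and unmapped records are dropped.  Proper-pair
    filtering is deliberately OFF by default: the proper-pair flag is
    assigned by aligners under a unimodal insert-size assumption that does
    not hold for cfDNA (di-/tri-nucleosome peaks), so enabling it loses
    long fragments.
    """

    min_mapq: int = 30
    require_paired: bool = True
    require_proper_pair: bool = False
    drop_duplicates: bool = True
    drop_secondary: bool = True
    drop_supplementary: bool = True
    drop_unmapped: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.min_mapq <= 255):
            raise ValueError(f"min_mapq must be in [0, 255], got {self.min_mapq}")


@dataclass
class Fragment:
    """A curated genomic interval representing one cfDNA molecule."""

    ref_name: str
    start: int  # 1-based
    end: int  # inclusive
    query_name: str = ""
    meta: dict = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, chrom: str, pos: int) -> bool:
        return self.ref_name == chrom and self.start <= pos <= self.end


@dataclass
class CurationOutcome:
    """Either a curated Fragment or a rejection reason; never both."""

    fragment: Fragment | None = None
    reason: CurationReason | None = None

    def __post_init__(self) -> None:
        if (self.fragment is None) == (self.reason is None):
            raise ValueError("exactly one of fragment / reason must be set")

    @property
    def ok(self) -> bool:
        return self.fragment is not None


@dataclass
class PairReadReport:
    """Accounting from one pass over an alignment file."""

    pairs: int = 0
    orphans: int = 0
    orphan_names: list[str] = field(default_factory=list)
    malformed: int = 0


def read_pairs(
    alignment_file: str | Path,
    region: str | None = None,
    report: PairReadReport | None = None,
) -> Iterator[ReadPair]:
    """Stream ReadPairs assembled by query name from primary records.

    Secondary/supplementary records are attached to neither slot of a pair;
    they are carried only when a template has fewer than two primary records
    (so QC can still see and reject them).  Memory is bounded by the number
    of simultaneously open (mate-pending) templates, not file size.

    With ``region`` (``"chr1:1-10000"`` or a contig name) only templates
    with a record overlapping the window are yielded; requires an index.
    Records whose mate never appears are counted as orphans in ``report``,
    not silently dropped.
    """
    path = str(alignment_file)
    mode = "r" if path.endswith(".sam") else "rb"
    pending: dict[str, pysam.AlignedSegment] = {}
    if report is None:
        report = PairReadReport()

    def make_pair(x: pysam.AlignedSegment, y: pysam.AlignedSegment) -> ReadPair:
        a, b = AlignmentRecord.from_pysam(x), AlignmentRecord.from_pysam(y)
        # keep read1 in slot r1 when identifiable
        if b.is_first_in_pair and not a.is_first_in_pair:
            a, b = b, a
        report.pairs += 1
        return ReadPair(a, b)

    with pysam.AlignmentFile(path, mode) as af:
        it = af.fetch(region=region) if region else af.fetch(until_eof=True)
        for rec in it:
            if rec.query_name is None:
                report.malformed += 1
                logger.warning("record with no query name skipped")
                continue
            if not rec.is_paired:
                raise NotPairedEndError(
                    f"{path}: record {rec.query_name!r} is not paired; "
                    "this tool requires paired-end alignments"
                )
            name = rec.query_name
            mate = pending.pop(name, None)
            if mate is None:
                pending[name] = rec
            else:
                yield make_pair(mate, rec)
    if region and pending:
        # mates outside the fetch window: resolve through the index so a
        # pair qualifies whenever either record overlaps the window
        with pysam.AlignmentFile(path, mode) as af2:
            for name in sorted(pending):
                rec = pending.pop(name)
                try:
                    mate = af2.mate(rec)
                except ValueError:
                    pending[name] = rec
                    continue
                yield make_pair(rec, mate)
    report.orphans = len(pending)
    report.orphan_names = sorted(pending)
    if report.orphans:
        logger.warning("%d records had no mate in the file", report.orphans)


def apply_qc(pair: ReadPair, policy: QCPolicy | None = None) -> tuple[bool, QCReason | None]:
    """Apply the QC policy to a read pair; fail if EITHER mate violates a rule.

    Reasons are evaluated in fixed order: unmapped, mapq, duplicate,
    secondary, supplementary, proper-pair (only when enabled), and the first
    violated rule is reported.
    """
    if policy is None:
        policy = QCPolicy()
    r1, r2 = pair.records
    if policy.drop_unmapped and (r1.is_unmapped or r2.is_unmapped):
        return False, QCReason.UNMAPPED
    if r1.mapq < policy.min_mapq or r2.mapq < policy.min_mapq:
        return False, QCReason.MAPQ
    if policy.drop_duplicates and (r1.is_duplicate or r2.is_duplicate):
        return False, QCReason.DUPLICATE
    if policy.drop_secondary and (r1.is_secondary or r2.is_secondary):
        return False, QCReason.SECONDARY
    if policy.drop_supplementary and (r1.is_supplementary or r2.is_supplementary):
        return False, QCReason.SUPPLEMENTARY
    if policy.require_proper_pair and not (r1.is_proper_pair and r2.is_proper_pair):
        return False, QCReason.PROPER_PAIR
    return True, None


def curate(pair: ReadPair, contig_lengths: dict[str, int]) -> CurationOutcome:
    """Curate a QC-passing pair into a fragment, or reject it.

    Curation steps, in fixed precedence: mates on one contig; both strands
    defined and opposite; inwardly directed (plus-strand read's start no
    greater than minus-strand read's end); fragment = [forward start,
    reverse end]; within contig bounds.
    """
    r1, r2 = pair.records
    if r1.ref_name != r2.ref_name:
        return CurationOutcome(reason=CurationReason.SEQNAME_DISCORDANT)
    fr = pair.forward_reverse()
    if fr is None:
        return CurationOutcome(reason=CurationReason.NO_STRAND)
    fwd, rev = fr
    if fwd.start > rev.end:
        return CurationOutcome(reason=CurationReason.NOT_INWARD)
    ref = r1.ref_name
    if ref not in contig_lengths:
        raise KeyError(f"unknown contig {ref!r} (not in provided contig lengths)")
    start, end = fwd.start, rev.end
    if start < 1 or end > contig_lengths[ref] or start > end:
        return CurationOutcome(reason=CurationReason.OUT_OF_BOUND)
    return CurationOutcome(
        fragment=Fragment(ref_name=ref, start=start, end=end, query_name=pair.query_name)
    )


def problematic_length(pair: ReadPair) -> int:
    """Outermost-boundaries length: max end - min start + 1.

    Diagnostic only — this definition over-counts sequence-through fragments
    whose forward read carries an untrimmed-adapter overhang.  Never used by
    feature calls.
    """
    r1, r2 = pair.records
    if r1.ref_name != r2.ref_name:
        raise ValueError(
            f"pair {pair.query_name!r}: mates on different contigs "
            f"({r1.ref_name} vs {r2.ref_name})"
        )
    return max(r1.end, r2.end) - min(r1.start, r2.start) + 1


@dataclass
class CurationReport:
    """Exact accounting: pairs_in == passing + sum of per-reason rejections."""

    pairs_in: int = 0
    passing: int = 0
    qc_rejections: dict[str, int] = field(default_factory=dict)
    curation_rejections: dict[str, int] = field(default_factory=dict)

    def total_rejected(self) -> int:
        return sum(self.qc_rejections.values()) + sum(self.curation_rejections.values())


def curated_fragments(
    pairs: Iterable[ReadPair],
    contig_lengths: dict[str, int],
    policy: QCPolicy | None = None,
    report: CurationReport | None = None,
) -> Iterator[Fragment]:
    """QC + curation over a stream of pairs, with exact rejection accounting."""
    if policy is None:
        policy = QCPolicy()
    for pair in pairs:
        if report is not None:
            report.pairs_in += 1
        ok, qc_reason = apply_qc(pair, policy)
        if not ok:
            if report is not None:
                report.qc_rejections[qc_reason.value] = (
                    report.qc_rejections.get(qc_reason.value, 0) + 1
                )
            continue
        outcome = curate(pair, contig_lengths)
        if not outcome.ok:
            if report is not None:
                report.curation_rejections[outcome.reason.value] = (
                    report.curation_rejections.get(outcome.reason.value, 0) + 1
                )
            continue
        if report is not None:
            report.passing += 1
        yield outcome.fragment


def read_frag_tsv(
    path: str | Path,
    min_mapq: int = 30,
    zero_based_half_open: bool = True,
) -> Iterator[Fragment]:
    """Read a FinaleDB-style fragment coordinate table.

    Expected tab-separated columns: chrom, start, end, mapq, strand.  The
    dialect is 0-based half-open by default (BED-like), converted to the
    internal 1-based inclusive convention, so length == end - start of the
    input row.  Rows below ``min_mapq`` are dropped.  A header line (first
    field non-numeric in column 2) is skipped.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected >= 4 tab-separated columns")
            chrom, s, e, mq = parts[0], parts[1], parts[2], parts[3]
            if lineno == 1 and not (s.lstrip("-").isdigit() and e.lstrip("-").isdigit()):
                continue  # header
            try:
                s_i, e_i, mq_i = int(s), int(e), int(mq)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric coordinate or mapq: {exc}") from exc
            if mq_i < min_mapq:
                continue
            if zero_based_half_open:
                start, end = s_i + 1, e_i
            else:
                start, end = s_i, e_i
            if start > end:
                raise ValueError(f"{path}:{lineno}: start > end after conversion")
            yield Fragment(ref_name=chrom, start=start, end=end, query_name=f"tsv:{lineno}")


def _keep_name(query_name: str, fraction: float, seed: int) -> bool:
    """Deterministic per-template keep decision from a seeded hash of the name."""
    h = hashlib.blake2b(f"{seed}:{query_name}".encode(), digest_size=8).digest()
    u = int.from_bytes(h, "big") / 2**64
    return u < fraction


def downsample(
    alignment_file: str | Path,
    out_file: str | Path,
    fraction: float | None = None,
    target_coverage: float | None = None,
    seed: int = 0,
) -> int:
    """Pair-preserving downsampling of an alignment file.

    Both mates of a template are kept or dropped together, decided by a
    seeded hash of the query name, so reruns with the same seed reproduce
    the identical record set and no mate is ever orphaned.  Either a keep
    ``fraction`` in (0, 1] or a ``target_coverage`` (converted to a fraction
    via the file's current mean coverage) must be given.  Returns the number
    of records written.
    """
    from cffrag.bamstats import summarise

    if (fraction is None) == (target_coverage is None):
        raise ValueError("give exactly one of fraction / target_coverage")
    if fraction is None:
        current = summarise(alignment_file).mean_coverage
        if target_coverage > current:
            raise ValueError(
                f"target coverage {target_coverage} exceeds current mean coverage {current:.4g}"
            )
        fraction = target_coverage / current
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")

    in_path, out_path = str(alignment_file), str(out_file)
    in_mode = "r" if in_path.endswith(".sam") else "rb"
    out_mode = "w" if out_path.endswith(".sam") else "wb"
    written = 0
    with pysam.AlignmentFile(in_path, in_mode) as src:
        with pysam.AlignmentFile(out_path, out_mode, template=src) as dst:
            for rec in src.fetch(until_eof=True):
                if fraction >= 1.0 or _keep_name(rec.query_name, fraction, seed):
                    dst.write(rec)
                    written += 1
    if out_path.endswith(".bam"):
        try:
            pysam.index(out_path)
        except pysam.SamtoolsError:  # unsorted input: leave unindexed
            logger.warning("could not index %s (input not coordinate-sorted?)", out_path)
    return written
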