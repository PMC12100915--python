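"""Mutation-overlap annotation and trinucleotide substitution profiles.

In paired-end cfDNA sequencing, short fragments are read by both mates, so a
variant locus inside the mate-overlap region is observed twice per molecule.
Each fragment overlapping an a priori variant locus is classified as:

- CO (concordant overlap): both reads cover the locus and support the same
  alternative base;
- SO (single-read overlap): exactly one read covers the locus and supports
  the alternative base;
- DO (discordant overlap): both reads cover the locus and disagree;
- REF_ONLY: at least one read covers the locus and no alternative observed;
- NO_COVER: the fragment overlaps the locus but no read base aligns there
  (long fragments have an unread gap between mates).

DO fragments gauge per-locus noise: removing DO events from a 96-context
single-base-substitution (SBS) profile can sharpen its resemblance to a
mutational signature.  Profiles use the standard pyrimidine-centric order
(C>A, C>G, C>T, T>A, T>C, T>G, each across 16 flanking contexts).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from cffrag.fragio import QCPolicy, ReadPair, apply_qc, read_pairs

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: the 96 SBS context labels, pyrimidine-centric, in COSMIC column order
SBS96_CONTEXTS: tuple[str, ...] = tuple(
    f"{five}[{ref}>{alt}]{three}"
    for ref, alts in (("C", "AGT"), ("T", "ACG"))
    for alt in alts
    for five in "ACGT"
    for three in "ACGT"
)
_CONTEXT_INDEX = {c: i for i, c in enumerate(SBS96_CONTEXTS)}

STRATA = ("ALL", "CO", "SO", "DO", "CO+SO")


class OverlapCategory(str, Enum):
    CO = "CO"
    SO = "SO"
    DO = "DO"
    REF_ONLY = "REF_ONLY"
    NO_COVER = "NO_COVER"


@dataclass(frozen=True)
class VariantLocus:
    """An a priori single-nucleotide variant site (1-based position)."""

    chrom: str
    pos: int
    ref_base: str
    alt_base: str

    def __post_init__(self) -> None:
        if self.ref_base not in "ACGT" or self.alt_base not in "ACGT":
            raise ValueError(f"{self}: ref and alt must be single A/C/G/T bases")
        if self.ref_base == self.alt_base:
            raise ValueError(f"{self}: ref == alt")

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref_base}>{self.alt_base}"


@dataclass
class OverlapAnnotation:
    """Per-fragment classification at one variant locus."""

    fragment_id: str
    locus: VariantLocus
    category: OverlapCategory
    base_r1: str | None = None
    base_r2: str | None = None
    both_reads_cover: bool = False


@dataclass
class LocusSupport:
    """Per-locus fragment tallies."""

    locus: VariantLocus
    ref_count: int = 0
    alt_count: int = 0
    category_counts: dict[str, int] = field(default_factory=dict)

    @property
    def total_overlapping(self) -> int:
        return sum(self.category_counts.values())


@dataclass
class SBSProfile:
    """96-context substitution count vector for one stratum."""

    counts: np.ndarray
    stratum: str = "ALL"
    empty: bool = False

    def __post_init__(self) -> None:
        if len(self.counts) != 96:
            raise ValueError(f"SBS profile must have 96 entries, got {len(self.counts)}")
        if np.any(np.asarray(self.counts) < 0):
            raise ValueError("SBS counts must be non-negative")

    @property
    def contexts(self) -> tuple[str, ...]:
        return SBS96_CONTEXTS

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"context": self.contexts, "count": self.counts})


def read_variant_loci(path: str | Path) -> list[VariantLocus]:
    """Read a tab-separated variant list: chrom, pos, ref, alt.

    A header line is detected by a non-numeric second field and skipped.
    VCF files (``.vcf``) are accepted as a convenience; only the first four
    variant fields are used and multi-allelic/indel rows are skipped.
    """
    path = Path(path)
    loci: list[VariantLocus] = []
    is_vcf = path.suffix == ".vcf"
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if is_vcf:
                if len(parts) < 5:
                    continue
                chrom, pos, ref, alt = parts[0], parts[1], parts[3], parts[4]
            else:
                if len(parts) < 4:
                    raise ValueError(f"{path}:{lineno}: expected 4 columns (chrom pos ref alt)")
                chrom, pos, ref, alt = parts[:4]
            if not pos.isdigit():
                if lineno == 1:
                    continue  # header
                raise ValueError(f"{path}:{lineno}: non-numeric position {pos!r}")
            if len(ref) != 1 or len(alt) != 1 or ref not in "ACGT" or alt not in "ACGT":
                if is_vcf:
                    continue  # indel / multi-allelic: out of scope
                raise ValueError(f"{path}:{lineno}: only single-nucleotide variants supported")
            loci.append(VariantLocus(chrom, int(pos), ref, alt))
    return loci


def locus_base_support(
    pair: ReadPair,
    locus: VariantLocus,
    min_base_quality: int = 20,
) -> tuple[str | None, str | None]:
    """Observed base at the locus for each read of the pair.

    None for a read that does not span the position, has a deletion over
    it, or whose base quality is below ``min_base_quality``.
    """
    out = []
    for rec in pair.records:
        if rec.is_unmapped or rec.ref_name != locus.chrom:
            out.append(None)
            continue
        out.append(rec.base_at(locus.pos, min_base_quality))
    return out[0], out[1]


def classify_overlap(
    support: tuple[str | None, str | None], locus: VariantLocus
) -> OverlapCategory:
    """Map a per-read base observation to a CO/SO/DO/REF_ONLY/NO_COVER category.

    Total function: every observation maps to exactly one category.
    """
    b1, b2 = support
    covering = [b for b in (b1, b2) if b is not None]
    if not covering:
        return OverlapCategory.NO_COVER
    alt_hits = sum(b == locus.alt_base for b in covering)
    if len(covering) == 2:
        if alt_hits == 2:
            return OverlapCategory.CO
        if alt_hits == 1:
            return OverlapCategory.DO
        return OverlapCategory.REF_ONLY
    # exactly one covering read
    return OverlapCategory.SO if alt_hits == 1 else OverlapCategory.REF_ONLY


def annotate_pairs(
    pairs: Iterable[ReadPair],
    loci: Sequence[VariantLocus],
    contig_lengths: dict[str, int],
    policy: QCPolicy | None = None,
    min_base_quality: int = 20,
) -> list[OverlapAnnotation]:
    """QC + curate pairs and classify every fragment x overlapping-locus pair."""
    from cffrag.fragio import curate

    if policy is None:
        policy = QCPolicy()
    by_chrom: dict[str, list[VariantLocus]] = defaultdict(list)
    for lc in loci:
        by_chrom[lc.chrom].append(lc)
    annotations: list[OverlapAnnotation] = []
    for pair in pairs:
        ok, _ = apply_qc(pair, policy)
        if not ok:
            continue
        outcome = curate(pair, contig_lengths)
        if not outcome.ok:
            continue
        frag = outcome.fragment
        for lc in by_chrom.get(frag.ref_name, ()):
            if not (frag.start <= lc.pos <= frag.end):
                continue
            support = locus_base_support(pair, lc, min_base_quality)
            cat = classify_overlap(support, lc)
            annotations.append(
                OverlapAnnotation(
                    fragment_id=frag.query_name,
                    locus=lc,
                    category=cat,
                    base_r1=support[0],
                    base_r2=support[1],
                    both_reads_cover=support[0] is not None and support[1] is not None,
                )
            )
    return annotations


def aggregate_support(
    annotations: Iterable[OverlapAnnotation],
    include_discordant_in_alt: bool = False,
) -> dict[str, LocusSupport]:
    """Per-locus ref/alt fragment tallies, keyed by locus id.

    DO fragments gauge locus-level noise, so by default they are tallied
    separately and NOT added to ``alt_count``; set
    ``include_discordant_in_alt`` to count them as alternative support.
    """
    out: dict[str, LocusSupport] = {}
    for ann in annotations:
        sup = out.get(ann.locus.id)
        if sup is None:
            sup = out[ann.locus.id] = LocusSupport(locus=ann.locus)
        cat = ann.category.value
        sup.category_counts[cat] = sup.category_counts.get(cat, 0) + 1
        if ann.category in (OverlapCategory.CO, OverlapCategory.SO):
            sup.alt_count += 1
        elif ann.category is OverlapCategory.DO and include_discordant_in_alt:
            sup.alt_count += 1
        elif ann.category is OverlapCategory.REF_ONLY:
            sup.ref_count += 1
    return out


def pileup_mismatches(
    alignment_file: str | Path,
    region: str,
    reference,
    min_base_quality: int = 20,
    min_mapq: int = 30,
    min_alt_fragments: int = 1,
    policy: QCPolicy | None = None,
) -> list[tuple[VariantLocus, int, int]]:
    """De novo mismatch candidates from a fragment-level pileup.

    Walks QC-passing read pairs over ``region`` (``"chrom:start-end"``,
    1-based inclusive) and tallies one observation per fragment per
    position: where both mates cover a position they must agree, otherwise
    the observation is discarded (the mate-overlap double-count guard, with
    disagreement treated as locus noise).  Positions where a non-reference
    base is supported by at least ``min_alt_fragments`` fragments are
    returned as (locus, ref_count, alt_count), ordered by position.
    """
    chrom, _, span = region.partition(":")
    if span:
        a, _, b = span.partition("-")
        start, end = int(a.replace(",", "")), int(b.replace(",", ""))
    else:
        start, end = 1, len(reference[chrom])
    if chrom not in reference:
        raise KeyError(f"unknown contig {chrom!r}")
    if end > len(reference[chrom]) or start < 1:
        raise ValueError(f"region {region} outside contig bounds")
    if policy is None:
        policy = QCPolicy(min_mapq=min_mapq)

    ref_seq = str(reference[chrom][start - 1 : end]).upper()
    base_tallies: dict[int, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    for pair in read_pairs(alignment_file, region=f"{chrom}:{start}-{end}"):
        ok, _ = apply_qc(pair, policy)
        if not ok:
            continue
        r1, r2 = pair.records
        lo = max(start, min(r.start for r in pair.records if not r.is_unmapped))
        hi = min(end, max(r.end for r in pair.records if not r.is_unmapped))
        for pos in range(lo, hi + 1):
            b1 = r1.base_at(pos, min_base_quality) if r1.ref_name == chrom else None
            b2 = r2.base_at(pos, min_base_quality) if r2.ref_name == chrom else None
            if b1 is not None and b2 is not None:
                if b1 != b2:
                    continue  # discordant mate observation: drop from depth
                base = b1
            else:
                base = b1 if b1 is not None else b2
            if base is None or base not in "ACGT":
                continue
            base_tallies[pos][base] += 1

    out: list[tuple[VariantLocus, int, int]] = []
    for pos in sorted(base_tallies):
        ref_base = ref_seq[pos - start]
        if ref_base not in "ACGT":
            continue
        tallies = base_tallies[pos]
        ref_count = tallies.get(ref_base, 0)
        for alt in "ACGT":
            if alt == ref_base:
                continue
            alt_count = tallies.get(alt, 0)
            if alt_count >= min_alt_fragments:
                out.append((VariantLocus(chrom, pos, ref_base, alt), ref_count, alt_count))
    return out


def sbs_context(locus: VariantLocus, reference) -> str:
    """Pyrimidine-centric trinucleotide context label of a substitution.

    If the reference base is a purine, the substitution is reported on the
    opposite strand: complemented alt, reverse-complemented flanks.
    """
    chrom_len = len(reference[locus.chrom])
    if not (2 <= locus.pos <= chrom_len - 1):
        raise ValueError(f"{locus.id}: no flanking bases within contig")
    tri = str(reference[locus.chrom][locus.pos - 2 : locus.pos + 1]).upper()
    if tri[1] != locus.ref_base:
        raise ValueError(
            f"{locus.id}: reference base at {locus.chrom}:{locus.pos} is {tri[1]}, "
            f"not {locus.ref_base}"
        )
    ref, alt = locus.ref_base, locus.alt_base
    five, three = tri[0], tri[2]
    if ref in "AG":
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        five, three = _COMPLEMENT[tri[2]], _COMPLEMENT[tri[0]]
    return f"{five}[{ref}>{alt}]{three}"


def call_trinucleotide(
    annotations: Iterable[OverlapAnnotation],
    reference,
    strata: Sequence[str] = STRATA,
) -> dict[str, SBSProfile]:
    """96-context substitution profiles stratified by overlap category.

    Each locus contributes to a stratum's profile with weight equal to the
    number of fragments in that stratum supporting the alternative base
    (fragment-weighted; ALL = CO + SO + DO).  The "DO-removed" profile is
    obtained as ALL minus DO, available via :func:`do_removed_profile`.
    """
    for s in strata:
        if s not in STRATA:
            raise ValueError(f"unknown stratum {s!r}; choose from {STRATA}")
    context_cache: dict[str, int] = {}
    profiles = {s: np.zeros(96, dtype=np.int64) for s in strata}
    for ann in annotations:
        if ann.category not in (OverlapCategory.CO, OverlapCategory.SO, OverlapCategory.DO):
            continue
        lid = ann.locus.id
        idx = context_cache.get(lid)
        if idx is None:
            idx = context_cache[lid] = _CONTEXT_INDEX[sbs_context(ann.locus, reference)]
        cat = ann.category.value
        for s in strata:
            if s == "ALL" or s == cat or (s == "CO+SO" and cat in ("CO", "SO")):
                profiles[s][idx] += 1
    out = {}
    for s, counts in profiles.items():
        empty = counts.sum() == 0
        if empty:
            logger.warning("stratum %s has no substitution events", s)
        out[s] = SBSProfile(counts=counts, stratum=s, empty=bool(empty))
    return out


def do_removed_profile(profiles: dict[str, SBSProfile]) -> SBSProfile:
    """ALL-minus-DO profile: the substitution spectrum after noise removal."""
    if "ALL" not in profiles or "DO" not in profiles:
        raise ValueError("need both ALL and DO strata to form the DO-removed profile")
    counts = profiles["ALL"].counts - profiles["DO"].counts
    if np.any(counts < 0):
        raise ValueError("DO counts exceed ALL counts; strata are inconsistent")
    return SBSProfile(counts=counts, stratum="ALL-DO", empty=bool(counts.sum() == 0))


def cosine_similarity(p: np.ndarray | SBSProfile, q: np.ndarray | SBSProfile) -> float:
    """Cosine similarity of two non-negative spectra; NaN for a zero vector."""
    vp = p.counts if isinstance(p, SBSProfile) else np.asarray(p, dtype=float)
    vq = q.counts if isinstance(q, SBSProfile) else np.asarray(q, dtype=float)
    if len(vp) != len(vq):
        raise ValueError("vectors differ in length")
    np_, nq = np.linalg.norm(vp), np.linalg.norm(vq)
    if np_ == 0 or nq == 0:
        return float("nan")
    return float(np.dot(vp, vq) / (np_ * nq))
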