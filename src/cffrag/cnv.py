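"""Simplified binned copy-number states from fragment counts.

Fragments are counted into fixed-width genomic bins (midpoint assignment,
half-open bins), corrected for GC content by a GC-decile median-ratio
normalization, converted to log2 ratios against the autosomal median, and
thresholded into gain / neutral / loss states.  Genes can then be annotated
with the bins they intersect and with mutated-fragment counts from the
mutation-overlap module.

This is a deliberately minimal, transparent re-implementation of binned
copy-number analysis: no segmentation, no mappability or blacklist
correction, no ploidy model.  It exists to make copy-number state calls and
their gene-level mutation annotation testable end to end, not to replace a
dedicated copy-number caller.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from cffrag.fragio import Fragment

logger = logging.getLogger(__name__)

SEX_MITO_CONTIGS = {"chrX", "chrY", "chrM", "X", "Y", "MT"}


@dataclass
class Bin:
    """One fixed-width genomic bin (1-based inclusive; last bin truncated)."""

    chrom: str
    start: int
    end: int
    raw_count: int = 0
    gc_fraction: float = float("nan")
    corrected_count: float = float("nan")
    log2_ratio: float = float("nan")
    state: str = "neutral"  # gain | neutral | loss | excluded


def bin_fragments(
    fragments: Iterable[Fragment],
    contig_lengths: dict[str, int],
    bin_size: int = 1_000_000,
    reference=None,
) -> list[Bin]:
    """Count fragments into fixed-width bins by midpoint.

    Bins tile each contig without overlap; the last bin is truncated at the
    contig end.  A fragment belongs to the bin containing its midpoint
    (half-open binning: a midpoint exactly on a boundary goes to the
    right-hand bin).  Fragment counts are conserved over included contigs.
    If ``reference`` is given, per-bin GC fractions are computed.
    """
    if bin_size < 10_000:
        warnings.warn(
            f"bin_size {bin_size} < 10 kb: per-bin counts will be sparse", stacklevel=2
        )
    bins: list[Bin] = []
    index: dict[str, int] = {}  # chrom -> offset of its first bin
    for chrom, clen in contig_lengths.items():
        index[chrom] = len(bins)
        for bstart in range(1, clen + 1, bin_size):
            bins.append(Bin(chrom=chrom, start=bstart, end=min(bstart + bin_size - 1, clen)))
    for frag in fragments:
        if frag.ref_name not in index:
            continue
        mid0 = frag.midpoint - 1  # 0-based for half-open arithmetic
        bins[index[frag.ref_name] + mid0 // bin_size].raw_count += 1
    if reference is not None:
        for b in bins:
            seq = str(reference[b.chrom][b.start - 1 : b.end]).upper()
            acgt = sum(seq.count(x) for x in "ACGT")
            gc = sum(seq.count(x) for x in "GC")
            b.gc_fraction = gc / acgt if acgt else float("nan")
    return bins


def gc_correct(bins: Sequence[Bin], n_strata: int = 10, min_stratum_bins: int = 3) -> list[Bin]:
    """GC-decile median-ratio correction of raw bin counts (in place).

    ``corrected = raw * global_median / stratum_median`` where strata are
    GC-fraction deciles over usable bins.  Bins falling in a stratum with
    fewer than ``min_stratum_bins`` members are marked ``excluded``.
    Requires at least 20 usable bins; all-zero counts are an error.
    """
    usable = [b for b in bins if not np.isnan(b.gc_fraction)]
    if len(usable) < 20:
        raise ValueError(f"need >= 20 bins with GC values for correction, got {len(usable)}")
    raw = np.array([b.raw_count for b in usable], dtype=float)
    if raw.sum() == 0:
        raise ValueError("all bin counts are zero; nothing to correct")
    gc = np.array([b.gc_fraction for b in usable])
    # rank-based deciles with tie merging: bins of equal GC always share a
    # stratum; stratum count shrinks when few bins are available
    n_strata = max(1, min(n_strata, len(usable) // min_stratum_bins))
    order = np.argsort(gc, kind="stable")
    ranks = np.empty(len(gc))
    ranks[order] = np.arange(len(gc))
    vals, inv = np.unique(gc, return_inverse=True)
    val_stratum = np.empty(len(vals), dtype=int)
    for i in range(len(vals)):
        mean_rank = ranks[inv == i].mean()
        val_stratum[i] = min(int(mean_rank / len(gc) * n_strata), n_strata - 1)
    stratum = val_stratum[inv]
    global_median = float(np.median(raw))
    for s in range(n_strata):
        mask = stratum == s
        members = [b for b, m in zip(usable, mask) if m]
        if not members:
            continue
        if len(members) < min_stratum_bins:
            for b in members:
                b.state = "excluded"
                b.corrected_count = float("nan")
            continue
        med = float(np.median([b.raw_count for b in members]))
        factor = global_median / med if med > 0 else float("nan")
        for b in members:
            b.corrected_count = b.raw_count * factor
            if np.isnan(factor):
                b.state = "excluded"
    return list(bins)


def call_states(
    bins: Sequence[Bin],
    gain_threshold: float = 0.2,
    loss_threshold: float = -0.2,
) -> list[Bin]:
    """Log2 ratios against the autosomal median and gain/neutral/loss states.

    ``log2_ratio = log2(corrected / median of autosomal corrected counts)``;
    sex chromosomes and the mitochondrion are excluded from the median but
    still receive ratios and states.  Excluded bins keep their state.
    """
    auto = [
        b.corrected_count
        for b in bins
        if b.state != "excluded"
        and not np.isnan(b.corrected_count)
        and b.chrom not in SEX_MITO_CONTIGS
    ]
    if not auto:
        raise ValueError("no usable autosomal bins")
    median = float(np.median(auto))
    if median == 0:
        raise ValueError("autosomal median corrected count is zero")
    for b in bins:
        if b.state == "excluded" or np.isnan(b.corrected_count):
            continue
        if b.corrected_count <= 0:
            b.log2_ratio = float("-inf")
        else:
            b.log2_ratio = float(np.log2(b.corrected_count / median))
        if b.log2_ratio >= gain_threshold:
            b.state = "gain"
        elif b.log2_ratio <= loss_threshold:
            b.state = "loss"
        else:
            b.state = "neutral"
    return list(bins)


def bins_to_frame(bins: Sequence[Bin]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": b.chrom, "start": b.start, "end": b.end,
                "raw": b.raw_count, "gc": b.gc_fraction,
                "corrected": b.corrected_count, "log2_ratio": b.log2_ratio,
                "state": b.state,
            }
            for b in bins
        ]
    )


def read_gene_bed(path: str | Path) -> list[tuple[str, str, int, int]]:
    """Read gene intervals from BED (0-based half-open, converted on read).

    Returns (name, chrom, start, end) with 1-based inclusive coordinates.
    Unnamed intervals get "gene<N>" names.
    """
    genes = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, s, e = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else f"gene{i + 1}"
            genes.append((name, chrom, s + 1, e))
    return genes


def annotate_genes(
    bins: Sequence[Bin],
    genes: Sequence[tuple[str, str, int, int]],
    fragments: Iterable[Fragment],
    locus_support: dict | None = None,
) -> pd.DataFrame:
    """Per-gene bin overlap, mutated-fragment count and total fragment count.

    For each gene (name, chrom, start, end; 1-based inclusive): the bins its
    span intersects, the sum of alternative-allele-supporting fragments at
    variant loci inside the gene (from the mutation-overlap module's
    per-locus support), and the total number of curated fragments whose
    interval overlaps the gene span.  Genes on contigs absent from the bin
    set are skipped with a warning.
    """
    known = {b.chrom for b in bins}
    rows = []
    frags = list(fragments)
    for name, chrom, gstart, gend in genes:
        if chrom not in known:
            logger.warning("gene %s on unknown contig %s: skipped", name, chrom)
            continue
        overlapping_bins = [
            i for i, b in enumerate(bins)
            if b.chrom == chrom and b.start <= gend and gstart <= b.end
        ]
        mutated = 0
        if locus_support:
            for sup in locus_support.values():
                lc = sup.locus
                if lc.chrom == chrom and gstart <= lc.pos <= gend:
                    mutated += sup.alt_count
        total = sum(
            1 for f in frags if f.ref_name == chrom and f.start <= gend and gstart <= f.end
        )
        rows.append(
            {
                "gene": name, "chrom": chrom, "start": gstart, "end": gend,
                "n_bins": len(overlapping_bins),
                "bin_indices": ",".join(map(str, overlapping_bins)),
                "mutated_fragments": mutated,
                "total_fragments": total,
            }
        )
    return pd.DataFrame(rows)
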