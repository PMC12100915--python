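"""Descriptive alignment-file summary metrics.

Library preparation kits leave measurable marks on sequencing data before
any fragmentomic feature is computed: the fraction of unmapped reads, the
fraction of reads from the mitochondrial genome, the per-base mismatch
rate, and the GC content of reads all differ between kits.  This module
computes those descriptive metrics over the primary records of an
alignment file.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

DEFAULT_MITO_NAMES = frozenset({"chrM", "MT"})


@dataclass
class BamSummary:
    """Summary metrics over the primary records of one alignment file.

    Fractions are per sequenced read (secondary/supplementary records
    excluded).  ``mismatch_fraction`` is the sum of per-read edit distances
    over the sum of aligned (reference-consuming) bases; None when no
    record carries an edit-distance tag.  ``mean_coverage`` is total
    aligned bases over total reference length.
    """

    total_records: int
    total_primary: int
    mapped_primary: int
    unmapped_fraction: float
    mito_fraction: float
    mismatch_fraction: float | None
    mean_read_gc: float
    sd_read_gc: float
    mean_coverage: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def summarise(
    alignment_file: str | Path,
    mito_names: frozenset[str] | set[str] = DEFAULT_MITO_NAMES,
    include_mito_in_coverage: bool = True,
) -> BamSummary:
    """One pass over an alignment file computing the descriptive metrics.

    unmapped fraction = unmapped primary / total primary;
    mitochondrial fraction = mapped primary on mitochondrial contigs /
    mapped primary; per-read GC = (G+C) / (A+C+G+T) with ambiguous bases
    excluded from the denominator.  All metrics are invariant to record
    order.
    """
    path = str(alignment_file)
    mode = "r" if path.endswith(".sam") else "rb"
    total = primary = mapped = unmapped = mito = 0
    nm_sum = 0
    aligned_bases = 0
    has_nm = False
    gc_vals: list[float] = []
    with pysam.AlignmentFile(path, mode) as af:
        contig_lengths = dict(zip(af.references, af.lengths))
        for rec in af.fetch(until_eof=True):
            total += 1
            if rec.is_secondary or rec.is_supplementary:
                continue
            primary += 1
            seq = rec.query_sequence or ""
            gc = sum(seq.count(b) for b in "GCgc")
            acgt = gc + sum(seq.count(b) for b in "ATat")
            if acgt:
                gc_vals.append(gc / acgt)
            if rec.is_unmapped:
                unmapped += 1
                continue
            mapped += 1
            if rec.reference_name in mito_names:
                mito += 1
            span = rec.reference_end - rec.reference_start
            aligned_bases += span
            if rec.has_tag("NM"):
                has_nm = True
                nm_sum += int(rec.get_tag("NM"))
    genome_size = sum(
        ln for name, ln in contig_lengths.items()
        if include_mito_in_coverage or name not in mito_names
    )
    gc_arr = np.array(gc_vals) if gc_vals else np.array([np.nan])
    return BamSummary(
        total_records=total,
        total_primary=primary,
        mapped_primary=mapped,
        unmapped_fraction=unmapped / primary if primary else float("nan"),
        mito_fraction=mito / mapped if mapped else float("nan"),
        mismatch_fraction=(nm_sum / aligned_bases) if (has_nm and aligned_bases) else None,
        mean_read_gc=float(np.mean(gc_arr)),
        sd_read_gc=float(np.std(gc_arr, ddof=1)) if len(gc_arr) > 1 else float("nan"),
        mean_coverage=aligned_bases / genome_size if genome_size else float("nan"),
    )
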