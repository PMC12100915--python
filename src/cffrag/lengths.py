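"""Fragment-length distributions and summaries.

cfDNA fragment lengths are multimodal: a mono-nucleosome mode near 167 bp,
a di-nucleosome region around 300-380 bp, and a sub-150 bp short-fragment
component enriched in tumour-derived DNA.  Only fragments in a retention
window (default 50-450 bp) are kept; fractions over standard sub-ranges and
element-wise median profiles across samples are the downstream summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from cffrag.fragio import Fragment

DEFAULT_RANGES: tuple[tuple[int, int], ...] = ((50, 99), (100, 150), (151, 220), (300, 380))


@dataclass
class LengthDistribution:
    """Dense per-integer-length counts over [min_len, max_len] for one sample."""

    sample_id: str
    min_len: int
    max_len: int
    counts: np.ndarray  # length max_len - min_len + 1
    total: int
    excluded: int  # fragments outside the retention window

    @property
    def fractions(self) -> np.ndarray | None:
        """Normalized fractions, or None when the distribution is empty."""
        if self.total == 0:
            return None
        return self.counts / self.total

    @property
    def lengths(self) -> np.ndarray:
        return np.arange(self.min_len, self.max_len + 1)

    def argmax_length(self) -> int | None:
        if self.total == 0:
            return None
        return int(self.min_len + int(np.argmax(self.counts)))

    def to_frame(self) -> pd.DataFrame:
        frac = self.fractions
        return pd.DataFrame(
            {
                "length": self.lengths,
                "count": self.counts,
                "fraction": frac if frac is not None else np.zeros_like(self.counts, dtype=float),
            }
        )


def call_length(
    fragments: Iterable[Fragment],
    min_len: int = 50,
    max_len: int = 450,
    sample_id: str = "sample",
) -> LengthDistribution:
    """Tally curated fragment lengths into a dense distribution.

    Fragments outside [min_len, max_len] are excluded and counted, so
    ``total + excluded`` equals the number of input fragments.  The dense
    vector covers every integer length in the window, including zeros.
    """
    if min_len > max_len:
        raise ValueError(f"min_len ({min_len}) > max_len ({max_len})")
    counts = np.zeros(max_len - min_len + 1, dtype=np.int64)
    excluded = 0
    total = 0
    for frag in fragments:
        ln = frag.length
        if min_len <= ln <= max_len:
            counts[ln - min_len] += 1
            total += 1
        else:
            excluded += 1
    return LengthDistribution(
        sample_id=sample_id, min_len=min_len, max_len=max_len,
        counts=counts, total=total, excluded=excluded,
    )


def range_fractions(
    dist: LengthDistribution,
    ranges: Sequence[tuple[int, int]] = DEFAULT_RANGES,
) -> dict[tuple[int, int], float]:
    """Sum of length fractions over each inclusive range.

    The default ranges are the four regions of interest — 50-99 bp,
    100-150 bp, 151-220 bp (mono-nucleosome) and 300-380 bp
    (di-nucleosome).  Ranges need not partition the window; overlapping
    ranges are allowed with a warning.
    """
    for i, (a1, b1) in enumerate(ranges):
        if not (dist.min_len <= a1 <= b1 <= dist.max_len):
            raise ValueError(f"range ({a1}, {b1}) not within [{dist.min_len}, {dist.max_len}]")
        for a2, b2 in list(ranges)[i + 1 :]:
            if a1 <= b2 and a2 <= b1:
                warnings.warn(f"ranges ({a1},{b1}) and ({a2},{b2}) overlap", stacklevel=2)
    frac = dist.fractions
    out: dict[tuple[int, int], float] = {}
    for a, b in ranges:
        if frac is None:
            out[(a, b)] = float("nan")
        else:
            out[(a, b)] = float(frac[a - dist.min_len : b - dist.min_len + 1].sum())
    return out


def median_profile(dists: Sequence[LengthDistribution]) -> np.ndarray:
    """Element-wise median of normalized fractions across samples.

    All inputs must share the same window.  With an even sample count the
    median is the mean of the central pair.  The result need not sum to 1.
    """
    if not dists:
        raise ValueError("need at least one distribution")
    ref = (dists[0].min_len, dists[0].max_len)
    for d in dists[1:]:
        if (d.min_len, d.max_len) != ref:
            raise ValueError(f"mismatched length windows: {ref} vs {(d.min_len, d.max_len)}")
    mat = []
    for d in dists:
        frac = d.fractions
        if frac is None:
            raise ValueError(f"sample {d.sample_id!r} has no retained fragments")
        mat.append(frac)
    return np.median(np.vstack(mat), axis=0)
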