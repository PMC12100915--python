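"""Fragment end-motif profiling.

The genomic sequence context at cfDNA fragment boundaries carries
information about the nucleases that generated the fragments.  Eight motif
types are supported, named by side and width: ``u`` (upstream of the start),
``s`` (at the start), ``e`` (at the end), ``d`` (downstream of the end),
each of any width k; ``umono``/``smono``/``emono``/``dmono`` are the k = 1
aliases.  The widely used "s3" motif is the three reference bases at the
fragment start.

Motifs are read from the reference genome at fragment coordinates, not from
read bases, which makes them immune to sequencing error.  All motifs are
reported on the genomic forward strand; an optional flag reverse-complements
e/d motifs for comparison with 5'-centric end-motif conventions in other
work.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from cffrag.fragio import Fragment

_ALIAS = {"umono": ("u", 1), "smono": ("s", 1), "emono": ("e", 1), "dmono": ("d", 1)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class MotifSpec:
    """A motif type: side in {u, s, e, d} and width k (1 <= k <= 10)."""

    side: str
    k: int

    def __post_init__(self) -> None:
        if self.side not in ("u", "s", "e", "d"):
            raise ValueError(f"side must be one of u/s/e/d, got {self.side!r}")
        if not (1 <= self.k <= 10):
            raise ValueError(f"motif width must be in [1, 10], got {self.k}")

    @classmethod
    def parse(cls, name: str) -> "MotifSpec":
        """Parse "s3", "umono", "e2", ... into a MotifSpec."""
        if name in _ALIAS:
            return cls(*_ALIAS[name])
        m = re.fullmatch(r"([used])(\d+)", name)
        if not m:
            raise ValueError(f"cannot parse motif spec {name!r}")
        return cls(m.group(1), int(m.group(2)))

    @property
    def name(self) -> str:
        return f"{self.side}{self.k}"

    def all_motifs(self) -> list[str]:
        """All 4^k motifs in fixed lexicographic order."""
        return ["".join(p) for p in itertools.product("ACGT", repeat=self.k)]


@dataclass
class MotifTable:
    """Frequency table over all 4^k motifs of one spec for one sample."""

    spec: MotifSpec
    counts: np.ndarray  # length 4^k, lexicographic motif order
    excluded_n: int  # motifs containing N, excluded from counts
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        if len(self.counts) != 4**self.spec.k:
            raise ValueError(f"expected {4**self.spec.k} rows, got {len(self.counts)}")

    @property
    def motifs(self) -> list[str]:
        return self.spec.all_motifs()

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def fractions(self) -> np.ndarray | None:
        if self.total == 0:
            return None
        return self.counts / self.total

    def to_frame(self):
        import pandas as pd

        frac = self.fractions
        return pd.DataFrame(
            {
                "motif": self.motifs,
                "count": self.counts,
                "fraction": frac if frac is not None else np.zeros(len(self.counts)),
            }
        )


def _fetch(reference, chrom: str, start: int, end: int, contig_len: int) -> str:
    """Reference bases over a 1-based inclusive window, N-padded out of bounds."""
    left_pad = max(0, 1 - start)
    right_pad = max(0, end - contig_len)
    s = max(start, 1)
    e = min(end, contig_len)
    core = "" if s > e else str(reference[chrom][s - 1 : e]).upper()
    return "N" * left_pad + core + "N" * right_pad


def extract_motif(
    fragment: Fragment,
    reference,
    spec: MotifSpec,
    reverse_complement_end: bool = False,
) -> str:
    """Reference sequence of one motif at a fragment boundary.

    Windows (1-based inclusive, forward strand): s = [start, start+k-1],
    e = [end-k+1, end], u = [start-k, start-1], d = [end+1, end+k].
    Windows extending past the contig are N-padded.  With
    ``reverse_complement_end`` the e/d motifs are reverse-complemented to a
    5'-centric orientation.
    """
    chrom = fragment.ref_name
    if chrom not in reference:
        raise KeyError(f"unknown contig {chrom!r} in reference")
    contig_len = len(reference[chrom])
    k = spec.k
    if spec.side == "s":
        window = (fragment.start, fragment.start + k - 1)
    elif spec.side == "e":
        window = (fragment.end - k + 1, fragment.end)
    elif spec.side == "u":
        window = (fragment.start - k, fragment.start - 1)
    else:  # d
        window = (fragment.end + 1, fragment.end + k)
    seq = _fetch(reference, chrom, window[0], window[1], contig_len)
    if reverse_complement_end and spec.side in ("e", "d"):
        seq = seq.translate(_COMPLEMENT)[::-1]
    return seq


def call_motif(
    fragments: Iterable[Fragment],
    reference,
    spec: MotifSpec | str,
    sample_id: str = "sample",
    reverse_complement_end: bool = False,
) -> MotifTable:
    """Tally one motif type over fragments into a complete 4^k table.

    Motifs containing N (ambiguous reference or out-of-bounds padding) are
    excluded from the counts and tallied separately, so the 4^k support is
    exact.  Rows appear in fixed lexicographic order regardless of observed
    diversity.
    """
    if isinstance(spec, str):
        spec = MotifSpec.parse(spec)
    index = {m: i for i, m in enumerate(spec.all_motifs())}
    counts = np.zeros(4**spec.k, dtype=np.int64)
    excluded = 0
    for frag in fragments:
        motif = extract_motif(frag, reference, spec, reverse_complement_end)
        i = index.get(motif)
        if i is None:
            excluded += 1
        else:
            counts[i] += 1
    return MotifTable(spec=spec, counts=counts, excluded_n=excluded, sample_id=sample_id)


def first_base_fractions(table: MotifTable) -> dict[str, float]:
    """Sum of motif fractions grouped by leading base; sums to 1.

    Intended for s-side tables ("sum of fractions of motifs starting with
    A, C, G and T").
    """
    frac = table.fractions
    out = {b: 0.0 for b in "ACGT"}
    if frac is None:
        return {b: float("nan") for b in "ACGT"}
    for motif, f in zip(table.motifs, frac):
        out[motif[0]] += float(f)
    return out


def motif_correlation(a: MotifTable | np.ndarray, b: MotifTable | np.ndarray) -> float:
    """Pearson correlation of two motif fraction vectors in fixed motif order.

    Either argument may be a raw fraction vector (e.g. an element-wise
    median profile across samples).  Zero-variance input yields NaN rather
    than an error.
    """
    va = a.fractions if isinstance(a, MotifTable) else np.asarray(a, dtype=float)
    vb = b.fractions if isinstance(b, MotifTable) else np.asarray(b, dtype=float)
    if va is None or vb is None:
        return float("nan")
    if isinstance(a, MotifTable) and isinstance(b, MotifTable) and a.spec != b.spec:
        raise ValueError(f"motif specs differ: {a.spec.name} vs {b.spec.name}")
    if len(va) != len(vb):
        raise ValueError("fraction vectors differ in length")
    if np.std(va) == 0 or np.std(vb) == 0:
        return float("nan")
    return float(np.corrcoef(va, vb)[0, 1])


def median_motif_profile(tables: Sequence[MotifTable]) -> np.ndarray:
    """Element-wise median fraction vector across samples (same spec)."""
    if not tables:
        raise ValueError("need at least one table")
    spec = tables[0].spec
    rows = []
    for t in tables:
        if t.spec != spec:
            raise ValueError("mixed motif specs")
        if t.fractions is None:
            raise ValueError(f"sample {t.sample_id!r} has an empty motif table")
        rows.append(t.fractions)
    return np.median(np.vstack(rows), axis=0)
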