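"""Synthetic reference + paired-end alignment generator with exhaustive truth.

Emulates the data a cfDNA fragmentomics pipeline consumes: a small
multi-chromosome reference (with one mitochondrion-like contig), fragments
drawn from a nucleosome-like length mixture (mono-nucleosome peak near
167 bp, a di-nucleosome component around 300-380 bp, and a sub-150 bp
component), sequence-through read pairs with optional 3' overhang artifacts
(untrimmed adapter aligned past the true fragment end), planted end-motif
biases, QC-violating records of every class, and spiked variants with
controllable concordant/discordant read-pair support.

Every fragment and every planted artifact or variant-support category is
recorded in a truth table, so downstream modules can be verified exactly.
Artifact labels are assigned at exact counts (``round(rate * n)``), not by
per-fragment coin flips, so rejection accounting can be checked without
sampling error.  Identical configuration (including seed) reproduces
byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from pyfaidx import Fasta, Faidx

logger = logging.getLogger(__name__)

BASES = np.array(["A", "C", "G", "T"])

ARTIFACT_CLASSES = (
    "duplicate",
    "low_mapq",
    "secondary",
    "unmapped",
    "discordant_chrom",
    "outward",
)

# planted per-fragment support categories at a spiked locus
SUPPORT_CATEGORIES = ("CO", "SO", "DO", "REF", "UNCOVERED")


class ConfigurationError(ValueError):
    pass


@dataclass
class VariantSpike:
    """One planted somatic variant.

    ``ref_base`` may be None, in which case the reference base at the locus
    is used (resolved when fragments are simulated).  ``vaf`` is the fraction
    of covering fragments carrying the alternative allele; of the alt
    fragments whose two reads both cover the locus, ``discordant_rate``
    have the reads disagree (one alt, one reference).
    """

    chrom: str
    pos: int  # 1-based
    alt_base: str
    vaf: float
    discordant_rate: float = 0.0
    ref_base: str | None = None


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    The default length mixture is the nucleosome-like three-component
    Gaussian mixture used throughout testing: 70% mono-nucleosome
    N(167, 10), 20% di-nucleosome N(334, 20), 10% short N(90, 15);
    read length 150 bp (paired-end 150 sequencing).  All artifact rates
    default to zero.
    """

    seed: int = 0
    chromosomes: list[tuple[str, int, float]] = field(
        default_factory=lambda: [
            ("chr1", 1_000_000, 0.41),
            ("chr2", 800_000, 0.45),
            ("chrM", 16_000, 0.44),
        ]
    )
    n_fragments: int = 50_000
    length_mixture: list[tuple[float, float, float]] = field(
        default_factory=lambda: [(0.7, 167.0, 10.0), (0.2, 334.0, 20.0), (0.1, 90.0, 15.0)]
    )
    read_length: int = 150
    overhang_rate: float = 0.0
    overhang_length: int = 10
    substitution_error_rate: float = 0.0
    duplicate_rate: float = 0.0
    low_mapq_rate: float = 0.0
    secondary_rate: float = 0.0
    unmapped_rate: float = 0.0
    discordant_chrom_rate: float = 0.0
    outward_rate: float = 0.0
    mito_fraction: float = 0.0
    variant_spikes: list[VariantSpike] = field(default_factory=list)
    motif_bias: dict[str, float] | None = None
    cnv_regions: list[tuple[str, int, int, float]] = field(default_factory=list)
    min_fragment_length: int = 30

    def __post_init__(self) -> None:
        w = sum(c[0] for c in self.length_mixture)
        if abs(w - 1.0) > 1e-9:
            raise ConfigurationError(f"length_mixture weights must sum to 1, got {w}")
        rates = {
            "overhang_rate": self.overhang_rate,
            "substitution_error_rate": self.substitution_error_rate,
            "duplicate_rate": self.duplicate_rate,
            "low_mapq_rate": self.low_mapq_rate,
            "secondary_rate": self.secondary_rate,
            "unmapped_rate": self.unmapped_rate,
            "discordant_chrom_rate": self.discordant_chrom_rate,
            "outward_rate": self.outward_rate,
            "mito_fraction": self.mito_fraction,
        }
        for name, r in rates.items():
            if not (0.0 <= r <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1], got {r}")
        for name, length, gc in self.chromosomes:
            if length < 1000:
                raise ConfigurationError(f"contig {name}: length must be >= 1 kb, got {length}")
            if not (0.0 <= gc <= 1.0):
                raise ConfigurationError(f"contig {name}: GC target must be in [0, 1], got {gc}")
        for sp in self.variant_spikes:
            bound = dict((n, l) for n, l, _ in self.chromosomes)
            if sp.chrom not in bound:
                raise ConfigurationError(f"variant spike on unknown contig {sp.chrom!r}")
            if not (1 <= sp.pos <= bound[sp.chrom]):
                raise ConfigurationError(f"variant spike position {sp.pos} outside {sp.chrom}")

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {name: length for name, length, _ in self.chromosomes}


@dataclass
class TruthTable:
    """Ground truth for one simulated dataset.

    ``fragments``: one row per fragment — fragment_id, chrom, true_start,
    true_end (both 1-based inclusive), true_length, mixture component index,
    artifact label ("none" or one of the artifact classes), overhang flag
    and the overhang length actually applied (possibly truncated at the
    contig end).

    ``support``: one row per (fragment x spiked locus) where the fragment
    overlaps the locus — fragment_id, locus id "chrom:pos:ref>alt", and the
    planted category: CO / SO / DO / REF, or UNCOVERED when the locus falls
    in the unread gap of a fragment longer than twice the read length.
    """

    fragments: pd.DataFrame
    support: pd.DataFrame

    def write(self, directory: str | Path, prefix: str = "truth") -> tuple[Path, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        fpath = directory / f"{prefix}_fragments.tsv"
        spath = directory / f"{prefix}_support.tsv"
        self.fragments.to_csv(fpath, sep="\t", index=False)
        self.support.to_csv(spath, sep="\t", index=False)
        return fpath, spath

    @classmethod
    def read(cls, directory: str | Path, prefix: str = "truth") -> "TruthTable":
        directory = Path(directory)
        return cls(
            fragments=pd.read_csv(directory / f"{prefix}_fragments.tsv", sep="\t"),
            support=pd.read_csv(directory / f"{prefix}_support.tsv", sep="\t"),
        )


def _contig_rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream])


def make_reference(config: SimulationConfig, fasta_path: str | Path) -> Fasta:
    """Write the synthetic reference FASTA (+ .fai sidecar) and open it.

    Each contig carries exactly ``round(gc * length)`` G/C bases placed by a
    seeded permutation, so the realized GC fraction matches the target to
    within one base.  Deterministic given the config seed.
    """
    fasta_path = Path(fasta_path)
    rng = _contig_rng(config.seed, 0)
    with open(fasta_path, "w") as fh:
        for name, length, gc in config.chromosomes:
            n_gc = int(round(gc * length))
            arr = np.empty(length, dtype=np.uint8)
            arr[:n_gc] = rng.choice(np.frombuffer(b"GC", dtype=np.uint8), size=n_gc)
            arr[n_gc:] = rng.choice(np.frombuffer(b"AT", dtype=np.uint8), size=length - n_gc)
            rng.shuffle(arr)
            seq = arr.tobytes().decode("ascii")
            fh.write(f">{name}\n")
            for i in range(0, length, 60):
                fh.write(seq[i : i + 60] + "\n")
    Faidx(str(fasta_path), rebuild=True)
    return Fasta(str(fasta_path))


def _sample_lengths(config: SimulationConfig, rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    weights = np.array([c[0] for c in config.length_mixture])
    means = np.array([c[1] for c in config.length_mixture])
    sds = np.array([c[2] for c in config.length_mixture])
    comp = rng.choice(len(weights), size=n, p=weights)
    lengths = np.rint(rng.normal(means[comp], sds[comp])).astype(int)
    return np.maximum(lengths, config.min_fragment_length), comp


def _sample_starts(
    rng: np.random.Generator,
    chrom: str,
    contig_len: int,
    contig_seq: np.ndarray | None,
    lengths: np.ndarray,
    config: SimulationConfig,
    max_rounds: int = 200,
) -> np.ndarray:
    """Uniform starts within bounds, with rejection sampling for motif bias
    and copy-number region multipliers.  ``contig_seq`` (S1 byte array) is
    only needed when a motif bias is configured."""
    n = len(lengths)
    if np.any(lengths > contig_len):
        raise ConfigurationError(
            f"contig {chrom} ({contig_len} bp) too short for drawn fragment lengths"
        )
    bias = config.motif_bias or {}
    max_bias = max(bias.values()) if bias else 1.0
    regions = [(s, e, m) for c, s, e, m in config.cnv_regions if c == chrom]
    max_mult = max([m for _, _, m in regions], default=1.0)

    starts = np.zeros(n, dtype=int)
    todo = np.arange(n)
    for _ in range(max_rounds):
        if len(todo) == 0:
            return starts
        cand = rng.integers(1, contig_len - lengths[todo] + 2)  # 1-based inclusive
        accept_p = np.ones(len(todo))
        if bias:
            lut = np.ones(256)
            for base, weight in bias.items():
                lut[ord(base)] = weight
            b = contig_seq.view(np.uint8)[cand - 1]
            accept_p *= lut[b] / max_bias
        if regions:
            w = np.ones(len(todo))
            for s, e, m in regions:
                w = np.where((cand >= s) & (cand <= e), np.maximum(w, m), w)
            accept_p *= w / max_mult
        keep = rng.random(len(todo)) < accept_p
        starts[todo[keep]] = cand[keep]
        todo = todo[~keep]
    raise ConfigurationError("rejection sampling of fragment starts did not converge")


def simulate_fragments(config: SimulationConfig, reference: Fasta) -> TruthTable:
    """Draw fragments from the length mixture and record complete truth.

    Fragment placement: the mitochondrion-like contig ("chrM") receives
    exactly ``round(mito_fraction * n_fragments)`` fragments; the remainder
    are distributed over the other contigs proportionally to length, with
    start positions uniform (modulated by motif bias / copy-number regions
    through rejection sampling).  Artifact labels are then planted at exact
    counts on non-mitochondrial fragments; outward-pair labels are restricted
    to fragments of at least twice the read length so the planted label is
    exactly recoverable by curation geometry.
    """
    rng = _contig_rng(config.seed, 1)
    n = config.n_fragments
    names = [c[0] for c in config.chromosomes]
    lengths_by_name = config.contig_lengths

    # contig assignment
    n_mito = int(round(config.mito_fraction * n)) if "chrM" in names else 0
    non_mito = [nm for nm in names if nm != "chrM"]
    if not non_mito:
        raise ConfigurationError("need at least one non-mitochondrial contig")
    w = np.array([lengths_by_name[nm] for nm in non_mito], dtype=float)
    w /= w.sum()
    chrom_idx = rng.choice(len(non_mito), size=n - n_mito, p=w)
    chroms = np.array([non_mito[i] for i in chrom_idx] + ["chrM"] * n_mito)

    frag_lengths, comp = _sample_lengths(config, rng, n)
    # chrM is short: re-draw any over-long mito fragments from the first component
    if n_mito:
        mito_len = lengths_by_name["chrM"]
        bad = (chroms == "chrM") & (frag_lengths > mito_len)
        while np.any(bad):
            redraw, comp_r = _sample_lengths(config, rng, int(bad.sum()))
            frag_lengths[bad], comp[bad] = redraw, comp_r
            bad = (chroms == "chrM") & (frag_lengths > mito_len)

    starts = np.zeros(n, dtype=int)
    for name in names:
        mask = chroms == name
        if not np.any(mask):
            continue
        seq = _contig_bytes(reference, name) if config.motif_bias else None
        starts[mask] = _sample_starts(
            rng, name, lengths_by_name[name], seq, frag_lengths[mask], config
        )
    ends = starts + frag_lengths - 1

    # exact-count artifact labels on non-mito fragments
    artifacts = np.array(["none"] * n, dtype=object)
    rates = {
        "duplicate": config.duplicate_rate,
        "low_mapq": config.low_mapq_rate,
        "secondary": config.secondary_rate,
        "unmapped": config.unmapped_rate,
        "discordant_chrom": config.discordant_chrom_rate,
        "outward": config.outward_rate,
    }
    if config.discordant_chrom_rate > 0 and len(non_mito) < 2:
        raise ConfigurationError("discordant_chrom artifacts require >= 2 non-mito contigs")
    order = rng.permutation(n)
    assignable = [i for i in order if chroms[i] != "chrM"]
    cursor = 0
    for cls in ARTIFACT_CLASSES:
        k = int(round(rates[cls] * n))
        if k == 0:
            continue
        if cls == "outward":
            eligible = [
                i
                for i in assignable[cursor:]
                if frag_lengths[i] >= 2 * config.read_length
            ][:k]
            if len(eligible) < k:
                raise ConfigurationError(
                    "not enough fragments of length >= 2 x read_length for outward artifacts"
                )
            for i in eligible:
                artifacts[i] = cls
            taken = set(eligible)
            assignable = assignable[:cursor] + [i for i in assignable[cursor:] if i not in taken]
        else:
            chosen = assignable[cursor : cursor + k]
            if len(chosen) < k:
                raise ConfigurationError("more artifact labels requested than fragments")
            for i in chosen:
                artifacts[i] = cls
            cursor += k

    # overhang labels on sequence-through fragments
    seq_through = frag_lengths < config.read_length
    has_overhang = np.zeros(n, dtype=bool)
    if config.overhang_rate > 0:
        has_overhang = seq_through & (rng.random(n) < config.overhang_rate)
    oh_applied = np.zeros(n, dtype=int)
    if config.overhang_length > 0:
        limit = np.array([lengths_by_name[c] for c in chroms])
        oh_applied = np.where(
            has_overhang, np.minimum(config.overhang_length, limit - ends), 0
        )

    fragments = pd.DataFrame(
        {
            "fragment_id": [f"frag{i:07d}" for i in range(n)],
            "chrom": chroms,
            "true_start": starts,
            "true_end": ends,
            "true_length": frag_lengths,
            "component": comp,
            "artifact": artifacts,
            "overhang": has_overhang,
            "overhang_len": oh_applied,
        }
    )

    support = _plant_variant_support(config, rng, fragments, reference)
    return TruthTable(fragments=fragments, support=support)


def _contig_bytes(reference, name: str) -> np.ndarray:
    """Contig sequence as an S1 byte array (uppercase)."""
    return np.frombuffer(str(reference[name][:]).upper().encode("ascii"), dtype="S1")


def _ref_base(reference, chrom: str, pos: int) -> str:
    return str(reference[chrom][pos - 1 : pos]).upper()


def _plant_variant_support(
    config: SimulationConfig,
    rng: np.random.Generator,
    fragments: pd.DataFrame,
    reference,
) -> pd.DataFrame:
    rows: list[tuple[str, str, str]] = []
    L = config.read_length
    for sp in config.variant_spikes:
        ref_base = sp.ref_base or _ref_base(reference, sp.chrom, sp.pos)
        if sp.ref_base is not None and _ref_base(reference, sp.chrom, sp.pos) != sp.ref_base:
            raise ConfigurationError(
                f"spike at {sp.chrom}:{sp.pos}: stated ref {sp.ref_base} does not match reference"
            )
        if ref_base == sp.alt_base:
            raise ConfigurationError(f"spike at {sp.chrom}:{sp.pos}: ref == alt")
        locus_id = f"{sp.chrom}:{sp.pos}:{ref_base}>{sp.alt_base}"
        sub = fragments[
            (fragments["chrom"] == sp.chrom)
            & (fragments["true_start"] <= sp.pos)
            & (fragments["true_end"] >= sp.pos)
            & (fragments["artifact"] == "none")
        ]
        for fid, s, e in zip(sub["fragment_id"], sub["true_start"], sub["true_end"]):
            fwd_covers = sp.pos <= min(s + L - 1, e)
            rev_covers = sp.pos >= max(s, e - L + 1)
            if not (fwd_covers or rev_covers):
                cat = "UNCOVERED"
            elif rng.random() >= sp.vaf:
                cat = "REF"
            elif fwd_covers and rev_covers:
                cat = "DO" if rng.random() < sp.discordant_rate else "CO"
            else:
                cat = "SO"
            rows.append((fid, locus_id, cat))
    return pd.DataFrame(rows, columns=["fragment_id", "locus_id", "category"])


def _apply_errors(seq: np.ndarray, rate: float, rng: np.random.Generator) -> None:
    if rate <= 0:
        return
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        alternatives = [b for b in (b"A", b"C", b"G", b"T") if b != seq[i]]
        seq[i] = alternatives[rng.integers(3)]


def emit_alignments(
    truth: TruthTable,
    config: SimulationConfig,
    reference: Fasta,
    out_path: str | Path,
) -> Path:
    """Write a coordinate-sorted SAM/BAM realizing the truth table.

    For each fragment one inward read pair is emitted: the forward read
    covers [start, min(start + read_length - 1, end)] and the reverse read
    covers [max(start, end - read_length + 1), end].  Overhang-labeled
    sequence-through fragments have the forward read extended past the
    fragment end by the applied overhang (reference bases, emulating
    untrimmed adapter that happens to align).  Artifact classes alter flags,
    mapping quality, or mate placement as labeled in truth.  Base qualities
    are constant high (Q37).  BAM output is indexed.
    """
    out_path = Path(out_path)
    rng = _contig_rng(config.seed, 2)
    names = [c[0] for c in config.chromosomes]
    lengths_by_name = config.contig_lengths
    seqs = {name: _contig_bytes(reference, name) for name in names}
    non_mito = [nm for nm in names if nm != "chrM"]

    # planted alt bases per fragment: {fragment_id: [(pos, base, which_reads)]}
    spike_edits: dict[str, list[tuple[int, str, str]]] = {}
    locus_info = {
        f"{sp.chrom}:{sp.pos}:{(sp.ref_base or _ref_base(reference, sp.chrom, sp.pos))}>{sp.alt_base}": sp
        for sp in config.variant_spikes
    }
    for fid, locus_id, cat in truth.support.itertuples(index=False):
        sp = locus_info[locus_id]
        if cat == "CO":
            which = "both"
        elif cat == "SO":
            which = "covering"
        elif cat == "DO":
            which = "fwd" if rng.random() < 0.5 else "rev"
        else:
            continue
        spike_edits.setdefault(fid, []).append((sp.pos, sp.alt_base, which))

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": lengths_by_name[name]} for name in names],
    }
    ref_index = {name: i for i, name in enumerate(names)}

    records: list[tuple[int, int, int, pysam.AlignedSegment]] = []
    serial = 0

    def add(rec: pysam.AlignedSegment) -> None:
        nonlocal serial
        tid = rec.reference_id if rec.reference_id >= 0 else len(names)
        pos = rec.reference_start if rec.reference_start >= 0 else 0
        records.append((tid, pos, serial, rec))
        serial += 1

    hdr = pysam.AlignmentHeader.from_dict(header)
    L = config.read_length

    for row in truth.fragments.itertuples(index=False):
        fid, chrom, s, e = row.fragment_id, row.chrom, row.true_start, row.true_end
        artifact = row.artifact
        oh = int(row.overhang_len) if row.overhang else 0
        # overhang reads carry the full adapter-length extension even when it
        # pushes the aligned span slightly past the nominal read length
        fwd_start, fwd_end = s, (e + oh) if oh else min(s + L - 1, e)
        rev_start, rev_end = max(s, e - L + 1), e

        fwd_seq = seqs[chrom][fwd_start - 1 : fwd_end].copy()
        rev_seq = seqs[chrom][rev_start - 1 : rev_end].copy()
        _apply_errors(fwd_seq, config.substitution_error_rate, rng)
        _apply_errors(rev_seq, config.substitution_error_rate, rng)
        for pos, alt, which in spike_edits.get(fid, ()):
            f_cov = fwd_start <= pos <= fwd_end
            r_cov = rev_start <= pos <= rev_end
            ref_here = seqs[chrom][pos - 1]
            alt_b = alt.encode("ascii")
            if which in ("both", "fwd", "covering") and f_cov:
                fwd_seq[pos - fwd_start] = alt_b
            if which == "rev" and f_cov:
                fwd_seq[pos - fwd_start] = ref_here
            if which in ("both", "rev", "covering") and r_cov:
                rev_seq[pos - rev_start] = alt_b
            if which == "fwd" and r_cov:
                rev_seq[pos - rev_start] = ref_here

        mapq = 5 if artifact == "low_mapq" else 60
        dup = artifact == "duplicate"

        r1 = pysam.AlignedSegment(hdr)
        r2 = pysam.AlignedSegment(hdr)
        r1.query_name = r2.query_name = fid
        r1.mapping_quality = r2.mapping_quality = mapq
        r1.query_sequence = fwd_seq.tobytes().decode("ascii")
        r2.query_sequence = rev_seq.tobytes().decode("ascii")
        r1.query_qualities = pysam.qualitystring_to_array("F" * len(fwd_seq))
        r2.query_qualities = pysam.qualitystring_to_array("F" * len(rev_seq))
        r1.reference_id = r2.reference_id = ref_index[chrom]
        r1.reference_start = fwd_start - 1
        r2.reference_start = rev_start - 1
        r1.cigarstring = f"{len(fwd_seq)}M"
        r2.cigarstring = f"{len(rev_seq)}M"

        r1.is_paired = r2.is_paired = True
        r1.is_read1, r2.is_read2 = True, True
        r1.is_duplicate = r2.is_duplicate = dup
        proper = artifact in ("none", "duplicate", "low_mapq", "secondary")
        r1.is_proper_pair = r2.is_proper_pair = proper

        if artifact == "outward":
            # swap strand assignments of the inward pair
            r1.is_reverse, r2.is_reverse = True, False
            r1.mate_is_reverse, r2.mate_is_reverse = False, True
            r1.is_proper_pair = r2.is_proper_pair = False
        else:
            r1.is_reverse, r2.is_reverse = False, True
            r1.mate_is_reverse, r2.mate_is_reverse = True, False

        if artifact == "secondary":
            r1.is_secondary = True
        if artifact == "unmapped":
            r2.is_unmapped = True
            r2.is_reverse = False
            r2.cigarstring = None
            r2.mapping_quality = 0
            r2.reference_start = fwd_start - 1  # placed with its mate
            r1.mate_is_unmapped = True
            r1.is_proper_pair = r2.is_proper_pair = False
        if artifact == "discordant_chrom":
            other = non_mito[(ref_index[chrom] + 1) % len(non_mito)]
            if other == chrom:
                other = next(nm for nm in non_mito if nm != chrom)
            other_len = lengths_by_name[other]
            new_start = min(rev_start, other_len - len(rev_seq) + 1)
            new_start = max(new_start, 1)
            r2.reference_id = ref_index[other]
            r2.reference_start = new_start - 1
            r2.query_sequence = (
                seqs[other][new_start - 1 : new_start - 1 + len(rev_seq)].tobytes().decode("ascii")
            )
            r2.query_qualities = pysam.qualitystring_to_array("F" * len(r2.query_sequence))
            r2.cigarstring = f"{len(r2.query_sequence)}M"
            r1.is_proper_pair = r2.is_proper_pair = False

        # mate fields and NM tags
        r1.next_reference_id = r2.reference_id
        r1.next_reference_start = r2.reference_start
        r2.next_reference_id = r1.reference_id
        r2.next_reference_start = r1.reference_start
        if r1.reference_id == r2.reference_id and not r2.is_unmapped:
            tlen = max(fwd_end, rev_end) - min(fwd_start, rev_start) + 1
            r1.template_length = tlen
            r2.template_length = -tlen
        for rec in (r1, r2):
            if rec.is_unmapped:
                continue
            rseq = seqs[names[rec.reference_id]]
            span = rseq[rec.reference_start : rec.reference_start + rec.query_length]
            query = np.frombuffer(rec.query_sequence.encode("ascii"), dtype="S1")
            rec.set_tag("NM", int(np.sum(span != query)), value_type="i")
        add(r1)
        add(r2)

    records.sort(key=lambda t: (t[0], t[1], t[2]))
    mode = "w" if str(out_path).endswith(".sam") else "wb"
    with pysam.AlignmentFile(str(out_path), mode, header=hdr) as out:
        for _, _, _, rec in records:
            out.write(rec)
    if str(out_path).endswith(".bam"):
        pysam.index(str(out_path))
    return out_path
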