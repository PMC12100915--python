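"""Shared fixtures: small synthetic datasets generated once per session."""

from __future__ import annotations

from pathlib import Path

import pytest

from cffrag import fragio, synthetic as syn


def make_record(
    name="q1",
    chrom="chr1",
    start=1001,
    end=1150,
    strand="+",
    mapq=60,
    first=True,
    **flags,
):
    """Handcrafted AlignmentRecord with an all-match CIGAR."""
    length = end - start + 1 if start is not None else 0
    return fragio.AlignmentRecord(
        query_name=name,
        ref_name=chrom,
        start=start,
        end=end,
        strand=strand,
        mapq=mapq,
        is_first_in_pair=first,
        bases="A" * length,
        cigartuples=[(0, length)] if length else None,
        **flags,
    )


def make_pair(s1, e1, strand1, s2, e2, strand2, chrom="chr1", chrom2=None, name="q1", **kw):
    r1 = make_record(name=name, chrom=chrom, start=s1, end=e1, strand=strand1, first=True, **kw)
    r2 = make_record(name=name, chrom=chrom2 or chrom, start=s2, end=e2, strand=strand2, first=False, **kw)
    return fragio.ReadPair(r1, r2)


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory) -> Path:
    return tmp_path_factory.mktemp("sim")


@pytest.fixture(scope="session")
def clean_sim(sim_dir):
    """Artifact-free dataset with sequence-through overhangs: 4000 fragments."""
    cfg = syn.SimulationConfig(seed=11, n_fragments=4000, overhang_rate=0.5)
    ref = syn.make_reference(cfg, sim_dir / "clean_ref.fa")
    truth = syn.simulate_fragments(cfg, ref)
    bam = syn.emit_alignments(truth, cfg, ref, sim_dir / "clean.bam")
    return cfg, ref, truth, bam


@pytest.fixture(scope="session")
def artifact_sim(sim_dir):
    """Dataset with every QC/curation artifact class planted at 2%."""
    cfg = syn.SimulationConfig(
        seed=12,
        n_fragments=3000,
        overhang_rate=0.3,
        duplicate_rate=0.02,
        low_mapq_rate=0.02,
        secondary_rate=0.02,
        unmapped_rate=0.02,
        discordant_chrom_rate=0.02,
        outward_rate=0.02,
    )
    ref = syn.make_reference(cfg, sim_dir / "artifact_ref.fa")
    truth = syn.simulate_fragments(cfg, ref)
    bam = syn.emit_alignments(truth, cfg, ref, sim_dir / "artifact.bam")
    return cfg, ref, truth, bam
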