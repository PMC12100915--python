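"""Minimal diagnostic plots (matplotlib, non-interactive backend)."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from cffrag.cnv import Bin
from cffrag.lengths import LengthDistribution
from cffrag.motifs import MotifTable

_STATE_COLOURS = {"gain": "tab:orange", "neutral": "0.6", "loss": "tab:blue", "excluded": "0.9"}


def plot_length_distribution(dist: LengthDistribution, out: str | Path) -> Path:
    fig, ax = plt.subplots(figsize=(7, 3.5))
    frac = dist.fractions
    if frac is not None:
        ax.plot(dist.lengths, frac, lw=0.8)
    ax.set_xlabel("fragment length (bp)")
    ax.set_ylabel("fraction")
    ax.set_title(dist.sample_id)
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return Path(out)


def plot_motif_table(table: MotifTable, out: str | Path) -> Path:
    """Motif fractions in lexicographic order as a line/point plot."""
    fig, ax = plt.subplots(figsize=(max(7, 4 ** table.spec.k * 0.12), 3.5))
    frac = table.fractions
    if frac is not None:
        ax.plot(range(len(frac)), frac, marker="o", ms=2, lw=0.6)
    if 4 ** table.spec.k <= 64:
        ax.set_xticks(range(len(table.motifs)))
        ax.set_xticklabels(table.motifs, rotation=90, fontsize=5)
    ax.set_ylabel("fraction")
    ax.set_title(f"{table.sample_id}: {table.spec.name}")
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return Path(out)


def plot_cnv(bins: Sequence[Bin], out: str | Path) -> Path:
    """Genome-wide per-bin log2 ratios coloured by state."""
    fig, ax = plt.subplots(figsize=(9, 3.5))
    xs = range(len(bins))
    colours = [_STATE_COLOURS.get(b.state, "k") for b in bins]
    ys = [b.log2_ratio for b in bins]
    ax.scatter(xs, ys, c=colours, s=8)
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("bin index (genome order)")
    ax.set_ylabel("log2 ratio")
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return Path(out)
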