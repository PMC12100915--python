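"""Mutation-overlap annotation: CO / SO / DO concordance at spiked loci.

Short fragments are read by both mates, so a variant inside the mate
overlap is observed twice per molecule.  Concordant (CO) double
observations are high confidence; discordant (DO) ones gauge noise.
"""

from pathlib import Path
import tempfile

from cffrag import fragio, mutations, synthetic as syn

workdir = Path(tempfile.mkdtemp())
chroms = [("chr1", 40_000, 0.5)]
ref = syn.make_reference(syn.SimulationConfig(seed=23, chromosomes=chroms), workdir / "ref.fa")
pos = 20_000
ref_base = str(ref["chr1"][pos - 1]).upper()
alt = "T" if ref_base != "T" else "A"
cfg = syn.SimulationConfig(
    seed=23, n_fragments=45_000, chromosomes=chroms,
    variant_spikes=[syn.VariantSpike("chr1", pos, alt, vaf=0.2, discordant_rate=0.15)],
)
truth = syn.simulate_fragments(cfg, ref)
bam = syn.emit_alignments(truth, cfg, ref, workdir / "aln.bam")

locus = mutations.VariantLocus("chr1", pos, ref_base, alt)
anns = mutations.annotate_pairs(fragio.read_pairs(bam), [locus], cfg.contig_lengths)
sup = mutations.aggregate_support(anns, include_discordant_in_alt=True)[locus.id]
cc = sup.category_counts

print(f"locus {locus.id}: {sup.total_overlapping} overlapping fragments")
for cat in ("CO", "SO", "DO", "REF_ONLY", "NO_COVER"):
    print(f"  {cat:<9} {cc.get(cat, 0)}")
vaf = sup.alt_count / (sup.alt_count + sup.ref_count)
disc = cc.get("DO", 0) / (cc.get("CO", 0) + cc.get("DO", 0))
print(f"recovered VAF:        {vaf:.3f}  (planted 0.200)")
print(f"DO / (CO + DO):       {disc:.3f}  (planted 0.150)")
print()
print("The discordant-overlap rate estimates per-locus noise independently")
print("of the variant allele fraction.")
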