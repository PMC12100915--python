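"""Stratified 96-context substitution profiles and signature similarity.

Removing discordant-overlap (DO) events from a substitution profile
sharpens its resemblance to the underlying mutational signature, because
DO events are dominated by artefactual base calls with unstructured
trinucleotide contexts.
"""

import numpy as np

from cffrag.mutations import (
    SBS96_CONTEXTS,
    OverlapAnnotation,
    OverlapCategory,
    VariantLocus,
    call_trinucleotide,
    cosine_similarity,
    do_removed_profile,
)

rng = np.random.default_rng(29)
seq = "".join(rng.choice(list("ACGT"), size=20_000))
ref = {"chr1": seq}
ctx_locus = {}
for ctx in SBS96_CONTEXTS:
    r, a = ctx[2], ctx[4]
    tri = ctx[0] + r + ctx[6]
    p = seq.find(tri, 2)
    if p >= 0:
        ctx_locus[ctx] = VariantLocus("chr1", p + 2, r, a)

# a 3-context signature plus uniform-context DO noise at 30% of events
sig_ctxs = [c for c in ("A[C>T]G", "C[C>T]T", "T[C>T]A") if c in ctx_locus]
sig_vec = np.zeros(96)
for c, w in zip(sig_ctxs, (0.5, 0.3, 0.2)):
    sig_vec[SBS96_CONTEXTS.index(c)] = w
anns = []
for i in range(200):
    if rng.random() < 0.30:
        ctx = SBS96_CONTEXTS[rng.integers(96)]
        cat = OverlapCategory.DO
    else:
        ctx = sig_ctxs[rng.choice(len(sig_ctxs), p=(0.5, 0.3, 0.2))]
        cat = OverlapCategory.CO if rng.random() < 0.5 else OverlapCategory.SO
    if ctx in ctx_locus:
        anns.append(OverlapAnnotation(f"f{i}", ctx_locus[ctx], cat))

profiles = call_trinucleotide(anns, ref)
removed = do_removed_profile(profiles)
cos_all = cosine_similarity(profiles["ALL"], sig_vec)
cos_rm = cosine_similarity(removed, sig_vec)
print(f"events: {len(anns)}  (DO: {int(profiles['DO'].counts.sum())})")
print(f"cosine similarity to planted signature, ALL profile:        {cos_all:.3f}")
print(f"cosine similarity to planted signature, DO-removed profile: {cos_rm:.3f}")
print()
print("Filtering the discordant stratum moves the profile closer to the")
print("true signature, mirroring the gain seen for real tumour signatures.")
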