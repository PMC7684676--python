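"""Codon-level annotation of single SNVs, including the classic notation.

Builds a toy one-exon transcript whose protein carries L at residue 858 and
V at residue 600, plants the canonical oncogenic codon changes, and prints
the resulting calls: p.L858R and p.V600E mean leucine-to-arginine at residue
858 and valine-to-glutamate at residue 600.
"""

import random

from varprotdb import SnvVariant, TranscriptModel, annotate_variant

rng = random.Random(0)
sense = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
         if a + b + c not in ("TAA", "TAG", "TGA")]

codons = ["ATG"] + [rng.choice(sense) for _ in range(898)] + ["TAA"]
codons[857] = "CTG"  # leucine at residue 858
codons[599] = "GTG"  # valine at residue 600
cds = "".join(codons)
genome = {"chr7": cds}
tx = TranscriptModel("NM_DEMO", "DEMO", "chr7", "+", ((0, len(cds)),), len(cds))

for residue, alt in ((858, "G"), (600, "A")):
    gpos = (residue - 1) * 3 + 1  # middle base of the codon, 0-based
    v = SnvVariant("chr7", gpos + 1, cds[gpos], alt)
    effect = annotate_variant(v, tx, genome)
    print(
        f"{v.chrom}:{v.pos} {v.ref_allele}>{v.alt_allele}  ->  "
        f"{effect.category}  {effect.ref_codon}->{effect.alt_codon}  {effect.hgvs_p}"
    )

# a third-position change is usually silent
v = SnvVariant("chr7", 858 * 3, cds[858 * 3 - 1], "G" if cds[858 * 3 - 1] != "G" else "A")
effect = annotate_variant(v, tx, genome)
print(f"third codon position change: {effect.category} ({effect.hgvs_p})")
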