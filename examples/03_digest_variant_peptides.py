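"""Enumerate variant tryptic peptides and their wild-type partners.

Digests a reference protein and its single-substitution variant with
trypsin + LysC (one missed cleavage, minimum length 7) and prints each
variant peptide — a peptide covering the substituted residue that does not
occur in the reference digest — next to the wild-type peptide(s) spanning
the same coordinates. A substitution to lysine creates a new cleavage site,
so the variant peptides are shorter fragments absent from the reference.
"""

from varprotdb import DigestParams, digest, variant_peptides

reference = "MSLNDFQKELTMNAAGGQVIRESPDRTLLWAAHEKGGVNYDSLMK"
position, alt = 22, "K"  # E22K creates a new LysC/trypsin site
ref_aa = reference[position - 1]
variant = reference[: position - 1] + alt + reference[position:]

params = DigestParams()  # trypsin+LysC, <=1 missed cleavage, min length 7
print(f"reference digest: {len(digest(reference, params))} peptides")
print(f"variant digest:   {len(digest(variant, params))} peptides")
print(f"substitution: {ref_aa}{position}{alt}\n")

pairs = variant_peptides(
    reference, variant, params, parent_id="DEMO", hgvs_p=f"p.{ref_aa}{position}{alt}"
)
print(f"{len(pairs)} variant peptides (each contains the substituted residue):")
for pair in pairs:
    vp = pair.variant_peptide
    partners = ", ".join(w.residues for w in pair.wildtype_peptides) or "(none)"
    print(f"  {vp.residues}  [{vp.start}-{vp.end}, missed={vp.missed_cleavages}]")
    print(f"    wild-type partner(s): {partners}")
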