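# varprotdb

**Sample-specific variant protein databases from called SNVs, for
proteogenomic variant-peptide detection.**

Standard shotgun-proteomics searches use a reference protein database, so a
peptide carrying a sample's own amino-acid substitution — the kind of
mutant peptide that can act as a neo-antigen in cancer — can never be
identified: its sequence is simply not in the search space. `varprotdb`
closes that gap for anyone with a variant call set in hand. Given

* a reference genome (FASTA),
* gene models (GTF with CDS features), and
* single-nucleotide variants (VCF),

it annotates each SNV at codon level against every overlapping transcript,
substitutes each amino-acid-changing variant into the translated reference
protein, and writes a customized protein FASTA — reference proteome plus one
entry per incorporated variant, optionally with reversed decoys — ready to
be used as the search space of any MS/MS search engine. It also enumerates
the variant tryptic peptides with their wild-type counterparts, which is
what a downstream search can actually observe.

## The model

For an SNV at genomic position *g* with forward-strand alleles *r* → *a* and
a transcript with spliced CDS *c₁…cₙ* (5'→3', minus-strand alleles are
complemented), the affected codon index is ⌈i/3⌉ for CDS index *i*, and the
consequence is read off the standard genetic code applied to the reference
and substituted codons:

| codon comparison | category | incorporated? |
|---|---|---|
| same residue (incl. stop→stop) | synonymous | no |
| residue → stop | stopgain | opt-in, as stop-truncated protein |
| stop → residue | stoploss | no |
| M1 destroyed | startloss | no |
| any other residue change | missense | **yes** |

A missense effect at residue *p* changing *R* to *A* produces a database
entry at Hamming distance exactly 1 from its base protein, labelled with
the one-letter protein-change shorthand `p.L858R` / `p.V600E` familiar from
the EGFR and BRAF oncogenic substitutions. Indels and frameshifts are out of
scope: only single-nucleotide substitutions are incorporated.

Digestion follows the common trypsin + LysC setup: cleave after every K
(LysC cuts K-P), after every R not followed by P, at most one missed
cleavage, minimum peptide length 7. A *variant peptide* is a peptide of the
variant protein that covers the substituted residue and is absent from the
reference digest; its wild-type partners are the reference peptides
overlapping the same coordinates.

## Worked example

No external data is needed — the built-in simulator generates a genome,
gene models and planted variants with a machine-readable truth table:

```bash
varprotdb simulate --out-dir demo --genes 10 --seed 1 --plant 12,6,2,4 --chrom-length 30000
varprotdb build-db --genome demo/genome.fa --gtf demo/genes.gtf --vcf demo/sample.vcf \
                   --out demo/db.fasta --decoy --report demo/report.tsv
```

Or equivalently from Python (`python examples/01_simulate_and_build.py`),
which prints:

```
reference proteins: 10
variant entries:    12  (planted missense: 12)
per-category effect counts: {'missense': 12, 'synonymous': 6, 'stopgain': 2,
                             'stoploss': 0, 'startloss': 0, 'noncoding': 4}

first variant headers (transcript|change, provenance, class):
  TX0002|p.I40N gene=GENE0002 var=chr1:1551A>T class=missense
  TX0002|p.R18P gene=GENE0002 var=chr1:1617C>G class=missense
  TX0002|p.S53G gene=GENE0002 var=chr1:1513T>C class=missense
```

Of the 24 planted SNVs, exactly the 12 missense ones become database
entries; synonymous, stopgain (by default) and noncoding variants are
counted but not incorporated. Each header records the protein change, the
gene and the genomic provenance of the variant. `varprotdb digest --db
demo/db.fasta --out demo/peptides.tsv` then tabulates the variant peptides
with their paired wild-type peptides, and `examples/02_annotate_variants.py`
/ `examples/03_digest_variant_peptides.py` walk through single-variant
annotation and peptide pairing.

Every subcommand accepts `--dry-run`, which prints the fully resolved plan
(inputs, options, output paths) and exits without writing anything.

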