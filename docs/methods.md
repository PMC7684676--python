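# Methods

## Problem and scope

`varprotdb` turns a per-sample SNV call set into the protein search space a
tandem-MS engine needs to see those variants at all. The pipeline is:
parse genome/GTF/VCF → classify each SNV at codon level against each
overlapping transcript → substitute each missense change into the
translated reference protein → emit a deterministic protein FASTA
(reference section, then variant section, optional reversed decoys) → and,
separately, enumerate the variant peptides a proteolytic digest can
actually produce, paired with their wild-type counterparts.

Only single-nucleotide substitutions are handled. Indels, frameshifts,
splice-altering variants, fusions, RNA editing and haplotype-combined
proteoforms are deliberate non-goals; upstream read alignment and variant
calling are likewise outside the package (any caller that writes a VCF
feeds it).

## Coordinates and parsing

VCF and GTF are 1-based inclusive on disk; the raw record types keep those
printed values, and every internal computation uses 0-based half-open
intervals. The conversion happens in exactly one place
(`gene_model.build_transcript`), which is the package's single locus of
off-by-one risk and is covered by a brute-force bijection test over every
coding base of every fixture transcript.

VCF handling keeps only alleles where both REF and ALT are a single
A/C/G/T base; multi-allelic records are split per ALT. Everything else —
indels, MNVs, symbolic alleles, non-PASS records — is counted per allele in
a skip report, never silently dropped: kept + skipped always equals the
number of allele pairs in the file. The FILTER policy keeps `PASS` and `.`
by default (`keep_filtered` disables the filter); genotype columns are
ignored, so every alt allele in the file is a candidate regardless of
zygosity. Chromosome naming is taken literally: a `chr1`/`1` mismatch
between VCF/GTF and genome is an error, not something to auto-heal, because
silent healing hides wrong-build mistakes.

## Gene models and translation

CDS phase attributes in the GTF are ignored: the first base of the 5'-most
coding segment in transcript orientation is codon position 0. The synthetic
generator guarantees this; real annotations violating it surface as
no-start / internal-stop flags in the build report rather than being
mis-translated silently. Translation uses the standard genetic code only
(no mitochondrial tables; UGA is always a stop, so selenoproteins appear as
internal-stop flags). Any codon containing N translates to X; a trailing
incomplete codon is dropped with a flag. Degenerate inputs produce flags,
never exceptions, so one malformed transcript cannot abort a build.

## Consequence calling

The affected codon is rebuilt from the spliced CDS; for minus-strand
transcripts the VCF's forward-strand alleles are complemented first.
Category order: same residue → synonymous (a stop mutating to another stop
is synonymous); residue→stop → stopgain; stop→residue → stoploss; a change
destroying M1 → startloss (hence M1→stop is a stopgain, because the stop
check comes first); anything else → missense. Protein changes use
one-letter shorthand (`p.L858R`, `p.R123*`, `p.K2=`, `p.M1?`), matching how
substitutions like EGFR L858R and BRAF V600E are conventionally written.
Note the notation reads reference→alternate (leucine at 858 replaced by
arginine), regardless of how prose sometimes inverts it.

The annotator is verified against an independent oracle that mutates the
entire chromosome string, re-extracts and re-translates the whole CDS with
Biopython, and compares; agreement on category, residue index and both
residues is required to be total over 1,000 random SNVs on mixed-strand
multi-exon transcripts.

A variant's REF allele must match the genome base (checked per variant);
mismatches — the classic wrong-genome-build signature — are counted and
skipped during a build, and raise when annotating a single variant
directly. Variants are annotated against **all** overlapping transcripts;
the database deduplicates downstream. In the summary counts, a variant
overlapping no transcript footprint at all is tallied as noncoding, so
every variant is accounted for exactly once per overlapping transcript, or
once if it overlaps none.

## Database construction

Reference entries are the translations of every translatable transcript,
sorted by identifier. When a reference protein FASTA plus id-map is
supplied, each translation is compared with the provided sequence; a
mismatch skips the transcript and counts it — historical annotation
mismatches must be visible, never silently papered over.

Variant entries: one per distinct (transcript_id, protein change), missense
only by default. Multiple missense variants on one transcript give multiple
single-substitution entries, never a combined haplotype (a plain VCF
carries no phasing). Distinct genomic SNVs producing the same protein
change merge into one entry whose header concatenates all provenance
(`var=chr1:100A>G;chr1:102C>T`). Stopgain effects can be opted in as
stop-truncated proteins; synonymous and noncoding effects are never
emitted. Every missense entry is asserted, on every build, to sit at
Hamming distance exactly 1 from its base protein (truncating stopgain
entries are exempt by definition). Output ordering is fully sorted, so a
build is a pure function of its inputs — two runs are byte-identical.

Decoys are sequence reversals with identifiers prefixed `rev_`, one per
target; reversal is an involution, which the tests exploit.

## Digestion and variant peptides

Cut sites: after every K (LysC cleaves K-P, toggleable via `kp_cut`), after
every R except before P (trypsin's proline rule); the C-terminus is never a
site. Peptides are the substrings between boundaries spanning at most
`max_missed_cleavages` internal sites (default 1), filtered to
`min_length` 7 with no maximum by default — the settings of a typical
trypsin + LysC search. The digest is validated against an exhaustive
substring oracle that re-derives boundary, missed-cleavage and length rules
independently for every (i, j) substring of random proteins.

Variant peptides must cover the substituted residue and be absent, as bare
sequences, from the reference digest; wild-type partners are matched by
coordinate overlap (not sequence alignment), which handles the
site-creating/destroying cases where pairing is many-to-one. When a created
cut site strands only sub-minimum fragments, the variant peptide set is
legitimately empty. Locality holds by construction and is tested: for a
site-preserving substitution every digest difference covers the substituted
residue; for site-changing substitutions every difference overlaps the
affected inter-cut interval of the reference digest (containment inside the
interval would be too strong — with one missed cleavage allowed, peptides
legitimately extend one interval beyond).

## The synthetic generator

The simulator emulates exactly what the pipeline consumes: uniform-base
chromosomes carrying non-overlapping genes, each a complete ORF (ATG start,
stop-free interior, terminal stop, length divisible by 3) split across 1–4
exons with introns of at least 20 bp (so no planted variant is ambiguous
between transcripts), half on each strand by default. Planted variants are
chosen so their codon-level effect is the requested category *by
construction* against the codon table, with forward-strand alleles matching
the genome; noncoding variants go to introns (preferred) or intergenic
space. Default gene sizes are 60–300 codons — small enough to keep the test
suite fast, large enough that every consequence category has abundant
eligible sites. Defaults plant 30 missense / 20 synonymous / 5 stopgain /
10 noncoding variants; the headline recovery analysis uses 200/100/20/50
across 48 genes on two 150 kb chromosomes.

What the generator does **not** emulate: realistic GC content and codon
usage, overlapping transcripts and alternative isoforms, UTRs, repeats,
sequencing or calling error (input VCFs are taken at face value), and Ns
(absent by default). Passing tests therefore demonstrate the correctness
of the coordinate arithmetic, consequence logic, substitution and
digestion machinery — not robustness to annotation pathologies such as
phase-shifted CDS or reference/transcript sequence disagreements, which are
instead surfaced as flags and skip counts on real data.

## Numerical and design choices

* Determinism everywhere: a single integer seed fixes simulator output to
  the byte; database FASTA ordering is sorted, not insertion-ordered.
* Degenerate inputs produce flags or counted skips; only structural errors
  (overlapping CDS, both-strand transcripts, malformed columns — with line
  numbers) raise.
* The acceptance script's problem sizes (1,000 oracle SNVs over 56 genes,
  370-variant recovery run, 100 random proteins per digest property) were
  chosen as the smallest sizes at which every category and edge
  (multi-exon, both strands, site-creating substitutions) is exercised many
  times over.
* FASTA/VCF readers are small dedicated parsers so that format errors can
  name line numbers and skip accounting can be exact per allele; Biopython
  and cyvcf2 read the same fixtures in the test suite as independent
  cross-checks. GTF parsing goes through gffutils.

## Known limitations

SNVs only; single canonical codon table; no phase/frame handling; decoys by
reversal only (no shuffling); GTF attribute dialect only (no GFF3); peptide
comparison ignores modifications (carbamidomethylation, oxidation and the
like are search-engine settings); FDR estimation and PSM scoring belong to
the search engine and are out of scope.
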