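"""Deterministic simulator of a genome, gene models and planted SNVs.

The simulator writes exactly the three inputs the database builder consumes
(genome FASTA, CDS-bearing GTF, SNV VCF) plus a machine-readable truth table
of the planted variant effects, so the whole pipeline can be exercised and
its output checked against a known answer without any external download.

Every simulated gene is a complete ORF — ATG start, stop-free interior,
terminal stop, CDS length divisible by 3 — possibly split across several CDS
segments separated by introns of at least 20 bp, on a configurable strand
mix. Base composition is uniform over A/C/G/T; no Ns are generated by
default. Genes never overlap, so a coding variant targets exactly one
transcript. All randomness flows from a single seed: outputs are
byte-identical across runs with the same configuration.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ConfigError
from .gene_model import (
    TranscriptModel,
    build_transcript,
    cds_index_to_genomic,
    codon_to_aa,
    complement_base,
    extract_cds,
)
from .io_formats import GtfTranscriptRaw, SequenceRecord, SnvVariant, write_fasta

_SENSE_CODONS = sorted(
    "".join((a, b, c))
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if "".join((a, b, c)) not in ("TAA", "TAG", "TGA")
)
_STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass
class SimulationConfig:
    """Study conditions of a simulated dataset.

    ``planted`` gives the requested variant counts per consequence category;
    noncoding variants are placed in introns when available, else between
    genes. ``exons_per_gene`` and ``n_codons_range`` are inclusive ranges.
    """

    n_chromosomes: int = 1
    chromosome_length: int = 100_000
    n_genes: int = 30
    exons_per_gene: tuple[int, int] = (1, 4)
    n_codons_range: tuple[int, int] = (60, 300)
    intron_length_range: tuple[int, int] = (20, 150)
    gene_spacing: int = 100
    fraction_minus_strand: float = 0.5
    planted: dict = field(
        default_factory=lambda: {"missense": 30, "synonymous": 20, "stopgain": 5, "noncoding": 10}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.n_genes < 1:
            raise ConfigError("need at least one chromosome and one gene")
        if any(count < 0 for count in self.planted.values()):
            raise ConfigError("planted counts must be >= 0")
        if not 0.0 <= self.fraction_minus_strand <= 1.0:
            raise ConfigError("fraction_minus_strand must be in [0,1]")
        if self.intron_length_range[0] < 20:
            raise ConfigError("introns must be at least 20 bp")


@dataclass(frozen=True)
class TruthRecord:
    """The intended effect of one planted variant on one transcript."""

    chrom: str
    pos: int  # 1-based, as in the VCF
    ref: str
    alt: str
    transcript_id: str
    category: str
    hgvs_p: str  # empty for noncoding


def _random_orf(rng: random.Random, n_codons: int) -> str:
    body = "".join(rng.choice(_SENSE_CODONS) for _ in range(n_codons - 2))
    return "ATG" + body + rng.choice(_STOP_CODONS)


def simulate_reference(
    config: SimulationConfig,
) -> tuple[list[SequenceRecord], list[GtfTranscriptRaw]]:
    """Generate the genome FASTA records and raw gene models.

    Genes are laid out left to right with at least ``gene_spacing`` bases
    between them, round-robin across chromosomes; infeasible packing raises
    :class:`ConfigError`.
    """
    rng = random.Random(config.seed)
    chroms = [
        [rng.choice("ACGT") for _ in range(config.chromosome_length)]
        for _ in range(config.n_chromosomes)
    ]
    cursors = [config.gene_spacing] * config.n_chromosomes
    transcripts: list[GtfTranscriptRaw] = []

    for g in range(config.n_genes):
        chrom_i = g % config.n_chromosomes
        chrom = chroms[chrom_i]
        n_codons = rng.randint(*config.n_codons_range)
        cds = _random_orf(rng, n_codons)
        n_exons = rng.randint(*config.exons_per_gene)
        n_exons = min(n_exons, len(cds) // 6)  # each exon at least 6 nt
        n_exons = max(n_exons, 1)
        # exon lengths: random composition of len(cds) into n_exons parts >= 6
        cuts = sorted(rng.sample(range(6, len(cds) - 5, 1), n_exons - 1)) if n_exons > 1 else []
        # enforce minimum 6 nt per part by rejection
        attempts = 0
        while cuts and min(
            b - a for a, b in zip([0] + cuts, cuts + [len(cds)])
        ) < 6:
            cuts = sorted(rng.sample(range(6, len(cds) - 5, 1), n_exons - 1))
            attempts += 1
            if attempts > 200:
                cuts = [len(cds) // n_exons * i for i in range(1, n_exons)]
                break
        exon_lengths = [b - a for a, b in zip([0] + cuts, cuts + [len(cds)])]
        introns = [rng.randint(*config.intron_length_range) for _ in range(n_exons - 1)]
        span = sum(exon_lengths) + sum(introns)

        start = cursors[chrom_i]
        if start + span + config.gene_spacing > config.chromosome_length:
            raise ConfigError(
                f"gene {g} does not fit on chromosome {chrom_i + 1}: "
                "increase chromosome_length or reduce n_genes"
            )
        strand = "-" if rng.random() < config.fraction_minus_strand else "+"
        # genomic bases of the gene region: CDS (or its reverse complement)
        # written segment by segment in genomic order
        genomic_cds = cds if strand == "+" else "".join(
            complement_base(b) for b in reversed(cds)
        )
        intervals: list[tuple[int, int]] = []
        pos = start
        consumed = 0
        genomic_exon_lengths = exon_lengths if strand == "+" else exon_lengths[::-1]
        for i, exon_len in enumerate(genomic_exon_lengths):
            piece = genomic_cds[consumed : consumed + exon_len]
            chrom[pos : pos + exon_len] = list(piece)
            intervals.append((pos + 1, pos + exon_len))  # GTF 1-based inclusive
            consumed += exon_len
            pos += exon_len
            if i < len(genomic_exon_lengths) - 1:
                pos += introns[i]
        cursors[chrom_i] = pos + config.gene_spacing

        tx_id = f"TX{g + 1:04d}"
        transcripts.append(
            GtfTranscriptRaw(
                transcript_id=tx_id,
                gene_name=f"GENE{g + 1:04d}",
                chrom=f"chr{chrom_i + 1}",
                strand=strand,
                cds_intervals=tuple(intervals),
            )
        )

    genome_records = [
        SequenceRecord(f"chr{i + 1}", "simulated", "".join(chroms[i]))
        for i in range(config.n_chromosomes)
    ]
    return genome_records, transcripts


def _plant_coding(
    rng: random.Random,
    models: list[TranscriptModel],
    cds_by_tx: dict[str, str],
    category: str,
    count: int,
    used_positions: set[tuple[str, int]],
) -> list[TruthRecord]:
    """Plant ``count`` coding variants whose codon-level effect is ``category``."""
    records: list[TruthRecord] = []
    attempts = 0
    max_attempts = 500 * max(count, 1) + 1000
    while len(records) < count:
        attempts += 1
        if attempts > max_attempts:
            raise ConfigError(
                f"could not find {count} eligible {category} sites; enlarge the simulation"
            )
        tx = rng.choice(models)
        cds = cds_by_tx[tx.transcript_id]
        n_protein = len(cds) // 3 - 1  # last codon is the stop
        if n_protein < 3:
            continue
        residue = rng.randint(2, n_protein)  # avoid start codon (startloss) and stop
        offset = rng.randint(0, 2)
        cds_index = (residue - 1) * 3 + offset
        codon_start = (residue - 1) * 3
        ref_codon = cds[codon_start : codon_start + 3]
        ref_aa = codon_to_aa(ref_codon)
        ref_base = cds[cds_index]
        candidates = []
        for alt_base in "ACGT":
            if alt_base == ref_base:
                continue
            alt_codon = ref_codon[:offset] + alt_base + ref_codon[offset + 1 :]
            alt_aa = codon_to_aa(alt_codon)
            if category == "missense" and alt_aa not in ("*", ref_aa):
                candidates.append((alt_base, alt_aa))
            elif category == "synonymous" and alt_aa == ref_aa:
                candidates.append((alt_base, alt_aa))
            elif category == "stopgain" and alt_aa == "*":
                candidates.append((alt_base, alt_aa))
        if not candidates:
            continue
        alt_base, alt_aa = rng.choice(candidates)
        gpos = cds_index_to_genomic(tx, cds_index)  # 0-based
        key = (tx.chrom, gpos)
        if key in used_positions:
            continue
        used_positions.add(key)
        if tx.strand == "+":
            ref_fwd, alt_fwd = ref_base, alt_base
        else:
            ref_fwd, alt_fwd = complement_base(ref_base), complement_base(alt_base)
        if category == "synonymous":
            hgvs = f"p.{ref_aa}{residue}="
        elif category == "stopgain":
            hgvs = f"p.{ref_aa}{residue}*"
        else:
            hgvs = f"p.{ref_aa}{residue}{alt_aa}"
        records.append(
            TruthRecord(tx.chrom, gpos + 1, ref_fwd, alt_fwd, tx.transcript_id, category, hgvs)
        )
    return records


def _plant_noncoding(
    rng: random.Random,
    genome: dict[str, str],
    models: list[TranscriptModel],
    count: int,
    used_positions: set[tuple[str, int]],
) -> list[TruthRecord]:
    """Plant variants in introns (preferred) or intergenic space."""
    records: list[TruthRecord] = []
    intronic_sites: list[tuple[TranscriptModel, int]] = []
    for tx in models:
        for (s1, e1), (s2, _) in zip(tx.cds_segments, tx.cds_segments[1:]):
            intronic_sites.extend((tx, p) for p in range(e1, s2))
    coding = {
        (tx.chrom, p) for tx in models for s, e in tx.cds_segments for p in range(s, e)
    }
    spans = [(tx.chrom, *tx.span) for tx in models]
    attempts = 0
    while len(records) < count:
        attempts += 1
        if attempts > 500 * max(count, 1) + 1000:
            raise ConfigError("could not place the requested noncoding variants")
        if intronic_sites and rng.random() < 0.7:
            tx, gpos = rng.choice(intronic_sites)
            chrom = tx.chrom
            tx_id = tx.transcript_id
        else:
            chrom = rng.choice(sorted(genome))
            gpos = rng.randrange(len(genome[chrom]))
            if (chrom, gpos) in coding:
                continue
            if any(c == chrom and s <= gpos < e for c, s, e in spans):
                continue  # keep pure intergenic picks outside every footprint
            tx_id = ""
        key = (chrom, gpos)
        if key in used_positions:
            continue
        ref = genome[chrom][gpos]
        if ref not in "ACGT":
            continue
        used_positions.add(key)
        alt = rng.choice([b for b in "ACGT" if b != ref])
        records.append(TruthRecord(chrom, gpos + 1, ref, alt, tx_id, "noncoding", ""))
    return records


def plant_variants(
    genome_records: list[SequenceRecord],
    transcripts: list[GtfTranscriptRaw],
    config: SimulationConfig,
) -> tuple[list[SnvVariant], list[TruthRecord]]:
    """Plant the configured variant counts; effects verified by construction.

    Returns VCF-ready variants (position-sorted, forward-strand alleles that
    match the genome) and the truth table recording each variant's intended
    category and protein change.
    """
    rng = random.Random(config.seed + 1_000_003)
    genome = {rec.identifier: rec.residues for rec in genome_records}
    models = [build_transcript(raw) for raw in transcripts]
    cds_by_tx = {m.transcript_id: extract_cds(m, genome).nucleotides for m in models}

    used: set[tuple[str, int]] = set()
    truth: list[TruthRecord] = []
    for category in ("missense", "synonymous", "stopgain"):
        truth += _plant_coding(
            rng, models, cds_by_tx, category, config.planted.get(category, 0), used
        )
    truth += _plant_noncoding(rng, genome, models, config.planted.get("noncoding", 0), used)

    truth.sort(key=lambda t: (t.chrom, t.pos, t.alt))
    variants = [
        SnvVariant(
            chrom=t.chrom,
            pos=t.pos,
            ref_allele=t.ref,
            alt_allele=t.alt,
            filter_status="PASS",
            record_index=i + 1,
        )
        for i, t in enumerate(truth)
    ]
    return variants, truth


def write_gtf(transcripts: list[GtfTranscriptRaw], path: str | Path) -> None:
    """Write CDS features, one GTF line per interval."""
    with open(path, "wt", encoding="ascii", newline="\n") as fh:
        for raw in transcripts:
            for start, end in raw.cds_intervals:
                attrs = (
                    f'gene_id "{raw.gene_name}"; transcript_id "{raw.transcript_id}"; '
                    f'gene_name "{raw.gene_name}";'
                )
                fh.write(
                    f"{raw.chrom}\tsim\tCDS\t{start}\t{end}\t.\t{raw.strand}\t0\t{attrs}\n"
                )


def write_vcf(variants: list[SnvVariant], path: str | Path, contigs: list[str] | None = None) -> None:
    """Write SNVs as a minimal sorted VCF v4.2."""
    with open(path, "wt", encoding="ascii", newline="\n") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=varprotdb-simulate\n")
        for contig in contigs or []:
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref_allele}\t{v.alt_allele}\t.\t{v.filter_status}\t.\n"
            )


def write_truth_table(truth: list[TruthRecord], path: str | Path) -> None:
    with open(path, "wt", encoding="ascii", newline="\n") as fh:
        fh.write("chrom\tpos\tref\talt\ttranscript_id\tcategory\thgvs_p\n")
        for t in truth:
            fh.write(
                f"{t.chrom}\t{t.pos}\t{t.ref}\t{t.alt}\t{t.transcript_id}\t{t.category}\t{t.hgvs_p}\n"
            )


def read_truth_table(path: str | Path) -> list[TruthRecord]:
    records = []
    with open(path, "rt", encoding="ascii") as fh:
        header = fh.readline()
        assert header.startswith("chrom\t")
        for line in fh:
            chrom, pos, ref, alt, tx_id, category, hgvs = line.rstrip("\n").split("\t")
            records.append(TruthRecord(chrom, int(pos), ref, alt, tx_id, category, hgvs))
    return records


def simulate_to_dir(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Run the full simulation and write genome.fa, genes.gtf, sample.vcf, truth.tsv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genome_records, transcripts = simulate_reference(config)
    variants, truth = plant_variants(genome_records, transcripts, config)
    paths = {
        "genome": out_dir / "genome.fa",
        "gtf": out_dir / "genes.gtf",
        "vcf": out_dir / "sample.vcf",
        "truth": out_dir / "truth.tsv",
    }
    write_fasta(genome_records, paths["genome"])
    write_gtf(transcripts, paths["gtf"])
    write_vcf(variants, paths["vcf"], contigs=[r.identifier for r in genome_records])
    write_truth_table(truth, paths["truth"])
    return paths
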