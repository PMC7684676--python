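"""Readers and writers for FASTA, VCF and GTF with strict coordinate handling.

Coordinate convention: VCF and GTF are 1-based inclusive on disk and are kept
that way in the raw record types defined here (:class:`SnvVariant`,
:class:`GtfTranscriptRaw`). All internal interval arithmetic downstream is
0-based half-open; the conversion happens exactly once, in
:func:`varprotdb.gene_model.build_transcript`, so there is a single locus of
off-by-one risk.

All readers accept plain or gzip-compressed input (sniffed by magic bytes).
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import gffutils

from .errors import FormatError

NUCLEOTIDE_ALPHABET = frozenset("ACGTN")
# 20 standard residues plus X (unknown, e.g. translated from an N codon)
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

Alphabet = Literal["nucleotide", "protein"]


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA entry.

    ``identifier`` is the first whitespace-delimited token of the header;
    ``description`` is the remainder (possibly empty). Residues are stored
    uppercase.
    """

    identifier: str
    description: str
    residues: str


@dataclass(frozen=True)
class SnvVariant:
    """A normalized single-nucleotide variant, forward-strand alleles.

    ``pos`` is the 1-based genomic coordinate exactly as printed in the VCF.
    Multi-allelic records are split upstream, so ``alt_allele`` is always a
    single base. ``record_index`` is the 1-based index of the source data
    line, kept for provenance.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    filter_status: str = "PASS"
    record_index: int = 0

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref and alt alleles identical: {self.ref_allele}")
        for allele in (self.ref_allele, self.alt_allele):
            if len(allele) != 1 or allele not in "ACGT":
                raise ValueError(f"not a single-nucleotide allele: {allele!r}")
        if self.pos < 1:
            raise ValueError(f"VCF position must be >= 1, got {self.pos}")


@dataclass(frozen=True)
class GtfTranscriptRaw:
    """CDS features of one transcript, coordinates as printed in the GTF.

    ``cds_intervals`` are 1-based inclusive (start, end) pairs in file order.
    """

    transcript_id: str
    gene_name: str
    chrom: str
    strand: str
    cds_intervals: tuple[tuple[int, int], ...]


@dataclass
class VcfSkipReport:
    """Allele-level accounting of VCF records not usable as SNVs.

    Every (REF, ALT) allele pair in the file is either kept as an
    :class:`SnvVariant` or counted in exactly one bucket here — indels and
    other unsupported classes are reported, never silently lost.
    """

    indel: int = 0
    mnv: int = 0
    symbolic: int = 0
    non_acgt: int = 0
    filtered: int = 0
    by_line: dict[str, list[int]] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return self.indel + self.mnv + self.symbolic + self.non_acgt + self.filtered

    def _count(self, bucket: str, line_number: int) -> None:
        setattr(self, bucket, getattr(self, bucket) + 1)
        self.by_line.setdefault(bucket, []).append(line_number)


def _open_text(path: str | Path) -> io.TextIOBase:
    """Open plain or gzip-compressed text, sniffing the gzip magic bytes."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="ascii")
    return open(path, "rt", encoding="ascii")


def read_fasta(path: str | Path, alphabet: Alphabet = "nucleotide") -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects, in file order.

    Wrapped sequence lines are concatenated and lowercase residues uppercased.
    A residue outside the chosen alphabet raises :class:`FormatError` naming
    the offending line.
    """
    allowed = NUCLEOTIDE_ALPHABET if alphabet == "nucleotide" else PROTEIN_ALPHABET
    records: list[SequenceRecord] = []
    identifier: str | None = None
    description = ""
    chunks: list[str] = []

    def flush(line_number: int) -> None:
        if identifier is None:
            return
        residues = "".join(chunks)
        if not residues:
            raise FormatError(f"{path}: record {identifier!r} has no sequence (before line {line_number})")
        records.append(SequenceRecord(identifier, description, residues))

    with _open_text(path) as fh:
        lineno = 0
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            if line.startswith(">"):
                flush(lineno)
                header = line[1:].strip()
                if not header:
                    raise FormatError(f"{path}: empty FASTA header at line {lineno}")
                parts = header.split(None, 1)
                identifier = parts[0]
                description = parts[1] if len(parts) == 2 else ""
                chunks = []
            else:
                if identifier is None:
                    raise FormatError(f"{path}: sequence before any header at line {lineno}")
                seq = line.strip().upper()
                bad = set(seq) - allowed
                if bad:
                    raise FormatError(
                        f"{path}: invalid {alphabet} character(s) {sorted(bad)} at line {lineno}"
                    )
                chunks.append(seq)
        flush(lineno + 1)
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, wrap_width: int = 60) -> None:
    """Write records as FASTA; output bytes are a pure function of the input.

    Records are written in input order, sequences wrapped at ``wrap_width``,
    with a trailing newline.
    """
    records = list(records)
    if not records:
        raise ValueError("write_fasta requires at least one record")
    if wrap_width < 1:
        raise ValueError("wrap_width must be positive")
    with open(path, "wt", encoding="ascii", newline="\n") as fh:
        for rec in records:
            header = rec.identifier if not rec.description else f"{rec.identifier} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), wrap_width):
                fh.write(rec.residues[i : i + wrap_width] + "\n")


def genome_as_dict(records: Iterable[SequenceRecord]) -> dict[str, str]:
    """Index genome records by chromosome name (first header token)."""
    genome: dict[str, str] = {}
    for rec in records:
        if rec.identifier in genome:
            raise FormatError(f"duplicate sequence identifier {rec.identifier!r}")
        genome[rec.identifier] = rec.residues
    return genome


_SYMBOLIC_MARKERS = ("<", ">", "[", "]", ".", "*")


def read_vcf_snvs(
    path: str | Path, keep_filtered: bool = False
) -> tuple[list[SnvVariant], VcfSkipReport]:
    """Read SNVs from a VCF, splitting multi-allelic records.

    Only alleles where both REF and ALT are a single A/C/G/T base are kept.
    Records whose FILTER is neither ``PASS`` nor ``.`` are dropped unless
    ``keep_filtered``. Everything dropped is counted, per allele, in the
    returned :class:`VcfSkipReport`; kept + skipped always equals the number
    of (REF, ALT) allele pairs in the file.
    """
    variants: list[SnvVariant] = []
    report = VcfSkipReport()
    data_index = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            data_index += 1
            fields = line.split("\t")
            if len(fields) < 8:
                # tolerate space-delimited minimal records (some hand-written VCFs)
                fields = line.split()
            if len(fields) < 7:
                raise FormatError(f"{path}: line {lineno}: fewer than 7 VCF columns")
            chrom, pos_s, _id, ref, alt_field, _qual, filt = fields[:7]
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: POS is not an integer: {pos_s!r}") from exc
            if pos < 1:
                raise FormatError(f"{path}: line {lineno}: POS must be >= 1")
            ref = ref.upper()
            filtered_out = filt not in ("PASS", ".") and not keep_filtered
            for alt in alt_field.upper().split(","):
                if any(m in alt for m in _SYMBOLIC_MARKERS) or any(m in ref for m in _SYMBOLIC_MARKERS):
                    report._count("symbolic", lineno)
                elif len(ref) != len(alt):
                    report._count("indel", lineno)
                elif len(ref) > 1:
                    report._count("mnv", lineno)
                elif ref not in "ACGT" or alt not in "ACGT" or ref == alt:
                    report._count("non_acgt", lineno)
                elif filtered_out:
                    report._count("filtered", lineno)
                else:
                    variants.append(
                        SnvVariant(
                            chrom=chrom,
                            pos=pos,
                            ref_allele=ref,
                            alt_allele=alt,
                            filter_status=filt,
                            record_index=data_index,
                        )
                    )
    return variants, report


def read_gtf_transcripts(path: str | Path) -> list[GtfTranscriptRaw]:
    """Group GTF CDS features by transcript_id.

    Only ``CDS`` feature lines are consumed; transcripts with zero CDS lines
    are omitted. Strand must be consistent within a transcript and the
    ``transcript_id`` attribute must be present on every CDS line.
    """
    with _open_text(path) as fh:
        text = fh.read()
    if not text.strip():
        return []
    try:
        db = gffutils.create_db(
            text,
            dbfn=":memory:",
            from_string=True,
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils raises assorted parse errors
        raise FormatError(f"{path}: cannot parse GTF: {exc}") from exc

    order: list[str] = []
    grouped: dict[str, dict] = {}
    for feat in db.features_of_type("CDS", order_by=("seqid", "start")):
        try:
            tx_id = feat.attributes["transcript_id"][0]
        except KeyError as exc:
            raise FormatError(
                f"{path}: CDS line at {feat.seqid}:{feat.start} lacks a transcript_id attribute"
            ) from exc
        gene = feat.attributes.get("gene_name", feat.attributes.get("gene_id", [tx_id]))[0]
        if feat.strand not in ("+", "-"):
            raise FormatError(f"{path}: CDS of {tx_id} has no strand")
        entry = grouped.setdefault(tx_id, {"gene": gene, "chrom": feat.seqid, "strand": feat.strand, "ivals": []})
        if tx_id not in order:
            order.append(tx_id)
        if entry["strand"] != feat.strand:
            raise FormatError(f"{path}: transcript {tx_id} has CDS lines on both strands")
        if entry["chrom"] != feat.seqid:
            raise FormatError(f"{path}: transcript {tx_id} has CDS lines on multiple chromosomes")
        if feat.start > feat.end:
            raise FormatError(f"{path}: CDS of {tx_id} has start > end")
        entry["ivals"].append((feat.start, feat.end))

    return [
        GtfTranscriptRaw(
            transcript_id=tx_id,
            gene_name=grouped[tx_id]["gene"],
            chrom=grouped[tx_id]["chrom"],
            strand=grouped[tx_id]["strand"],
            cds_intervals=tuple(grouped[tx_id]["ivals"]),
        )
        for tx_id in order
    ]
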