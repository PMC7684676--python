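"""Transcript coordinate machinery: spliced CDS extraction, strand-aware
genomic<->CDS<->protein mapping, and translation.

A :class:`TranscriptModel` stores CDS segments as 0-based half-open genomic
intervals sorted in genomic order, regardless of strand. The coding sequence
of a minus-strand transcript is the reverse complement of the concatenated
genomic segments, so CDS index 0 always means the first base of the start
codon in transcript orientation.

CDS phase/frame attributes are ignored: the first base of the 5'-most coding
segment (in transcript orientation) is assumed to be codon position 0. Real
annotations violating this show up as no-ATG / internal-stop flags in the
build report rather than being mis-translated silently. Only the standard
genetic code is supported; UGA is always a stop (no selenocysteine recoding).
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import reverse_complement as _bio_revcomp

from .errors import CoordinateError, ModelError
from .io_formats import GtfTranscriptRaw

_STANDARD_TABLE = unambiguous_dna_by_id[1]
_CODON_TO_AA = dict(_STANDARD_TABLE.forward_table)
for _stop in _STANDARD_TABLE.stop_codons:
    _CODON_TO_AA[_stop] = "*"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return _bio_revcomp(seq)


def complement_base(base: str) -> str:
    return base.translate(_COMPLEMENT)


@dataclass(frozen=True)
class TranscriptModel:
    """Gene model for one transcript: strand plus sorted CDS segments.

    ``cds_segments`` are 0-based half-open genomic intervals in ascending
    genomic order; ``cds_length`` is their total span in nucleotides.
    """

    transcript_id: str
    gene_name: str
    chrom: str
    strand: str
    cds_segments: tuple[tuple[int, int], ...]
    cds_length: int

    @property
    def span(self) -> tuple[int, int]:
        """Genomic footprint (0-based half-open) from first to last CDS base."""
        return self.cds_segments[0][0], self.cds_segments[-1][1]


@dataclass(frozen=True)
class CodingSequence:
    """Spliced CDS nucleotides, 5'->3' in coding orientation."""

    transcript_id: str
    nucleotides: str
    complete_flag: bool  # length divisible by 3


@dataclass(frozen=True)
class ProteinPosition:
    """1-based residue index plus the offset of a base within its codon."""

    residue_index: int
    codon_offset: int

    def __post_init__(self) -> None:
        if self.residue_index < 1:
            raise ValueError("residue_index is 1-based")
        if self.codon_offset not in (0, 1, 2):
            raise ValueError("codon_offset must be 0, 1 or 2")


@dataclass(frozen=True)
class Translation:
    """Protein product plus degeneracy flags (never an exception)."""

    protein: str
    incomplete_codon: bool  # trailing 1-2 bases dropped
    internal_stop: bool  # translation truncated at a premature stop
    starts_with_met: bool


def build_transcript(raw: GtfTranscriptRaw) -> TranscriptModel:
    """Convert a raw GTF transcript to the internal 0-based model.

    1-based inclusive intervals become 0-based half-open, sorted ascending by
    genomic start; overlapping CDS intervals are a model error.
    """
    segments = sorted((start - 1, end) for start, end in raw.cds_intervals)
    for (_, prev_end), (next_start, _) in zip(segments, segments[1:]):
        if next_start < prev_end:
            raise ModelError(f"transcript {raw.transcript_id}: overlapping CDS intervals")
    length = sum(end - start for start, end in segments)
    return TranscriptModel(
        transcript_id=raw.transcript_id,
        gene_name=raw.gene_name,
        chrom=raw.chrom,
        strand=raw.strand,
        cds_segments=tuple(segments),
        cds_length=length,
    )


def extract_cds(tx: TranscriptModel, genome: dict[str, str]) -> CodingSequence:
    """Extract the spliced coding sequence, 5'->3' of the mRNA.

    For minus-strand transcripts this is the reverse complement of the
    concatenated genomic segments. Chromosome-name mismatches are not
    auto-healed: "chr1" and "1" are different sequences here.
    """
    if tx.chrom not in genome:
        raise LookupError(
            f"chromosome {tx.chrom!r} not in genome (note: 'chr'-prefix mismatches are not auto-healed)"
        )
    chrom_seq = genome[tx.chrom]
    parts = []
    for start, end in tx.cds_segments:
        if start < 0 or end > len(chrom_seq):
            raise CoordinateError(
                f"transcript {tx.transcript_id}: CDS segment [{start},{end}) outside {tx.chrom} "
                f"(length {len(chrom_seq)})"
            )
        parts.append(chrom_seq[start:end])
    forward = "".join(parts)
    nucleotides = forward if tx.strand == "+" else reverse_complement(forward)
    return CodingSequence(tx.transcript_id, nucleotides, len(nucleotides) % 3 == 0)


def codon_to_aa(codon: str) -> str:
    """Translate one codon; any codon containing N (or other ambiguity) -> X."""
    return _CODON_TO_AA.get(codon, "X")


def translate(cds: CodingSequence | str) -> Translation:
    """Translate a coding sequence under the standard genetic code.

    Stops at the first stop codon (a premature one sets ``internal_stop``);
    a trailing incomplete codon is dropped with ``incomplete_codon`` set.
    Degenerate inputs produce flags, never exceptions.
    """
    nt = cds.nucleotides if isinstance(cds, CodingSequence) else cds
    n_codons = len(nt) // 3
    incomplete = len(nt) % 3 != 0
    residues: list[str] = []
    internal_stop = False
    for i in range(n_codons):
        aa = codon_to_aa(nt[3 * i : 3 * i + 3])
        if aa == "*":
            # a stop at the final codon position is the normal terminator
            internal_stop = i < n_codons - 1
            break
        residues.append(aa)
    protein = "".join(residues)
    return Translation(
        protein=protein,
        incomplete_codon=incomplete,
        internal_stop=internal_stop,
        starts_with_met=protein.startswith("M"),
    )


def genomic_to_cds_index(tx: TranscriptModel, gpos: int) -> int | None:
    """Map a 0-based genomic position to its 0-based index in the spliced CDS.

    Strand-aware: on the minus strand the CDS counts from the genomic
    3'-most coding base. Returns None for intronic / outside-CDS positions.
    """
    offset = 0
    for start, end in tx.cds_segments:
        if start <= gpos < end:
            forward_index = offset + (gpos - start)
            if tx.strand == "+":
                return forward_index
            return tx.cds_length - 1 - forward_index
        offset += end - start
    return None


def cds_index_to_genomic(tx: TranscriptModel, index: int) -> int:
    """Inverse of :func:`genomic_to_cds_index` (0-based genomic position)."""
    if not 0 <= index < tx.cds_length:
        raise CoordinateError(f"CDS index {index} outside [0,{tx.cds_length})")
    forward_index = index if tx.strand == "+" else tx.cds_length - 1 - index
    offset = 0
    for start, end in tx.cds_segments:
        if forward_index < offset + (end - start):
            return start + (forward_index - offset)
        offset += end - start
    raise AssertionError("unreachable: index within cds_length")


def cds_index_to_protein(index: int) -> ProteinPosition:
    """Codon arithmetic: CDS index -> (1-based residue, offset in codon)."""
    if index < 0:
        raise ValueError("CDS index must be >= 0")
    return ProteinPosition(residue_index=index // 3 + 1, codon_offset=index % 3)
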