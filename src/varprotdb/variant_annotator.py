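"""Codon-level SNV consequence annotation.

Each SNV is classified against each overlapping transcript by rebuilding the
affected codon: the variant's forward-strand alleles are complemented for
minus-strand transcripts, the codon is substituted, and the reference and
alternate codons are translated and compared. Categories:

* ``synonymous`` — same residue (a stop codon mutating to another stop also
  counts as synonymous);
* ``stopgain`` — sense codon to stop;
* ``stoploss`` — stop codon to sense;
* ``startloss`` — residue 1 loses its initiator methionine (a change of M1
  to a stop is a stopgain, since the stop check precedes the start check);
* ``missense`` — any other residue change;
* ``noncoding`` — the position is intronic or outside the CDS.

Protein changes are reported in one-letter HGVS-style shorthand, the form
used for the canonical oncogenic substitutions EGFR p.L858R and BRAF p.V600E.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import ReferenceMismatchError
from .gene_model import (
    ProteinPosition,
    TranscriptModel,
    cds_index_to_protein,
    codon_to_aa,
    complement_base,
    extract_cds,
    genomic_to_cds_index,
)
from .io_formats import SnvVariant

CATEGORIES = ("missense", "synonymous", "stopgain", "stoploss", "startloss", "noncoding")


@dataclass(frozen=True)
class VariantEffect:
    """Consequence of one SNV on one transcript.

    Protein-level fields are None for noncoding effects. For coding effects
    ``ref_codon``/``alt_codon`` are in transcript orientation and ``hgvs_p``
    is always populated.
    """

    variant: SnvVariant
    transcript_id: str
    category: str
    protein_pos: ProteinPosition | None = None
    ref_codon: str | None = None
    alt_codon: str | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None
    hgvs_p: str | None = None


def format_hgvs_p(ref_aa: str, residue_index: int, alt_aa: str) -> str:
    """Render a protein change as p.<ref><pos><alt> shorthand.

    Missense: ``p.L858R``; stopgain: ``p.R123*``; synonymous: ``p.K2=``;
    stoploss keeps ``*`` as the reference residue (``p.*100L``).
    """
    if ref_aa == alt_aa:
        return f"p.{ref_aa}{residue_index}="
    return f"p.{ref_aa}{residue_index}{alt_aa}"


def annotate_variant(
    v: SnvVariant,
    tx: TranscriptModel,
    genome: dict[str, str],
    cds: str | None = None,
) -> VariantEffect:
    """Classify one SNV against one transcript at codon level.

    The genome base at ``v.pos`` must equal ``v.ref_allele``; a mismatch
    raises :class:`ReferenceMismatchError` (the signature of annotating
    against the wrong genome build). ``cds`` may carry a precomputed spliced
    coding sequence to avoid re-extraction in bulk runs.
    """
    if v.chrom != tx.chrom:
        raise ValueError(f"variant on {v.chrom} annotated against transcript on {tx.chrom}")
    genome_base = genome[v.chrom][v.pos - 1]
    if genome_base != v.ref_allele:
        raise ReferenceMismatchError(
            f"{v.chrom}:{v.pos}: VCF REF {v.ref_allele} != genome base {genome_base} "
            "(wrong genome build?)"
        )

    cds_index = genomic_to_cds_index(tx, v.pos - 1)
    if cds_index is None:
        return VariantEffect(variant=v, transcript_id=tx.transcript_id, category="noncoding")

    if cds is None:
        cds = extract_cds(tx, genome).nucleotides
    pp = cds_index_to_protein(cds_index)
    codon_start = (pp.residue_index - 1) * 3
    ref_codon = cds[codon_start : codon_start + 3]
    if len(ref_codon) < 3:
        # dangling incomplete codon at the CDS 3' end: no residue to report
        return VariantEffect(variant=v, transcript_id=tx.transcript_id, category="noncoding")

    if tx.strand == "+":
        alt_base = v.alt_allele
    else:
        alt_base = complement_base(v.alt_allele)
    alt_codon = ref_codon[: pp.codon_offset] + alt_base + ref_codon[pp.codon_offset + 1 :]
    ref_aa = codon_to_aa(ref_codon)
    alt_aa = codon_to_aa(alt_codon)

    if ref_aa == alt_aa:
        category = "synonymous"
    elif alt_aa == "*":
        category = "stopgain"
    elif ref_aa == "*":
        category = "stoploss"
    elif pp.residue_index == 1 and ref_aa == "M":
        category = "startloss"
    else:
        category = "missense"

    if category == "startloss":
        hgvs = "p.M1?"  # initiator lost; downstream effect undefined
    else:
        hgvs = format_hgvs_p(ref_aa, pp.residue_index, alt_aa)

    return VariantEffect(
        variant=v,
        transcript_id=tx.transcript_id,
        category=category,
        protein_pos=pp,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        hgvs_p=hgvs,
    )


def annotate_all(
    variants: Iterable[SnvVariant],
    transcripts: Sequence[TranscriptModel],
    genome: dict[str, str],
) -> tuple[list[VariantEffect], Counter]:
    """Annotate every variant against every overlapping transcript.

    Returns one :class:`VariantEffect` per (variant, overlapping transcript)
    pair plus per-category summary counts. A variant overlapping no
    transcript footprint at all contributes one count to ``noncoding`` in the
    summary (but no effect object), so the summary accounts for every
    variant at least once.
    """
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for tx in transcripts:
        by_chrom.setdefault(tx.chrom, []).append(tx)
    cds_cache: dict[str, str] = {}

    effects: list[VariantEffect] = []
    summary: Counter = Counter({cat: 0 for cat in CATEGORIES})
    for v in variants:
        hit = False
        for tx in by_chrom.get(v.chrom, []):
            start, end = tx.span
            if not (start <= v.pos - 1 < end):
                continue
            hit = True
            if tx.transcript_id not in cds_cache:
                cds_cache[tx.transcript_id] = extract_cds(tx, genome).nucleotides
            effect = annotate_variant(v, tx, genome, cds=cds_cache[tx.transcript_id])
            effects.append(effect)
            summary[effect.category] += 1
        if not hit:
            summary["noncoding"] += 1
    return effects, summary


def effects_to_rows(
    effects: Iterable[VariantEffect], gene_by_transcript: dict[str, str] | None = None
) -> list[dict]:
    """Flatten effects into the fixed TSV column order of the annotate command."""
    gene_by_transcript = gene_by_transcript or {}
    rows = []
    for e in effects:
        rows.append(
            {
                "chrom": e.variant.chrom,
                "pos": e.variant.pos,
                "ref": e.variant.ref_allele,
                "alt": e.variant.alt_allele,
                "transcript_id": e.transcript_id,
                "gene": gene_by_transcript.get(e.transcript_id, ""),
                "category": e.category,
                "protein_pos": e.protein_pos.residue_index if e.protein_pos else "",
                "ref_aa": e.ref_aa or "",
                "alt_aa": e.alt_aa or "",
                "hgvs_p": e.hgvs_p or "",
            }
        )
    return rows
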