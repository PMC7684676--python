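"""Build the customized variant protein database.

The database is a protein FASTA holding the reference proteome (one entry
per translatable transcript, or a user-supplied reference protein FASTA
cross-validated against the genomic translation) followed by one entry per
incorporated variant: a reference protein with exactly one residue
substituted. Missense effects are incorporated by default; stopgain effects
can be opted in as stop-truncated proteins; synonymous and noncoding effects
are never emitted. Indels and frameshifts are out of scope by design — only
single-nucleotide substitutions are incorporated.

Multiple missense variants on the same transcript yield multiple
single-substitution entries, never a combined haplotype protein (phasing is
unavailable from a plain VCF). Deduplication key is (transcript_id, hgvs_p):
the same protein change reached from different genomic variants yields one
entry whose header concatenates all genomic provenance.

Header grammar (bit-exact, parseable by :func:`parse_header`)::

    reference:  >{transcript_id} gene={gene_name}
    variant:    >{transcript_id}|{hgvs_p} gene={gene} var={chrom}:{pos}{ref}>{alt}[;...] class={category}
    decoy:      >rev_{original identifier} ...
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import BuildError, SubstitutionError
from .gene_model import TranscriptModel, extract_cds, translate
from .io_formats import SequenceRecord, SnvVariant, write_fasta
from .variant_annotator import CATEGORIES, VariantEffect, annotate_all


@dataclass(frozen=True)
class VariantProteinEntry:
    """One variant entry of the database: a single-residue substitution.

    ``variants`` carries the genomic provenance (chrom, pos, ref, alt) of
    every SNV that produces this protein change on this transcript.
    """

    base_id: str
    hgvs_p: str
    residues: str
    gene_name: str
    category: str
    variants: tuple[tuple[str, int, str, str], ...]


@dataclass
class BuildOptions:
    """Knobs of the database build (defaults mirror the standard workflow)."""

    include_stopgain: bool = False
    include_reference: bool = True
    wrap_width: int = 60


@dataclass
class BuildReport:
    """Accounting of one build: per-category effect counts plus skips."""

    category_counts: dict = field(default_factory=lambda: {c: 0 for c in CATEGORIES})
    n_reference: int = 0
    n_variant_entries: int = 0
    skipped_ref_mismatch: int = 0
    skipped_protein_mismatch: int = 0
    skipped_untranslatable: int = 0
    flagged_internal_stop: int = 0
    flagged_no_start: int = 0
    flagged_incomplete: int = 0

    def lines(self) -> list[str]:
        out = ["category\tcount"]
        out += [f"{cat}\t{self.category_counts[cat]}" for cat in CATEGORIES]
        out += [
            f"reference_entries\t{self.n_reference}",
            f"variant_entries\t{self.n_variant_entries}",
            f"skipped_ref_mismatch\t{self.skipped_ref_mismatch}",
            f"skipped_protein_mismatch\t{self.skipped_protein_mismatch}",
            f"skipped_untranslatable\t{self.skipped_untranslatable}",
            f"flagged_internal_stop\t{self.flagged_internal_stop}",
            f"flagged_no_start\t{self.flagged_no_start}",
            f"flagged_incomplete\t{self.flagged_incomplete}",
        ]
        return out


def apply_substitution(protein: str, protein_pos: int, ref_aa: str, alt_aa: str) -> str:
    """Substitute one residue, verifying the expected reference residue.

    A mismatch between ``ref_aa`` and the residue actually found signals a
    desynchronization between annotation and protein sequence and raises
    :class:`SubstitutionError`.
    """
    if not 1 <= protein_pos <= len(protein):
        raise SubstitutionError(
            f"position {protein_pos} outside protein of length {len(protein)}"
        )
    found = protein[protein_pos - 1]
    if found != ref_aa:
        raise SubstitutionError(
            f"expected {ref_aa} at position {protein_pos}, found {found}"
        )
    return protein[: protein_pos - 1] + alt_aa + protein[protein_pos:]


def make_header(entry: VariantProteinEntry) -> str:
    """Variant-entry FASTA header; multiple provenance joined with ';'."""
    var = ";".join(f"{c}:{p}{r}>{a}" for c, p, r, a in entry.variants)
    return (
        f"{entry.base_id}|{entry.hgvs_p} gene={entry.gene_name} "
        f"var={var} class={entry.category}"
    )


def make_reference_header(base_id: str, gene_name: str) -> str:
    return f"{base_id} gene={gene_name}"


_VAR_RE = re.compile(
    r"^(?P<base_id>\S+)\|(?P<hgvs>p\.\S+) gene=(?P<gene>\S+) var=(?P<var>\S+) class=(?P<cls>\S+)$"
)
_PROV_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<pos>\d+)(?P<ref>[ACGT])>(?P<alt>[ACGT])$")


def parse_header(header: str) -> dict:
    """Parse a database header back into its fields.

    Returns a dict with ``kind`` in {"reference", "variant", "decoy"}; for
    variant entries also base_id, hgvs_p, gene, class and the provenance list.
    """
    header = header.strip().lstrip(">")
    decoy = header.startswith("rev_")
    m = _VAR_RE.match(header[4:] if decoy else header)
    if m:
        provenance = []
        for token in m.group("var").split(";"):
            pm = _PROV_RE.match(token)
            if not pm:
                raise ValueError(f"malformed var= token {token!r}")
            provenance.append(
                (pm.group("chrom"), int(pm.group("pos")), pm.group("ref"), pm.group("alt"))
            )
        return {
            "kind": "decoy" if decoy else "variant",
            "base_id": m.group("base_id"),
            "hgvs_p": m.group("hgvs"),
            "gene": m.group("gene"),
            "class": m.group("cls"),
            "variants": provenance,
        }
    token = header.split(None, 1)
    gene = None
    if len(token) == 2 and token[1].startswith("gene="):
        gene = token[1][5:]
    return {"kind": "decoy" if decoy else "reference", "base_id": token[0], "gene": gene}


def generate_decoy(entries: Sequence[SequenceRecord], mode: str = "reverse") -> list[SequenceRecord]:
    """One reversed-sequence decoy per target, identifier prefixed ``rev_``."""
    if mode != "reverse":
        raise ValueError(f"unsupported decoy mode {mode!r}")
    if not entries:
        raise ValueError("decoy generation requires at least one target entry")
    return [
        SequenceRecord("rev_" + rec.identifier, rec.description, rec.residues[::-1])
        for rec in entries
    ]


def _translate_reference(
    transcripts: Sequence[TranscriptModel],
    genome: dict[str, str],
    report: BuildReport,
    protein_by_transcript: dict[str, str] | None = None,
) -> dict[str, tuple[str, str]]:
    """Translate every transcript; returns {transcript_id: (protein, gene)}.

    When ``protein_by_transcript`` supplies an external reference protein, the
    genomic translation must match it exactly; mismatching transcripts are
    skipped and counted, never silently substituted.
    """
    proteins: dict[str, tuple[str, str]] = {}
    for tx in transcripts:
        tr = translate(extract_cds(tx, genome))
        if tr.internal_stop:
            report.flagged_internal_stop += 1
        if not tr.starts_with_met:
            report.flagged_no_start += 1
        if tr.incomplete_codon:
            report.flagged_incomplete += 1
        if not tr.protein:
            report.skipped_untranslatable += 1
            continue
        if protein_by_transcript is not None:
            expected = protein_by_transcript.get(tx.transcript_id)
            if expected is not None and expected != tr.protein:
                report.skipped_protein_mismatch += 1
                continue
        proteins[tx.transcript_id] = (tr.protein, tx.gene_name)
    return proteins


def build_database(
    genome: dict[str, str],
    transcripts: Sequence[TranscriptModel],
    variants: Iterable[SnvVariant],
    options: BuildOptions | None = None,
    protein_by_transcript: dict[str, str] | None = None,
) -> tuple[list[SequenceRecord], list[VariantProteinEntry], BuildReport]:
    """Annotate variants and incorporate them into the protein database.

    Returns reference records (sorted by identifier), variant entries (sorted
    by identifier then protein change) and the build report. Every returned
    missense entry is verified to sit at Hamming distance exactly 1 from its
    base protein.
    """
    options = options or BuildOptions()
    report = BuildReport()

    proteins = _translate_reference(transcripts, genome, report, protein_by_transcript)
    if not proteins:
        raise BuildError("no translatable transcripts: cannot build a protein database")
    report.n_reference = len(proteins)

    usable_tx = [tx for tx in transcripts if tx.transcript_id in proteins]
    effects: list[VariantEffect] = []
    good_variants: list[SnvVariant] = []
    for v in variants:
        base = genome.get(v.chrom, "")
        if v.pos > len(base) or base[v.pos - 1] != v.ref_allele:
            # wrong-build signal; counted per variant, build continues
            report.skipped_ref_mismatch += 1
            continue
        good_variants.append(v)
    effects, summary = annotate_all(good_variants, usable_tx, genome)
    report.category_counts = {cat: summary.get(cat, 0) for cat in CATEGORIES}

    # deduplicate by (transcript, protein change); merge genomic provenance
    merged: dict[tuple[str, str], dict] = {}
    for e in effects:
        if e.category == "missense":
            include = True
        elif e.category == "stopgain" and options.include_stopgain:
            include = True
        else:
            include = False
        if not include:
            continue
        base_protein, gene = proteins[e.transcript_id]
        pos = e.protein_pos.residue_index
        if e.category == "missense":
            residues = apply_substitution(base_protein, pos, e.ref_aa, e.alt_aa)
        else:  # stopgain: truncate before the new stop
            if pos - 1 < 1:
                continue  # stop at residue 1 leaves no product
            if base_protein[pos - 1] != e.ref_aa:
                raise SubstitutionError(
                    f"{e.transcript_id} {e.hgvs_p}: expected {e.ref_aa} at {pos}"
                )
            residues = base_protein[: pos - 1]
        key = (e.transcript_id, e.hgvs_p)
        prov = (e.variant.chrom, e.variant.pos, e.variant.ref_allele, e.variant.alt_allele)
        slot = merged.setdefault(
            key, {"residues": residues, "gene": gene, "category": e.category, "prov": set()}
        )
        slot["prov"].add(prov)

    entries = [
        VariantProteinEntry(
            base_id=tx_id,
            hgvs_p=hgvs,
            residues=slot["residues"],
            gene_name=slot["gene"],
            category=slot["category"],
            variants=tuple(sorted(slot["prov"])),
        )
        for (tx_id, hgvs), slot in sorted(merged.items())
    ]
    report.n_variant_entries = len(entries)

    # output invariant: every missense entry is Hamming distance 1 from base
    for entry in entries:
        if entry.category != "missense":
            continue
        base = proteins[entry.base_id][0]
        diff = sum(a != b for a, b in zip(base, entry.residues))
        if len(base) != len(entry.residues) or diff != 1:
            raise BuildError(
                f"internal error: {entry.base_id} {entry.hgvs_p} is not a single substitution"
            )

    reference_records = [
        SequenceRecord(tx_id, f"gene={gene}", protein)
        for tx_id, (protein, gene) in sorted(proteins.items())
    ]
    return reference_records, entries, report


def database_records(
    reference_records: Sequence[SequenceRecord],
    entries: Sequence[VariantProteinEntry],
    options: BuildOptions | None = None,
) -> list[SequenceRecord]:
    """Assemble the final FASTA records: reference section then variants."""
    options = options or BuildOptions()
    records: list[SequenceRecord] = []
    if options.include_reference:
        records.extend(reference_records)
    for entry in entries:
        header = make_header(entry)
        identifier, description = header.split(" ", 1)
        records.append(SequenceRecord(identifier, description, entry.residues))
    return records


def write_database(
    records: Sequence[SequenceRecord], path, wrap_width: int = 60, with_decoy: bool = False
) -> None:
    """Write the database FASTA, optionally appending reversed decoys."""
    out = list(records)
    if with_decoy:
        out.extend(generate_decoy(out))
    write_fasta(out, path, wrap_width=wrap_width)
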