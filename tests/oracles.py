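"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the library's own code paths: consequence calls are
made by mutating the entire chromosome, re-extracting and re-translating the
whole CDS with Biopython; digestion is checked by exhaustively enumerating
all substrings and testing boundary/missed-cleavage/length rules per
substring.
"""

from __future__ import annotations

from Bio.Seq import Seq


def _spliced_cds(chrom_seq: str, segments, strand: str) -> str:
    s = "".join(chrom_seq[a:b] for a, b in segments)
    if strand == "-":
        s = str(Seq(s).reverse_complement())
    return s


def _bio_codon(codon: str) -> str:
    aa = str(Seq(codon).translate())
    return aa  # '*' for stops, 'X' for ambiguous


def oracle_annotate(variant, tx, genome: dict[str, str]):
    """Whole-CDS re-translation oracle.

    Returns (category, residue_index, ref_aa, alt_aa); residue fields are
    None for noncoding calls.
    """
    chrom_seq = genome[variant.chrom]
    assert chrom_seq[variant.pos - 1] == variant.ref_allele
    mutated = chrom_seq[: variant.pos - 1] + variant.alt_allele + chrom_seq[variant.pos :]
    ref_cds = _spliced_cds(chrom_seq, tx.cds_segments, tx.strand)
    alt_cds = _spliced_cds(mutated, tx.cds_segments, tx.strand)
    if ref_cds == alt_cds:
        return ("noncoding", None, None, None)
    diffs = [i for i, (a, b) in enumerate(zip(ref_cds, alt_cds)) if a != b]
    assert len(diffs) == 1, "an SNV must change exactly one CDS base"
    residue = diffs[0] // 3 + 1
    ref_codon = ref_cds[residue * 3 - 3 : residue * 3]
    alt_codon = alt_cds[residue * 3 - 3 : residue * 3]
    if len(ref_codon) < 3:
        return ("noncoding", None, None, None)
    ref_aa, alt_aa = _bio_codon(ref_codon), _bio_codon(alt_codon)
    if ref_aa == alt_aa:
        category = "synonymous"
    elif alt_aa == "*":
        category = "stopgain"
    elif ref_aa == "*":
        category = "stoploss"
    elif residue == 1 and ref_aa == "M":
        category = "startloss"
    else:
        category = "missense"
    return (category, residue, ref_aa, alt_aa)


def oracle_cleavage_sites(residues: str, enzymes=("trypsin", "lysc"), kp_cut: bool = True):
    """Residue-by-residue scan of the trypsin/LysC cutting rules."""
    enzymes = set(enzymes)
    sites = set()
    for i, res in enumerate(residues[:-1]):
        following = residues[i + 1]
        if "trypsin" in enzymes and res in ("K", "R") and following != "P":
            sites.add(i + 1)
        if "lysc" in enzymes and res == "K":
            if kp_cut or following != "P":
                sites.add(i + 1)
    return sorted(sites)


def oracle_digest(protein: str, max_missed: int = 1, min_length: int = 7,
                  max_length: int | None = None, enzymes=("trypsin", "lysc"),
                  kp_cut: bool = True):
    """Exhaustive substring enumeration checked against the cutting rules.

    Returns the set of (sequence, start, end, missed_cleavages) with 1-based
    inclusive coordinates.
    """
    n = len(protein)
    sites = set(oracle_cleavage_sites(protein, enzymes, kp_cut))
    boundaries = sites | {0, n}
    peptides = set()
    for i in range(n):
        for j in range(i + 1, n + 1):
            if i not in boundaries or j not in boundaries:
                continue
            internal = sum(1 for s in sites if i < s < j)
            if internal > max_missed:
                continue
            length = j - i
            if length < min_length or (max_length is not None and length > max_length):
                continue
            peptides.add((protein[i:j], i + 1, j, internal))
    return peptides
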