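"""In-silico proteolysis and variant/wild-type peptide pairing.

Default digestion parameters mirror a standard trypsin + LysC shotgun
workflow: cleave C-terminal to every K and to every R not followed by P, at
most one missed cleavage, minimum peptide length seven residues, no maximum.
Because LysC cleaves lysine even before proline, K-P bonds ARE cut when LysC
is active; this behaviour is exposed as the ``kp_cut`` switch.

A variant peptide is a peptide of the variant protein that covers the
substituted residue and is absent (as a bare sequence) from the reference
digest. Each variant peptide is paired, by coordinate overlap, with the
wild-type peptide(s) of the reference digest spanning the same region; when
the substitution creates or destroys a cleavage site the pairing can be
many-to-one. Peptides are compared as bare sequences — modifications are a
search-engine concern, not modelled here.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

VALID_ENZYMES = frozenset({"trypsin", "lysc"})


@dataclass(frozen=True)
class DigestParams:
    """Proteolysis settings.

    ``enzymes`` is a subset of {trypsin, lysc}; ``kp_cut`` controls whether a
    K-P bond is cleaved (true when LysC is active in the standard workflow).
    """

    enzymes: frozenset = frozenset({"trypsin", "lysc"})
    max_missed_cleavages: int = 1
    min_length: int = 7
    max_length: int | None = None
    kp_cut: bool = True

    def __post_init__(self) -> None:
        if not self.enzymes or not set(self.enzymes) <= VALID_ENZYMES:
            raise ValueError(f"enzymes must be a non-empty subset of {sorted(VALID_ENZYMES)}")
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages must be >= 0")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.max_length is not None and self.max_length < self.min_length:
            raise ValueError("max_length must be >= min_length")


@dataclass(frozen=True)
class Peptide:
    """A proteolytic fragment located within its parent protein.

    ``start``/``end`` are 1-based inclusive positions in the parent;
    ``variant_offset`` (variant peptides only) is the 1-based position of the
    substituted residue within the peptide.
    """

    residues: str
    start: int
    end: int
    missed_cleavages: int
    parent_id: str = ""
    is_variant: bool = False
    variant_offset: int | None = None

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.residues):
            raise ValueError("peptide coordinates inconsistent with its length")
        if self.is_variant and not (
            self.variant_offset is not None and 1 <= self.variant_offset <= len(self.residues)
        ):
            raise ValueError("variant peptide must locate its substituted residue")

    @property
    def has_ambiguous_residue(self) -> bool:
        return "X" in self.residues

    def covers(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class PeptidePair:
    """A variant peptide with its coordinate-matched wild-type peptide(s)."""

    parent_id: str
    hgvs_p: str
    variant_peptide: Peptide
    wildtype_peptides: tuple[Peptide, ...] = field(default=())


def cleavage_sites(
    residues: str, enzymes: Iterable[str] = ("trypsin", "lysc"), kp_cut: bool = True
) -> list[int]:
    """After-residue cut positions (1-based), strictly increasing.

    Trypsin cuts after K/R except before P; LysC cuts after K (before P too
    when ``kp_cut``). The protein C-terminus is never listed as a site.
    """
    enzymes = set(enzymes)
    if not enzymes or not enzymes <= VALID_ENZYMES:
        raise ValueError(f"enzymes must be a non-empty subset of {sorted(VALID_ENZYMES)}")
    sites: list[int] = []
    for i in range(len(residues) - 1):
        res, nxt = residues[i], residues[i + 1]
        cut = False
        if "trypsin" in enzymes and res in "KR" and nxt != "P":
            cut = True
        if "lysc" in enzymes and res == "K" and (kp_cut or nxt != "P"):
            cut = True
        if cut:
            sites.append(i + 1)
    return sites


def digest(protein: str, params: DigestParams | None = None, parent_id: str = "") -> list[Peptide]:
    """Enumerate peptides spanning at most ``max_missed_cleavages`` sites.

    Peptides are the substrings delimited by consecutive cut positions (and
    the protein termini); fragments shorter than ``min_length`` or longer
    than ``max_length`` are filtered out.
    """
    params = params or DigestParams()
    sites = cleavage_sites(protein, params.enzymes, params.kp_cut)
    boundaries = [0] + sites + [len(protein)]
    peptides: list[Peptide] = []
    for k in range(len(boundaries) - 1):
        for m in range(k + 1, min(k + 2 + params.max_missed_cleavages, len(boundaries))):
            start, end = boundaries[k], boundaries[m]
            length = end - start
            if length < params.min_length:
                continue
            if params.max_length is not None and length > params.max_length:
                continue
            peptides.append(
                Peptide(
                    residues=protein[start:end],
                    start=start + 1,
                    end=end,
                    missed_cleavages=m - k - 1,
                    parent_id=parent_id,
                )
            )
    return peptides


def _substituted_position(reference: str, variant: str) -> int:
    """1-based position of the single differing residue (Hamming distance 1)."""
    if len(reference) != len(variant):
        raise ValueError("reference and variant proteins differ in length")
    diffs = [i for i, (a, b) in enumerate(zip(reference, variant)) if a != b]
    if len(diffs) != 1:
        raise ValueError(f"expected exactly one substitution, found {len(diffs)}")
    return diffs[0] + 1


def variant_peptides(
    reference_protein: str,
    variant_protein: str,
    params: DigestParams | None = None,
    parent_id: str = "",
    hgvs_p: str = "",
) -> list[PeptidePair]:
    """Variant peptides of a single-substitution protein, paired with wild type.

    Variant peptides must cover the substituted residue and be absent from
    the reference digest; wild-type partners are the reference peptides whose
    coordinates overlap the variant peptide. An empty list means the
    substitution produced no observable variant peptide under the length and
    missed-cleavage filters (e.g. a created cut site leaving only short
    fragments).
    """
    params = params or DigestParams()
    position = _substituted_position(reference_protein, variant_protein)
    ref_digest = digest(reference_protein, params, parent_id=parent_id)
    ref_sequences = {p.residues for p in ref_digest}
    pairs: list[PeptidePair] = []
    for pep in digest(variant_protein, params, parent_id=parent_id):
        if not pep.covers(position) or pep.residues in ref_sequences:
            continue
        marked = Peptide(
            residues=pep.residues,
            start=pep.start,
            end=pep.end,
            missed_cleavages=pep.missed_cleavages,
            parent_id=parent_id,
            is_variant=True,
            variant_offset=position - pep.start + 1,
        )
        partners = tuple(
            q for q in ref_digest if q.start <= marked.end and marked.start <= q.end
        )
        pairs.append(PeptidePair(parent_id, hgvs_p, marked, partners))
    return pairs


PEPTIDE_TABLE_COLUMNS = (
    "serial",
    "parent_id",
    "hgvs_p",
    "variant_peptide",
    "start",
    "end",
    "missed_cleavages",
    "paired_wildtype_peptides",
)


def export_peptide_table(pairs: Sequence[PeptidePair], path: str | Path) -> None:
    """Write variant/wild-type pairs as a TSV with a fixed column order."""
    with open(path, "wt", encoding="ascii", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(PEPTIDE_TABLE_COLUMNS)
        for serial, pair in enumerate(pairs, start=1):
            vp = pair.variant_peptide
            writer.writerow(
                [
                    serial,
                    pair.parent_id,
                    pair.hgvs_p,
                    vp.residues,
                    vp.start,
                    vp.end,
                    vp.missed_cleavages,
                    ";".join(q.residues for q in pair.wildtype_peptides),
                ]
            )


def read_peptide_table(path: str | Path) -> pd.DataFrame:
    """Read an exported peptide table back into a DataFrame."""
    return pd.read_csv(path, sep="\t", dtype={"paired_wildtype_peptides": "string"})
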