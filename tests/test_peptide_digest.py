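"""Proteolysis rules versus an exhaustive substring oracle, and the
variant/wild-type peptide pairing contracts."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from varprotdb.peptide_digest import (
    DigestParams,
    cleavage_sites,
    digest,
    export_peptide_table,
    read_peptide_table,
    variant_peptides,
)

from .conftest import AMINO_ACIDS, random_protein
from .oracles import oracle_cleavage_sites, oracle_digest

proteins = st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=120)


def as_tuples(peptides):
    return {(p.residues, p.start, p.end, p.missed_cleavages) for p in peptides}


class TestCleavageSites:
    def test_rp_bond_protected_terminal_r_not_a_site(self):
        assert cleavage_sites("MAAKGGGRPGGGR") == [4]

    def test_kp_bond_cut_by_lysc(self):
        assert cleavage_sites("MKPR") == [2]

    def test_kp_protected_when_lysc_absent(self):
        assert cleavage_sites("MKPR", enzymes=("trypsin",)) == []

    def test_kp_cut_switch(self):
        assert cleavage_sites("MKPR", kp_cut=False) == []

    def test_no_basic_residues_no_sites(self):
        assert cleavage_sites("MAGICALLYQWET".replace("L", "G")) == []

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(proteins, st.booleans())
    def test_matches_residue_scan_oracle(self, protein, kp):
        assert cleavage_sites(protein, kp_cut=kp) == oracle_cleavage_sites(protein, kp_cut=kp)


class TestDigest:
    def test_short_protein_filtered_out(self):
        assert digest("MAGIC", DigestParams()) == []

    def test_zero_missed_peptides_partition_protein(self, rng):
        params = DigestParams(max_missed_cleavages=1, min_length=1)
        for _ in range(20):
            protein = random_protein(rng, rng.randint(10, 150))
            fragments = sorted(
                (p for p in digest(protein, params) if p.missed_cleavages == 0),
                key=lambda p: p.start,
            )
            assert "".join(p.residues for p in fragments) == protein
            assert fragments[0].start == 1 and fragments[-1].end == len(protein)

    def test_equals_exhaustive_substring_oracle_on_random_proteins(self, rng):
        params = DigestParams()  # trypsin+LysC, <=1 missed, min length 7
        for _ in range(100):
            protein = random_protein(rng, rng.randint(1, 200))
            assert as_tuples(digest(protein, params)) == oracle_digest(protein)

    def test_oracle_agreement_with_max_length_and_more_missed(self, rng):
        params = DigestParams(max_missed_cleavages=2, min_length=5, max_length=30)
        for _ in range(30):
            protein = random_protein(rng, rng.randint(1, 150))
            assert as_tuples(digest(protein, params)) == oracle_digest(
                protein, max_missed=2, min_length=5, max_length=30
            )

    def test_determinism(self, rng):
        protein = random_protein(rng, 120)
        assert digest(protein) == digest(protein)


def substitute(protein, pos, alt):
    return protein[: pos - 1] + alt + protein[pos:]


class TestVariantPeptides:
    def test_site_preserving_substitution_changes_only_covering_peptides(self, rng):
        params = DigestParams()
        done = 0
        while done < 40:
            protein = random_protein(rng, rng.randint(40, 200))
            pos = rng.randint(1, len(protein))
            ref = protein[pos - 1]
            if ref in "KRP":
                continue
            alt = rng.choice([a for a in AMINO_ACIDS if a not in "KRP" and a != ref])
            variant = substitute(protein, pos, alt)
            diff = as_tuples(digest(protein, params)) ^ as_tuples(digest(variant, params))
            assert all(start <= pos <= end for _, start, end, _ in diff)
            done += 1

    def test_created_cut_site_yields_new_short_fragments(self):
        protein = "M" + "A" * 20 + "Q" + "A" * 20 + "K" + "A" * 10
        pos = 22  # the Q
        variant = substitute(protein, pos, "K")
        pairs = variant_peptides(protein, variant, DigestParams(), parent_id="p", hgvs_p="p.Q22K")
        assert pairs, "a created lysine site must produce variant peptides"
        ref_seqs = {p.residues for p in digest(protein, DigestParams())}
        for pair in pairs:
            assert pair.variant_peptide.residues not in ref_seqs
            assert pair.variant_peptide.covers(pos)

    def test_every_variant_peptide_contains_the_substituted_residue(self, rng):
        params = DigestParams()
        for _ in range(40):
            protein = random_protein(rng, rng.randint(30, 150))
            pos = rng.randint(1, len(protein))
            alt = rng.choice([a for a in AMINO_ACIDS if a != protein[pos - 1]])
            variant = substitute(protein, pos, alt)
            for pair in variant_peptides(protein, variant, params):
                vp = pair.variant_peptide
                assert vp.covers(pos)
                assert vp.variant_offset == pos - vp.start + 1
                assert vp.residues[vp.variant_offset - 1] == alt

    def test_wildtype_partners_overlap_variant_coordinates(self, rng):
        params = DigestParams()
        for _ in range(25):
            protein = random_protein(rng, rng.randint(40, 150))
            pos = rng.randint(1, len(protein))
            alt = rng.choice([a for a in AMINO_ACIDS if a != protein[pos - 1]])
            for pair in variant_peptides(protein, substitute(protein, pos, alt), params):
                vp = pair.variant_peptide
                for wt in pair.wildtype_peptides:
                    assert wt.start <= vp.end and vp.start <= wt.end

    def test_length_filter_applies_to_variant_fragments(self):
        # a cut created near the terminus strands fragments under 7 residues;
        # they must be excluded, possibly leaving no variant peptide at all
        protein = "MAAAAAAAAAK" + "AAAAA"  # 5-residue tail after the K site
        variant = substitute(protein, 14, "K")  # splits the tail further
        pairs = variant_peptides(protein, variant, DigestParams())
        for pair in pairs:
            assert len(pair.variant_peptide.residues) >= 7
        strict = variant_peptides(protein, variant, DigestParams(max_missed_cleavages=0))
        assert strict == []  # all site-spanning fragments fall under the minimum


class TestExportTable:
    def test_empty_pair_set_writes_header_only(self, tmp_path):
        p = tmp_path / "t.tsv"
        export_peptide_table([], p)
        assert p.read_text().count("\n") == 1
        assert read_peptide_table(p).empty

    def test_round_trip_recovers_fields(self, tmp_path, rng):
        protein = random_protein(rng, 80)
        pos = 40
        alt = rng.choice([a for a in AMINO_ACIDS if a != protein[39]])
        pairs = variant_peptides(
            protein, substitute(protein, pos, alt), DigestParams(),
            parent_id="TX0001", hgvs_p=f"p.{protein[39]}40{alt}",
        )
        p = tmp_path / "t.tsv"
        export_peptide_table(pairs, p)
        df = read_peptide_table(p)
        assert len(df) == len(pairs)
        if pairs:
            assert df.loc[0, "parent_id"] == "TX0001"
            assert df.loc[0, "variant_peptide"] == pairs[0].variant_peptide.residues
            assert int(df.loc[0, "start"]) == pairs[0].variant_peptide.start
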