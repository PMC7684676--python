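"""Database assembly: substitution, dedup, headers, decoys, determinism."""

import pytest

from varprotdb.db_builder import (
    BuildOptions,
    VariantProteinEntry,
    apply_substitution,
    build_database,
    database_records,
    generate_decoy,
    make_header,
    parse_header,
    write_database,
)
from varprotdb.errors import BuildError, SubstitutionError
from varprotdb.io_formats import SequenceRecord, SnvVariant, read_fasta


class TestApplySubstitution:
    def test_l858r_on_long_synthetic_protein(self):
        protein = "A" * 857 + "L" + "G" * 42  # L at residue 858, 900 residues
        result = apply_substitution(protein, 858, "L", "R")
        assert len(result) == len(protein)
        assert result[857] == "R"
        assert sum(a != b for a, b in zip(protein, result)) == 1

    def test_boundary_position_one(self):
        assert apply_substitution("MKR", 1, "M", "V") == "VKR"

    def test_mismatch_guard(self):
        with pytest.raises(SubstitutionError):
            apply_substitution("MKR", 2, "R", "Q")

    def test_position_outside_protein(self):
        with pytest.raises(SubstitutionError):
            apply_substitution("MKR", 9, "K", "Q")


class TestHeaders:
    ENTRY = VariantProteinEntry(
        base_id="NM_0001",
        hgvs_p="p.L858R",
        residues="MKR" * 10,
        gene_name="EGFR",
        category="missense",
        variants=(("chr7", 55259515, "T", "G"),),
    )

    def test_variant_header_format(self):
        assert make_header(self.ENTRY) == (
            "NM_0001|p.L858R gene=EGFR var=chr7:55259515T>G class=missense"
        )

    def test_reference_header_format(self):
        rec = SequenceRecord("NM_0002", "gene=BRAF", "MV")
        parsed = parse_header(f"{rec.identifier} {rec.description}")
        assert parsed == {"kind": "reference", "base_id": "NM_0002", "gene": "BRAF"}

    def test_header_round_trip_recovers_all_fields(self):
        parsed = parse_header(">" + make_header(self.ENTRY))
        assert parsed["kind"] == "variant"
        assert parsed["base_id"] == self.ENTRY.base_id
        assert parsed["hgvs_p"] == self.ENTRY.hgvs_p
        assert parsed["gene"] == self.ENTRY.gene_name
        assert parsed["class"] == self.ENTRY.category
        assert parsed["variants"] == [("chr7", 55259515, "T", "G")]

    def test_multi_provenance_round_trip(self):
        entry = VariantProteinEntry(
            base_id="TX1", hgvs_p="p.K2Q", residues="MQ" * 5, gene_name="G1",
            category="missense",
            variants=(("chr1", 10, "A", "C"), ("chr1", 12, "A", "G")),
        )
        parsed = parse_header(make_header(entry))
        assert parsed["variants"] == [("chr1", 10, "A", "C"), ("chr1", 12, "A", "G")]


class TestDecoy:
    TARGETS = [SequenceRecord("p1", "", "MKR"), SequenceRecord("p2", "d", "WYECK")]

    def test_reversal_and_prefix(self):
        decoys = generate_decoy(self.TARGETS)
        assert decoys[0].residues == "RKM"
        assert all(d.identifier.startswith("rev_") for d in decoys)

    def test_count_bijection(self):
        assert len(generate_decoy(self.TARGETS)) == len(self.TARGETS)

    def test_involution_restores_targets(self):
        twice = generate_decoy(generate_decoy(self.TARGETS))
        assert [d.residues for d in twice] == [t.residues for t in self.TARGETS]


class TestBuildDatabase:
    def test_empty_vcf_is_byte_identical_to_reference_only(self, small_inputs, tmp_path):
        genome, txs = small_inputs["genome"], small_inputs["transcripts"]
        refs_a, entries_a, _ = build_database(genome, txs, [])
        assert entries_a == []
        refs_b, entries_b, _ = build_database(genome, txs, small_inputs["variants"])
        pa, pb = tmp_path / "a.fa", tmp_path / "b.fa"
        write_database(database_records(refs_a, entries_a), pa)
        write_database(database_records(refs_b, []), pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_planted_missense_recovered_with_hamming_distance_one(self, small_inputs):
        refs, entries, report = build_database(
            small_inputs["genome"], small_inputs["transcripts"], small_inputs["variants"]
        )
        truth = {(t.transcript_id, t.hgvs_p) for t in small_inputs["truth"] if t.category == "missense"}
        assert {(e.base_id, e.hgvs_p) for e in entries} == truth
        base = {r.identifier: r.residues for r in refs}
        for e in entries:
            ref_protein = base[e.base_id]
            assert len(ref_protein) == len(e.residues)
            assert sum(a != b for a, b in zip(ref_protein, e.residues)) == 1

    def test_synonymous_only_vcf_yields_zero_entries(self, small_inputs):
        synonymous = [
            SnvVariant(t.chrom, t.pos, t.ref, t.alt)
            for t in small_inputs["truth"]
            if t.category == "synonymous"
        ]
        _, entries, report = build_database(
            small_inputs["genome"], small_inputs["transcripts"], synonymous
        )
        assert entries == []
        assert report.category_counts["synonymous"] == len(synonymous)

    def test_stopgain_excluded_by_default_included_on_option(self, small_inputs):
        stopgains = [
            t for t in small_inputs["truth"] if t.category == "stopgain"
        ]
        variants = [SnvVariant(t.chrom, t.pos, t.ref, t.alt) for t in stopgains]
        genome, txs = small_inputs["genome"], small_inputs["transcripts"]
        _, default_entries, _ = build_database(genome, txs, variants)
        assert default_entries == []
        refs, entries, _ = build_database(
            genome, txs, variants, BuildOptions(include_stopgain=True)
        )
        assert {(e.base_id, e.hgvs_p) for e in entries} == {
            (t.transcript_id, t.hgvs_p) for t in stopgains
        }
        base = {r.identifier: r.residues for r in refs}
        for e in entries:
            assert len(e.residues) < len(base[e.base_id])  # truncated product
            assert base[e.base_id].startswith(e.residues)

    def test_ref_mismatch_counted_not_fatal(self, small_inputs):
        genome, txs = small_inputs["genome"], small_inputs["transcripts"]
        good = small_inputs["truth"][0]
        chrom_seq = genome[good.chrom]
        bad_ref = next(b for b in "ACGT" if b != chrom_seq[good.pos - 1])
        alt = next(b for b in "ACGT" if b not in (bad_ref,))
        bad = SnvVariant(good.chrom, good.pos, bad_ref, alt)
        _, _, report = build_database(genome, txs, [bad])
        assert report.skipped_ref_mismatch == 1

    def test_category_counts_conserve_effects(self, small_inputs):
        _, entries, report = build_database(
            small_inputs["genome"], small_inputs["transcripts"], small_inputs["variants"]
        )
        planted = small_inputs["config"].planted
        assert sum(report.category_counts.values()) == sum(planted.values())
        assert report.n_variant_entries == len(entries) == planted["missense"]

    def test_dedup_key_is_transcript_and_protein_change(self):
        genome = {"chr1": "ATGTTATAA"}  # M L *
        from varprotdb.gene_model import TranscriptModel

        tx = TranscriptModel("TX1", "G1", "chr1", "+", ((0, 9),), 9)
        # the same record listed twice must collapse to one entry
        v = SnvVariant("chr1", 5, "T", "C")  # TTA(L) -> TCA(S)
        _, entries, _ = build_database(genome, [tx], [v, v])
        assert len(entries) == 1
        assert entries[0].hgvs_p == "p.L2S"

    def test_zero_translatable_transcripts_is_build_error(self):
        genome = {"chr1": "TAATAATAA"}
        from varprotdb.gene_model import TranscriptModel

        tx = TranscriptModel("TX1", "G1", "chr1", "+", ((0, 9),), 9)
        with pytest.raises(BuildError):
            build_database(genome, [tx], [])

    def test_protein_validation_skips_mismatching_transcript(self, small_inputs):
        genome, txs = small_inputs["genome"], small_inputs["transcripts"]
        refs, _, _ = build_database(genome, txs, [])
        provided = {r.identifier: r.residues for r in refs}
        victim = txs[0].transcript_id
        provided[victim] = "M" + "A" * 50  # wrong on purpose
        refs2, _, report = build_database(genome, txs, [], protein_by_transcript=provided)
        assert report.skipped_protein_mismatch == 1
        assert victim not in {r.identifier for r in refs2}

    def test_builds_are_byte_deterministic(self, small_inputs, tmp_path):
        genome, txs = small_inputs["genome"], small_inputs["transcripts"]
        out = []
        for name in ("x.fa", "y.fa"):
            refs, entries, _ = build_database(genome, txs, small_inputs["variants"])
            p = tmp_path / name
            write_database(database_records(refs, entries), p, with_decoy=True)
            out.append(p.read_bytes())
        assert out[0] == out[1]

    def test_database_fasta_round_trips_through_reader(self, small_inputs, tmp_path):
        genome, txs = small_inputs["genome"], small_inputs["transcripts"]
        refs, entries, report = build_database(genome, txs, small_inputs["variants"])
        p = tmp_path / "db.fa"
        write_database(database_records(refs, entries), p)
        records = read_fasta(p, alphabet="protein")
        kinds = [parse_header(r.identifier + " " + r.description)["kind"] for r in records]
        assert kinds.count("reference") == report.n_reference
        assert kinds.count("variant") == report.n_variant_entries
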