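import random

import pytest

from varprotdb.gene_model import build_transcript
from varprotdb.io_formats import genome_as_dict, read_fasta, read_gtf_transcripts, read_vcf_snvs
from varprotdb.synthetic_data import (
    SimulationConfig,
    plant_variants,
    read_truth_table,
    simulate_reference,
    simulate_to_dir,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture
def rng():
    return random.Random(20240917)


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A modest deterministic dataset shared by read-only tests."""
    out = tmp_path_factory.mktemp("sim")
    config = SimulationConfig(
        n_chromosomes=2,
        chromosome_length=40_000,
        n_genes=12,
        fraction_minus_strand=0.5,
        planted={"missense": 30, "synonymous": 20, "stopgain": 5, "noncoding": 10},
        seed=11,
    )
    paths = simulate_to_dir(config, out)
    return config, paths


@pytest.fixture(scope="session")
def small_inputs(small_sim):
    """Parsed genome/transcripts/variants/truth of the shared dataset."""
    config, paths = small_sim
    genome = genome_as_dict(read_fasta(paths["genome"]))
    transcripts = [build_transcript(raw) for raw in read_gtf_transcripts(paths["gtf"])]
    variants, skip_report = read_vcf_snvs(paths["vcf"])
    truth = read_truth_table(paths["truth"])
    return {
        "config": config,
        "paths": paths,
        "genome": genome,
        "transcripts": transcripts,
        "variants": variants,
        "skip_report": skip_report,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def strand_mix_models():
    """In-memory genome + transcripts with both strands and multi-exon genes."""
    config = SimulationConfig(
        n_chromosomes=1,
        chromosome_length=60_000,
        n_genes=15,
        exons_per_gene=(1, 5),
        fraction_minus_strand=0.5,
        planted={"missense": 0, "synonymous": 0, "stopgain": 0, "noncoding": 0},
        seed=23,
    )
    genome_records, raws = simulate_reference(config)
    genome = genome_as_dict(genome_records)
    models = [build_transcript(raw) for raw in raws]
    return genome, models


def random_protein(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(AMINO_ACIDS) for _ in range(length))
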