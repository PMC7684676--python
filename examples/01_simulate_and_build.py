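"""Simulate a small genome with planted SNVs and build the variant database.

Prints the build report and the first few database headers. The variant
entry count should equal the number of planted missense variants: only
amino-acid-changing SNVs are incorporated.
"""

import tempfile
from pathlib import Path

from varprotdb import (
    SimulationConfig,
    build_database,
    build_transcript,
    database_records,
    genome_as_dict,
    make_header,
    read_fasta,
    read_gtf_transcripts,
    read_vcf_snvs,
    simulate_to_dir,
    write_database,
)

workdir = Path(tempfile.mkdtemp(prefix="varprotdb_example_"))
config = SimulationConfig(
    n_genes=10,
    chromosome_length=30_000,
    planted={"missense": 12, "synonymous": 6, "stopgain": 2, "noncoding": 4},
    seed=1,
)
paths = simulate_to_dir(config, workdir)
print(f"simulated inputs in {workdir}")

genome = genome_as_dict(read_fasta(paths["genome"]))
transcripts = [build_transcript(r) for r in read_gtf_transcripts(paths["gtf"])]
variants, skips = read_vcf_snvs(paths["vcf"])

refs, entries, report = build_database(genome, transcripts, variants)
db_path = workdir / "db.fasta"
write_database(database_records(refs, entries), db_path, with_decoy=True)

print(f"reference proteins: {report.n_reference}")
print(f"variant entries:    {report.n_variant_entries}  (planted missense: 12)")
print("per-category effect counts:", report.category_counts)
print("\nfirst variant headers (transcript|change, provenance, class):")
for entry in entries[:3]:
    print(" ", make_header(entry))
print(f"\ndatabase with decoys written to {db_path}")
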