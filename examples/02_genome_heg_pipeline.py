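"""Run the full genome branch: ORF calling, HEG search, statistics.

Builds a synthetic reference database (10 HEG families), plants exact
back-translations of the family masters in a synthetic genome, then runs
the pipeline: the ORF caller proposes coding regions, the translated
Smith-Waterman search picks the best CDS per family, and the codon
statistics are written to usage.csv / hegs.fasta.
"""

from pathlib import Path
from tempfile import TemporaryDirectory

from hegcodon.cli import RunConfig, run_profile
from hegcodon.io_seq import CdsRecord, write_fasta
from hegcodon.synth import (make_reference_db, plant_genome, uniform_spec,
                            write_reference_fasta)

db = make_reference_db(n_families=10, per_family=2, seed=7)
masters = [e.seq for e in db.entries if e.protein_id.endswith("_1")]
genome, truth = plant_genome(uniform_spec(seed=3), intergenic_len=100,
                             seed=3, proteins=masters)

with TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    write_reference_fasta(db, tmp / "ref.faa")
    write_fasta([CdsRecord(id=c, seq=s) for c, s in genome],
                tmp / "genome.fna")
    table, hits = run_profile(RunConfig(
        input_path=str(tmp / "genome.fna"), input_kind="genome",
        refdb_path=str(tmp / "ref.faa"), output_dir=str(tmp / "out")))

print(f"genome length: {len(genome[0][1])} nt, planted genes: "
      f"{len(truth)}")
print(f"HEG families recovered: {len(hits)} of {len(db.families)}")
for h in hits[:3]:
    print(f"  {h.family_id}: {h.cds_id}  bitscore={h.bitscore:.1f} "
          f"E={h.evalue:.2e}")
print(f"sense codons counted over the HEG set: "
      f"{table.n_codons_counted}")

# Every planted family should be found with a huge bitscore and a
# vanishing E-value; the usage table aggregates codon counts over the
# recovered HEG sequences only.
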