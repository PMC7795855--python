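"""Generate a seeded synthetic whole-transcriptome dataset with planted truth.

The generator emulates a 2-tissue x 2-condition x 3-replicate salt-stress
design: a random genome with mRNA/lncRNA/circRNA gene models, mature miRNAs
with planted cleavage and target-mimic sites, NB count matrices with planted
differential expression and ceRNA-triplet correlation, and a degradome
profile with peaks at the planted cleavage positions.
"""

from collections import Counter

from cernet.synthetic import generate_dataset, write_dataset

ds = generate_dataset(seed=1)

print(f"genome: {len(ds.genome['chr1']):,} nt on 1 chromosome")
print("transcripts:", Counter(t.biotype for t in ds.transcripts))
print(f"miRNAs: {len(ds.mirnas)} (lengths {sorted({len(s) for _, s in ds.mirnas})})")
print(
    f"planted truth: {len(ds.truth.planted_cleavage)} cleavage sites, "
    f"{len(ds.truth.planted_mimics)} mimic sites, "
    f"{len(ds.truth.planted_de)} DE features, "
    f"{len(ds.truth.planted_cerna_triplets)} ceRNA triplets"
)
write_dataset(ds, "scratch_dataset")
print("wrote FASTA/GFF3/TSV inputs + truth.json to scratch_dataset/")
# Every downstream stage can be tested against truth.json: the generator's
# point is that planted structure is recoverable by the pipeline.
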