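# "JW81-like" fixture: wild-type-Kras leukemia whose relapse under combined
# MEK/PI3K inhibition is driven by a de novo Pten-class mutation (absent from
# the primary tumor) inside its own CN-LOH, at the cost of the ancestral
# Notch1-mutant clone.
seed: 81
n_chromosomes: 3
chrom_length_bp: 60000000
snp_density: 1.0
mean_depth_normal: 120.0
mean_depth_tumor: 140.0
purity_primary: 0.92
purity_relapse: 0.92
target_mb: 50.0
bin_size_bp: 2000000
error_rate: 0.001
overdispersion: 0.0
events:
  - {chrom: chr3, start: 1, end: 60000000, kind: CN_LOH, haplotype: S129, clone_ids: [resistant]}
clones:
  - clone_id: ancestral
    fraction_primary: 1.0
    fraction_relapse: 0.4
    mutations:
      - {chrom: chr2, pos: 40000000, gene: Notch1, multiplicity: 1}
      - {chrom: chr1, pos: 15000000, gene: Myb, multiplicity: 1}
  - clone_id: resistant
    fraction_primary: 0.0
    fraction_relapse: 0.6
    mutations:
      - {chrom: chr3, pos: 30000000, gene: Pten, multiplicity: 2}
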