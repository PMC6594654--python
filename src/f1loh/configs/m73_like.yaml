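# "73M-like" fixture: Kras-driven leukemia whose primary tumor carries a
# duplicated mutant driver inside chromosome-scale copy-neutral LOH, with a
# pre-existing minor resistant subclone (het driver + its own CN-LOH around a
# Pten-class mutation) that takes over at relapse, restoring driver
# heterozygosity.  Clone fractions and purities are solved so the expected
# VAF trajectory is driver 0.896 -> 0.547 and resistance 0.108 -> 0.618.
seed: 73
n_chromosomes: 3
chrom_length_bp: 60000000
snp_density: 1.0
mean_depth_normal: 120.0
mean_depth_tumor: 140.0
purity_primary: 0.95
purity_relapse: 0.856
target_mb: 50.0
bin_size_bp: 2000000
error_rate: 0.001
overdispersion: 0.0
events:
  - {chrom: chr2, start: 1, end: 60000000, kind: CN_LOH, haplotype: S129, clone_ids: [ancestral]}
  - {chrom: chr3, start: 1, end: 60000000, kind: CN_LOH, haplotype: S129, clone_ids: [resistant]}
clones:
  - clone_id: ancestral
    fraction_primary: 0.886
    fraction_relapse: 0.278
    mutations:
      - {chrom: chr2, pos: 30000000, gene: Kras, multiplicity: 2}
      - {chrom: chr1, pos: 10000000, gene: Notch1, multiplicity: 1}
      - {chrom: chr1, pos: 25000000, gene: Ikzf1, multiplicity: 1}
  - clone_id: resistant
    fraction_primary: 0.114
    fraction_relapse: 0.722
    mutations:
      - {chrom: chr2, pos: 30000000, gene: Kras, multiplicity: 1}
      - {chrom: chr3, pos: 30000000, gene: Pten, multiplicity: 2}
      - {chrom: chr1, pos: 40000000, gene: Kdm6a, multiplicity: 1}
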