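# f1loh

Allelic-imbalance and clonal-dynamics analysis for tumor/normal whole-exome
data from **F1-hybrid mice** (C57Bl/6 × 129Sv/Jae), the background on which
retrovirally induced T-lineage acute lymphoblastic leukemias are commonly
generated.  Because every strain-discriminating SNP in an F1 animal is
germline heterozygous, somatic loss of one parental haplotype is directly
visible genome-wide — which makes this setting ideal for detecting
**copy-neutral loss of heterozygosity (CN-LOH / uniparental disomy)** and for
tracking clonal evolution across paired primary/relapse leukemias treated
with targeted (MEK / PI3K inhibitor) therapy.

The package is aimed at people analyzing mouse cancer-model exomes: it
consumes upstream variant-caller outputs (per-site allele counts, somatic
variant tables, binned coverage) and provides

* **BAF / logR tracks** — tumor B-allele fraction at strain-informative SNPs
  passing a germline-heterozygosity gate (normal BAF ∈ [0.25, 0.75]) and a
  ≥ 20× depth gate in both samples, plus median-centered log2 tumor/normal
  coverage ratios;
* **copy-state classification** — per segment (whole chromosomes by default,
  optional binary segmentation), a threshold decision table on
  (mean folded BAF, mean logR) separating `CN_LOH`, `DELETION`, `GAIN` and
  `RETAINED_HET`;
* **mutant-allele duplication (UPD) calls** — a somatic mutation with
  VAF > 0.8 inside a CN-LOH segment is explained by duplication of the
  mutant allele, while the same VAF inside a deletion is hemizygous loss;
* **paired primary/relapse clonal dynamics** — per-variant Fisher exact
  tests with Benjamini–Hochberg correction, Clopper–Pearson intervals, and
  status labels (`ENRICHED`, `DEPLETED`, `STABLE`, `DE_NOVO`, `LOST`), plus
  detection of heterozygosity re-acquisition and average-linkage clone
  grouping in (primary, relapse) VAF space;
* **cohort summaries** — mutation burden per callable megabase and
  per-pathway recurrence fractions;
* **a synthetic-data generator** — a cell-population-mixture simulator of
  matched normal/primary/relapse exome read counts with configurable purity,
  clones, CN events and mutant multiplicities, so the whole pipeline runs
  and is testable with no external data.

## The model in brief

A tumor sample is a mixture of normal cells and tumor clones.  At a
strain-informative SNP where tumor cells carry `(c_B6, c_129)` haplotype
copies, the expected 129-allele fraction at purity `p` is

    BAF = ((1 − p)·1 + p·c_129) / ((1 − p)·2 + p·(c_B6 + c_129))

so clonal CN-LOH (0, 2) gives folded BAF `(1 + p)/2` at neutral logR,
hemizygous deletion gives `1/(2 − p)` at logR `log2(1 − p/2)`, and trisomy
gives `logR ≈ log2(1 + p/2)`.  Somatic VAFs follow the same counting model:
a mutation at multiplicity `m` in cells comprising a fraction `φ` of the
sample has expected VAF `φ·m / (φ·c_tot + (1 − φ)·2)` — a duplicated driver
inside CN-LOH therefore sits near `φ` itself, which is why mutant VAFs above
80% flag UPD.  Purity is estimated from clonal CN-LOH as `p = 2·BAF_folded − 1`.

## Worked example

Simulate the packaged "73m-like" fixture — a leukemia whose primary tumor
carries a duplicated mutant driver (Kras-class, multiplicity 2 inside
chromosome-scale CN-LOH) and a minor resistant subclone (het driver plus a
Pten-class mutation in its own CN-LOH) that takes over at relapse:

```python
import f1loh as f

config = f.preset_config("73m-like")
result = f.simulate_pair(config)

caller = f.AllelicImbalanceCaller().fit(result.snp_primary, result.bins_primary)
for seg in caller.segments_:
    print(f"{seg.chrom}  {seg.state:<12}  folded BAF {seg.mean_folded_baf:.3f}  "
          f"logR {seg.mean_logr:+.3f}")
print(f"purity estimate from CN-LOH: {caller.purity_estimate_:.3f}")

kras = caller.call_duplications(result.variants)[3]
print(f"{kras.variant_id}: duplicated={kras.duplicated} ({kras.mechanism})")

table = f.analyze_pair(result.variants)
print(table[["variant_id", "vaf_primary", "vaf_relapse", "q", "status"]]
      .to_string(index=False))

row = result.variants[result.variants.gene == "Kras"].iloc[0]
print("heterozygosity re-acquired at relapse:",
      f.detect_heterozygosity_reacquisition(kras, int(row.relapse_alt),
                                            int(row.relapse_depth)))
```

prints

```
chr1  RETAINED_HET  folded BAF 0.539  logR -0.003
chr2  CN_LOH        folded BAF 0.921  logR -0.010
chr3  RETAINED_HET  folded BAF 0.557  logR +0.010
purity estimate from CN-LOH: 0.843
v4_Kras: duplicated=True (copy-neutral LOH with increased mutant-allele dosage)
variant_id  vaf_primary  vaf_relapse            q   status
 v1_Notch1        0.492        0.106 2.695106e-12 DEPLETED
  v2_Ikzf1        0.438        0.122 5.034746e-09 DEPLETED
  v3_Kdm6a        0.064        0.259 7.381425e-06 ENRICHED
   v4_Kras        0.875        0.570 3.338385e-09 DEPLETED
   v5_Pten        0.134        0.662 1.361603e-20 ENRICHED
heterozygosity re-acquired at relapse: True
```

Reading it: chr2 shows extreme folded BAF at neutral coverage — copy-neutral
LOH — and the driver mutation inside it has VAF 0.875, so its mutant allele
was duplicated (UPD).  At relapse the driver is significantly depleted
toward heterozygosity while the resistance mutation is enriched: the
resistant subclone, not a new mutation, took over under therapy.  The
purity estimate 0.843 is the *cell fraction carrying the event*
(purity × clone fraction), a lower bound on sample purity for subclonal
events.

The same chain is available from the shell:

```bash
f1loh simulate --preset 73m-like --out run/
f1loh call-ai --snps run/snps_primary.tsv --bins run/bins_primary.tsv \
              --variants run/variants.tsv --out run/
f1loh compare --variants run/variants.tsv --out run/
f1loh report --run-dir run/ --out run/report.json
```

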