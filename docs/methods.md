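# Methods

## The inference problem

On a C57Bl/6 × 129Sv/Jae F1 background every strain-discriminating SNP is
germline heterozygous, so a matched tumor/normal exome pair yields a dense
genome-wide readout of somatic haplotype loss.  The package infers, per
genomic segment, one of four copy states from two summary tracks —
the tumor B-allele fraction (BAF) at strain-informative SNPs and the binned
log2 tumor/normal coverage ratio (logR) — and then interprets somatic
variant allele frequencies (VAFs) in light of those states, both within one
tumor and across a paired primary/relapse leukemia.

## Cell-population model

All expected allele fractions come from one counting model.  A sample is a
mixture of populations `(φ_i, c_B6,i, c_129,i, m_i)` — cell fraction,
haplotype copy numbers, mutant copies — and the expected fraction of an
allele is the ratio of its population-weighted copy count to the total copy
count.  Special cases used throughout:

* germline het SNP, tumor cells `(c_B6, c_129)`, purity `p`:
  `BAF_129 = ((1−p) + p·c_129) / (2(1−p) + p(c_B6 + c_129))`;
* somatic mutation at multiplicity `m` in a fraction `φ` of all cells with
  local tumor copy number `c`: `VAF = φm / (φc + 2(1−φ))`.

Consequences that the thresholds below exploit: clonal CN-LOH has folded
BAF `(1+p)/2` at logR 0; a clonal hemizygous deletion has folded BAF
`1/(2−p)` at logR `log2(1 − p/2)`; a clonal trisomy has logR `log2(1 + p/2)`
with folded BAF only `(1+2p)/(2+2p)` (≈ 2/3 when pure); and a duplicated
mutant allele inside CN-LOH has VAF equal to its clone's cell fraction.
These expressions are verified in the tests against an independent oracle
that literally counts allele copies over an integer population of 10,000
cells.

## Gates and tracks

A SNP site enters the BAF track only if the normal-sample BAF lies in
[0.25, 0.75] (confirming the germline het genotype against sequencing error
and mis-genotyping) and both samples have depth ≥ 20 reads.  The depth gate
is applied to tumor *and* normal symmetrically — a deliberate, conservative
choice.  Excluded sites are counted, never silently dropped.  The folded BAF
`max(BAF, 1−BAF)` removes the arbitrariness of which strain is tracked;
relabeling the strains provably changes nothing downstream (tested as a
symmetry property).

logR is computed per coverage bin as `log2(tumor/normal)` and centered by
subtracting the genome-wide median.  Bins with zero depth on either side are
excluded.  Median centering assumes a majority-diploid genome; a massively
aneuploid sample would shift the baseline, and this is documented as an
assumption rather than defended against.

## Segmentation and classification

Default segmentation is one segment per chromosome, matching the
whole-chromosome scale at which F1 LOH events are typically inspected; the
events of interest here (driver-locus UPD, whole-chromosome trisomy) are
chromosome-scale.  An optional recursive binary segmentation splits at the
point maximizing the between-side difference in mean folded BAF, accepting a
split when the difference exceeds 0.15 and both sides retain ≥ `min_sites`
(default 10) points; ties break leftmost, making the procedure
deterministic.

Classification is an explicit decision table with config-exposed cuts:

| folded BAF | logR | state |
|---|---|---|
| ≥ 0.85 | within ±0.2 | `CN_LOH` |
| ≥ 0.85 | ≤ −0.35 | `DELETION` |
| < 0.85 | ≥ +0.3 | `GAIN` |
| otherwise | | `RETAINED_HET` |

Combinations matching no row (e.g. extreme BAF with logR in the gap between
the neutral band and the deletion cut) fall back to `RETAINED_HET` with an
`ambiguous` flag.  The band edges must not overlap, which is validated.  The
logR cuts sit between the pure-tumor expectations (−1 for deletion, +0.585
for trisomy) and 0, retaining power at realistic purities; `GAIN` is called
from coverage alone because trisomy moves folded BAF only to ≈ 2/3 even when
pure.  Known limitation of the table itself: a hemizygous deletion's folded
BAF `1/(2−p)` drops below the 0.85 cut when purity < ~0.87, so low-purity
deletions surface as ambiguous `RETAINED_HET` rather than `DELETION`; the
reference conditions used throughout testing (purity 0.9) sit safely above
this.  No joint purity/ploidy grid search (ASCAT-style allele-specific
copy-number fitting) is attempted — the inference is deliberately
threshold-based.

Purity is estimated from clonal CN-LOH by inverting the folded-BAF
expectation, `p = 2·BAF_folded − 1`, clipped to [0, 1].  For a subclonal
event this returns the event's cell fraction, i.e. a lower bound on purity.

## Mutant-allele duplication (UPD) calls

A somatic variant is called *duplicated* iff its VAF exceeds 0.8 (the
configurable operationalization of "mutant allele frequency above 80%") and
its enclosing segment is `CN_LOH`.  The same VAF inside a `DELETION` segment
is mechanistically different — hemizygous loss of the wild-type allele — and
is reported as such, not as duplication.  Variants outside all segments get
an unassigned negative call with a warning.

## Paired primary/relapse analysis

Each variant's counts are compared with a two-sided Fisher exact test on the
2×2 table of alt/ref reads — exact at exome depths (~100–150×), which is why
it is preferred over a normal-approximation test.  p-values are
Benjamini–Hochberg adjusted across the variants of one pair (pairs are
independent analyses).  Status rules, with limit of detection
`lod = 3` alt reads and `α = 0.05` on the adjusted q:

* `DE_NOVO`: q < α, primary alt < lod, relapse VAF > 0;
* `LOST`: the mirror image;
* `ENRICHED` / `DEPLETED`: q < α, by direction of the raw VAF change;
* `STABLE`: everything else.

Reported VAFs are rounded half-up to 3 decimals; all internal arithmetic is
unrounded.  Clopper–Pearson intervals accompany every estimate.
*Heterozygosity re-acquisition* — a duplicated driver returning to het state
at relapse — fires when the primary call is a duplication and the relapse
CI, divided by purity to rescale to the pure tumor, overlaps [0.4, 0.6].

Clone grouping is average-linkage hierarchical clustering of variants in
(primary VAF, relapse VAF) space, cut at Euclidean distance 0.1, with
deterministic relabeling by lowest member id.  The group maximal in **both**
coordinates, when one exists, is flagged ancestral.  This is an explicit
simplification — a two-sample VAF clustering, not phylogeny inference or
copy-number-aware cancer-cell-fraction modeling (PyClone-style deconvolution
is out of scope).

## Synthetic data generator

The simulator emulates exactly the statistical structure the analysis
assumes: evenly spread informative SNPs at a configurable density (default
1/Mb — exome-scale informative density), binomial allele counts at
Poisson-distributed depths (negative-binomial with an overdispersion
parameter as a robustness switch), a symmetric per-read error rate (default
0.001) so the het and depth gates are exercised, per-sample purity, and
tumor clones carrying CN events and mutations whose expected allele
fractions follow the cell-population model above.  Haplotype phase exists
internally but is never emitted — only per-site counts, as in real data.
RNG streams are keyed per (role, chromosome), so adding a chromosome or
sample never perturbs existing draws, and regeneration from the same config
is byte-identical.

What it does *not* emulate: read-level artifacts (mapping bias, strand
effects, GC waves in coverage), indels, segmental CN finer than the
configured events, and sampling correlation between neighboring sites.
Passing recovery tests therefore demonstrate correctness of the inference
given the model's assumptions, not robustness to real-exome artifacts.

Packaged fixtures: the `73m-like` preset encodes a duplicated driver
(multiplicity 2 in CN-LOH) with a pre-existing resistant subclone that
carries the het driver plus its own CN-LOH resistance mutation; clone
fractions (0.886→0.278 ancestral, 0.114→0.722 resistant) and purities
(0.95 primary, 0.856 relapse) were solved from the model so the expected
trajectories are driver 0.896→0.547 and resistance 0.108→0.618.  The
`jw81-like` preset encodes a de novo resistance mutation (clone fraction
0→0.6 at purity 0.92) at the cost of the ancestral clone.  Tumor purity of
transplanted leukemias is not something the data constrain tightly, so
recovery benchmarks use a purity grid around 0.9 (0.7–0.95 where exercised)
rather than asserting a single value.

## Reference study conditions for benchmarks

Recovery benchmarks run at purity 0.9, mean depth 100–150×, 50 informative
SNPs per chromosome, with 100–200 simulation seeds per condition — sizes at
which every rate is stable to well under a percentage point while the whole
benchmark suite completes in about a minute on one CPU.  The Fisher-vs-
enumeration agreement check is exhaustive over all 2×2 tables with total
≤ 30 (~46k tables) and sampled (1000 seeded tables) for totals 31–60;
agreement is at machine precision, so sampling loses nothing.

## Numerical and interface choices

* Coordinates: 1-based inclusive for SNPs/variants (VCF convention),
  0-based half-open for bins and segments (BED convention).
* Strain-informative sites are supplied with designated B6/129 alleles; the
  F1 design makes the germline het set self-identifying in the normal, so no
  external strain reference is consulted.
* Segment files round-trip losslessly (floats written at repr precision).
* Zero depth yields errors (`VAF undefined`), not silent zeros; degenerate
  configurations (overlapping events, multiplicity exceeding copy number,
  overlapping threshold bands) are rejected at validation time with the
  offending record named.
* Estimator classes (`AllelicImbalanceCaller`, `PairedVafAnalyzer`,
  `CloneGrouper`) follow scikit-learn conventions — constructor-only
  parameters, `fit`, trailing-underscore fitted attributes,
  `get_params`/`set_params` — so they compose with sklearn model selection;
  module-level functions are the thin functional interface over them.
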