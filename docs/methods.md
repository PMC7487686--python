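# Methods

This note records the models, formulas and parameter choices implemented in
`aneukit`, in enough detail to re-derive every number the package produces.

## Karyotype model

A karyotype is a per-chromosome copy-number vector over the sixteen nuclear
chromosomes (`chrI`..`chrXVI`) with a base ploidy (1 for the haploid strains
considered here). The packaged disome panel contains six strains: `D2`,
`D1/2`, `D1/2/8`, `D1/2/8/11`, `D1/8` and `D13`, each carrying the named
chromosomes at two copies. Mitochondrial DNA (`chrMito`) is not part of a
karyotype; wherever a copy number for it is needed, the base ploidy is used.

## qPCR copy-number estimation

Each chromosome is probed on both arms with three technical replicates. Under
perfect amplification efficiency, Ct decreases by one cycle per doubling of
template, so copy number is estimated per arm as

    copy = base_ploidy * 2^(reference_Ct - Ct)

using the mean Ct of the three replicates and the paired euploid reference
table. The chromosome estimate is the mean of the two arm values; `copy_sd`
is the standard deviation between the two arms. Calls round to the nearest
positive integer. The simulator uses a fixed reference Ct of 20.0 and adds
Gaussian noise (`ct_sd`, default 0.1 cycles) to every replicate.

## Depth-window copy-number estimation

Read depth (window RPKM) is computed in non-overlapping 1-kb windows,
exported with 1-based inclusive coordinates. For each window the log2 ratio
to the matching euploid window is taken (windows with zero euploid depth are
excluded and counted); the chromosome copy number is

    copy = base_ploidy * 2^(median window log2 ratio)

rounded to the nearest positive integer. A chromosome is flagged as
segmentally abnormal when a contiguous run of at least 50 windows deviates
from the chromosome call by at least 0.58 in log2 (just under a 1.5-fold
step, i.e. half a copy at base ploidy 1). The simulator draws window depth
from a mean-one lognormal with coefficient of variation `depth_noise_cv`
(default 0.2) scaled by the true copy ratio.

## Expression quantification and normalization

RPKM for gene *g* in sample *s* is

    RPKM = count / (CDS length in kb) / (non-mitochondrial total counts / 1e6)

Mitochondrial genes are excluded both from the output and from the per-sample
totals, because mitochondrial content varies independently of the nuclear
karyotype.

Each aneuploid sample is normalized to its batch-paired euploid sample by a
median-ratio scale factor computed **only over nonduplicated genes** with
positive euploid RPKM:

    scale = median(aneuploid RPKM / euploid RPKM)   over eligible genes
    normalized = aneuploid RPKM / scale

This pins the post-normalization nonduplicated median ratio to exactly 1
(verified to 1e-12) and is idempotent. Restricting to nonduplicated genes is
what lets duplicated chromosomes show their true dosage: a whole-transcriptome
median would absorb part of the duplication into the scale factor.

Fold changes are `log2(normalized / euploid)`; genes with a zero in either
sample get `NaN` rather than a pseudocount, so downstream statistics never
mix real and imputed values. Ribosome density is footprint abundance divided
by mRNA abundance; its log2 fold change is the difference of the two assay
fold changes.

Per-chromosome dosage is summarized as the median gene-level log2 fold
change, compared with the copy-number expectation
`log2(copies / base_ploidy)`. A duplicated chromosome is reported as
*compensated* when its median falls more than 0.3 below the expectation —
far enough that gene-level noise (median standard error well under 0.05 at
the default simulation settings) cannot produce it.

## Signature scoring

A gene-set score for one sample is the **mean** log2 fold change over set
members that are present in the data, have a defined fold change, and lie on
nonduplicated chromosomes (dosage would otherwise masquerade as regulation).
The cross-sample matrix used for heatmaps keeps only genes nonduplicated in
*all* strains and defined in *all* samples, so every column summarizes the
same gene list.

## Enrichment, thresholds and intersections

Up- or down-regulated genes are selected by inclusive log2 fold-change
cutoffs: 0.585 (= round(log2(1.5), 3)) for the strict 1.5-fold criterion and
0.38 (= round(log2(1.3), 2)) for the relaxed 1.3-fold criterion, with genes
on duplicated or explicitly excluded chromosomes removed. Term enrichment is
the upper-tail hypergeometric probability

    p = P(X >= k),  X ~ Hypergeometric(N, K, n)

computed with `scipy.stats.hypergeom.sf(k - 1, N, K, n)` and
Bonferroni-corrected by the number of terms with at least one member in the
universe (capped at 1). The packaged functional-category fixture assigns 251
curated genes to 12 categories (66 ribosome homeostasis, 20 protein
degradation/quality control, 36 metabolism, ...), and cross-strain
intersections report the genes up-regulated in every strain together with
their category counts.

## Variant filtering and classification

A variant is retained when base quality >= 15, mapping quality >= 15, and
allele frequency >= 0.70 on haploid chromosomes or >= 0.40 on duplicated
chromosomes (all inclusive) — a heterozygous-like frequency near 0.5 is a
legitimate call on a two-copy chromosome but noise on a one-copy chromosome.
Wild-type-shared calls are subtracted by exact (chromosome, position, ref,
alt) identity. Coding effects are classified by substituting the alternate
base into the annotated CDS (strand-aware, with reverse-complementation on
minus-strand genes) and translating the affected codon: missense, synonymous,
nonsense, intergenic, or unclassified (indels).

## Assay formulas

- Miller units: `1000 * (OD420 - 1.75 * OD550) / (2 * t_min * OD600)`.
- ER-GFP: fluorescence divided by loading-corrected total GFP level,
  reported as percent of the same ratio in the wild type.
- Pulse-chase: signal as percent of the t = 0 mean; half-life from a
  log2-linear least-squares fit (slope = -1 / half-life).
- HAC1 splicing: spliced / (spliced + unspliced) after dividing both bands
  by the loading control (which therefore cancels).
- Growth: doubling time `ln 2 / slope` of ln(OD600) against time over a
  chosen window; ORF-burden relationships use the Pearson correlation.
- Two-sample comparisons: Student's t (pooled variance, df = n + m - 2) when
  variances are assumed equal, Welch's t with Satterthwaite df otherwise,
  both via `scipy.stats.ttest_ind`.

## Count simulator

The simulator exists to give every analysis a known ground truth. Expected
counts for sample *s* are

    mu_g = library_size * w_g / sum(w)
    w_g  = baseline_g * (copies_g / base_ploidy)^(1 - compensation_fraction)
           * 2^(activated effect, if g is in an activated set for this assay)

where `baseline_g` is a lognormal expression level (log-sd 1.0) drawn once
per genome seed and **shared across strains, assays and replicates**, so fold
changes between samples reflect only copy number and activation. Counts are
negative binomial with dispersion `nb_dispersion` (variance
`mu + dispersion * mu^2`; dispersion 0 falls back to Poisson).

Default parameters, chosen a priori as plausible bulk-experiment settings:
`library_size` 5e6, `nb_dispersion` 0.01, `ct_sd` 0.1 cycles,
`depth_noise_cv` 0.2, pulse-chase `noise_sd` 5 percentage points. At these
settings a 2000-gene genome gives per-gene log2 fold-change noise of roughly
0.2 sd, so chromosome medians (125 genes) are estimated to about 0.02.

The generator emulates dosage, optional compensation, activated expression
programs, qPCR and depth noise, variant frequency strata and first-order
decay. It does **not** emulate GC or mappability bias, batch effects, length-
dependent count bias, multi-mapping, or transcript isoforms; conclusions
about those phenomena cannot be drawn from it.

## Numerical and reproducibility choices

All random streams are `numpy.random.default_rng` seeded with structured
integer sequences (seed plus stage/strain/replicate tags), so any quantity is
reproducible from a single integer seed and independent of execution order.
Strain tags come from a stable byte-sum of the strain id, not Python's
randomized `hash`. Pipeline outputs carry provenance comments (version, seed,
thresholds, input SHA-256 checksums) and a JSON manifest; reruns are
byte-identical.

## Limitations

- The statistical tests are the classical small-sample t and hypergeometric
  procedures; no multiple-testing control beyond Bonferroni is provided.
- Copy-number calling assumes whole-chromosome events; the segmental flag
  detects but does not genotype partial duplications.
- The variant classifier handles single-nucleotide substitutions only;
  indels are reported as unclassified rather than frame-annotated.
- All validation is against simulated data with known truth; performance
  numbers (e.g. karyotype call accuracy) describe the simulator's noise
  model, not any particular sequencing platform.
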