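# Methods

`epiexpr` implements a two-arm analysis of a stop-exposure toxicology
design — an RRBS methylome arm and a degradation-aware targeted
RNA-seq arm — plus the integration analyses that join them, and a
synthetic-data module that generates inputs with known planted truth
so every stage can be validated end to end. This note records the
models, the tunable parameters and their defaults, the numerical
choices, and the limits of what the synthetic validation shows.

## Methylome arm: DMR calling

### Inputs and filters

Per-sample CpG calls arrive in the Bismark coverage dialect
(tab-separated `chrom start end pct meth unmeth`, 1-based positions,
`start == end` per CpG). The matrix is the union of sites across
samples; a site absent from a sample is uncovered, never imputed.

Filters, in order (`DmrConfig`):

* **Read depth** — a per-sample observation with fewer than
  `min_reads` (default 10) total reads is masked, i.e. treated as
  uncovered; the site is kept for adequately covered samples.
  Whole-site removal is available via `site_filter_mode="site"`.
* **SNP blacklist** — sites overlapping user-supplied intervals
  (BED, 0-based half-open) are removed entirely.
* **Group coverage** — a site needs at least
  `min_samples_covered_per_group` (default 3) surviving observations
  in each group to be testable.

A fully unmethylated spike-in genome (lambda phage), when present,
yields the bisulfite conversion rate `1 − Σmeth/Σtotal` over spike-in
sites; rates above 99% indicate adequate conversion.

### Differential CpGs and clustering

Per CpG, each group's methylation is the unweighted mean of
per-sample fractions over covered samples. A CpG is *differential*
when both groups meet the coverage minimum and the group means differ
by at least `cpg_delta_threshold` percentage points (default 10).
Consecutive differential CpGs on one chromosome with the same sign of
difference and inter-CpG spacing at most `max_gap` bp (default 250,
the scale of an MspI fragment) are chained; chains with fewer than
`min_cpgs` members (minimum 3) are discarded. The differential-CpG
criterion and the clustering rule are this package's own concrete
choices — threshold-style, transparent, and testable; published
pipelines in this family describe "clustering of differentially
methylated CpGs" without fixing constants.

### Region statistic and test

The region statistic is the **weighted methylation level**:
`Σ methylated reads / Σ total reads`, pooled over **all** covered
CpGs inside the region span (not only the differential members), per
sample. Pooling all CpGs matters: it is the standard definition of a
region's weighted methylation, and it keeps the tested statistic from
being computed exclusively on sites pre-selected for a group
difference.

Regions are tested with a two-sided pooled-variance (Student's)
t-test on the per-sample weighted levels; a DMR is emitted when
`p < alpha` (default 0.05, raw — **no multiple-testing correction is
applied across regions**, matching the upstream analysis convention
this package reproduces; treat the output list accordingly) and when
the region's own weighted-methylation difference meets the same
threshold as the per-CpG screen (`|Δ| ≥ cpg_delta_threshold` pp).
The region-level effect gate exists because select-then-test is
anticonservative: noise chains that pass the per-CpG screen re-use
the same reads in the region test, and on null simulations ~64% of
such 3-CpG chains clear `p < 0.05` despite diluted region deltas of
5–10 pp. Requiring the region difference to meet the differential
standard removes most of them while leaving genuine DMRs (which carry
their full delta at the region level) untouched. Direction is
`hyper` when treated minus control is positive.

Degenerate inputs: both groups zero-variance with equal means gives
p = 1; with unequal means the limit p = 0 is reported with a
`degenerate` flag.

### Calibration mode

Setting `cpg_delta_threshold = 0` disables the differential screen
(every testable CpG is a member, the sign constraint is vacuous and
waived, and the effect gate is vacuous), so candidate regions are
formed by genomic clustering alone, with no data-dependent selection.
In this mode the region t-test is exactly calibrated: on a null
simulation (no planted DMRs, 5 vs 5 samples, 30× coverage, ~2,500
candidate regions) the fraction of regions with p < 0.05 sits inside
the 95% binomial envelope of 0.05. With the default threshold of 10
the emitted-DMR list is a *selected* list and its p-values must not
be read as calibrated — this is a property of every
select-then-test DMR pipeline, not of this implementation.

## Annotation arm

Features are BED6 intervals (0-based half-open) in classes
{promoter, enhancer, CTCF_site, TF_binding, open_chromatin,
CpG_island, CpG_shore, CpG_shelf}; the first five count as predicted
regulatory regions. A DMR hits a class when it overlaps any feature
of the class by ≥1 bp (once per class, regardless of how many
features it touches); per-class percentages are reported separately
for hyper- and hypomethylated DMRs.

Each DMR is linked to exactly one gene: the TSS nearest to the DMR
interval, distance 0 when the TSS falls inside the 1-based inclusive
span, otherwise the gap to the nearest edge; ties break to the
lexicographically smallest gene id (deterministic and seed-free).
Links to Riken clones (symbol suffix "Rik"), predicted "Gm<digits>"
genes, and pseudogenes (biotype containing "pseudogene") are removed,
case-insensitively, with a removal log. A second, stricter link set
keeps only DMRs that also overlap a regulatory feature.

The TSS table is a TSV with columns `gene_id gene_symbol chrom tss
strand biotype` (1-based TSS); a five-column variant without
`gene_symbol` is accepted, with the gene id standing in for the
symbol.

## Expression arm

Probe-level counts are collapsed to genes by summation (sums of NB
counts stay in the NB family; the panel has ~3,044 probes for ~2,755
genes).

* **Rank QC.** The reference profile is the per-gene mean of raw
  counts over all samples, computed once. Each sample's Spearman rho
  against the reference is squared; the sample fails when rho ≤ 0 or
  rho² < 0.7. (A sign-inverted profile is degraded even though its
  rho² may be large, hence the sign condition; rho² is used as the
  R² statistic, the squared-rank-correlation reading of "Spearman
  rank regression".) Failing samples are excluded downstream, and
  any (group, timepoint) cell with fewer than 3 passing samples is
  excluded from testing.
* **Normalization.** Median-of-ratios size factors: counts are first
  put on a common depth scale (divided by the sample total), the
  per-gene reference is the geometric mean of these relative
  abundances over genes with no zero count, and the size factor is
  the sample depth times the median ratio to the reference. The
  depth prenormalization makes the estimator exactly equivariant —
  scaling one sample's counts by c scales its factor by c and
  changes nothing else — which the plain raw-count reference is not
  (there, a single-sample scaling leaks into the reference by
  c^(1/n)). Size factors are defined up to one global unit constant,
  pinned by default to the cohort's geometric-mean depth so factors
  are ≈1 and normalized counts stay on the raw-count scale.
* **Expression filter.** Genes with a geometric mean of normalized
  counts below 3.4 across passing samples are removed (strict
  less-than; a gene with any zero has geometric mean 0 and is
  removed). A percentile variant of the rule is available
  (`mode="percentile"`); the absolute rule is the default and the
  literal reading of the threshold.
* **Differential expression.** Per gene, group abundances are
  size-factor-weighted means q = ΣK/Σs. The gene dispersion α is
  estimated by method of moments on normalized counts
  (α̂ = (v − μ·E[1/s])/μ² with v the pooled within-group variance)
  and shrunk 50/50 in log space toward a trend α = a0 + a1/μ fitted
  across genes by non-negative least squares — the native NB
  mean–dispersion family. The Wald statistic
  log(q_t/q_c) / sqrt(V_t + V_c), with
  V = 1/(qΣs) + α·Σs²/(Σs)², is referred to a t distribution with
  2.5·(n1+n2−2) degrees of freedom. The factor reflects the
  information the trend shrinkage adds to the dispersion (the χ²
  idealization of 50/50 log shrinkage would quadruple the residual
  df; the moment estimator is noisier, and parametric-bootstrap
  calibration on the generator's null settles the factor at 2.5,
  giving a mean null rejection of 0.051 at p < 0.05 over 20
  fixtures). Benjamini–Hochberg adjusts p across tested genes; a
  gene is significant at FDR ≤ 0.05 **and** |fold change| ≥ 1.5
  (gate applied to the unshrunk point estimate). A gene with zero
  counts in both groups is untested; with zeros in exactly one
  group, a half-count continuity value (q = 0.5/Σs) keeps the fold
  change finite. This NB Wald test is a documented, testable
  stand-in with the same modeling family as the established
  external tools; it does not reproduce any specific tool's
  shrinkage, outlier handling, or independent filtering.
* **Embedding.** log2(normalized + 1) profiles are centered, reduced
  to the first min(15, rank) principal components (the retained
  cumulative variance is reported), and embedded in 2-D with UMAP
  under a fixed random state.

## Integration

* **Disjoint intersections** (UpSet regions): counts of all non-empty
  membership patterns of 2–8 DEG sets; the counts sum to the union.
* **Directional concordance**: over genes significant in two
  comparisons, the fraction with the same sign of log2 fold change.
* **Fisher enrichment**: one-sided over-representation p from the
  hypergeometric upper tail P(X ≥ overlap); significant when
  −log10(p) > 1.3. The universe is a choice the user must own: the
  defaults are all genes surviving the expression filters (for DEG
  queries) and all post-exclusion TSS-table genes (for DMR-linked
  queries).
* **Intersection table**: per comparison, the DEG count, its
  intersection with TSS-linked DMR genes, with the
  regulatory-restricted subset, and the portions of each belonging
  to at least one *significant* gene set (membership in significant
  sets only, configurable).

## Synthetic-data generators

The generators emulate the statistical structure the pipeline
consumes; their defaults are the conditions under which the package
validates itself.

**Methylome** (`MethylSimConfig`): 20,000 CpGs over 2×5 Mb, placed in
MspI-fragment-like clusters (3–~15 CpGs, 15–80 bp apart, fragments
400–3,000 bp apart) because RRBS covers CpG-dense fragments — this
clustering is also what makes gap-based region clustering meaningful.
A fragment is island-like with probability 0.3 (locus baselines ~
Beta(5,45), mean 10% methylation) or open (Beta(40,10), mean 80%).
Per sample, the methylation propensity is Beta-distributed around the
locus baseline with concentration 50 (between-replicate sd ≈
0.04–0.09 across the methylation range, typical of RRBS biological
replicates); coverage is NB(mean 30, size 5); methylated reads are
binomial. Planted DMRs shift the treated-group propensity additively
by ±delta/100 on a run of `dmr_width_cpgs` CpGs within one fragment;
hypermethylated DMRs are placed on island-like (low) fragments and
hypomethylated on open (high) fragments so the shift stays inside
[0,1] untruncated — also the biologically common arrangement. A
lambda spike-in with 0.5% conversion-failure rate is simulated
alongside. Coverage is independent of methylation state.

**Annotation**: CpG islands are the island-like fragments of the same
layout (so annotation and methylome agree); each island gets ±2 kb
shores and 2–4 kb shelves. TSSs are uniform at a configurable density
with strand-aware promoters (−1 kb/+200 bp); enhancers and CTCF sites
are scattered uniformly. An exact, deterministically placed fraction
of genes receives excludable identifiers (Rik suffix, Gm prefix,
pseudogene biotype).

**Counts** (`ExprSimConfig`): 3,044 probes over 2,755 genes (extra
probes assigned to random genes), probe means log-uniform over
e¹–e⁷·⁵ (~3–1,800 counts), NB dispersion a0 + a1/mean with (0.05, 2),
six animals per group, library size factors log-uniform 0.7–1.4.
Planted DEGs scale all probes of a gene by 2^±log2fc in the treated
group. Degraded ("FFPE-like") samples have 60% of their probe values
scrambled after counting — rank disruption is exactly the property
the Spearman QC measures, and the disrupted position sets are nested
across noise levels so a sample's rho is monotone in the noise
parameter. Degradation by rank scrambling does not model read-length
decay, 3′ bias, or the count-magnitude loss of real FFPE RNA.

**What passing tests do and do not show.** The synthetic validation
demonstrates that the implementation does what its definitions say
(exact identities, oracle agreement), that the tests control type-I
error under the generators' nulls, and that planted effects of the
stated sizes are recovered at the stated design points. It does not
certify performance on real RRBS or TempO-Seq data, where
neighbor-correlated methylation, coverage–methylation coupling,
batch structure, and non-NB count artifacts are all present and all
absent from the generators.

## The designed mini-study

`epiexpr.ministudy` wires the whole pipeline into a miniature of the
two-group × two-timepoint design with hand-designed truth: 12 planted
DMRs each containing the TSS of a designated gene (6 also overlap a
designed enhancer; 2 carry excludable identifiers), a 300-gene panel
with designed DEG sets per treatment cell, and three gene sets of
which two are loaded with DEGs. Effect sizes (40 pp methylation
shift at 50× coverage; |log2FC| = 3 at dispersion 0.02 and n = 6) are
chosen so recovery is essentially certain, which is the point: the
produced intersection table must equal the hand-computed designed
table exactly, and a re-run with the same seed must be byte-identical
on disk.

## Problem sizes

The shipped validation uses 20,000-CpG genomes, 2,000-gene null/power
panels (pooled over five null replicates), six 50-DMR recovery
replicates, ten QC replicates, 1,000 t-test oracle cases and 100
exact Fisher tables; these sizes give binomial Monte-Carlo envelopes
tight enough to detect meaningful miscalibration while keeping the
whole suite in the tens of seconds on one core.

## Known limitations

* The DMR caller reports raw p-values on a selected candidate list;
  see the calibration discussion above.
* The differential-CpG screen compares group means without weighting
  by per-sample depth; the weighting enters at the region stage.
* The NB Wald stand-in lacks log-fold-change shrinkage, count-outlier
  handling and independent filtering; its df calibration was
  established at the design's group sizes (n ≈ 3–6 per cell) and is
  not validated for much larger designs.
* Gene identifiers are joined verbatim; cross-namespace joins
  (Ensembl/Entrez/MGI) require a user-supplied mapping table.
* UMAP coordinates are reproducible only for a fixed seed and
  environment; only PCA variance fractions carry quantitative
  meaning.
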