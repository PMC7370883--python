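# Methods

This note documents the statistical model behind `mosaiscan`, the
choices made where the design was genuinely open, what the synthetic
cohorts do and do not emulate, and the known limitations.

## Quality control and stratification

Analysis is restricted to the 22 autosomes. Cells strictly below the
0.10 quantile (type-7, linear interpolation) of mapped reads *or* of
percent mapped reads are removed; both the quantile and the
strict/non-strict inequality are configurable
(`cell_depth_quantile`, `depth_filter_strict`), since the union-of-two-
tails rule can remove at most 20% of cells when both metrics are
tie-free. Retained cells are partitioned into (embryonic stage × cell
type) strata. CPM is computed per cell over the full retained autosomal
gene set *before* any per-stratum filtering, so library-size
normalization never depends on stratum membership. Within each stratum,
genes with median CPM ≥ 50 are retained; strata with fewer than
`min_genes` (default 2000) such genes, or fewer than two cells, fail QC
and contribute no calls. The 2000-gene floor is a conservative
separator: well-behaved blastocyst strata express roughly 3000+ genes
at this threshold, while the failing groups fall far below it. Embryos
with fewer than two retained cells still receive chromosome-level calls
but are `indeterminate` for origin classification.

## Expression dosage score

For stratum cells *i* = 1…n and genes *g* with leave-one-out mean
CPM m<sub>−i,g</sub> > 0, the ratio ρ<sub>ig</sub> = CPM<sub>ig</sub> /
m<sub>−i,g</sub> is summarized per chromosome *j* as
s<sub>ij</sub> = median<sub>g∈j</sub> ρ<sub>ig</sub>, requiring
≥ `min_genes_per_chrom` (default 25) usable genes for a stable median.
Genes whose leave-one-out mean is zero are skipped for that cell rather
than pseudocounted.

The Z-statistic divides by a robust per-stratum, per-chromosome scale,
1.4826 × MAD of {s<sub>i′j</sub>}, and the p-value is the two-sided
normal tail, clipped to [1e-300, 1] so that log p stays finite in the
omnibus step. The null **center** is the stratum-wide median of s
pooled over all chromosomes rather than the theoretical value 1: the
median of right-skewed count ratios sits slightly below its mean, by an
amount comparable to the cell-to-cell spread of s, so a fixed center of
1 would shift the null Z distribution by as much as one SD. The pooled
median absorbs this bias while remaining robust both to aneuploid
cells (MAD and median are resistant) and to strata in which *every*
cell shares a meiotic aneuploidy, which perturbs at most 1/22 of the
pooled values. A fixed numeric center (e.g. `center=1.0`) remains
available. The gene-level summary is deliberately a median, not a
trimmed or weighted mean: it is order-invariant and resistant to
individual outlier genes.

## Allelic imbalance

For each cell-chromosome with ≥ `min_reads` (20) allele-supporting
reads at ≥ `min_snps` (5) heterozygous SNPs, the min-allele ratio is
Σ min(ref, alt) / Σ (ref + alt) ∈ [0, 0.5]. Both coverage floors are
package choices: without them the ratio's sampling variance at
low-coverage chromosomes dominates the null fit. The observed ratio
correlates with depth, so a single ordinary-least-squares fit of ratio
on log10(total reads), pooled across all cell-chromosomes, is removed
(log-linearization is the package's choice of functional form; a pooled
single fit matches the assumption of one common technical depth
effect). With all depths equal the residual degenerates gracefully to
the mean-centered ratio.

Under the assumption that most cell-chromosomes are disomic, residuals
between the first and third quartile (type-7) are treated as null:
μ is their mean and σ = IQR / (2 Φ⁻¹(0.75)), the normal-consistent IQR
estimator, which a constant fraction of aneuploid outliers cannot
perturb. The null selection operates on *residuals* (not raw ratios),
consistent with estimating the residual's null moments. One-sided
p-values use the lower normal tail: both monosomy (1:0) and trisomy
(2:1) shrink the min-allele ratio.

## Omnibus test, hierarchical FDR, and call types

Expression p-values are gated to 1 when |1 − s| < 0.2 (inclusive
boundary), mirroring the dosage caller's effect-size threshold, and
combined with the allelic p-value by Fisher's method (χ² with 4 df).
When only one signal exists for a cell-chromosome — e.g. no SNP
coverage — the omnibus degrades to the single p with 2 df (for two df
this is the identity), and the leaf stays in the hypothesis ledger;
dropping such leaves would silently bias per-cell aneuploidy counts.
The ledger always contains every retained cell × 22 autosomes.

Selection runs on the tree chromosomes ⊂ cells ⊂ embryos. Parent
p-values are Simes-aggregated (min over sorted children of
m·p<sub>(i)</sub>/i); BH runs at the embryo level at the nominal q
(default 0.01), then within each selected embryo at q·(R₁/m₁), then
within each selected cell at q·(R₁/m₁)·(R₂ₑ/m₂ₑ), the standard
selection-fraction adjustment for tree-structured BH. The adjusted
levels are exposed in the result object, and the hierarchy invariant —
no rejected node without a rejected ancestor — is asserted on every
run. Rejection sets are monotone non-increasing as q shrinks.

Selected leaves are labeled by 2-means on (z_expr, z_ai) with
deterministic initialization at the componentwise minimum and maximum;
the cluster with the lower mean Z is monosomy (ties break toward
monosomy). Degenerate inputs (< 2 usable points, identical points, or a
missing Z) fall back to the sign of the available Z-score, preferring
z_expr.

## Origin classification and embryo summaries

A called (chromosome, gain-or-loss) pair is meiotic when ≥ 75%
(`meiotic_cutoff`) of the embryo's retained cells carry that exact
aneuploidy, or — under the alternative `lt2_normal` criterion — when
fewer than two cells are normal for that chromosome; otherwise mitotic.
The denominator defaults to all retained cells of the embryo
(`called_cells` restricts it to cells with a usable test on that
chromosome). Reciprocal monosomy and trisomy of one chromosome count as
two mitotic events, matching their origin in mitotic nondisjunction.
Cohort summaries re-run the selection over a grid of FDR levels,
producing monotone proportion curves for chromosomes, cells and
embryos. Per-embryo aneuploidy signatures (cells × chromosomes of Z or
s, missing entries imputed to the null value) are clustered with
average-linkage Euclidean agglomeration, whose leaf order approximates
clonal ancestry; per-chromosome aneuploidy rates (rejected / tested
leaves) can be correlated with protein-coding gene counts.

## Synthetic cohorts

The generator's defaults describe a reduced blastocyst-like study: 20
embryos × 8 cells in one stratum, meiotic error probability 0.2 per
embryo (a random chromosome gains or loses one copy in every cell),
mitotic error probability 0.05 per division of a binary lineage tree
(the affected daughter's descendants inherit the event; with
probability 0.5 the sister lineage receives the reciprocal event,
mimicking mitotic nondisjunction). Events that would push a chromosome
outside 1–3 copies are skipped and logged.

Expression: 140 genes per autosome with log-normal baseline means
(log-mean log 100, log-SD 1 — about 2800 genes pass the median-CPM
filter, matching the scale of a real passing stratum), log-normal cell
size factors (log-SD 0.15), and negative-binomial counts with mean
λ_g · (copy number / 2) · sf and dispersion 0.1 scaled by the
overdispersion factor (0.3 / 1 / 5 span reduced, baseline and inflated
variance; benchmarks default to 100 replicates per factor).

Allelic imbalance: each cell-chromosome draws a target min-allele ratio
from a ploidy-state beta — disomy mean 0.38 SD 0.06, trisomy 0.28/0.07,
monosomy 0.02/0.02, configurable stand-ins with variance scaled by the
same overdispersion factor and capped below the feasibility bound
m(1−m); `estimate_sim_params` refits them by method of moments from
called data when real inputs exist. These betas describe *observed*
ratios, so the target is realized directly: minor-haplotype reads are
allocated across 25 SNPs of Poisson(30) depth by stochastic rounding of
target × depth, making the expected chromosome-level ratio exactly the
target. A naive per-SNP binomial draw was rejected: the min() statistic
folds sampling noise back below 0.5, its expectation has a ceiling of
roughly 0.5 − 0.4/√depth, and realizing near-balanced targets that way
both misses the target mean and left-skews the null enough to break
far-tail calibration of the IQR-based Z — re-adding binomial noise on
top of a variance already fitted to observed ratios double-counts
dispersion.

All randomness derives from one seed through named streams
(`default_rng([seed, replicate, component])`), so identical
configurations reproduce byte-identical cohorts.

What the generator does **not** emulate: doublets, ambient RNA,
segmental CNVs, X-inactivation, reference/mapping bias at individual
SNPs, per-gene depth burstiness of allele sampling, or real strata
heterogeneity (a single stratum is simulated). Passing benchmarks
therefore demonstrate correctness and calibration of the statistical
machinery under the stated generative model, not performance on any
particular real data set.

## Numerical conventions and degenerate inputs

Type-7 (linear interpolation) quantiles everywhere; p-values clipped to
[1e-300, 1]; zero-MAD chromosomes and sub-5-cell strata yield p = 1
with a warning; zero-IQR nulls, zero-total-count cells, empty gene sets
and invalid configurations are hard errors naming the offender.
Benchmarks score leaf-level calls against planted truth with
sensitivity, specificity and precision; sensitivity is undefined (NA)
on all-null runs.

## Limitations

Segmental CNVs are not distinguished from whole-chromosome events;
haplotype phasing is not used (it would mainly benefit trisomy
detection); uniparental diploidy is indistinguishable from haploidy in
the allelic signal; and the expression signal requires a euploid-
dominated stratum baseline, so genome-wide abnormalities (e.g. near-
haploidy) are detectable only through allelic imbalance.
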