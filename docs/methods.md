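# Methods

This note records the statistical models the package implements, the
choices made where the design was genuinely open, and what the synthetic
generators do and do not emulate.

## Private-variant filtering

Somatic status is approximated by privacy: a variant counts as a candidate
somatic mutation when it is absent from the population databases (1000
Genomes, NHLBI exomes) and from every control exome. Two flags carry this
upstream annotation (`in_population_db`, `in_control_exomes`); the filter
is their conjunction. The predicted-impact screen then removes missense
variants called non-damaging (tolerated/benign/unknown) by **both** SIFT
and PolyPhen-2 — i.e. one damaging call suffices to keep a missense
variant. This is the literal reading of a both-predictors rule; the
alternative (requiring both to call damaging) is strictly stronger and is
not used. Truncating classes (nonsense, frameshift, splice-site) bypass
the screen entirely because the predictors only score amino-acid
substitutions. Synonymous and unclassified variants never qualify.

Residue conservation is reported but is **not** a filter by default:
conserved missense variants are highlighted in study tables rather than
being a stated inclusion rule. `require_conserved=True` (CLI
`--require-conserved`) adds the requirement for missense variants only.

The filter trace records the first failing rule in the fixed order
population database → control exomes → not damaging → (truncating mode
only) not truncating. The last value extends the nominal three-rule
vocabulary so that the trace always partitions the input.

## Carrier burden test

Carrier counting (a sample with ≥1 kept variant in the gene counts once)
rather than variant counting keeps the 2×2 margins equal to the cohort
sizes, so the test conditions on cohort size and the comparison absorbs
per-gene background mutability (gene length, local mutation rate). A
variant-level Poisson comparison is out of scope.

The two-sided Fisher exact p-value uses the minimum-likelihood definition:
with both margins fixed, cell *a* is hypergeometric; the p-value sums the
point probabilities of all tables in the support whose probability does
not exceed the observed one, with a relative slack of 1e−7 guarding float
ties. This matches the convention of mainstream statistics software, and
the implementation (vectorized `scipy.stats.hypergeom` over the support)
is verified in the tests against an independent log-factorial enumeration
oracle on **every** 2×2 table with total ≤ 30, and against
`scipy.stats.fisher_exact` on random larger tables. Degenerate margins
(an all-zero row or column) leave a single feasible table and return
p = 1. A one-sided (tumor-enrichment) variant is available behind a flag;
two-sided is the default because the direction of a reported test is
rarely stated.

Benjamini–Hochberg: q₍ᵢ₎ = min₍ⱼ≥ᵢ₎ p₍ⱼ₎·m/j clipped to 1, mapped back to
input order; ties share a q. The denominator *m* defaults to the number
of tested genes — here, all genes with ≥1 kept variant in either arm —
and can be set larger (`--universe`) when the scan should be interpreted
against an exome-wide universe. The published exome-wide FDR values for
this design cannot be recomputed without the full per-gene supplementary
counts, so the test suite substitutes operating-characteristic checks:
type-I-error control under the null generator and injected-driver
recovery (below). Note that BH is not idempotent (reapplying the step-up
to adjusted values inflates them again); the suite checks monotonicity,
q ≥ p, and agreement with `statsmodels` instead.

## Cohort association

Frequency tables stratify by WHO grade × pediatric/adult age group;
samples whose status for the queried gene is unknown are excluded from
numerator and denominator, since denominators legitimately vary with
assay coverage. The pediatric/adult boundary is a metadata field, not an
age cutoff applied by the code. Grade, location and pairwise
mutual-exclusivity tests all reduce to 2×2 tables tested by the single
exact-test implementation. Exclusivity direction compares the observed
double-mutant count with its independence expectation.

The packaged 183-sample fixture reproduces every printed cell of the
published SETD2 frequency table. Its location column is a synthetic
reconstruction: all 16 mutants are hemispheric (as reported), but
wild-type locations are unprinted and are filled by an alternating
hemispheric/midline rule — location p-values on the fixture are therefore
illustrative, and the published hemispheric p-value is not a package
target. Likewise the published H3F3A mutual-exclusivity p-value cannot be
reconstructed without per-sample assignments, so the fixture leaves
H3F3A/IDH1 statuses unknown.

## Methylation consensus clustering

Probe filtering keeps autosomal, non-cross-reactive probes whose binding
region has no known variant at minor-allele frequency ≥ 2/120 (an unknown
MAF counts as no variant). The published post-filter probe count depends
on the physical array manifest and SNP build and is reproduced only as a
rule, not a number. Betas are assumed normalized upstream (SWAN in the
original workflow); the provided `quantile_normalize` helper is a plain
per-sample quantile normalization, **not** SWAN, and is labeled as such.

Probe selection ranks by across-sample SD (n−1 denominator), ties broken
lexicographically. Hierarchical clustering is average-linkage (UPGMA) on
1 − Pearson correlation between sample columns, delegated to
`scipy.cluster.hierarchy` and verified against a brute-force O(n³)
pairwise-mean oracle.

Consensus k-means follows the resampling scheme of consensus clustering:
per k, B rounds each draw ⌈0.8·n⌉ samples without replacement (item
resampling; 0.8 is the canonical default, exposed as `--item-frac`) and
run one k-means (Euclidean on beta values — no M-value transform —
k-means++ initialization, ≤100 Lloyd iterations, one restart) via
scikit-learn. The consensus entry for a pair is its co-clustering
frequency among rounds where both were drawn; a pair never co-drawn is an
error advising a larger B. Final labels cut the average-linkage dendrogram
of 1 − consensus at k. The per-round subsamples and k-means seeds derive
from one `numpy` generator, so a fixed seed gives bit-identical results.

Model selection: the empirical CDF of upper-triangle consensus values is
evaluated on a fixed 101-point grid and integrated by the trapezoid rule
to give A(k); Δ(2) = A(2) and Δ(k) = (A(k) − A(k−1))/A(k−1). The selected
k — smallest k after which Δ drops below 0.025 — is advisory output: the
threshold is a convention, and the consensus matrices and CDF curves
remain the primary result.

## Histone densitometry

Each (sample, blot) pair contributes one H3K36me3 / total-H3 ratio;
ratios are averaged across replicate blots per sample, and the per-sample
means are compared with a two-tailed Welch t-test (the pooled Student
variant sits behind `equal_var=True`). Welch is the default because
equal group variances cannot be assumed for densitometry; testing across
samples (blots averaged first) rather than across blot-replicates avoids
pseudo-replication. The published group p-value lacks raw intensities and
is replaced by a power check at the same effect scale (below).

## Synthetic generators: what they emulate

**Variant cohorts** (default 60 tumors vs 543 controls, 200 genes):
background kept-variant counts per sample × gene are Poisson with rate
1e−2 — anchored on the observed per-gene control-exome private-variant
rate for a large gene (≈7/543 ≈ 1.3e−2) and corresponding to order 10²
private damaging variants per exome over ~2×10⁴ genes. The generator
emits a superset for the filter to work on: the raw rate is inflated so
the kept rate is exact in expectation, with decoys flagged in the
population database at rate 0.3 and background missense called
non-damaging by both predictors at rate 0.3; background variants are 5 %
truncating. Injected drivers add private damaging variants in tumors only
at `background_rate × (multiplier − 1)` with their own truncating
fraction — multiplier semantics, so a zero-background cohort emits
nothing. The driver-recovery condition used in the acceptance checks
(multiplier 14, truncating fraction 0.6) emulates the observed driver
signal of ≈8/60 tumor carriers with a 5/8 truncating excess; a
design-stage power analysis put per-seed rank-1 recovery in the
truncating-only scan at ≈0.93, so the check requires recovery in ≥15 of
20 seeds. The null check requires no gene at q < 0.05 in ≥95 % of 20
replicates. The generator does not model gene length variation,
mutational signatures, sample contamination or relatedness — passing
these checks shows the statistical machinery behaves correctly under its
own assumptions, not that real cohorts meet them.

**Beta matrices** (default 60 samples × 500 probes, 3 balanced clusters,
100 informative probes, between-cluster separation 0.25, noise SD 0.05):
cluster blocks sit at 0.5 ± shift/2; values are clipped to
[0.001, 0.999]. The sizes are scaled down from a real 450K experiment
(~4×10⁵ probes, top 8,000 used) to keep the consensus run light while
preserving the signal-to-noise regime of a clear 3-cluster structure; the
acceptance check runs B = 250 resampling rounds per seed and requires
ARI ≥ 0.9 recovery of the true labels in ≥18 of 20 seeds. Real arrays
add probe-type chemistry effects, batch structure and unbalanced
clusters, none of which are modeled.

**Densitometry** (6 samples/group, 4 replicate blots, per-blot ratio
noise SD 0.15): the mutant group's true ratio sits 3 noise-SD below the
wildtype group's 1.0. Averaging the 4 blots shrinks the per-sample SD
twofold, so the Welch test at n = 6/6 detects the shift at p < 0.001 in
nearly every seed; the check requires ≥18 of 20.

## Numerical and degenerate-input conventions

Out-of-range betas, malformed tokens, duplicate identifiers and unknown
enum values are errors naming file, line and token — never silent
coercions. Exact-test point-probability comparisons use a 1e−7 relative
slack. Burden reports order by p with ties broken by gene symbol.
Identical seeds give byte-identical generator output and pipeline TSVs
(provenance headers carry no timestamps). The beta-matrix writer emits
shortest round-trip float representations and the reader parses them
exactly, so write∘read is the identity.

## Known limitations

Published exome-wide FDR values, the hemispheric and mutual-exclusivity
p-values, the post-filter probe count and the immunoblot p-value are not
reproducible from printed data and are deliberately not asserted. The
pipeline consumes annotations (consequence, SIFT/PolyPhen-2,
conservation, database membership) and never computes them; read
alignment, variant calling and SWAN normalization are upstream concerns.
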