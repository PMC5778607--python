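# Methods

This note documents the statistical model, the numerical choices and the
synthetic-data conditions behind `tdexon`, and what the test suite does
and does not establish about real data.

## Counting units

Transcript annotations are reduced to disjoint **exonic regions**: per
gene, each transcript's exons are collapsed to their base-level union,
and the gene's pooled exon union is cut at every base where the set of
covering transcripts changes. Every region is therefore fully inside or
fully outside each annotated isoform. Genes whose exon unions overlap on
the same strand are merged into one aggregate gene group (reads in the
shared span cannot be attributed to a single gene); a drop-overlaps mode
removes them instead. Merging is strand-specific by default; a flag makes
strand `*` compatible with both strands. Coordinates are GTF/GFF 1-based
inclusive at the file boundary and half-open 0-based internally.

Paired-end mates are merged into one **fragment** before counting. A
unique fragment increments the inclusion count `k_ij1` of every region of
a single gene group that any of its aligned blocks overlaps by ≥ 1 base;
fragments touching several gene groups are discarded as ambiguous.
Skipping counts ρ require the fragment's splice gap to contain the region
entirely *and* blocks overlapping same-gene regions strictly upstream and
strictly downstream — partial gap overlap earns no credit. Rest-of-gene
counts are fragment-level: `k_ij0(region) = fragments of the gene −
fragments touching the region`, so the λ/ε split is disjoint and
`λ + ε` equals the number of distinct gene fragments (an invariant the
tests assert). When only per-region column sums are available (no
fragment stream), gene totals default to column sums — a documented
once-per-fragment-per-gene approximation.

## The Gamma-Poisson usage model

For region *i*, sample *j*, level *l* (1 = region counts, 0 = comparison
counts):

    K_ijl ~ GP(mean = s_j μ_ijl, dispersion = α_i),   Var = μ + α μ²
    log μ_ijl = β^S_ij + l β^E_i + l x^sex_j β^sex_i + l β_i,u(j),t(j)

**Size factors** are median-of-ratios over rows with no zero entry.
Because `β^S_ij` is a free per-sample effect shared by both levels, size
factors cancel from the usage coefficients; they still matter for
expression strata and normalized skipping means.

**Dispersion.** One `α_i` per region (the per-level refinement collapses
to a shared value because the reduced sample+level design pools levels),
estimated by maximizing the Cox–Reid adjusted profile likelihood
`ll(α) − ½ log det(XᵀWX)` on a grid-free bounded search over `log α ∈
[log 10⁻⁸, log 10]`. The means are **refitted at every candidate α**:
with one nuisance parameter per sample (leverage ≈ ½) the common
fixed-means shortcut biases the profile upward by O(1/μ) — on Poisson
data it produced α ≈ 2·10⁻³ where refitting correctly returns the floor.
Profiles flat down to the floor are clipped there. Across regions an
optional trend `α(μ) = a0 + a1/μ` is least-squares fitted to interior
estimates and per-region values are shrunk toward it by a fixed-weight
(default 0.5) log-space average.

**Ridge shrinkage.** `β^E` equals the column sum of the interaction
block, so the unpenalized optimum is a flat manifold; the quadratic
penalty `‖β_UT‖²/2v + (β^sex)²/2v_sex` both resolves the confounding and
implements a zero-centred normal prior. The prior variance is estimated
empirically: unpenalized first-pass fits on up to 500 regions pool their
interaction MLEs, and `v` is the upper-quantile match of a zero-centred
normal (97.5% quantile of |β| divided by z₀.₉₈₇₅, squared), minus the
mean sampling variance when supplied, floored at 0.01; fewer than 50
finite MLEs fall back to `v = 1`. Fitting is penalized Fisher scoring
(IRLS with weights `μ/(1+αμ)`), convergence at max |Δβ| < 10⁻⁸ or 100
iterations, linear predictors clipped to ±30. An infinite prior variance
is realized as a 10⁻⁶ stabilizing ridge on the penalized blocks — the
minimum-norm representative of the flat direction with an acceptably
conditioned system. Two consequences worth knowing: shrunken
coefficients are *attenuated* by roughly `κ = v/(v + sampling variance)`
(the tests verify recovery against `κ·truth`), and exact sample-rescaling
invariance holds only for unpenalized fits.

**Expression filters.** Regions need a total count ≥ 10 (configurable)
across samples and levels; the spliced-in fit additionally requires a
mean skipping count ≥ 1 — below that the denominator is noise and the
region is flagged `skip_below_floor`, never silently zeroed.

## Testing and scoring

The **tissue score** robust-standardizes a region's REUC matrix
(median/SD over all (u,t) entries, n−1 denominator, Z ≡ 0 when the SD is
0) and takes the largest absolute per-tissue mean over individuals. The
**LRT** compares GP GLMs with and without the level:tissue interaction
(per-sample effects, level, level:sex in both; sex dropped when
constant), statistic referred to χ² with (tissues − 1) df, BH-adjusted
across all tested regions of the dataset. Individual is not in the
testing model by default (keeps df small); `with_individual=True` adds
level:individual to both models. TDU requires padj ≤ 0.1 *and* score
strictly > 1. The code path is unit-agnostic: any units×samples table
with a unit→group map (e.g. CAGE TSS clusters within genes) is testable,
giving per-gene differential-TSS calls.

## Mechanism attribution

Three signals per TDU region: the skipping stratum of the size-factor
normalized mean skip count (none = 0, weak ≤ 1, moderate ≤ 10, strong
> 10 — only the "> 10" bound is anchored externally; the inner edges are
configurable conventions), the tissue partial R² of REUC and RSIC
matrices (`1 − RSS_full/RSS_reduced` from closed-form two-way ANOVA group
means; implemented literally against the individual-only reduced model,
not total variance), and the REUC–RSIC Pearson correlation over shared
entries (≥ 3 required, undefined for constant rows). The label rule:
TDU-AS when stratum is strong *and* r ≥ 0.5 *and* RSIC R² ≥ 0.3; TDU-NAS
when stratum is none/weak; otherwise unresolved. All three signals are
reported so users can apply their own rule.

## Synthetic studies

The generator inverts the fitted model: fully crossed m×T designs
(defaults 10 individuals × 6 tissues, alternating sexes), 300 genes of
3–8 regions (100 bp exons, 200 bp introns), baseline region means
log-normal(log 100, 1), constant α = 0.05, size factors log-uniform in
[0.5, 2], 10% of genes carrying one affected region with a 1.5 log-unit
shift in one tissue, split evenly between mechanisms. Values chosen once
as a plausible bulk-cohort scale: dispersions of a few percent and
region means of ~10²–10³ fragments are typical of deep bulk RNA-seq, and
one affected region per affected gene keeps gene expression and usage
unconfounded.

Mechanism emulation: a **splicing** event sits on an internal region;
its skipping mean is 0.3× its baseline (a well-supported cassette exon)
and shifts opposite to inclusion, approximately conserving gene totals. A
**boundary** (start/termination) event either sits on a terminal region,
which has *no* skipping reads at all (no flanking anchors exist), or —
with probability 0.5 — emulates an internal alternative TSS/polyA: its
junction reads come from the same long isoform as its inclusion reads,
so the skipping mean co-shifts proportionally and the spliced-in ratio
stays flat. Unaffected internal regions keep a small constitutive
skipping rate (5·10⁻⁴ of the region mean). The emitted count tables are
exactly reproducible from the emitted fragment stream: inclusion counts
include the junction fragments' anchor blocks in neighbouring regions,
and gene totals count each fragment once; the tests assert byte-exact
recount equality. PRNG is numpy's PCG64 (`default_rng`); a seed is
mandatory and fully determines all outputs.

**What the generator does not emulate:** overlapping genes, multi-mapper
ambiguity, fragment-length and positional coverage biases, correlated
effects across regions, isoform-level linkage between events, or
between-individual biological variation beyond the GP dispersion.
Passing tests demonstrate the estimator and test are correct *under the
stated model*, not that real consortium-scale data meet its assumptions.

**Relative-usage coupling.** Usage is relative within a gene: planting a
shift in one region genuinely moves its gene-mates' usage coefficients
(their ε pools include the shifted region, and junction anchors add
tissue-dependent inclusion to neighbours). Empirical FDR on simulations
is therefore evaluated at the gene level — a false discovery is a call
in a gene with *no* planted effect. Measured margins under the default
conditions: pooled null KS ≈ 0.02, gene-level empirical FDR ≈ 0–3% at a
nominal 10%, recall of strong planted events ≈ 100%, mechanism labels
≥ 90% correct per class.

## Enrichment machinery

Background sets are built by 1:1 nearest-neighbour matching without
replacement on standardized covariates (log mean count + region count
for genes; log mean count + width for exons), ties broken by unit id,
targets processed in input order; a warning fires when matched covariate
means deviate by > 0.25 SD. Category enrichment is the Pearson χ² on the
k×2 categories×{target, background} table (continuity correction off by
default) with per-category odds ratios. High-expression genes are those
with a mean of ≥ 100 fragments per sample.

## Problem sizes and determinism

The shipped test and acceptance runs use deliberately modest study sizes
— null calibration on 20 seeds × ~500 regions (60 samples), FDR/recall on
20 mixed studies of 60 genes, mechanism attribution on one 300-gene
study — chosen so the full suite completes in minutes on a single core
while leaving the asserted margins wide. All stochastic tests pin seeds;
pipeline outputs carry the package version, a config hash and the seed in
their headers, and identical inputs reproduce byte-identical files.

## Known limitations

* The ridge attenuates strong effects (by design); reported REUCs are
  conservative effect sizes, not unbiased MLEs.
* One dispersion per region, not per level; severely different
  overdispersion between a region and its gene remainder is absorbed
  imperfectly.
* The LRT's χ² reference is asymptotic; with very small designs (< ~4
  samples per tissue) p-values can drift from nominal.
* The TDU-AS/TDU-NAS rule is a calibrated convention on three continuous
  signals; borderline regions (moderate skipping) land in `unresolved`
  rather than being forced into a class.
* The matcher is greedy, not optimal assignment; with highly imbalanced
  pools the covariate-mean warning should be heeded.
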