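# tdexon

Tissue-dependent exon usage from RNA-seq counts, and the attribution of
each event to alternative splicing versus alternative transcription
start/termination sites.

## The problem

Most multi-exonic genes express several transcript isoforms, produced by
three processes: alternative splicing, alternative transcription start
sites (TSS) and alternative polyadenylation/termination sites. Bulk
RNA-seq of a tissue panel shows *which exons* change their usage between
tissues, but not *which process* drives the change. `tdexon` implements a
count-level strategy that separates the two: an exon removed by splicing
leaves a footprint of exon–exon junction reads that skip it, whereas an
exon dropped by a shifted transcript boundary does not.

The package is aimed at analysts with (a) a transcript annotation
(GTF/GFF), (b) per-sample fragment alignments (SAM) or precomputed count
tables, and (c) a **fully crossed** design — every individual sampled in
every tissue — plus a sex covariate.

## Model

Transcripts are flattened into disjoint *exonic regions* (the base-level
exon union of a gene, cut wherever any transcript boundary falls), so
every aligned fragment is countable unambiguously. For region *i* of a
gene, sample *j* and level *l* ∈ {0, 1}:

* `k_ij1` — fragments overlapping region *i* (inclusion, λ);
* `k_ij0` — either the fragments of the same gene **not** touching *i*
  (rest-of-gene, ε; the exon-usage scheme) or the fragments whose splice
  gap skips *i* while anchoring both upstream and downstream (ρ; the
  spliced-in scheme).

Counts follow a Gamma-Poisson (negative binomial) GLM,

    K_ijl ~ GP(mean = s_j · μ_ijl,  dispersion = α_i)
    log μ_ijl = β^S_ij + l·β^E_i + l·x^sex_j·β^sex_i + l·β_iu(j)t(j)

with `s_j` the median-of-ratios size factor, `β^S` per-sample expression,
`β^E` the mean log usage, `x^sex` coded −1/2 (male) / +1/2 (female), and
`β_iut` the individual×tissue interaction — the **relative exon usage
coefficient (REUC)** under the ε scheme, the **relative spliced-in
coefficient (RSIC)** under the ρ scheme. Interaction and sex coefficients
carry a ridge (zero-centred normal) prior whose variance is estimated
empirically across regions; dispersions are Cox–Reid adjusted profile ML
estimates with an optional `a0 + a1/μ` trend shrinkage.

A region shows **tissue-dependent usage (TDU)** when (1) a χ² likelihood
ratio test of the level:tissue interaction is significant at
Benjamini–Hochberg FDR ≤ 10% and (2) its tissue score
`T_i = max_t |mean_u Z_iut| > 1`, where `Z` are median/SD z-scores of the
REUCs. TDU events are then attributed: strong skipping evidence
(normalized mean skip count > 10) together with high REUC–RSIC agreement
(Pearson r and tissue partial R² of the RSIC ANOVA) ⇒ splicing-driven
(**TDU-AS**); no or weak skipping evidence ⇒ consistent with alternative
transcript boundaries (**TDU-NAS**). The partial R² compares two-way
(individual + tissue) against individual-only least-squares fits of the
coefficient matrix: `R² = 1 − RSS_full / RSS_reduced`.

## Worked example

A synthetic fully crossed study (10 individuals × 6 tissues, 80 genes,
15% of genes carrying one planted event of 1.5 log units):

```python
import numpy as np
from tdexon import ExonUsageModel, SimulationConfig, simulate_study

study = simulate_study(
    SimulationConfig(seed=42, n_genes=80, fraction_affected=0.15,
                     effect_size=1.5, baseline_log_mean=(np.log(300.0), 0.5))
)
results = ExonUsageModel(study.tables, study.design, study.model).fit()
mech = results.attribute_mechanisms()
print(results.summary())
```

```
Tissue-dependent exon usage
==========================================
samples:             60 (10 individuals x 6 tissues)
regions:             450
tested regions:      450
TDU regions:         55 (FDR 10%, score > 1)
fraction TDU:        0.122 of tested
shrinkage prior var: 0.08412
mechanism labels:    TDU-NAS=50, TDU-AS=5
```

55 of 450 regions are called tissue-dependent; the shrinkage prior
variance 0.084 is the estimated spread of true interaction effects. The
three most significant calls:

```
            pvalue  padj  tissue_score argmax_tissue
G0061:E003     0.0   0.0        2.2901            T5
G0021:E006     0.0   0.0        2.4577            T1
G0034:E004     0.0   0.0        2.3387            T5

            mean_skip skip_stratum  r2_reuc  r2_rsic  pearson_r    label
G0061:E003     50.247       strong    0.881    0.935      0.959   TDU-AS
G0021:E006      0.000         none    0.911      NaN        NaN  TDU-NAS
G0034:E004     97.864       strong    0.871    0.939      0.956   TDU-AS
```

`G0061:E003` is a cassette exon: ~50 junction reads per sample skip it,
its REUC and RSIC matrices agree (r = 0.96) and both ANOVAs put ~90% of
coefficient variance between tissues — splicing-driven. `G0021:E006` has
a tissue-dependent REUC pattern (R² = 0.91) but not a single skipping
read: its usage change can only come from an alternative transcription
start or termination site.

The same machinery runs from the shell (`tdexon flatten / count /
simulate / estimate / test / run`), and
`ExonUsageModel.from_unit_counts` applies the identical test to any
units-within-groups count table, e.g. CAGE TSS clusters within genes,
yielding per-gene differential-TSS calls.

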