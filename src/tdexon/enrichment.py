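"""Gene-level TDU summaries and matched-background enrichment tests.

Gene summaries report, per gene, the fraction of its exonic regions and
of its exonic base pairs called tissue-dependent, plus a high-expression
flag (mean of at least 100 sequenced fragments per sample).

Enrichment against a matched background: because TDU calls correlate with
expression strength and gene/exon size, category enrichment (e.g. coding
principal / coding non-principal / 5'UTR / 3'UTR / processed transcript)
is tested against a background of units matched 1:1 on standardized
covariates (nearest neighbour without replacement), with a Pearson
chi-square test on the category x {target, background} table and
per-category odds ratios.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .annotation import FlattenedGeneModel

__all__ = [
    "summarize_gene_tdu",
    "matched_background",
    "category_enrichment",
    "HIGH_EXPRESSION_MEAN",
]

HIGH_EXPRESSION_MEAN = 100.0


def summarize_gene_tdu(
    tdu: pd.DataFrame,
    model: FlattenedGeneModel,
    inclusion: pd.DataFrame,
    *,
    high_expression_mean: float = HIGH_EXPRESSION_MEAN,
) -> pd.DataFrame:
    """Per-gene TDU summary.

    Returns one row per gene group: number of regions, number and
    fraction of TDU regions, total and TDU base pairs, mean fragments per
    sample (sum of the gene's inclusion counts) and the high-expression
    flag (mean >= ``high_expression_mean``).
    """
    is_tdu = tdu["is_tdu"].astype(bool)
    rows = []
    for gid in model.gene_ids:
        regs = model.regions_of(gid)
        keys = [r.key for r in regs]
        widths = np.array([r.width for r in regs])
        flags = np.array([bool(is_tdu.get(k, False)) for k in keys])
        mean_frag = float(
            inclusion.reindex(keys).fillna(0).to_numpy().sum(axis=0).mean()
        )
        rows.append(
            {
                "gene_id": gid,
                "n_regions": len(regs),
                "n_tdu_regions": int(flags.sum()),
                "frac_regions_tdu": float(flags.mean()),
                "total_bp": int(widths.sum()),
                "tdu_bp": int(widths[flags].sum()),
                "frac_bp_tdu": float(widths[flags].sum() / widths.sum()),
                "mean_fragments": mean_frag,
                "high_expression": mean_frag >= high_expression_mean,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def matched_background(
    targets: list[str],
    pool: list[str],
    covariates: pd.DataFrame,
    *,
    max_mean_gap_sd: float = 0.25,
) -> list[str]:
    """1:1 nearest-neighbour covariate matching without replacement.

    ``covariates`` holds one row per unit (targets and pool) and one
    column per matching covariate (e.g. log mean count and region count).
    Covariates are standardized over the union; each target, in input
    order, takes the closest remaining pool unit (Euclidean distance, ties
    broken by unit id).  Raises when the pool (after removing targets) is
    smaller than the target set; warns via the returned diagnostics when
    the matched covariate means differ from the targets' by more than
    ``max_mean_gap_sd`` standard deviations.
    """
    target_set = set(targets)
    pool_clean = [u for u in pool if u not in target_set]
    if len(pool_clean) < len(targets):
        raise ValueError(
            f"matching pool too small: {len(pool_clean)} candidates for "
            f"{len(targets)} targets"
        )
    X = covariates.loc[list(targets) + pool_clean].astype(float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0).replace(0, 1.0)
    Xs = (X - mu) / sd
    tX = Xs.loc[targets].to_numpy()
    pX = Xs.loc[pool_clean].to_numpy()
    available = np.ones(len(pool_clean), dtype=bool)
    pool_ids = np.array(pool_clean)
    chosen: list[str] = []
    for i in range(len(targets)):
        d = np.sqrt(((pX - tX[i]) ** 2).sum(axis=1))
        d[~available] = np.inf
        best = np.min(d)
        tied = np.flatnonzero(d == best)
        pick = tied[np.argsort(pool_ids[tied], kind="mergesort")[0]]
        available[pick] = False
        chosen.append(str(pool_ids[pick]))
    gap = np.abs(
        Xs.loc[targets].mean(axis=0).to_numpy() - Xs.loc[chosen].mean(axis=0).to_numpy()
    )
    if (gap > max_mean_gap_sd).any():
        import warnings

        warnings.warn(
            f"matched covariate means deviate by up to {gap.max():.2f} SD "
            f"(threshold {max_mean_gap_sd})",
            stacklevel=2,
        )
    return chosen


def category_enrichment(
    targets: list[str],
    background: list[str],
    labels: pd.Series,
    *,
    continuity_correction: bool = False,
) -> pd.DataFrame:
    """Category x {target, background} enrichment table.

    Pearson chi-square test over the k x 2 contingency table plus a
    per-category odds ratio (target odds of the category vs background
    odds).  Categories absent from both arms are dropped.  The resulting
    frame carries the chi2 statistic, p-value and df in ``attrs``.
    """
    missing = [u for u in list(targets) + list(background) if u not in labels.index]
    if missing:
        raise ValueError(f"units without category label: {missing[:5]}")
    t_counts = labels.loc[targets].value_counts()
    b_counts = labels.loc[background].value_counts()
    cats = sorted(set(t_counts.index) | set(b_counts.index))
    table = pd.DataFrame(
        {
            "target": [int(t_counts.get(c, 0)) for c in cats],
            "background": [int(b_counts.get(c, 0)) for c in cats],
        },
        index=pd.Index(cats, name="category"),
    )
    zero = table.sum(axis=1) == 0
    if zero.any():
        table = table[~zero]
    obs = table.to_numpy()
    if obs.shape[0] < 2:
        chi2_stat, pval, dof = 0.0, 1.0, 0
    else:
        chi2_stat, pval, dof, _exp = chi2_contingency(
            obs, correction=continuity_correction
        )
    n_t, n_b = obs[:, 0].sum(), obs[:, 1].sum()
    odds = []
    for a, c in obs:
        b = n_t - a
        d = n_b - c
        if b == 0 or c == 0:
            odds.append(np.inf if a > 0 and d > 0 else np.nan)
        elif a == 0 or d == 0:
            odds.append(0.0)
        else:
            odds.append((a / b) / (c / d))
    table["odds_ratio"] = odds
    table.attrs["chi2"] = float(chi2_stat)
    table.attrs["pvalue"] = float(pval)
    table.attrs["df"] = int(dof)
    return table
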