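"""Per-region usage coefficients (REUC / RSIC) across a study.

For every exonic region this module pairs the region's inclusion counts
with a comparison count vector and fits the penalized Gamma-Poisson GLM:

* REUC scheme: comparison = rest-of-gene counts.  The interaction
  coefficients are Relative Exon Usage Coefficients — log fold changes of
  the region's usage in each individual-tissue combination relative to the
  average usage.
* RSIC scheme: comparison = skipping-junction counts.  The interaction
  coefficients are Relative Spliced-In Coefficients, which respond only to
  splicing-driven usage changes: a shift in transcript start/termination
  site changes inclusion and rest-of-gene counts but produces no
  exon-exon junction reads across the region.

Regions are fitted independently; results do not depend on execution
order.  The shrinkage prior for the interaction (and sex) coefficients is
estimated once per study from unpenalized first-pass fits of a subsample
of regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .counting import CountTables
from .glm import (
    DesignTable,
    SizeFactors,
    estimate_dispersion,
    estimate_shrinkage_prior,
    estimate_size_factors,
    fit_dispersion_trend,
    fit_gp_glm,
)

__all__ = ["UsageCoefficientMatrix", "estimate_usage", "estimate_reucs", "estimate_rsics"]

DEFAULT_MIN_TOTAL = 10
DEFAULT_SKIP_FLOOR = 1.0
PRIOR_SUBSAMPLE = 500


@dataclass
class UsageCoefficientMatrix:
    """Fitted usage coefficients for all (estimable) regions of a study.

    ``values`` has one row per region and one ``individual:tissue`` column
    per design combination; excluded regions carry NaN rows and a reason
    in ``fit_flags`` — never silent zeros.
    """

    scheme: str  # "reuc" or "rsic"
    values: pd.DataFrame
    mean_usage: pd.Series
    sex_effect: pd.Series
    fit_flags: pd.DataFrame  # columns: fitted, converged, reason
    dispersions: pd.Series
    individuals: list[str]
    tissues: list[str]
    prior_variance: float = np.nan
    prior_variance_sex: float = np.nan
    size_factors: SizeFactors | None = None

    def matrix(self, region: str) -> pd.DataFrame:
        """One region's coefficients as an individuals x tissues DataFrame."""
        row = self.values.loc[region]
        m = pd.DataFrame(np.nan, index=self.individuals, columns=self.tissues)
        for label, v in row.items():
            u, t = label.rsplit(":", 1)
            m.at[u, t] = v
        return m

    @property
    def fitted_regions(self) -> list[str]:
        return list(self.fit_flags.index[self.fit_flags["fitted"]])

    def to_tsv(self, path, meta: dict | None = None) -> None:
        from ._io import write_tsv

        out = self.values.copy()
        out.insert(0, "mean_usage", self.mean_usage)
        out.insert(1, "sex_effect", self.sex_effect)
        out.index.name = "region"
        header = {
            "scheme": self.scheme,
            "prior_variance": self.prior_variance,
            "prior_variance_sex": self.prior_variance_sex,
        }
        if meta:
            header.update(meta)
        write_tsv(out.reset_index(), path, header)


def _align(counts: pd.DataFrame, design: DesignTable) -> None:
    extra = set(counts.columns) ^ set(design.samples)
    if extra:
        raise ValueError(
            f"count/design sample mismatch: {sorted(extra)[:10]}"
        )


def estimate_usage(
    tables: CountTables,
    design: DesignTable,
    scheme: str = "reuc",
    *,
    size_factors: SizeFactors | None = None,
    min_total: int = DEFAULT_MIN_TOTAL,
    skip_floor: float = DEFAULT_SKIP_FLOOR,
    alpha: float | pd.Series | None = None,
    prior_variance: float | None = None,
    prior_variance_sex: float | None = None,
    dispersion_trend: bool = True,
    trend_shrink_weight: float = 0.5,
    prior_subsample: int = PRIOR_SUBSAMPLE,
    rng: np.random.Generator | None = None,
) -> UsageCoefficientMatrix:
    """Estimate usage coefficients for every estimable region.

    Parameters largely mirror the fitting pipeline: an expression filter
    (total count across samples and levels >= ``min_total``), per-region
    Cox-Reid dispersions with an optional ``a0 + a1/mu`` trend shrinkage,
    an empirical-Bayes ridge prior estimated from unpenalized first-pass
    fits (unless ``prior_variance`` is given), then the penalized fit.

    ``alpha`` overrides dispersion estimation with a fixed scalar or a
    per-region Series (used by simulations where truth is known).
    """
    if scheme not in ("reuc", "rsic"):
        raise ValueError(f"unknown scheme {scheme!r}")
    if tables.rest is None and scheme == "reuc":
        raise ValueError("rest-of-gene counts missing; run build_reuc_pairs first")
    k1_mat = tables.inclusion
    k0_mat = tables.rest if scheme == "reuc" else tables.skipping
    _align(k1_mat, design)
    order = design.samples
    k1_mat = k1_mat[order]
    k0_mat = k0_mat[order]

    if size_factors is None:
        size_factors = estimate_size_factors(k1_mat)
    s = size_factors.to_numpy()

    regions = list(k1_mat.index)
    flags = pd.DataFrame(
        {"fitted": False, "converged": False, "reason": ""}, index=regions
    )
    k1a = k1_mat.to_numpy(dtype=np.int64)
    k0a = k0_mat.to_numpy(dtype=np.int64)

    estimable = np.ones(len(regions), dtype=bool)
    tot = k1a.sum(axis=1) + k0a.sum(axis=1)
    low = tot < min_total
    flags.loc[low, "reason"] = "low_count"
    estimable &= ~low
    no_comparison = k0a.sum(axis=1) == 0
    flags.loc[no_comparison & estimable, "reason"] = (
        "no_rest_counts" if scheme == "reuc" else "never_skipped"
    )
    estimable &= ~no_comparison
    no_signal = k1a.sum(axis=1) == 0
    flags.loc[no_signal & estimable, "reason"] = "no_inclusion_counts"
    estimable &= ~no_signal
    if scheme == "rsic":
        low_skip = k0a.mean(axis=1) < skip_floor
        flags.loc[low_skip & estimable, "reason"] = "skip_below_floor"
        estimable &= ~low_skip

    idx_est = np.flatnonzero(estimable)

    # dispersions
    mean_norm = ((k1a + k0a) / s[None, :]).mean(axis=1) / 2.0
    if alpha is None:
        raw = pd.Series(np.nan, index=regions, dtype=float)
        for i in idx_est:
            raw.iloc[i] = estimate_dispersion(k1a[i], k0a[i], design, size_factors)
        if dispersion_trend:
            est = fit_dispersion_trend(
                raw.iloc[idx_est],
                pd.Series(mean_norm[idx_est], index=raw.index[idx_est]),
                shrink_weight=trend_shrink_weight,
            )
            dispersions = raw.copy()
            dispersions.iloc[idx_est] = est.alpha.to_numpy()
        else:
            dispersions = raw
    elif np.isscalar(alpha):
        dispersions = pd.Series(
            np.where(estimable, float(alpha), np.nan), index=regions
        )
    else:
        dispersions = pd.Series(alpha).reindex(regions)

    # empirical-Bayes prior from unpenalized first-pass fits on a subsample
    if prior_variance is None or prior_variance_sex is None:
        rng = rng or np.random.default_rng(0)
        sub = idx_est
        if len(sub) > prior_subsample:
            sub = np.sort(rng.choice(sub, size=prior_subsample, replace=False))
        mle_ut: list[np.ndarray] = []
        mle_sex: list[float] = []
        for i in sub:
            cs = fit_gp_glm(
                k1a[i], k0a[i], design, size_factors,
                dispersions.iloc[i], prior_variance=np.inf,
                prior_variance_sex=np.inf,
            )
            mle_ut.append(cs.beta_UT.to_numpy().ravel())
            mle_sex.append(cs.beta_sex)
        pooled = np.concatenate(mle_ut) if mle_ut else np.array([])
        if prior_variance is None:
            prior_variance = estimate_shrinkage_prior(pooled)
        if prior_variance_sex is None:
            prior_variance_sex = estimate_shrinkage_prior(np.asarray(mle_sex))

    combo_labels = [
        f"{u}:{t}" for u, t in zip(design.table["individual"], design.table["tissue"])
    ]
    values = pd.DataFrame(np.nan, index=regions, columns=combo_labels, dtype=float)
    mean_usage = pd.Series(np.nan, index=regions, dtype=float)
    sex_effect = pd.Series(np.nan, index=regions, dtype=float)

    for i in idx_est:
        r = regions[i]
        cs = fit_gp_glm(
            k1a[i], k0a[i], design, size_factors,
            dispersions.iloc[i],
            prior_variance=prior_variance,
            prior_variance_sex=prior_variance_sex,
        )
        values.iloc[i] = cs.ut_vector(design)
        mean_usage.iloc[i] = cs.beta_E
        sex_effect.iloc[i] = cs.beta_sex
        flags.loc[r, "fitted"] = True
        flags.loc[r, "converged"] = cs.converged
        if not cs.converged:
            flags.loc[r, "reason"] = "not_converged"

    return UsageCoefficientMatrix(
        scheme=scheme,
        values=values,
        mean_usage=mean_usage,
        sex_effect=sex_effect,
        fit_flags=flags,
        dispersions=dispersions,
        individuals=design.individuals,
        tissues=design.tissues,
        prior_variance=float(prior_variance),
        prior_variance_sex=float(prior_variance_sex),
        size_factors=size_factors,
    )


def estimate_reucs(tables: CountTables, design: DesignTable, **kw) -> UsageCoefficientMatrix:
    """Relative exon usage coefficients (inclusion vs rest-of-gene)."""
    return estimate_usage(tables, design, scheme="reuc", **kw)


def estimate_rsics(tables: CountTables, design: DesignTable, **kw) -> UsageCoefficientMatrix:
    """Relative spliced-in coefficients (inclusion vs skipping junctions)."""
    return estimate_usage(tables, design, scheme="rsic", **kw)
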