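"""Gamma-Poisson GLM core: size factors, dispersion, penalized fitting.

The count model.  For exonic region i, sample j and level l (l = 1 for the
region's own counts, l = 0 for the comparison counts — rest-of-gene for the
exon-usage scheme, skipping junctions for the spliced-in scheme):

    K_ijl ~ GP(mean = s_j * mu_ijl, dispersion = alpha_i)
    log mu_ijl = beta_S[j] + l*beta_E + l*x_sex[j]*beta_sex + l*beta_UT[u(j), t(j)]

where s_j is a per-sample scaling factor for sequencing depth, beta_S
absorbs overall gene expression of sample j, beta_E is the mean log usage
ratio across samples, beta_sex a sex effect (x_sex = -1/2 male, +1/2
female), and beta_UT the individual-by-tissue interaction — the relative
usage coefficient.  The Gamma-Poisson (negative binomial) variance is
mu + alpha*mu^2.

The interaction (and sex) coefficients are ridge-penalized with an
empirically estimated prior variance: without the penalty beta_E and the
beta_UT block are confounded (their column sums coincide), and the
per-(u,t) coefficients of a saturated design would be noisy.  The ridge is
the quadratic-penalty form of a zero-centred normal prior, so the fit is a
maximum a-posteriori estimate and the penalized likelihood is strictly
concave.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

__all__ = [
    "DesignTable",
    "SizeFactors",
    "CoefficientSet",
    "DispersionEstimate",
    "estimate_size_factors",
    "nb_loglik",
    "fit_gp_glm",
    "estimate_dispersion",
    "fit_dispersion_trend",
    "estimate_shrinkage_prior",
    "usage_design_matrix",
]

ALPHA_FLOOR = 1e-8
ALPHA_CEILING = 10.0
IRLS_TOL = 1e-8
IRLS_MAXIT = 100
# small stabilizing ridge so an infinite prior variance (no shrinkage)
# still yields the minimum-norm representative of the confounded directions
# with an acceptably conditioned system
STABILIZER = 1e-6


# ---------------------------------------------------------------------------
# Design table
# ---------------------------------------------------------------------------


class DesignError(ValueError):
    pass


@dataclass
class DesignTable:
    """Sample layout: individual, tissue and sex per sample.

    Sex may be given as 'M'/'F' (mapped to -1/2 and +1/2) or directly as
    the numeric covariate.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample", "individual", "tissue"}
        missing = required - set(self.table.columns)
        if missing:
            raise DesignError(f"design table missing columns: {sorted(missing)}")
        t = self.table.copy()
        t["sample"] = t["sample"].astype(str)
        t["individual"] = t["individual"].astype(str)
        t["tissue"] = t["tissue"].astype(str)
        if t["sample"].duplicated().any():
            raise DesignError("duplicate sample ids in design table")
        if "sex" not in t.columns:
            t["sex"] = 0.0
        self.table = t.reset_index(drop=True)

    @classmethod
    def from_tsv(cls, path) -> "DesignTable":
        return cls(pd.read_csv(path, sep="\t", comment="#"))

    @property
    def samples(self) -> list[str]:
        return list(self.table["sample"])

    @property
    def individuals(self) -> list[str]:
        return sorted(self.table["individual"].unique())

    @property
    def tissues(self) -> list[str]:
        return sorted(self.table["tissue"].unique())

    @property
    def n_samples(self) -> int:
        return len(self.table)

    @property
    def x_sex(self) -> np.ndarray:
        """Sex covariate per sample: -1/2 for male, +1/2 for female."""
        v = self.table["sex"]
        if v.dtype == object:
            mapping = {"M": -0.5, "male": -0.5, "F": 0.5, "female": 0.5}
            try:
                return v.map(mapping).astype(float).to_numpy()
            except Exception as e:  # noqa: BLE001
                raise DesignError(f"cannot interpret sex column: {e}") from e
        return v.astype(float).to_numpy()

    def is_fully_crossed(self) -> bool:
        """True when every individual x tissue combination occurs exactly once."""
        ct = pd.crosstab(self.table["individual"], self.table["tissue"])
        return (
            ct.shape == (len(self.individuals), len(self.tissues))
            and (ct.to_numpy() == 1).all()
        )

    def require_fully_crossed(self) -> None:
        if not self.is_fully_crossed():
            raise DesignError(
                "design is not fully crossed: every individual x tissue "
                "combination must be present exactly once"
            )

    def reorder(self, samples: list[str]) -> "DesignTable":
        missing = set(samples) - set(self.samples)
        if missing:
            raise DesignError(f"samples absent from design: {sorted(missing)[:5]}")
        t = self.table.set_index("sample").loc[samples].reset_index()
        return DesignTable(t)


# ---------------------------------------------------------------------------
# Size factors (median-of-ratios)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SizeFactors:
    s: pd.Series  # per sample, positive

    def __post_init__(self) -> None:
        if (self.s <= 0).any() or not np.isfinite(self.s).all():
            raise ValueError("size factors must be positive and finite")

    def __getitem__(self, sample: str) -> float:
        return float(self.s[sample])

    def to_numpy(self) -> np.ndarray:
        return self.s.to_numpy(dtype=float)


def estimate_size_factors(counts: pd.DataFrame) -> SizeFactors:
    """Median-of-ratios size factors.

    s_j = median over rows of count_ij / geometric-mean_i, where the
    median runs over rows whose geometric mean across samples is positive
    (i.e. rows with no zero entry).
    """
    m = np.asarray(counts, dtype=float)
    with np.errstate(divide="ignore"):
        log_m = np.log(m)
    log_gm = log_m.mean(axis=1)
    ok = np.isfinite(log_gm)
    if not ok.any():
        raise ValueError(
            "cannot estimate size factors: no row has positive counts in all "
            "samples; filter or pseudo-count the input"
        )
    ratios = log_m[ok] - log_gm[ok, None]
    s = np.exp(np.median(ratios, axis=0))
    cols = counts.columns if isinstance(counts, pd.DataFrame) else range(m.shape[1])
    return SizeFactors(pd.Series(s, index=cols, name="size_factor"))


# ---------------------------------------------------------------------------
# Gamma-Poisson likelihood
# ---------------------------------------------------------------------------


def nb_loglik(y: np.ndarray, mu: np.ndarray, alpha) -> float:
    """Log-likelihood of counts y under GP(mean=mu, dispersion=alpha).

    ``alpha`` may be a scalar or an array broadcastable to y; alpha = 0
    gives the Poisson limit.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), y.shape)
    out = np.empty_like(y)
    pois = alpha <= 0
    if pois.any():
        m = mu[pois]
        yy = y[pois]
        with np.errstate(divide="ignore", invalid="ignore"):
            val = yy * np.log(m) - m - gammaln(yy + 1)
        out[pois] = np.where(m == 0, np.where(yy == 0, 0.0, -np.inf), val)
    nb = ~pois
    if nb.any():
        r = 1.0 / alpha[nb]
        m = mu[nb]
        yy = y[nb]
        out[nb] = (
            gammaln(yy + r)
            - gammaln(r)
            - gammaln(yy + 1)
            + r * np.log(r / (r + m))
            + yy * np.log(m / (r + m))
        )
    return float(out.sum())


# ---------------------------------------------------------------------------
# Penalized IRLS
# ---------------------------------------------------------------------------


def irls_nb(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    alpha: np.ndarray | float,
    penalty: np.ndarray,
    *,
    tol: float = IRLS_TOL,
    maxit: int = IRLS_MAXIT,
    beta0: np.ndarray | None = None,
) -> tuple[np.ndarray, bool, int]:
    """Penalized Fisher scoring for the log-link Gamma-Poisson GLM.

    Maximizes sum nb_loglik(y; exp(offset + X beta), alpha) minus
    0.5 * sum penalty_k * beta_k^2.  ``penalty`` is the per-coefficient
    ridge weight (0 = unpenalized).  Returns (beta, converged, n_iter).
    """
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), y.shape)
    P = np.asarray(penalty, dtype=float)
    if beta0 is None:
        beta = np.zeros(p)
        # crude start: intercept-free, work from log(y + 0.5)
        eta = np.log(y + 0.5) - offset
    else:
        beta = beta0.copy()
        eta = X @ beta
    converged = False
    it = 0
    for it in range(1, maxit + 1):
        eta = np.clip(eta, -30.0, 30.0)
        mu = np.exp(offset + eta)
        w = mu / (1.0 + alpha * mu)
        z = eta + (y - mu) / mu
        XtW = X.T * w
        A = XtW @ X
        A[np.diag_indices_from(A)] += P
        b = XtW @ z
        try:
            beta_new = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            beta_new = np.linalg.lstsq(A, b, rcond=None)[0]
        delta = np.max(np.abs(beta_new - beta))
        beta = beta_new
        eta = X @ beta
        if delta < tol:
            converged = True
            break
    return beta, converged, it


# ---------------------------------------------------------------------------
# The usage model design
# ---------------------------------------------------------------------------


def usage_design_matrix(design: DesignTable) -> tuple[np.ndarray, np.ndarray, dict]:
    """Stacked design matrix for the per-region usage fit.

    Rows: the n samples at level 0 followed by the n samples at level 1.
    Columns: n per-sample effects beta_S, one beta_E, one beta_sex, then
    one interaction column per (individual, tissue) combination present
    in the design.  Returns (X, penalized_mask, meta) where meta records
    the column layout.
    """
    n = design.n_samples
    individuals = design.individuals
    tissues = design.tissues
    combos = [
        (u, t)
        for u, t in zip(design.table["individual"], design.table["tissue"])
    ]
    combo_labels = [f"{u}:{t}" for u, t in combos]
    p = n + 2 + n  # S block, E, sex, UT block (one combo per sample)
    X = np.zeros((2 * n, p))
    l = np.concatenate([np.zeros(n), np.ones(n)])
    for j in range(n):
        X[j, j] = 1.0
        X[n + j, j] = 1.0
    X[:, n] = l
    X[n:, n + 1] = design.x_sex
    for j in range(n):
        X[n + j, n + 2 + j] = 1.0
    meta = {
        "n": n,
        "col_S": slice(0, n),
        "col_E": n,
        "col_sex": n + 1,
        "col_UT": slice(n + 2, p),
        "combos": combos,
        "combo_labels": combo_labels,
        "individuals": individuals,
        "tissues": tissues,
    }
    pen_mask = np.zeros(p, dtype=bool)
    pen_mask[n + 1 :] = True  # sex + UT shrunken; S and E free
    return X, pen_mask, meta


@dataclass
class CoefficientSet:
    """Fitted coefficients of one region's usage GLM."""

    beta_S: pd.Series
    beta_E: float
    beta_sex: float
    beta_UT: pd.DataFrame  # individuals x tissues
    prior_variance: float
    prior_variance_sex: float
    converged: bool
    loglik: float  # penalized log-likelihood at the optimum
    n_iter: int = 0

    def ut_vector(self, design: DesignTable) -> np.ndarray:
        """Interaction coefficients in design sample order."""
        return np.array(
            [
                self.beta_UT.at[u, t]
                for u, t in zip(design.table["individual"], design.table["tissue"])
            ]
        )


def fit_gp_glm(
    k1: np.ndarray,
    k0: np.ndarray,
    design: DesignTable,
    size_factors: SizeFactors,
    alpha,
    prior_variance: float = 1.0,
    prior_variance_sex: float = 1.0,
) -> CoefficientSet:
    """Fit the penalized Gamma-Poisson usage GLM for one region.

    ``k1``/``k0`` are the level-1 and level-0 counts per sample (in design
    order); ``alpha`` is the fixed dispersion — a scalar, or a pair
    ``(alpha_l0, alpha_l1)``.  ``prior_variance`` may be ``np.inf`` for an
    (essentially) unpenalized fit.
    """
    k1 = np.asarray(k1, dtype=float)
    k0 = np.asarray(k0, dtype=float)
    n = design.n_samples
    if k1.shape != (n,) or k0.shape != (n,):
        raise ValueError("count vectors must have one entry per design sample")
    if np.isscalar(alpha) or np.ndim(alpha) == 0:
        if float(alpha) < 0:
            raise ValueError("dispersion must be >= 0")
        alpha_vec = np.full(2 * n, float(alpha))
    else:
        a0, a1 = (float(a) for a in alpha)
        if a0 < 0 or a1 < 0:
            raise ValueError("dispersion must be >= 0")
        alpha_vec = np.concatenate([np.full(n, a0), np.full(n, a1)])

    X, pen_mask, meta = usage_design_matrix(design)
    y = np.concatenate([k0, k1])
    s = size_factors.to_numpy()
    offset = np.concatenate([np.log(s), np.log(s)])

    penalty = np.zeros(X.shape[1])
    inv_pv = 0.0 if math.isinf(prior_variance) else 1.0 / prior_variance
    inv_pv_sex = 0.0 if math.isinf(prior_variance_sex) else 1.0 / prior_variance_sex
    penalty[meta["col_UT"]] = inv_pv + STABILIZER
    penalty[meta["col_sex"]] = inv_pv_sex + STABILIZER

    beta, converged, n_iter = irls_nb(y, X, offset, alpha_vec, penalty)

    mu = np.exp(offset + np.clip(X @ beta, -30, 30))
    pll = nb_loglik(y, mu, alpha_vec) - 0.5 * float(penalty @ beta**2)

    individuals, tissues = meta["individuals"], meta["tissues"]
    ut = pd.DataFrame(np.nan, index=individuals, columns=tissues, dtype=float)
    for (u, t), b in zip(meta["combos"], beta[meta["col_UT"]]):
        ut.at[u, t] = b
    return CoefficientSet(
        beta_S=pd.Series(beta[meta["col_S"]], index=design.samples),
        beta_E=float(beta[meta["col_E"]]),
        beta_sex=float(beta[meta["col_sex"]]),
        beta_UT=ut,
        prior_variance=prior_variance,
        prior_variance_sex=prior_variance_sex,
        converged=converged,
        loglik=pll,
        n_iter=n_iter,
    )


# ---------------------------------------------------------------------------
# Dispersion estimation (Cox-Reid adjusted profile likelihood)
# ---------------------------------------------------------------------------


@dataclass
class DispersionEstimate:
    """Per-region dispersions plus the fitted mean-dispersion trend."""

    alpha: pd.Series  # final per-region values (possibly trend-shrunken)
    alpha_raw: pd.Series = None
    trend: tuple[float, float] | None = None  # (a0, a1) of a0 + a1/mu
    floor: float = ALPHA_FLOOR

    def trend_at(self, mu) -> np.ndarray:
        if self.trend is None:
            raise ValueError("no trend fitted")
        a0, a1 = self.trend
        return np.maximum(a0 + a1 / np.asarray(mu, dtype=float), self.floor)


def _irls_reduced(
    y: np.ndarray,
    offset: np.ndarray,
    alpha,
    n: int,
    *,
    tol: float = IRLS_TOL,
    maxit: int = IRLS_MAXIT,
) -> np.ndarray:
    """IRLS for the reduced design, exploiting its arrowhead normal matrix.

    Coefficients: n per-sample effects + one level effect.  X'WX is
    diag(w0 + w1) bordered by the column w1 with corner sum(w1), so each
    scoring step is O(n).
    """
    y = np.asarray(y, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), y.shape)
    beta = np.zeros(n + 1)
    eta = np.log(y + 0.5) - offset
    for _ in range(maxit):
        eta = np.clip(eta, -30.0, 30.0)
        mu = np.exp(offset + eta)
        w = mu / (1.0 + alpha * mu)
        z = eta + (y - mu) / mu
        wz = w * z
        w0, w1 = w[:n], w[n:]
        d = w0 + w1
        r_s = wz[:n] + wz[n:]
        r_e = wz[n:].sum()
        corner = w1.sum() - (w1**2 / d).sum()
        if corner <= 1e-12:
            corner = 1e-12
        b_e = (r_e - (w1 * r_s / d).sum()) / corner
        b_s = (r_s - w1 * b_e) / d
        beta_new = np.concatenate([b_s, [b_e]])
        delta = np.max(np.abs(beta_new - beta))
        beta = beta_new
        eta = np.concatenate([b_s, b_s + b_e])
        if delta < tol:
            break
    return beta


def _cr_logdet_reduced(w: np.ndarray, n: int) -> float:
    """log det(X'WX) for the reduced design, in closed form.

    X'WX is an arrowhead matrix: diag(w0_j + w1_j) with border column
    w1_j and corner sum(w1).  Its determinant is
    prod(w0+w1) * (sum w1 - sum w1^2/(w0+w1)).
    """
    w0, w1 = w[:n], w[n:]
    d = w0 + w1
    corner = w1.sum() - (w1**2 / d).sum()
    if corner <= 0 or (d <= 0).any():
        return -np.inf
    return float(np.log(d).sum() + np.log(corner))


def estimate_dispersion(
    k1: np.ndarray,
    k0: np.ndarray,
    design: DesignTable,
    size_factors: SizeFactors,
    *,
    floor: float = ALPHA_FLOOR,
    ceiling: float = ALPHA_CEILING,
) -> float:
    """Cox-Reid adjusted profile ML dispersion for one region.

    For each candidate dispersion the means are refitted under a reduced
    design (per-sample and level main effects) and the adjusted profile
    likelihood ll - 0.5 log det(X'WX) is evaluated; the returned value
    maximizes it, clipped to [floor, ceiling].  Refitting the means per
    candidate matters: with one nuisance parameter per sample the
    fixed-means shortcut biases the profile.  All-zero counts raise
    ValueError (dispersion undefined; callers flag and exclude the
    region).
    """
    k1 = np.asarray(k1, dtype=float)
    k0 = np.asarray(k0, dtype=float)
    n = design.n_samples
    if len(k1) < 3:
        raise ValueError("dispersion estimation needs >= 3 samples")
    if k1.sum() + k0.sum() == 0:
        raise ValueError("all-zero counts: dispersion undefined")
    y = np.concatenate([k0, k1])
    s = size_factors.to_numpy()
    offset = np.concatenate([np.log(s), np.log(s)])

    def neg_apl(log_a: float) -> float:
        a = math.exp(log_a)
        beta = _irls_reduced(y, offset, a, n)
        eta = np.concatenate([beta[:n], beta[:n] + beta[n]])
        mu = np.exp(offset + np.clip(eta, -30, 30))
        w = mu / (1.0 + a * mu)
        return -(nb_loglik(y, mu, a) - 0.5 * _cr_logdet_reduced(w, n))

    lo = math.log(max(floor, 1e-12))
    res = minimize_scalar(
        neg_apl, bounds=(lo, math.log(ceiling)), method="bounded",
        options={"xatol": 1e-4},
    )
    alpha = float(np.clip(math.exp(res.x), floor, ceiling))
    # flat profile down to the floor (Poisson-like or under-dispersed
    # data): no interior optimum, clip at the floor
    if neg_apl(lo) <= res.fun + 1e-3:
        alpha = floor
    return alpha


def fit_dispersion_trend(
    alphas: pd.Series,
    means: pd.Series,
    *,
    floor: float = ALPHA_FLOOR,
    shrink_weight: float = 0.5,
) -> DispersionEstimate:
    """Fit the mean-dispersion trend alpha(mu) = a0 + a1/mu and shrink.

    The trend is a least-squares fit of per-region dispersion estimates on
    1/mean (regions at the floor or ceiling excluded); per-region values
    are then shrunk toward the trend by a fixed-weight average in log
    space.  ``shrink_weight`` is the weight on the trend (0 = raw
    per-region estimates, 1 = pure trend).
    """
    alphas = alphas.astype(float)
    means = means.astype(float).reindex(alphas.index)
    interior = (alphas > floor * 1.01) & (alphas < ALPHA_CEILING * 0.99) & (means > 0)
    if interior.sum() >= 10:
        x = 1.0 / means[interior].to_numpy()
        yv = alphas[interior].to_numpy()
        A = np.column_stack([np.ones_like(x), x])
        coef, *_ = np.linalg.lstsq(A, yv, rcond=None)
        a0, a1 = float(coef[0]), float(coef[1])
        a0 = max(a0, 0.0)
        a1 = max(a1, 0.0)
        trend_vals = np.maximum(a0 + a1 / np.maximum(means.to_numpy(), 1e-8), floor)
        final = np.exp(
            (1 - shrink_weight) * np.log(np.maximum(alphas.to_numpy(), floor))
            + shrink_weight * np.log(trend_vals)
        )
        trend = (a0, a1)
    else:
        final = alphas.to_numpy()
        trend = None
    final = np.clip(final, floor, ALPHA_CEILING)
    return DispersionEstimate(
        alpha=pd.Series(final, index=alphas.index),
        alpha_raw=alphas,
        trend=trend,
        floor=floor,
    )


# ---------------------------------------------------------------------------
# Empirical-Bayes shrinkage prior
# ---------------------------------------------------------------------------


def estimate_shrinkage_prior(
    betas: np.ndarray,
    sampling_variances: np.ndarray | None = None,
    *,
    quantile: float = 0.975,
    min_prior: float = 0.01,
    default: float = 1.0,
    min_count: int = 50,
) -> float:
    """Prior variance for ridge shrinkage from unpenalized coefficients.

    Matches an upper quantile of the empirical |beta| distribution to a
    zero-centred normal: for N(0, v_tot), the q-quantile of |beta| is
    sqrt(v_tot) * z with z = Phi^-1((1+q)/2).  The prior variance is the
    excess of v_tot over the mean sampling variance (if supplied),
    floored at ``min_prior``.  With fewer than ``min_count`` finite
    inputs, or an all-zero input, returns ``default`` / ``min_prior``
    respectively.
    """
    from scipy.stats import norm

    b = np.asarray(betas, dtype=float).ravel()
    b = b[np.isfinite(b)]
    if b.size < min_count:
        return default
    if np.all(b == 0):
        return min_prior
    z = norm.ppf((1 + quantile) / 2)
    v_tot = (np.quantile(np.abs(b), quantile) / z) ** 2
    v_noise = 0.0
    if sampling_variances is not None:
        sv = np.asarray(sampling_variances, dtype=float).ravel()
        sv = sv[np.isfinite(sv)]
        if sv.size:
            v_noise = float(np.mean(sv))
    return float(max(v_tot - v_noise, min_prior))
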