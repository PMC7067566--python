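"""Prediction-accuracy and variance/heritability diagnostics.

* ``incremental_r2`` — gain in (unadjusted, in-sample) R^2 when a polygenic
  score is added to a covariates-only linear model.
* ``incremental_auc`` — gain in AUC when the score is added to a
  covariates-only logistic model; AUC is the concordant-pair rank statistic
  with ties counted 1/2 (exactly the trapezoidal ROC area).
* ``rank_sum_test`` — two-sided Mann-Whitney U, normal approximation with
  tie correction; used to compare per-iteration accuracy distributions.
* ``stratum_adjusted_variance`` — per-stratum variance of the
  pooled-covariate-residualized phenotype, with a fourth-moment SE.
* ``h2_moment_estimate`` — Haseman-Elston regression of phenotype
  cross-products on off-diagonal GRM entries; a moment substitute for
  likelihood or LD-score methods that is valid on simulator-controlled
  panels (unlinked SNP sets, or the known causal set).
* ``fit_inverse_proportionality`` — through-origin fit of h^2 on
  1/variance, the diagnostic for "environmental variance differences alone"
  across strata: if genetic variance is constant, h^2 must be inversely
  proportional to phenotypic variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .assoc import _orthonormal_basis, residualize
from .popsim import GenotypeMatrix

__all__ = [
    "incremental_r2",
    "incremental_auc",
    "auc_rank",
    "rank_sum_test",
    "stratum_adjusted_variance",
    "h2_moment_estimate",
    "InverseProportionalityFit",
    "fit_inverse_proportionality",
]


def _r2(y: np.ndarray, design: np.ndarray) -> float:
    """Unadjusted R^2 of OLS with the given design (intercept included)."""
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        raise ValueError("constant phenotype")
    return 1.0 - float(resid @ resid) / tss


def incremental_r2(y: np.ndarray, covariates, score: np.ndarray) -> float:
    """R^2(covariates + score) - R^2(covariates), fit on the same sample."""
    y = np.asarray(y, dtype=float)
    score = np.asarray(score, dtype=float)
    n = len(y)
    q = _orthonormal_basis(covariates, n)
    return _r2(y, np.column_stack([q, score])) - _r2(y, q)


def auc_rank(y_binary: np.ndarray, score: np.ndarray) -> float:
    """AUC by the rank (concordant-pair) statistic, ties counted 1/2."""
    y = np.asarray(y_binary)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes present")
    ranks = sps.rankdata(np.asarray(score, dtype=float))
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _fitted_logistic_prob(y: np.ndarray, design: np.ndarray) -> np.ndarray:
    import statsmodels.api as sm

    import warnings

    model = sm.Logit(y, design)
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = model.fit(disp=0, maxiter=200)
            params = fit.params
        except np.linalg.LinAlgError:
            params = None
        if params is None or not np.all(np.isfinite(params)):
            # quasi-separated data: Newton's Hessian degenerates; a gradient
            # method still yields a monotone (rank-preserving) predictor
            fit = model.fit(method="lbfgs", disp=0, maxiter=500)
        return np.asarray(fit.predict(design))


def incremental_auc(y_binary: np.ndarray, covariates, score: np.ndarray) -> float:
    """AUC(logistic: covariates + score) - AUC(logistic: covariates only)."""
    y = np.asarray(y_binary)
    if len(np.unique(y)) < 2:
        raise ValueError("binary outcome has a single class")
    score = np.asarray(score, dtype=float)
    n = len(y)
    q = _orthonormal_basis(covariates, n)
    if q.shape[1] == 1:
        auc_cov = 0.5  # intercept-only model: constant probability
    else:
        auc_cov = auc_rank(y, _fitted_logistic_prob(y, q))
    auc_full = auc_rank(y, _fitted_logistic_prob(y, np.column_stack([q, score])))
    return auc_full - auc_cov


def rank_sum_test(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Mann-Whitney U p-value (normal approximation, tie-corrected)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("rank-sum test needs nonempty samples")
    return float(sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue)


def stratum_adjusted_variance(y: np.ndarray, covariates, strata) -> pd.DataFrame:
    """Within-stratum variance of the pooled-covariate-residualized phenotype.

    Returns a frame with columns stratum, variance, se, n; the SE uses the
    fourth-moment formula Var(s^2) ~ (m4 - s^4 (n-3)/(n-1)) / n.
    """
    res = residualize(np.asarray(y, dtype=float), covariates)
    strata = np.asarray(strata)
    rows = []
    for s in pd.unique(strata):
        r = res[strata == s]
        n = len(r)
        if n < 2:
            raise ValueError(f"stratum {s!r} has fewer than 2 members")
        v = float(r.var(ddof=1))
        m4 = float(((r - r.mean()) ** 4).mean())
        se = np.sqrt(max(m4 - v**2 * (n - 3) / (n - 1), 0.0) / n)
        rows.append({"stratum": s, "variance": v, "se": se, "n": n})
    return pd.DataFrame(rows)


def _standardized_genotypes(counts: np.ndarray) -> np.ndarray:
    x = counts.astype(np.float64)
    p = x.mean(axis=0) / 2.0
    sd = np.sqrt(2.0 * p * (1.0 - p))
    ok = sd > 0
    z = np.zeros_like(x)
    z[:, ok] = (x[:, ok] - 2.0 * p[ok]) / sd[ok]
    return z


def h2_moment_estimate(
    genotypes: GenotypeMatrix,
    y: np.ndarray,
    covariates=None,
    snps: str | np.ndarray = "all",
) -> tuple[float, float]:
    """Haseman-Elston SNP-heritability estimate with a jackknife SE.

    Regresses products of standardized residualized phenotypes on the
    off-diagonal entries of the GRM built from standardized genotypes
    (``snps='all'`` or an explicit SNP-id subset, e.g. the known causal
    set).  The regression slope and its delete-one-individual jackknife SE
    are computed in closed form via trace identities, so the n x n GRM is
    never materialized.

    With ``snps='all'`` the panel must be unlinked (within_block_r == 0 or
    single-SNP blocks); on a linked panel the estimator's moment conditions
    are not guaranteed, so an explicit causal subset is required instead.
    """
    panel = genotypes.panel
    if isinstance(snps, str) and snps == "all":
        block_sizes = np.bincount(panel.block_ids)
        if panel.within_block_r > 0 and block_sizes.max() > 1:
            raise ValueError(
                "h2_moment_estimate on a linked panel requires an explicit "
                "(e.g. causal) SNP subset"
            )
        counts = genotypes.counts
    else:
        counts = genotypes.counts[:, panel.index_of(np.asarray(snps))]

    yv = residualize(np.asarray(y, dtype=float), covariates)
    sd = yv.std()
    if sd == 0:
        raise ValueError("constant phenotype")
    yv = (yv - yv.mean()) / sd

    z = _standardized_genotypes(counts)
    n, m = z.shape
    zty = z.T @ yv                       # (m,)
    zt1 = z.sum(axis=0)                  # (m,)
    g = z.T @ z                          # (m, m)
    w = z @ g                            # (n, m); row k = (A Z)_k * m^2 pieces
    a_diag = np.einsum("ij,ij->i", z, z) / m          # A_kk
    ay = z @ zty / m                                   # (A y)_k
    a1 = z @ zt1 / m                                   # (A 1)_k
    row_sq = np.einsum("ij,ij->i", w, z) / m**2        # sum_j A_kj^2

    s_xy = float(zty @ zty) / m - float(a_diag @ (yv**2))
    s_xx = float(np.einsum("ij,ij->", g, g)) / m**2 - float((a_diag**2).sum())
    s_x = float(zt1 @ zt1) / m - float(a_diag.sum())
    s_y = float(yv.sum()) ** 2 - float((yv**2).sum())
    n_pairs = n * (n - 1)

    def _slope(sxy, sxx, sx, sy, npair):
        denom = npair * sxx - sx**2
        return (npair * sxy - sx * sy) / denom

    slope = _slope(s_xy, s_xx, s_x, s_y, n_pairs)

    # delete-one jackknife via per-individual contributions to each sum
    c_xy = 2.0 * yv * (ay - a_diag * yv)
    c_xx = 2.0 * (row_sq - a_diag**2)
    c_x = 2.0 * (a1 - a_diag)
    c_y = 2.0 * yv * (yv.sum() - yv)
    npair_k = (n - 1) * (n - 2)
    denom_k = npair_k * (s_xx - c_xx) - (s_x - c_x) ** 2
    slopes_k = (npair_k * (s_xy - c_xy) - (s_x - c_x) * (s_y - c_y)) / denom_k
    se = float(np.sqrt((n - 1) / n * ((slopes_k - slopes_k.mean()) ** 2).sum()))
    return float(slope), se


@dataclass
class InverseProportionalityFit:
    """Least-squares fit of h^2 on 1/variance."""

    constant: float
    intercept: float
    fitted: np.ndarray
    residuals: np.ndarray
    rss: float
    with_intercept: bool


def fit_inverse_proportionality(
    h2_estimates: np.ndarray, variances: np.ndarray, *, with_intercept: bool = False
) -> InverseProportionalityFit:
    """Fit h2_s = c / var_s (through the origin on 1/variance by default;
    set with_intercept=True for the free-intercept variant)."""
    h2 = np.asarray(h2_estimates, dtype=float)
    v = np.asarray(variances, dtype=float)
    if len(h2) != len(v) or len(h2) < 2:
        raise ValueError("need h2 and variance for at least 2 strata")
    if np.any(v <= 0):
        raise ValueError("variances must be positive")
    x = 1.0 / v
    if with_intercept:
        design = np.column_stack([np.ones_like(x), x])
        coef, _, _, _ = np.linalg.lstsq(design, h2, rcond=None)
        intercept, c = float(coef[0]), float(coef[1])
        fitted = design @ coef
    else:
        c = float((h2 @ x) / (x @ x))
        intercept = 0.0
        fitted = c * x
    residuals = h2 - fitted
    return InverseProportionalityFit(
        constant=c,
        intercept=intercept,
        fitted=fitted,
        residuals=residuals,
        rss=float(residuals @ residuals),
        with_intercept=with_intercept,
    )
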