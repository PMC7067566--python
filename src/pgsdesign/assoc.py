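"""Per-SNP association testing.

Three designs are provided:

* ``ols_gwas`` — covariate-adjusted linear regression on unrelated
  individuals, computed by exact Frisch-Waugh-Lovell residualization of the
  phenotype and each genotype column on [intercept | covariates].  The
  reported beta, classical SE and two-sided t p-value are identical to the
  full per-SNP multiple regression with n - n_cov - 2 degrees of freedom.
* ``logistic_gwas`` — per-SNP maximum-likelihood logistic regression; the
  reported effect is the log odds ratio with its Wald SE.
* ``sib_diff_gwas`` — within-sibling-pair regression of phenotype-residual
  differences on genotype differences, which conditions out everything
  shared by the pair (parental genotypes, family environment) and hence
  removes indirect parental effects and assortative-mating signal.

Monomorphic or otherwise degenerate SNPs are excluded from the output (with
a logged count) rather than emitted as NaN rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .popsim import FamilyCohort, GenotypeMatrix

logger = logging.getLogger(__name__)

SUMSTATS_COLUMNS = ["CHR", "POS", "ID", "EA", "OA", "BETA", "SE", "P", "N"]

__all__ = ["SummaryStats", "residualize", "ols_gwas", "logistic_gwas", "sib_diff_gwas"]


@dataclass
class SummaryStats:
    """Per-SNP association output.

    ``table`` columns: CHR POS ID EA OA BETA SE P N.  ``design`` is one of
    'standard', 'sib' or 'logistic'; N counts individuals for the standard
    designs and pairs for the sib design.
    """

    table: pd.DataFrame
    design: str
    excluded_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.design not in ("standard", "sib", "logistic"):
            raise ValueError("design must be 'standard', 'sib' or 'logistic'")
        missing = set(SUMSTATS_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"summary table missing columns: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.table)

    def median_se(self, snp_ids=None) -> float:
        t = self.table
        if snp_ids is not None:
            t = t[t["ID"].isin(np.asarray(snp_ids))]
        return float(t["SE"].median())

    def subset(self, snp_ids) -> "SummaryStats":
        mask = self.table["ID"].isin(np.asarray(snp_ids))
        return SummaryStats(self.table[mask].reset_index(drop=True), self.design)

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out["DESIGN"] = self.design
        out.to_csv(path, sep="\t", index=False, float_format="%.12g")

    @classmethod
    def from_tsv(cls, path) -> "SummaryStats":
        t = pd.read_csv(path, sep="\t")
        design = str(t["DESIGN"].iloc[0]) if len(t) else "standard"
        return cls(t.drop(columns=["DESIGN"]), design)


def _design_with_intercept(covariates, n: int) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    c = np.asarray(covariates, dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    if c.shape[1] == 0:
        return np.ones((n, 1))
    return np.column_stack([np.ones(n), c])


def _orthonormal_basis(covariates, n: int) -> np.ndarray:
    """Orthonormal basis of span([1 | covariates]); raises if rank-deficient."""
    cmat = _design_with_intercept(covariates, n)
    q, r = np.linalg.qr(cmat)
    if np.any(np.abs(np.diag(r)) < 1e-10 * max(1.0, np.abs(r).max())):
        raise ValueError("covariate matrix is rank-deficient after adding an intercept")
    return q


def residualize(y: np.ndarray, covariates=None) -> np.ndarray:
    """y minus its least-squares projection on [intercept | covariates]."""
    y = np.asarray(y, dtype=float)
    q = _orthonormal_basis(covariates, len(y))
    return y - q @ (q.T @ y)


def _sumstats_frame(panel_table: pd.DataFrame, keep: np.ndarray, beta, se, p, n) -> pd.DataFrame:
    sub = panel_table.iloc[keep]
    return pd.DataFrame(
        {
            "CHR": sub["chrom"].to_numpy(),
            "POS": sub["pos"].to_numpy(),
            "ID": sub["snp_id"].to_numpy(),
            "EA": sub["effect_allele"].to_numpy(),
            "OA": sub["other_allele"].to_numpy(),
            "BETA": beta,
            "SE": se,
            "P": p,
            "N": n,
        }
    )


def ols_gwas(
    genotypes: GenotypeMatrix,
    y: np.ndarray,
    covariates=None,
    *,
    chunk_size: int = 512,
) -> SummaryStats:
    """Standard GWAS: per-SNP linear regression y ~ intercept + SNP + covariates."""
    y = np.asarray(y, dtype=float)
    n, m = genotypes.counts.shape
    if len(y) != n:
        raise ValueError("phenotype and genotype rows are misaligned")
    q = _orthonormal_basis(covariates, n)
    n_cov = q.shape[1] - 1
    dof = n - n_cov - 2
    if dof <= 0:
        raise ValueError("too few individuals for the covariate count")
    yr = y - q @ (q.T @ y)
    syy = float(yr @ yr)

    poly = np.flatnonzero(genotypes.counts.min(axis=0) != genotypes.counts.max(axis=0))
    polyset = set(poly.tolist())
    excluded = [s for j, s in enumerate(genotypes.panel.snp_ids) if j not in polyset]
    if excluded:
        logger.info("ols_gwas: excluded %d monomorphic SNPs", len(excluded))

    beta = np.empty(len(poly))
    se = np.empty(len(poly))
    for start in range(0, len(poly), chunk_size):
        idx = poly[start : start + chunk_size]
        x = genotypes.counts[:, idx].astype(np.float64)
        xr = x - q @ (q.T @ x)
        sxx = np.einsum("ij,ij->j", xr, xr)
        sxy = xr.T @ yr
        b = sxy / sxx
        rss = syy - b * sxy
        sigma2 = np.maximum(rss, 0.0) / dof
        beta[start : start + len(idx)] = b
        se[start : start + len(idx)] = np.sqrt(sigma2 / sxx)
    tstat = beta / se
    p = 2.0 * sps.t.sf(np.abs(tstat), dof)
    table = _sumstats_frame(genotypes.panel.table, poly, beta, se, p, n)
    return SummaryStats(table, "standard", excluded_ids=excluded)


def logistic_gwas(
    genotypes: GenotypeMatrix, y_binary: np.ndarray, covariates=None
) -> SummaryStats:
    """Per-SNP logistic regression; effects are log odds ratios (Wald SE,
    normal-reference two-sided p)."""
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    y = np.asarray(y_binary)
    n, m = genotypes.counts.shape
    if len(y) != n:
        raise ValueError("phenotype and genotype rows are misaligned")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("binary outcome has a single class")
    cmat = _design_with_intercept(covariates, n)

    keep, beta, se = [], [], []
    excluded: list[str] = []
    for j in range(m):
        x = genotypes.counts[:, j].astype(float)
        if x.min() == x.max():
            excluded.append(genotypes.panel.snp_ids[j])
            continue
        design = np.column_stack([cmat, x])
        try:
            import warnings

            with np.errstate(all="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, design).fit(disp=0, maxiter=100)
            b, s = fit.params[-1], fit.bse[-1]
            if not (np.isfinite(b) and np.isfinite(s)) or s > 1e3:
                raise PerfectSeparationError
        except (PerfectSeparationError, np.linalg.LinAlgError):
            excluded.append(genotypes.panel.snp_ids[j])
            continue
        keep.append(j)
        beta.append(b)
        se.append(s)
    if excluded:
        logger.info("logistic_gwas: excluded %d degenerate/separated SNPs", len(excluded))
    beta = np.asarray(beta)
    se = np.asarray(se)
    p = 2.0 * sps.norm.sf(np.abs(beta / se))
    table = _sumstats_frame(genotypes.panel.table, np.asarray(keep, dtype=int), beta, se, p, n)
    return SummaryStats(table, "logistic", excluded_ids=excluded)


def sib_diff_gwas(
    cohort: FamilyCohort, y: np.ndarray, covariates_age_sex=None
) -> SummaryStats:
    """Sibling-difference GWAS.

    The phenotype is residualized on the covariates over all siblings, then
    for each SNP the within-pair residual difference is regressed on the
    within-pair genotype difference (with intercept); classical SEs with
    n_pairs - 2 degrees of freedom.  Output is invariant, up to the sign of
    beta, under reversal of the within-pair ordering.
    """
    if cohort.n_offspring_per_family != 2:
        raise ValueError("sib-difference GWAS needs exactly one sibling pair per family")
    y = np.asarray(y, dtype=float)
    n = cohort.offspring.n
    if len(y) != n:
        raise ValueError("phenotype and offspring rows are misaligned")
    res = residualize(y, covariates_age_sex)
    d_res = res[0::2] - res[1::2]
    f = cohort.n_families
    dof = f - 2
    if dof <= 0:
        raise ValueError("need more than 2 sibling pairs")

    dx = (cohort.offspring.counts[0::2].astype(np.float64)
          - cohort.offspring.counts[1::2].astype(np.float64))
    poly = np.flatnonzero(dx.min(axis=0) != dx.max(axis=0))
    polyset = set(poly.tolist())
    excluded = [s for j, s in enumerate(cohort.panel.snp_ids) if j not in polyset]
    if excluded:
        logger.info("sib_diff_gwas: excluded %d SNPs with constant genotype differences",
                    len(excluded))

    xc = dx[:, poly] - dx[:, poly].mean(axis=0)
    yc = d_res - d_res.mean()
    sxx = np.einsum("ij,ij->j", xc, xc)
    sxy = xc.T @ yc
    beta = sxy / sxx
    rss = float(yc @ yc) - beta * sxy
    se = np.sqrt(np.maximum(rss, 0.0) / dof / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / se, 0.0)
    p = 2.0 * sps.t.sf(np.abs(tstat), dof)
    table = _sumstats_frame(cohort.panel.table, poly, beta, se, p, f)
    return SummaryStats(table, "sib", excluded_ids=excluded)
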