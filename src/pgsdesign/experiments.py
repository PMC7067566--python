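"""End-to-end study designs on synthetic cohorts.

Two harnesses mirror the two study designs:

* ``run_stratified_experiment`` — GWAS performed within strata of a single
  cohort (and in a stratum-balanced "diverse" sample of the same size),
  polygenic scores evaluated in held-out per-stratum prediction sets, with
  per-stratum heritability and adjusted-variance diagnostics attached.
* ``run_sib_compare`` — SNPs ascertained by a large standard discovery
  GWAS; effects re-estimated both by a standard GWAS on an ``n*``-sized
  estimation set and by sibling-difference regression; the two scores are
  compared on identical SNP lists and identical prediction individuals.
  ``n*`` is the standard-GWAS sample size whose median effect-estimate SE
  matches the sibling design's, which equalizes expected prediction
  accuracy under a vanilla model (no indirect effects, no assortative
  mating).

All randomness flows from the config seed; a fixed config is
bit-reproducible, including every subsampling step.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import popsim
from .assoc import SummaryStats, logistic_gwas, ols_gwas, sib_diff_gwas
from .evalmetrics import (
    h2_moment_estimate,
    incremental_auc,
    incremental_r2,
    stratum_adjusted_variance,
)
from .pgs import build_score_model, clump, score_individuals, threshold_grid
from .popsim import GenotypeMatrix, StratumSpec, binarize_trait

logger = logging.getLogger(__name__)

__all__ = [
    "h2_recovery_experiment",
    "StratumConfig",
    "SimulationConfig",
    "DesignConfig",
    "ExperimentConfig",
    "NStarFit",
    "SibCompareReport",
    "StratifiedReport",
    "EffectReestimate",
    "estimate_n_star",
    "run_sib_compare",
    "threshold_sweep",
    "run_stratified_experiment",
    "reestimate_effects_by_stratum",
]


# --------------------------------------------------------------------------
# configuration


@dataclass
class StratumConfig:
    label: str
    amplification: float = 1.0
    env_scale: float = 1.0
    weight: float = 1.0

    def to_spec(self) -> StratumSpec:
        return StratumSpec(self.label, self.amplification, self.env_scale, self.weight)


@dataclass
class SimulationConfig:
    """Synthetic-cohort parameters (desk-scale defaults)."""

    m_snps: int = 2000
    block_size: int = 10
    within_block_r: float = 0.8
    maf_low: float = 0.05
    maf_high: float = 0.5
    within_block_spacing_bp: int = 5_000
    between_block_gap_bp: int = 2_000_000
    m_causal: int = 500
    h2: float = 0.5
    rho_di: float = 0.0
    indirect_scale: float = 0.0
    indirect_weight: float = 0.0
    am_strength: float = 0.0
    n_unrelated: int = 30_000
    n_sib_families: int = 4_000
    # families simulated for the sibling side; each iteration resamples
    # n_sib_families of them, so sib-GWAS noise is not shared across
    # iterations (0 means: exactly n_sib_families, fixed sib set)
    n_sib_family_pool: int = 12_000
    strata: list[StratumConfig] = field(default_factory=lambda: [StratumConfig("all")])
    stratum_assignment: str = "random"
    collider_r: float = 0.6
    sex_effect: float = 0.2
    age_effect: float = 0.1
    binary: bool = False
    binary_quantile: float = 0.8


@dataclass
class DesignConfig:
    """Analysis-side parameters: splits, grids, clumping."""

    n_iterations: int = 10
    p_grid: list[float] | None = None
    clump_r2: float = 0.1
    clump_window_bp: int = 1_000_000
    ld_reference_size: int = 5_000
    nstar_grid: list[int] = field(default_factory=lambda: list(range(1000, 8001, 500)))
    nstar_se_snps: int | None = 500
    nstar_per_iteration: bool = True
    prediction_fraction: float = 0.10
    n_prediction_per_stratum: int = 2_500
    stratified_p_threshold: float = 1e-3
    include_pooled: bool = False
    reestimate: bool = False
    reestimate_p_threshold: float = 1e-4

    def thresholds(self) -> list[float]:
        return threshold_grid(self.p_grid)


@dataclass
class ExperimentConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    design: DesignConfig = field(default_factory=DesignConfig)
    seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        sim_raw = dict(raw.get("simulation", {}))
        strata = [StratumConfig(**s) for s in sim_raw.pop("strata", [])] or None
        sim = SimulationConfig(**sim_raw)
        if strata:
            sim.strata = strata
        design = DesignConfig(**raw.get("design", {}))
        if "seed" not in raw:
            raise ValueError("config must state a seed")
        return cls(simulation=sim, design=design, seed=int(raw["seed"]))


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n)]


def _build_effects(sim: SimulationConfig, seed: int):
    panel = popsim.make_snp_panel(
        sim.m_snps,
        sim.maf_low,
        sim.maf_high,
        sim.block_size,
        sim.within_block_r,
        seed=seed,
        within_block_spacing_bp=sim.within_block_spacing_bp,
        between_block_gap_bp=sim.between_block_gap_bp,
    )
    effects = popsim.draw_effect_sizes(
        panel, sim.m_causal, sim.h2, sim.rho_di, sim.indirect_scale, seed=seed + 1
    )
    effects.am_strength = sim.am_strength
    effects.strata = [s.to_spec() for s in sim.strata]
    return effects, panel


def h2_recovery_experiment(
    h2: float, n: int = 10_000, m: int = 2_000, n_seeds: int = 10, seed: int = 0
) -> dict:
    """Parameter-recovery check for the Haseman-Elston moment estimator.

    For each seed: simulate an unlinked panel of ``m`` SNPs all causal with
    effects beta ~ N(0, h2/m), draw ``n`` unrelated individuals, assemble
    the standardized trait, and estimate h2 by HE regression of phenotype
    cross-products on GRM off-diagonals.  Returns per-seed estimates and
    their mean.
    """
    ests = []
    for s in _child_seeds(seed, n_seeds):
        s_panel, s_eff, s_geno, s_pheno = _child_seeds(s, 4)
        panel = popsim.make_snp_panel(m, block_size=1, within_block_r=0.0, seed=s_panel)
        eff = popsim.draw_effect_sizes(panel, m, h2, seed=s_eff)
        geno = popsim.simulate_unrelated(panel, n, seed=s_geno, keep_haplotypes=False)
        pheno = popsim.assemble_phenotype(geno, eff, seed=s_pheno)
        est, _ = h2_moment_estimate(geno, pheno["y"].to_numpy(), None, snps="all")
        ests.append(float(est))
    return {"mean": float(np.mean(ests)), "estimates": ests, "n": n, "m": m, "h2_true": h2}


# --------------------------------------------------------------------------
# n* estimation


@dataclass
class NStarFit:
    """Linear fit of 1/median-SE on sqrt(n) and the matched sample size."""

    grid_n: list[int]
    inv_median_se: list[float]
    slope: float
    intercept: float
    fit_correlation: float
    sib_median_se: float
    n_star: int
    se_snp_ids: np.ndarray | None = None


def estimate_n_star(
    sib_stats: SummaryStats,
    unrelated_pool: GenotypeMatrix,
    y: np.ndarray,
    covariates,
    grid: list[int],
    seed: int = 0,
    se_snps: int | None = None,
) -> NStarFit:
    """Find the standard-GWAS size whose median SE matches the sib design's.

    For each grid size a standard GWAS is run on a random subsample and the
    median effect-estimate SE recorded; 1/median-SE is regressed on
    sqrt(n) and the fitted line inverted at the sibling GWAS's median SE.
    ``n_star`` is the smallest integer n whose predicted median SE does not
    exceed the sib median SE.  ``se_snps`` optionally restricts the median
    to a fixed random SNP subset (the same subset on both designs), which
    trades a little Monte-Carlo noise for speed.
    """
    grid = sorted(int(n) for n in grid)
    if len(grid) < 2:
        raise ValueError("n* grid needs at least 2 sizes")
    if grid[-1] > unrelated_pool.n:
        raise ValueError("n* grid exceeds the unrelated pool size")
    if len(sib_stats) == 0:
        raise ValueError("sibling summary statistics are empty")
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    cov = np.asarray(covariates, dtype=float) if covariates is not None else None

    if se_snps is not None and se_snps < unrelated_pool.panel.m:
        sub_ids = np.sort(
            rng.choice(unrelated_pool.panel.snp_ids, size=se_snps, replace=False)
        )
        pool = unrelated_pool.subset_snps(sub_ids)
    else:
        sub_ids = None
        pool = unrelated_pool
    sib_median = sib_stats.median_se(snp_ids=sub_ids)

    inv_se = []
    for n in grid:
        idx = rng.choice(pool.n, size=n, replace=False)
        stats = ols_gwas(
            pool.subset_individuals(idx), y[idx], cov[idx] if cov is not None else None
        )
        inv_se.append(1.0 / stats.median_se())
    sqrt_n = np.sqrt(np.asarray(grid, dtype=float))
    design = np.column_stack([np.ones_like(sqrt_n), sqrt_n])
    (intercept, slope), _, _, _ = np.linalg.lstsq(design, np.asarray(inv_se), rcond=None)
    corr = float(np.corrcoef(sqrt_n, inv_se)[0, 1])
    if slope <= 0:
        raise RuntimeError("1/median-SE did not increase with sqrt(n)")

    target = 1.0 / sib_median
    max_inv = intercept + slope * np.sqrt(unrelated_pool.n)
    if target > max_inv:
        raise ValueError(
            f"sib median SE {sib_median:.4g} unattainable on this pool; achievable "
            f"median SE range is [{1.0 / max_inv:.4g}, inf)"
        )
    n_star = int(np.ceil(((target - intercept) / slope) ** 2))
    n_star = max(n_star, 1)
    return NStarFit(
        grid_n=grid,
        inv_median_se=[float(v) for v in inv_se],
        slope=float(slope),
        intercept=float(intercept),
        fit_correlation=corr,
        sib_median_se=float(sib_median),
        n_star=n_star,
        se_snp_ids=sub_ids,
    )


# --------------------------------------------------------------------------
# sib-vs-standard comparison


@dataclass
class SibCompareReport:
    """Per iteration x p-threshold accuracies of the two designs.

    ``table`` columns: iteration, p_threshold, n_snps, n_star,
    r2_standard, r2_sib, ratio (sib/standard).  Cells with no ascertained
    SNP at a threshold are present with NaN accuracies.
    """

    table: pd.DataFrame
    config: ExperimentConfig

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _assert_disjoint(*index_sets) -> None:
    seen: set = set()
    for s in index_sets:
        s = set(np.asarray(s).tolist())
        if seen & s:
            raise AssertionError("analysis sets share individuals")
        seen |= s


def run_sib_compare(config: ExperimentConfig) -> SibCompareReport:
    """Discovery / n*-estimation / prediction pipeline over resampling
    iterations; both scores always use identical SNP lists and identical
    prediction individuals."""
    sim, design = config.simulation, config.design
    (s_model, s_cohort, s_split, s_ld, *iter_seeds) = _child_seeds(
        config.seed, 4 + design.n_iterations
    )
    effects, panel = _build_effects(sim, s_model)
    sib_pool = max(sim.n_sib_family_pool, sim.n_sib_families)
    n_fam_total = sim.n_unrelated + sib_pool
    cohort, pheno = popsim.simulate_two_generation_cohort(
        panel,
        effects,
        n_fam_total,
        seed=s_cohort,
        indirect_weight=sim.indirect_weight,
        sex_effect=sim.sex_effect,
        age_effect=sim.age_effect,
    )

    rng = np.random.default_rng(s_split)
    fam_perm = rng.permutation(n_fam_total)
    sib_pool_fams = np.sort(fam_perm[:sib_pool])
    unrel_fams = np.sort(fam_perm[sib_pool:])
    sib_pool_cohort = cohort.subset_families(sib_pool_fams)
    sib_pool_rows = cohort.offspring_rows(sib_pool_fams)
    unrel_rows = cohort.offspring_rows(unrel_fams)[0::2]  # one offspring per family
    unrel_geno = cohort.offspring.subset_individuals(unrel_rows)

    y = pheno["y"].to_numpy()
    cov = pheno[["sex", "age"]].to_numpy(dtype=float)
    sib_pool_y, sib_pool_cov = y[sib_pool_rows], cov[sib_pool_rows]
    un_y, un_cov = y[unrel_rows], cov[unrel_rows]
    del cohort  # free the full offspring/parent matrices

    ld_rng = np.random.default_rng(s_ld)
    ld_ref = unrel_geno.subset_individuals(
        ld_rng.choice(unrel_geno.n, size=min(design.ld_reference_size, unrel_geno.n), replace=False)
    )

    thresholds = design.thresholds()
    nstar_fit: NStarFit | None = None
    rows = []
    for it, it_seed in enumerate(iter_seeds):
        it_rng = np.random.default_rng(it_seed)
        # resample the sibling set so sib-GWAS noise is iteration-specific
        fam_idx = it_rng.choice(sib_pool_cohort.n_families, size=sim.n_sib_families, replace=False)
        fam_idx = np.sort(fam_idx)
        sib_cohort = sib_pool_cohort.subset_families(fam_idx)
        sib_member_rows = sib_pool_cohort.offspring_rows(fam_idx)
        sib_stats = sib_diff_gwas(
            sib_cohort, sib_pool_y[sib_member_rows], sib_pool_cov[sib_member_rows]
        )
        if nstar_fit is None or design.nstar_per_iteration:
            nstar_fit = estimate_n_star(
                sib_stats,
                unrel_geno,
                un_y,
                un_cov,
                design.nstar_grid,
                seed=int(it_rng.integers(2**31)),
                se_snps=design.nstar_se_snps,
            )
        n_star = nstar_fit.n_star
        if n_star >= unrel_geno.n:
            raise ValueError("n* exceeds the available unrelated pool")

        perm = it_rng.permutation(unrel_geno.n)
        est_idx = perm[:n_star]
        rest = perm[n_star:]
        n_pred = int(round(design.prediction_fraction * len(rest)))
        pred_idx, disc_idx = rest[:n_pred], rest[n_pred:]
        _assert_disjoint(est_idx, pred_idx, disc_idx)

        disc_stats = ols_gwas(
            unrel_geno.subset_individuals(disc_idx), y=un_y[disc_idx], covariates=un_cov[disc_idx]
        )
        selected_by_t = {
            t: clump(disc_stats, ld_ref, t, design.clump_r2, design.clump_window_bp)
            for t in thresholds
        }
        union = sorted(set().union(*selected_by_t.values()))
        pred_geno = unrel_geno.subset_individuals(pred_idx)

        if union:
            est_geno = unrel_geno.subset_individuals(est_idx).subset_snps(union)
            est_stats = ols_gwas(est_geno, un_y[est_idx], un_cov[est_idx])
            estimable = set(est_stats.table["ID"]) & set(sib_stats.table["ID"])
        else:
            est_stats = None
            estimable = set()

        for t in thresholds:
            sel = [s for s in selected_by_t[t] if s in estimable]
            if not sel:
                rows.append(
                    {
                        "iteration": it,
                        "p_threshold": t,
                        "n_snps": 0,
                        "n_star": n_star,
                        "r2_standard": np.nan,
                        "r2_sib": np.nan,
                        "ratio": np.nan,
                    }
                )
                continue
            model_std = build_score_model(est_stats, sel, t)
            model_sib = build_score_model(sib_stats, sel, t)
            score_std = score_individuals(pred_geno, model_std)
            score_sib = score_individuals(pred_geno, model_sib)
            r2_std = incremental_r2(un_y[pred_idx], un_cov[pred_idx], score_std)
            r2_sib = incremental_r2(un_y[pred_idx], un_cov[pred_idx], score_sib)
            rows.append(
                {
                    "iteration": it,
                    "p_threshold": t,
                    "n_snps": len(sel),
                    "n_star": n_star,
                    "r2_standard": r2_std,
                    "r2_sib": r2_sib,
                    "ratio": r2_sib / r2_std if r2_std > 0 else np.nan,
                }
            )
    return SibCompareReport(pd.DataFrame(rows), config)


def threshold_sweep(report: SibCompareReport) -> pd.DataFrame:
    """Per-threshold summary of the sib/standard accuracy ratio.

    Columns: p_threshold, n_iterations, median_ratio, ratio_q10, ratio_q90,
    median_n_snps.  The frame's ``attrs['n_snps_monotone']`` records
    whether the SNP count was nondecreasing in the threshold within every
    iteration.
    """
    t = report.table
    if t["p_threshold"].nunique() < 2:
        raise ValueError("threshold sweep needs at least 2 thresholds")
    monotone = True
    for _, sub in t.sort_values("p_threshold").groupby("iteration"):
        monotone &= bool(np.all(np.diff(sub["n_snps"].to_numpy()) >= 0))
    out = []
    for thr, sub in t.groupby("p_threshold"):
        ratios = sub["ratio"].dropna()
        out.append(
            {
                "p_threshold": thr,
                "n_iterations": len(ratios),
                "median_ratio": ratios.median() if len(ratios) else np.nan,
                "ratio_q10": ratios.quantile(0.10) if len(ratios) else np.nan,
                "ratio_q90": ratios.quantile(0.90) if len(ratios) else np.nan,
                "median_n_snps": sub["n_snps"].median(),
            }
        )
    summary = pd.DataFrame(out).sort_values("p_threshold").reset_index(drop=True)
    summary.attrs["n_snps_monotone"] = monotone
    return summary


# --------------------------------------------------------------------------
# stratified experiment


@dataclass
class EffectReestimate:
    """Per-stratum re-estimated effects of ascertained SNPs.

    Effects are oriented so the discovery estimate is positive
    (trait-increasing alleles).  ``slopes`` holds, for each ordered stratum
    pair, the attenuation-corrected regression slope of one stratum's
    effects on the other's with a delete-one-SNP jackknife SE.
    """

    effects: pd.DataFrame  # stratum, ID, beta, se
    means: pd.DataFrame  # stratum, mean_beta, se
    slopes: pd.DataFrame  # stratum_a, stratum_b, slope, se, n_snps


def _corrected_slope(b_a, b_b, se_b) -> float:
    # errors-in-variables correction: subtract the sampling variance of the
    # predictor's estimates from its observed variance
    denom = np.var(b_b, ddof=1) - np.mean(se_b**2)
    if denom <= 0:
        return np.nan
    return float(np.cov(b_a, b_b, ddof=1)[0, 1] / denom)


def reestimate_effects_by_stratum(
    selected_snps: list[str],
    stats_discovery: SummaryStats,
    genotypes: GenotypeMatrix,
    y: np.ndarray,
    covariates,
    reestimation_idx_by_stratum: dict[str, np.ndarray],
    ascertainment_idx=None,
) -> EffectReestimate:
    """Re-estimate ascertained SNP effects separately in each stratum.

    ``ascertainment_idx`` (the discovery sample, if it lives in the same
    genotype matrix) must be disjoint from every re-estimation set.
    """
    if ascertainment_idx is not None:
        asc = set(np.asarray(ascertainment_idx).tolist())
        for label, idx in reestimation_idx_by_stratum.items():
            if asc & set(np.asarray(idx).tolist()):
                raise ValueError(f"ascertainment overlaps re-estimation stratum {label!r}")
    disc = stats_discovery.table.set_index("ID")
    missing = [s for s in selected_snps if s not in disc.index]
    if missing:
        raise KeyError(f"selected SNPs absent from discovery stats: {missing[:5]}")
    # express discovery betas on the panel's effect-allele coding, so the
    # trait-increasing orientation is invariant to allele flips in the stats
    panel_idx = genotypes.panel.index_of(np.asarray(selected_snps))
    panel_ea = genotypes.panel.table["effect_allele"].to_numpy()[panel_idx]
    disc_sel = disc.loc[list(selected_snps)]
    flip = disc_sel["EA"].to_numpy() != panel_ea
    orient = np.sign(np.where(flip, -1.0, 1.0) * disc_sel["BETA"].to_numpy())
    orient[orient == 0] = 1.0

    y = np.asarray(y, dtype=float)
    cov = np.asarray(covariates, dtype=float) if covariates is not None else None
    frames, mean_rows, per_stratum = [], [], {}
    for label, idx in reestimation_idx_by_stratum.items():
        idx = np.asarray(idx)
        sub = genotypes.subset_individuals(idx).subset_snps(selected_snps)
        stats = ols_gwas(sub, y[idx], cov[idx] if cov is not None else None)
        t = stats.table.set_index("ID").reindex(selected_snps)
        beta = t["BETA"].to_numpy() * orient
        se = t["SE"].to_numpy()
        frames.append(
            pd.DataFrame({"stratum": label, "ID": selected_snps, "beta": beta, "se": se})
        )
        ok = np.isfinite(beta)
        mean_rows.append(
            {
                "stratum": label,
                "mean_beta": float(np.nanmean(beta)),
                "se": float(np.nanstd(beta[ok], ddof=1) / np.sqrt(ok.sum())),
                "n_snps": int(ok.sum()),
            }
        )
        per_stratum[label] = (beta, se)

    slope_rows = []
    labels = list(reestimation_idx_by_stratum)
    for la in labels:
        for lb in labels:
            if la == lb:
                continue
            b_a, _ = per_stratum[la]
            b_b, se_b = per_stratum[lb]
            ok = np.isfinite(b_a) & np.isfinite(b_b)
            b_a, b_b, se_b = b_a[ok], b_b[ok], se_b[ok]
            slope = _corrected_slope(b_a, b_b, se_b)
            jk = np.array(
                [
                    _corrected_slope(np.delete(b_a, j), np.delete(b_b, j), np.delete(se_b, j))
                    for j in range(len(b_a))
                ]
            )
            jk = jk[np.isfinite(jk)]
            if len(jk) > 1:
                se = float(np.sqrt((len(jk) - 1) / len(jk) * ((jk - jk.mean()) ** 2).sum()))
            else:
                se = np.nan
            slope_rows.append(
                {"stratum_a": la, "stratum_b": lb, "slope": slope, "se": se, "n_snps": int(ok.sum())}
            )
    return EffectReestimate(
        effects=pd.concat(frames, ignore_index=True),
        means=pd.DataFrame(mean_rows),
        slopes=pd.DataFrame(slope_rows),
    )


@dataclass
class StratifiedReport:
    """Stratified-GWAS experiment output.

    ``accuracy`` columns: iteration, gwas_set, prediction_stratum, metric,
    value, n_prediction, n_snps, n_gwas.  ``h2`` and ``variance`` hold the
    per-stratum diagnostics; ``reestimate`` the optional cross-stratum
    effect re-estimation.
    """

    accuracy: pd.DataFrame
    h2: pd.DataFrame
    variance: pd.DataFrame
    config: ExperimentConfig
    reestimate: EffectReestimate | None = None

    def to_tsv(self, path) -> None:
        self.accuracy.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_stratified_experiment(config: ExperimentConfig) -> StratifiedReport:
    """Per-stratum and diverse GWAS, scored in per-stratum prediction sets."""
    sim, design = config.simulation, config.design
    labels = [s.label for s in sim.strata]
    if len(labels) < 2:
        raise ValueError("stratified experiment needs at least 2 strata")
    (s_model, s_geno, s_pheno, s_ld, *iter_seeds) = _child_seeds(
        config.seed, 4 + design.n_iterations
    )
    effects, panel = _build_effects(sim, s_model)
    geno = popsim.simulate_unrelated(panel, sim.n_unrelated, seed=s_geno, keep_haplotypes=False)
    pheno = popsim.assemble_phenotype(
        geno,
        effects,
        seed=s_pheno,
        sex_effect=sim.sex_effect,
        age_effect=sim.age_effect,
        stratum_assignment=sim.stratum_assignment,
        collider_r=sim.collider_r,
    )
    y = pheno["y"].to_numpy()
    cov = pheno[["sex", "age"]].to_numpy(dtype=float)
    strata = pheno["stratum"].to_numpy()
    if sim.binary:
        y_bin = binarize_trait(y, quantile=sim.binary_quantile)

    ld_rng = np.random.default_rng(s_ld)
    ld_ref = geno.subset_individuals(
        ld_rng.choice(geno.n, size=min(design.ld_reference_size, geno.n), replace=False)
    )

    variance = stratum_adjusted_variance(y, cov, strata)
    h2_rows = []
    for lab in labels:
        members = np.flatnonzero(strata == lab)
        est, se = h2_moment_estimate(
            geno.subset_individuals(members), y[members], cov[members], snps=effects.causal_ids
        )
        h2_rows.append({"stratum": lab, "h2": est, "se": se, "n": len(members)})
    h2_table = pd.DataFrame(h2_rows)

    members_by = {lab: np.flatnonzero(strata == lab) for lab in labels}
    n_pred = design.n_prediction_per_stratum
    for lab, mem in members_by.items():
        if len(mem) <= n_pred:
            raise ValueError(f"stratum {lab!r} too small for the prediction split")

    rows = []
    for it, it_seed in enumerate(iter_seeds):
        it_rng = np.random.default_rng(it_seed)
        pred_idx = {
            lab: it_rng.choice(mem, size=n_pred, replace=False) for lab, mem in members_by.items()
        }
        eligible = {
            lab: np.setdiff1d(mem, pred_idx[lab], assume_unique=False)
            for lab, mem in members_by.items()
        }
        q = min(len(e) for e in eligible.values())
        q = (q // len(labels)) * len(labels)
        gwas_sets = {
            lab: it_rng.choice(eligible[lab], size=q, replace=False) for lab in labels
        }
        gwas_sets["diverse"] = np.concatenate(
            [it_rng.choice(eligible[lab], size=q // len(labels), replace=False) for lab in labels]
        )
        if design.include_pooled:
            gwas_sets["pooled"] = np.concatenate(
                [it_rng.choice(eligible[lab], size=q, replace=False) for lab in labels]
            )

        for set_label, idx in gwas_sets.items():
            for lab in labels:
                _assert_disjoint(idx, pred_idx[lab])
            sub = geno.subset_individuals(idx)
            if sim.binary:
                stats = logistic_gwas(sub, y_bin[idx], cov[idx])
            else:
                stats = ols_gwas(sub, y[idx], cov[idx])
            sel = clump(
                stats, ld_ref, design.stratified_p_threshold, design.clump_r2,
                design.clump_window_bp,
            )
            model = build_score_model(stats, sel, design.stratified_p_threshold)
            for lab in labels:
                p_idx = pred_idx[lab]
                score = score_individuals(geno.subset_individuals(p_idx), model)
                if model.n_snps == 0:
                    value, metric = np.nan, "incremental_auc" if sim.binary else "incremental_r2"
                elif sim.binary:
                    metric = "incremental_auc"
                    value = incremental_auc(y_bin[p_idx], cov[p_idx], score)
                else:
                    metric = "incremental_r2"
                    value = incremental_r2(y[p_idx], cov[p_idx], score)
                rows.append(
                    {
                        "iteration": it,
                        "gwas_set": set_label,
                        "prediction_stratum": lab,
                        "metric": metric,
                        "value": value,
                        "n_prediction": len(p_idx),
                        "n_snps": model.n_snps,
                        "n_gwas": len(idx),
                    }
                )

    reest = None
    if design.reestimate:
        it_rng = np.random.default_rng(iter_seeds[0])
        pred_idx = {
            lab: it_rng.choice(mem, size=n_pred, replace=False) for lab, mem in members_by.items()
        }
        eligible = np.concatenate(
            [np.setdiff1d(mem, pred_idx[lab]) for lab, mem in members_by.items()]
        )
        pooled_geno = geno.subset_individuals(eligible)
        pooled_stats = ols_gwas(pooled_geno, y[eligible], cov[eligible])
        sel = clump(
            pooled_stats, ld_ref, design.reestimate_p_threshold, design.clump_r2,
            design.clump_window_bp,
        )
        if sel:
            reest = reestimate_effects_by_stratum(
                sel, pooled_stats, geno, y, cov, pred_idx, ascertainment_idx=eligible
            )
    return StratifiedReport(
        accuracy=pd.DataFrame(rows),
        h2=h2_table,
        variance=variance,
        config=config,
        reestimate=reest,
    )
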