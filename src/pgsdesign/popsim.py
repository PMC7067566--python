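"""Forward simulation of genotypes, families and phenotypes.

The generator produces the statistical structure that downstream analyses
assume: biallelic SNPs in LD blocks, unrelated individuals, two-generation
families with Mendelian transmission, additive direct effects, optional
per-SNP indirect parental effects, optional positive assortative mating on
the phenotype, and strata that modulate either the magnitude of genetic
effects ("amplification") or the environmental variance.

The quantitative trait follows the standardization

    y = a_s * sqrt(h2) * (g - mean(g)) / sd(g)
        + eta * z_ind
        + e_s * sqrt(1 - h2) * (eps - mean(eps)) / sd(eps)

where ``g`` is the additive genetic score, ``eps`` i.i.d. Gaussian noise,
``z_ind`` the standardized sum of the two parents' indirect genetic scores,
and ``a_s``/``e_s`` per-stratum multipliers. With unit multipliers and no
indirect term the trait has zero mean, unit variance and corr^2(y, g) = h2.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))

__all__ = [
    "SnpPanel",
    "GenotypeMatrix",
    "StratumSpec",
    "EffectModel",
    "FamilyCohort",
    "make_snp_panel",
    "simulate_unrelated",
    "draw_effect_sizes",
    "genetic_score",
    "mate_parents",
    "simulate_offspring",
    "assemble_phenotype",
    "binarize_trait",
    "check_mendelian",
    "simulate_two_generation_cohort",
    "trait_simulation_grid",
]


@dataclass(frozen=True)
class SnpPanel:
    """Per-SNP metadata: identity, position, alleles, frequency, LD block.

    ``table`` columns: snp_id, chrom, pos, effect_allele, other_allele,
    maf, block_id.  ``within_block_r`` records the haplotype-copying
    parameter the panel was built for (0 means unlinked), so estimators
    whose validity depends on linkage can check it.
    """

    table: pd.DataFrame
    within_block_r: float = 0.0

    def __post_init__(self) -> None:
        t = self.table
        required = {"snp_id", "chrom", "pos", "effect_allele", "other_allele", "maf", "block_id"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"panel table missing columns: {sorted(missing)}")
        if t["snp_id"].duplicated().any():
            raise ValueError("duplicate SNP ids in panel")
        maf = t["maf"].to_numpy()
        if np.any(maf <= 0) or np.any(maf > 0.5):
            raise ValueError("maf must lie in (0, 0.5]")
        for _, sub in t.groupby("chrom"):
            if not np.all(np.diff(sub["pos"].to_numpy()) > 0):
                raise ValueError("positions must be strictly increasing within a chromosome")

    @property
    def m(self) -> int:
        return len(self.table)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.table["snp_id"].to_numpy()

    @property
    def maf(self) -> np.ndarray:
        return self.table["maf"].to_numpy()

    @property
    def block_ids(self) -> np.ndarray:
        return self.table["block_id"].to_numpy()

    def index_of(self, snp_ids) -> np.ndarray:
        """Positional indices of the given SNP ids; raises on unknown ids."""
        lookup = pd.Index(self.table["snp_id"])
        idx = lookup.get_indexer(np.asarray(snp_ids))
        if np.any(idx < 0):
            bad = np.asarray(snp_ids)[idx < 0]
            raise KeyError(f"SNPs absent from panel: {list(bad[:5])}")
        return idx

    def subset(self, indices) -> "SnpPanel":
        return SnpPanel(self.table.iloc[indices].reset_index(drop=True), self.within_block_r)


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs effect-allele counts, optionally with haplotypes.

    ``haplotypes`` has shape (2n, m); rows 2i and 2i+1 are individual i's
    two haplotypes and sum to ``counts[i]``.
    """

    panel: SnpPanel
    counts: np.ndarray
    haplotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[1] != self.panel.m:
            raise ValueError("counts must be (n_individuals, m_snps)")
        if self.counts.size and (self.counts.min() < 0 or self.counts.max() > 2):
            raise ValueError("allele counts must be in {0, 1, 2}")
        if self.haplotypes is not None:
            h = np.asarray(self.haplotypes)
            if h.shape != (2 * self.n, self.panel.m):
                raise ValueError("haplotypes must be (2n, m)")
            if not np.array_equal(h[0::2] + h[1::2], self.counts):
                raise ValueError("haplotypes inconsistent with counts")

    @property
    def n(self) -> int:
        return self.counts.shape[0]

    def subset_individuals(self, indices) -> "GenotypeMatrix":
        indices = np.asarray(indices)
        haps = None
        if self.haplotypes is not None:
            hap_idx = np.empty(2 * len(indices), dtype=np.int64)
            hap_idx[0::2] = 2 * indices
            hap_idx[1::2] = 2 * indices + 1
            haps = self.haplotypes[hap_idx]
        return GenotypeMatrix(self.panel, self.counts[indices], haps)

    def subset_snps(self, snp_ids) -> "GenotypeMatrix":
        idx = self.panel.index_of(snp_ids)
        haps = self.haplotypes[:, idx] if self.haplotypes is not None else None
        return GenotypeMatrix(self.panel.subset(idx), self.counts[:, idx], haps)

    def drop_haplotypes(self) -> None:
        self.haplotypes = None


@dataclass(frozen=True)
class StratumSpec:
    """One stratum: label, genetic-amplification and environment multipliers,
    and its sampling weight under random assignment."""

    label: str
    amplification: float = 1.0
    env_scale: float = 1.0
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.amplification <= 0 or self.env_scale <= 0:
            raise ValueError("stratum multipliers must be positive")


@dataclass
class EffectModel:
    """Generative parameters of the trait."""

    causal_ids: np.ndarray
    beta_direct: np.ndarray
    beta_indirect: np.ndarray
    h2: float
    rho_di: float = 0.0
    am_strength: float = 0.0
    strata: list[StratumSpec] = field(default_factory=lambda: [StratumSpec("all")])

    def __post_init__(self) -> None:
        self.causal_ids = np.asarray(self.causal_ids)
        self.beta_direct = np.asarray(self.beta_direct, dtype=float)
        self.beta_indirect = np.asarray(self.beta_indirect, dtype=float)
        if len(self.beta_direct) != len(self.causal_ids):
            raise ValueError("beta_direct length must match causal_ids")
        if len(self.beta_indirect) != len(self.causal_ids):
            raise ValueError("beta_indirect length must match causal_ids")
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must lie in [0, 1]")
        if abs(self.rho_di) > 1.0:
            raise ValueError("rho_di must lie in [-1, 1]")
        if not 0.0 <= self.am_strength < 1.0:
            raise ValueError("am_strength must lie in [0, 1)")

    @property
    def stratum_labels(self) -> list[str]:
        return [s.label for s in self.strata]

    def with_strata(self, strata: list[StratumSpec]) -> "EffectModel":
        return replace(self, strata=list(strata))


@dataclass
class FamilyCohort:
    """Two-generation families: parental genotype pairs plus two offspring.

    Offspring rows are family-major: rows ``2f`` and ``2f + 1`` of
    ``offspring.counts`` are the sibling pair of family ``f``.  Exactly one
    sibling pair is retained per family.  ``parents`` optionally carries the
    parental phenotypes and genetic scores used for mating.
    """

    mothers: GenotypeMatrix
    fathers: GenotypeMatrix
    offspring: GenotypeMatrix
    family_id: np.ndarray
    parents: pd.DataFrame | None = None
    n_offspring_per_family: int = 2

    def __post_init__(self) -> None:
        f = self.n_families
        if self.fathers.n != f:
            raise ValueError("mothers and fathers must align one per family")
        if self.offspring.n != self.n_offspring_per_family * f:
            raise ValueError("offspring rows must be n_offspring_per_family per family")

    @property
    def n_families(self) -> int:
        return self.mothers.n

    @property
    def panel(self) -> SnpPanel:
        return self.offspring.panel

    def offspring_rows(self, family_indices) -> np.ndarray:
        """Row indices into ``offspring`` for the given families, kept
        family-major (all offspring of a family stay adjacent)."""
        fam = np.asarray(family_indices)
        k = self.n_offspring_per_family
        return (fam[:, None] * k + np.arange(k)[None, :]).ravel()

    def subset_families(self, family_indices) -> "FamilyCohort":
        fam = np.asarray(family_indices)
        parents = self.parents.iloc[fam].reset_index(drop=True) if self.parents is not None else None
        return FamilyCohort(
            mothers=self.mothers.subset_individuals(fam),
            fathers=self.fathers.subset_individuals(fam),
            offspring=self.offspring.subset_individuals(self.offspring_rows(fam)),
            family_id=self.family_id[fam],
            parents=parents,
            n_offspring_per_family=self.n_offspring_per_family,
        )


def make_snp_panel(
    m: int,
    maf_low: float = 0.05,
    maf_high: float = 0.5,
    block_size: int = 10,
    within_block_r: float = 0.8,
    seed: int = 0,
    *,
    within_block_spacing_bp: int = 5_000,
    between_block_gap_bp: int = 2_000_000,
    chrom: int = 1,
) -> SnpPanel:
    """Lay out ``m`` SNPs in contiguous LD blocks of ``block_size``.

    Blocks share a single MAF (drawn uniformly from [maf_low, maf_high]) so
    the haplotype-copying process preserves marginal frequencies exactly.
    Consecutive blocks are separated by ``between_block_gap_bp`` so that,
    with the default 2 Mb gap, distinct blocks fall outside a 1 Mb clumping
    window; shrink the gap to place them inside it.
    """
    if m <= 0 or block_size <= 0:
        raise ValueError("m and block_size must be positive")
    if not (0.0 < maf_low <= maf_high <= 0.5):
        raise ValueError("need 0 < maf_low <= maf_high <= 0.5")
    if not 0.0 <= within_block_r < 1.0:
        raise ValueError("within_block_r must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    n_blocks = -(-m // block_size)
    block_maf = rng.uniform(maf_low, maf_high, size=n_blocks)
    block_id = np.arange(m) // block_size
    maf = block_maf[block_id]

    pos = np.empty(m, dtype=np.int64)
    cursor = 1
    for j in range(m):
        if j > 0:
            cursor += between_block_gap_bp if block_id[j] != block_id[j - 1] else within_block_spacing_bp
        pos[j] = cursor

    allele_pairs = np.array([rng.choice(4, size=2, replace=False) for _ in range(m)])
    table = pd.DataFrame(
        {
            "snp_id": [f"snp{j:05d}" for j in range(m)],
            "chrom": np.full(m, chrom, dtype=np.int64),
            "pos": pos,
            "effect_allele": _BASES[allele_pairs[:, 0]],
            "other_allele": _BASES[allele_pairs[:, 1]],
            "maf": maf,
            "block_id": block_id,
        }
    )
    return SnpPanel(table, within_block_r=within_block_r)


def simulate_unrelated(
    panel: SnpPanel, n: int, seed: int = 0, *, keep_haplotypes: bool = True
) -> GenotypeMatrix:
    """Draw ``n`` unrelated individuals as 2n haplotypes.

    Within each block a haplotype is a first-order copying chain: the allele
    at a SNP is copied from the previous SNP's allele with probability
    ``panel.within_block_r`` and drawn fresh Bernoulli(maf) otherwise, which
    gives adjacent-SNP haplotype correlation ~ within_block_r and exact
    Bernoulli(maf) margins (block members share a MAF).  Blocks are
    independent.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    m = panel.m
    r = panel.within_block_r
    maf = panel.maf
    block = panel.block_ids
    # SNP-major layout so each column fill is contiguous; transposed at the end
    haps_t = np.empty((m, 2 * n), dtype=np.int8)
    for j in range(m):
        fresh = (rng.random(2 * n) < maf[j]).astype(np.int8)
        if r > 0 and j > 0 and block[j] == block[j - 1]:
            copy = rng.random(2 * n) < r
            haps_t[j] = np.where(copy, haps_t[j - 1], fresh)
        else:
            haps_t[j] = fresh
    haps = np.ascontiguousarray(haps_t.T)
    del haps_t
    counts = haps[0::2] + haps[1::2]
    return GenotypeMatrix(panel, counts, haps if keep_haplotypes else None)


def draw_effect_sizes(
    panel: SnpPanel,
    m_causal: int,
    h2: float,
    rho_di: float = 0.0,
    indirect_scale: float = 0.0,
    seed: int = 0,
) -> EffectModel:
    """Draw per-SNP effects: beta_direct ~ i.i.d. N(0, h2 / m_causal).

    ``beta_indirect`` is constructed to have sample correlation exactly
    ``rho_di`` with ``beta_direct`` and standard deviation
    ``indirect_scale * sd(beta_direct)``; with ``indirect_scale = 0`` it is
    identically zero.  Non-causal SNPs carry no effect.
    """
    if not 1 <= m_causal <= panel.m:
        raise ValueError("m_causal must lie in [1, panel.m]")
    if not 0.0 <= h2 <= 1.0:
        raise ValueError("h2 must lie in [0, 1]")
    if abs(rho_di) > 1.0:
        raise ValueError("rho_di must lie in [-1, 1]")
    if indirect_scale < 0.0:
        raise ValueError("indirect_scale must be nonnegative")
    rng = np.random.default_rng(seed)
    causal_idx = np.sort(rng.choice(panel.m, size=m_causal, replace=False))
    causal_ids = panel.snp_ids[causal_idx]
    beta = rng.normal(0.0, np.sqrt(h2 / m_causal), size=m_causal) if h2 > 0 else np.zeros(m_causal)

    if indirect_scale == 0.0 or h2 == 0.0:
        beta_ind = np.zeros(m_causal)
    else:
        if m_causal < 3:
            raise ValueError("indirect effects need at least 3 causal SNPs")
        z_b = (beta - beta.mean()) / beta.std()
        e = rng.normal(size=m_causal)
        e = e - e.mean() - z_b * (z_b @ (e - e.mean())) / (z_b @ z_b)
        z_e = e / e.std()
        mix = rho_di * z_b + np.sqrt(max(0.0, 1.0 - rho_di**2)) * z_e
        beta_ind = indirect_scale * beta.std() * mix / mix.std()
    return EffectModel(causal_ids, beta, beta_ind, h2=h2, rho_di=rho_di)


def genetic_score(
    genotypes: GenotypeMatrix, effects: EffectModel, which: str = "direct"
) -> np.ndarray:
    """g = sum over causal SNPs of effect * allele count."""
    if which not in ("direct", "indirect"):
        raise ValueError("which must be 'direct' or 'indirect'")
    idx = genotypes.panel.index_of(effects.causal_ids)
    beta = effects.beta_direct if which == "direct" else effects.beta_indirect
    return genotypes.counts[:, idx].astype(np.float64) @ beta


def mate_parents(
    parent_phenotypes: np.ndarray, am_strength: float, seed: int = 0
) -> np.ndarray:
    """Pair parents into couples with target spousal phenotype correlation.

    The pool is split in half by index order into two mating sides.  Under
    random mating (am_strength = 0) sides are paired by a random
    permutation.  Otherwise each side's phenotype is perturbed with
    Gaussian noise and the two sides are rank-matched on the noisy values;
    with noise variance s * Var(y) per side the matched correlation is
    about 1 / (1 + s), so s = 1/r - 1 is the closed-form start, refined by
    one calibration iteration against the realized correlation.

    Returns an (n_couples, 2) integer array of (side-A, side-B) indices
    into the input vector; every parent is used exactly once.
    """
    if not 0.0 <= am_strength < 1.0:
        raise ValueError("am_strength must lie in [0, 1)")
    y = np.asarray(parent_phenotypes, dtype=float)
    if y.ndim != 1 or len(y) % 2:
        raise ValueError("need an even number of parents")
    n_c = len(y) // 2
    side_a = np.arange(n_c)
    side_b = np.arange(n_c, 2 * n_c)
    rng = np.random.default_rng(seed)
    if am_strength == 0.0:
        return np.column_stack([side_a, rng.permutation(side_b)])

    v = y.var()
    if v == 0.0:
        return np.column_stack([side_a, rng.permutation(side_b)])

    def _match(noise_var: float) -> np.ndarray:
        na = y[side_a] + rng.normal(0.0, np.sqrt(noise_var), n_c)
        nb = y[side_b] + rng.normal(0.0, np.sqrt(noise_var), n_c)
        return np.column_stack([side_a[np.argsort(na)], side_b[np.argsort(nb)]])

    s = (1.0 / am_strength - 1.0) * v
    couples = _match(s)
    realized = np.corrcoef(y[couples[:, 0]], y[couples[:, 1]])[0, 1]
    if realized > 1e-3 and s > 0:
        # invert the realized attenuation curve r(s) = 1/(1 + c*s)
        c = (1.0 / realized - 1.0) / s
        if c > 0:
            s2 = (1.0 / am_strength - 1.0) / c
            couples = _match(s2)
    return couples


def simulate_offspring(
    couples: np.ndarray,
    parental_genotypes: GenotypeMatrix,
    n_offspring_per_family: int = 2,
    seed: int = 0,
    *,
    keep_haplotypes: bool = False,
) -> FamilyCohort:
    """Mendelian transmission: each parent passes, independently per LD
    block, one of its two within-block haplotypes intact (free recombination
    between blocks, none within)."""
    if parental_genotypes.haplotypes is None:
        raise ValueError("offspring simulation requires parental haplotypes")
    couples = np.asarray(couples)
    rng = np.random.default_rng(seed)
    haps = parental_genotypes.haplotypes
    panel = parental_genotypes.panel
    block = panel.block_ids
    # blocks are contiguous SNP runs, so each is a cheap column slice
    boundaries = np.flatnonzero(np.diff(block)) + 1
    spans = list(zip(np.r_[0, boundaries], np.r_[boundaries, panel.m]))
    f = len(couples)
    k = n_offspring_per_family

    child_haps = np.empty((2 * f * k, panel.m), dtype=np.int8)
    for parent_col, hap_slot in ((0, 0), (1, 1)):
        parent_idx = couples[:, parent_col]
        for j in range(k):
            # offspring rows are family-major, so this is a strided slice
            target = slice(2 * j + hap_slot, None, 2 * k)
            for start, stop in spans:
                choice = rng.integers(0, 2, size=f)
                child_haps[target, start:stop] = haps[2 * parent_idx + choice, start:stop]
    counts = child_haps[0::2] + child_haps[1::2]
    offspring = GenotypeMatrix(panel, counts, child_haps if keep_haplotypes else None)
    mothers = parental_genotypes.subset_individuals(couples[:, 0])
    fathers = parental_genotypes.subset_individuals(couples[:, 1])
    if not keep_haplotypes:
        mothers.drop_haplotypes()
        fathers.drop_haplotypes()
    return FamilyCohort(
        mothers=mothers,
        fathers=fathers,
        offspring=offspring,
        family_id=np.arange(f),
        n_offspring_per_family=k,
    )


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def assemble_phenotype(
    data: GenotypeMatrix | FamilyCohort,
    effects: EffectModel,
    seed: int = 0,
    *,
    indirect_weight: float = 0.0,
    sex_prob: float = 0.5,
    sex_effect: float = 0.0,
    age_range: tuple[float, float] = (40.0, 70.0),
    age_effect: float = 0.0,
    stratum_assignment: str = "random",
    collider_r: float = 0.6,
) -> pd.DataFrame:
    """Build the phenotype table for a genotype matrix or family cohort.

    Columns: individual_id, y, sex, age, stratum, g (true direct genetic
    score, for diagnostics), and family_id for cohorts.  ``indirect_weight``
    (eta) weights the standardized sum of the two parents' indirect genetic
    scores and requires parental genotypes, i.e. a FamilyCohort.  Sex and
    age act additively on y (age standardized), both 0 by default so that
    the unit-multiplier, no-indirect case reproduces the standardization
    formula exactly.
    """
    rng = np.random.default_rng(seed)
    is_cohort = isinstance(data, FamilyCohort)
    genotypes = data.offspring if is_cohort else data
    n = genotypes.n

    g = genetic_score(genotypes, effects, "direct")
    z_g = _standardize(g)
    eps = rng.normal(size=n)
    z_eps = _standardize(eps)

    if indirect_weight != 0.0:
        if not is_cohort:
            raise ValueError("indirect effects require parental genotypes (a FamilyCohort)")
        gi = genetic_score(data.mothers, effects, "indirect") + genetic_score(
            data.fathers, effects, "indirect"
        )
        z_ind = np.repeat(_standardize(gi), data.n_offspring_per_family)
    else:
        z_ind = np.zeros(n)

    labels = np.array(effects.stratum_labels)
    weights = np.array([s.weight for s in effects.strata], dtype=float)
    weights = weights / weights.sum()
    h2 = effects.h2
    if len(labels) == 1:
        stratum_idx = np.zeros(n, dtype=np.int64)
    elif stratum_assignment == "random":
        stratum_idx = rng.choice(len(labels), size=n, p=weights)
    elif stratum_assignment == "collider":
        # SES-like stratification: threshold a collider correlated with the
        # (unit-multiplier) phenotype, emulating range restriction.
        y0 = np.sqrt(h2) * z_g + np.sqrt(1.0 - h2) * z_eps
        c = collider_r * y0 + np.sqrt(max(0.0, 1.0 - collider_r**2)) * rng.normal(size=n)
        edges = np.quantile(c, np.cumsum(weights)[:-1])
        stratum_idx = np.searchsorted(edges, c)
    else:
        raise ValueError("stratum_assignment must be 'random' or 'collider'")

    a_s = np.array([s.amplification for s in effects.strata])[stratum_idx]
    e_s = np.array([s.env_scale for s in effects.strata])[stratum_idx]

    sex = rng.binomial(1, sex_prob, size=n)
    age = rng.uniform(*age_range, size=n)
    y = (
        a_s * np.sqrt(h2) * z_g
        + indirect_weight * z_ind
        + e_s * np.sqrt(1.0 - h2) * z_eps
        + sex_effect * sex
        + age_effect * _standardize(age)
    )

    frame = pd.DataFrame(
        {
            "individual_id": [f"ind{j:06d}" for j in range(n)],
            "y": y,
            "sex": sex,
            "age": age,
            "stratum": labels[stratum_idx],
            "g": g,
        }
    )
    if is_cohort:
        frame["family_id"] = np.repeat(data.family_id, data.n_offspring_per_family)
    return frame


def binarize_trait(
    y: np.ndarray, threshold: float | None = None, quantile: float | None = None
) -> np.ndarray:
    """1 iff y strictly exceeds the threshold (or the given quantile of y)."""
    y = np.asarray(y, dtype=float)
    if (threshold is None) == (quantile is None):
        raise ValueError("give exactly one of threshold or quantile")
    if quantile is not None:
        if not 0.0 < quantile < 1.0:
            raise ValueError("quantile must lie in (0, 1)")
        threshold = float(np.quantile(y, quantile))
    return (y > threshold).astype(np.int8)


def check_mendelian(cohort: FamilyCohort) -> bool:
    """True iff every offspring allele count is achievable from its parents.

    A parent with count 0/1/2 can transmit {0}/{0,1}/{1}; the offspring
    count must lie between the summed minima and maxima.
    """
    gm = np.repeat(cohort.mothers.counts, cohort.n_offspring_per_family, axis=0)
    gf = np.repeat(cohort.fathers.counts, cohort.n_offspring_per_family, axis=0)
    go = cohort.offspring.counts
    lo = (gm == 2).astype(np.int8) + (gf == 2).astype(np.int8)
    hi = (gm > 0).astype(np.int8) + (gf > 0).astype(np.int8)
    return bool(np.all((go >= lo) & (go <= hi)))


def simulate_two_generation_cohort(
    panel: SnpPanel,
    effects: EffectModel,
    n_families: int,
    seed: int = 0,
    *,
    indirect_weight: float = 0.0,
    keep_haplotypes: bool = False,
    sex_effect: float = 0.0,
    age_effect: float = 0.0,
) -> tuple[FamilyCohort, pd.DataFrame]:
    """Simulate parents, mate them (per ``effects.am_strength``), transmit,
    and phenotype the offspring; returns (cohort, offspring phenotypes).

    Parental phenotypes are assembled under the single-stratum model with no
    indirect term (the grandparental generation is not simulated) and kept
    on the cohort together with parental genetic scores.
    """
    ss = np.random.SeedSequence(seed)
    s_par, s_pheno_par, s_mate, s_meiosis, s_pheno = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(5)
    ]
    parents = simulate_unrelated(panel, 2 * n_families, seed=s_par)
    parent_effects = effects.with_strata([StratumSpec("all")])
    parent_pheno = assemble_phenotype(parents, parent_effects, seed=s_pheno_par)
    couples = mate_parents(parent_pheno["y"].to_numpy(), effects.am_strength, seed=s_mate)
    cohort = simulate_offspring(couples, parents, seed=s_meiosis, keep_haplotypes=keep_haplotypes)
    cohort.parents = pd.DataFrame(
        {
            "family_id": cohort.family_id,
            "mother_y": parent_pheno["y"].to_numpy()[couples[:, 0]],
            "father_y": parent_pheno["y"].to_numpy()[couples[:, 1]],
            "mother_g": parent_pheno["g"].to_numpy()[couples[:, 0]],
            "father_g": parent_pheno["g"].to_numpy()[couples[:, 1]],
        }
    )
    pheno = assemble_phenotype(
        cohort,
        effects,
        seed=s_pheno,
        indirect_weight=indirect_weight,
        sex_effect=sex_effect,
        age_effect=age_effect,
    )
    return cohort, pheno


def trait_simulation_grid(
    h2_values: tuple[float, ...] = (0.1, 0.5),
    m_causal_values: tuple[int, ...] = (10_000, 100_000),
    n_replicates: int = 3,
) -> list[dict]:
    """Enumerate the simulated-trait validation grid: every combination of
    heritability and causal-SNP count, replicated."""
    return [
        {"h2": h2, "m_causal": mc, "replicate": r}
        for h2, mc, r in itertools.product(h2_values, m_causal_values, range(n_replicates))
    ]
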