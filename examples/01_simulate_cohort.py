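"""Simulate a two-generation cohort and inspect the trait's moments.

Builds a small SNP panel in LD blocks, draws additive effects at h2=0.5,
simulates parents, mates them at random, transmits haplotypes Mendelianly,
and assembles the standardized trait for the offspring.
"""

import numpy as np

import pgsdesign as pg

panel = pg.make_snp_panel(m=500, block_size=10, within_block_r=0.8, seed=1)
effects = pg.draw_effect_sizes(panel, m_causal=150, h2=0.5, seed=2)
cohort, pheno = pg.simulate_two_generation_cohort(panel, effects, n_families=2000, seed=3)

print(f"families: {cohort.n_families}, offspring: {cohort.offspring.n}")
print(f"Mendelian-consistent: {pg.check_mendelian(cohort)}")
print(f"Var(y) = {pheno['y'].var():.3f}   (standardized trait; expect ~1)")
r2 = np.corrcoef(pheno["y"], pheno["g"])[0, 1] ** 2
print(f"corr^2(y, true genetic score) = {r2:.3f}   (expect ~h2 = 0.5)")
sib_r = np.corrcoef(pheno["y"][0::2], pheno["y"][1::2])[0, 1]
print(f"sibling phenotype correlation = {sib_r:.3f}   (expect ~h2/2 under this model)")
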