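"""Compare standard and sibling-based polygenic scores at matched precision.

SNPs are ascertained in a large discovery GWAS; their effects are then
re-estimated (i) by a standard GWAS on an n*-sized estimation set and
(ii) by sibling-difference regression, where n* is chosen so the median
effect-estimate SEs match.  Under a vanilla generative model (no indirect
effects, no assortative mating) the two scores predict equally well, so
the sib/standard incremental-R^2 ratio scatters around 1.
"""

from pgsdesign.experiments import (
    DesignConfig,
    ExperimentConfig,
    SimulationConfig,
    run_sib_compare,
    threshold_sweep,
)

config = ExperimentConfig(
    simulation=SimulationConfig(
        m_snps=800, m_causal=250, n_unrelated=10_000, n_sib_families=1500,
        n_sib_family_pool=4500,
    ),
    design=DesignConfig(
        n_iterations=8, nstar_grid=list(range(500, 4001, 500)), p_grid=[1e-5, 1e-4, 1e-3, 1e-2]
    ),
    seed=42,
)
report = run_sib_compare(config)
sweep = threshold_sweep(report)
print(sweep.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
print(f"\nmedian n* across iterations: {report.table['n_star'].median():.0f} individuals")
print("ratios scatter around 1: SE-matching equalizes the designs here (at this")
print("small demo scale the per-threshold medians wobble by a few percent).")
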