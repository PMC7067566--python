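"""Polygenic-score accuracy across strata under genetic amplification.

Two strata share the same causal variants, but effect magnitudes are
scaled 1.3x in stratum A ("amplification").  GWAS are run within each
stratum and in a stratum-balanced diverse sample of the same size; every
score is evaluated in held-out per-stratum prediction sets.  Prediction
accuracy is systematically higher in the amplified stratum, whichever
sample the GWAS used — the signature that distinguishes amplification from
mere environmental-variance differences.
"""

from pgsdesign.experiments import (
    DesignConfig,
    ExperimentConfig,
    SimulationConfig,
    StratumConfig,
    run_stratified_experiment,
)

config = ExperimentConfig(
    simulation=SimulationConfig(
        m_snps=800, m_causal=250, n_unrelated=12_000,
        strata=[StratumConfig("A", amplification=1.3), StratumConfig("B")],
    ),
    design=DesignConfig(n_iterations=5, n_prediction_per_stratum=1200, reestimate=True),
    seed=7,
)
report = run_stratified_experiment(config)

medians = report.accuracy.groupby(["gwas_set", "prediction_stratum"])["value"].median()
print("median incremental R^2 by GWAS set x prediction stratum:")
print(medians.unstack().round(3))
print("\nper-stratum diagnostics (HE heritability, adjusted phenotypic variance):")
print(report.h2.merge(report.variance, on="stratum")[
    ["stratum", "h2", "se_x", "variance", "se_y"]
].round(3).to_string(index=False))
if report.reestimate is not None:
    slopes = report.reestimate.slopes.set_index(["stratum_a", "stratum_b"])
    row = slopes.loc[("A", "B")]
    print(f"\nre-estimated effect slope A-on-B = {row['slope']:.2f} (SE {row['se']:.2f}); "
          "expect ~1.3, the amplification factor")
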