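import numpy as np
import pytest

import pgsdesign as pg


@pytest.fixture(scope="session")
def small_panel() -> pg.SnpPanel:
    return pg.make_snp_panel(40, block_size=5, within_block_r=0.8, seed=11)


@pytest.fixture(scope="session")
def unlinked_panel() -> pg.SnpPanel:
    return pg.make_snp_panel(60, block_size=1, within_block_r=0.0, seed=13)


@pytest.fixture(scope="session")
def small_geno(small_panel) -> pg.GenotypeMatrix:
    return pg.simulate_unrelated(small_panel, 300, seed=17)


@pytest.fixture(scope="session")
def small_effects(small_panel) -> pg.EffectModel:
    return pg.draw_effect_sizes(small_panel, 12, h2=0.5, seed=19)


@pytest.fixture(scope="session")
def small_cohort(small_panel, small_effects):
    cohort, pheno = pg.simulate_two_generation_cohort(small_panel, small_effects, 250, seed=23)
    return cohort, pheno


def sumstats_from_arrays(panel: pg.SnpPanel, beta, se, p, n=1000, design="standard"):
    """Hand-built SummaryStats over a panel, for clumping/scoring tests."""
    import pandas as pd

    t = panel.table
    table = pd.DataFrame(
        {
            "CHR": t["chrom"].to_numpy(),
            "POS": t["pos"].to_numpy(),
            "ID": t["snp_id"].to_numpy(),
            "EA": t["effect_allele"].to_numpy(),
            "OA": t["other_allele"].to_numpy(),
            "BETA": np.asarray(beta, dtype=float),
            "SE": np.asarray(se, dtype=float),
            "P": np.asarray(p, dtype=float),
            "N": n,
        }
    )
    return pg.SummaryStats(table, design)
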