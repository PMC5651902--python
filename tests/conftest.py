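import numpy as np
import pytest

import epimeth as em


@pytest.fixture(scope="session")
def small_pair():
    """Small paired cohorts with one planted epistatic effect and one main."""
    cfg = em.SimulationConfig(
        n_snps=80, n_cpgs=8, seed=7, block_rho=0.6, maf_range=(0.3, 0.5)
    )
    effects = [
        em.PlantedEffect(
            cpg_id="cg00001", kind="epistatic",
            snp_ids=("snp00010", "snp00050"), target_r2=0.15,
        ),
        em.PlantedEffect(
            cpg_id="cg00002", kind="main_additive",
            snp_ids=("snp00030",), target_r2=0.3,
        ),
    ]
    return em.simulate_cohort_pair(cfg, effects)


@pytest.fixture(scope="session")
def triad():
    """LD-triad scenario: strong main on C, spurious A x B interaction."""
    return em.make_ld_triad_scenario(seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
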