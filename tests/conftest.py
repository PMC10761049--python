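import numpy as np
import pandas as pd
import pytest

from methpanel.containers import BetaMatrix
from methpanel.synthetic import (
    SimArrayConfig,
    SimCohortConfig,
    SimWgbsConfig,
    simulate_array_cohort,
    simulate_msp_cohort,
    simulate_wgbs_pairs,
)


@pytest.fixture(scope="session")
def small_array():
    """100-site, 30+30-sample cohort with 10 strong planted DMCs."""
    cfg = SimArrayConfig(
        n_sites=100, n_tumour=30, n_normal=30, n_planted=10,
        planted_effect=(0.5, 0.05), na_rate=0.05, seed=7,
    )
    matrix, planted = simulate_array_cohort(cfg)
    return matrix, planted, cfg


@pytest.fixture(scope="session")
def wgbs_sim():
    cfg = SimWgbsConfig(
        n_pairs=4, n_cpgs=300, cpg_spacing=60,
        planted_dmrs=[("chr1", 1001, 1400, 0.9, 0.1),
                      ("chr1", 9001, 9300, 0.85, 0.1)],
        depth_mean=50.0, conversion_failure_rate=0.01, seed=11,
    )
    tables, lam = simulate_wgbs_pairs(cfg)
    return tables, lam, cfg


@pytest.fixture(scope="session")
def msp_cohort():
    cfg = SimCohortConfig(n_hcc=60, n_cld=60, n_normal=30, seed=5)
    ct, clinical = simulate_msp_cohort(cfg)
    return ct, clinical, cfg


@pytest.fixture
def tiny_beta():
    """3x3 matrix with one missing entry and hand-checkable neighbours."""
    values = pd.DataFrame(
        [[0.10, np.nan, 0.30],
         [0.10, 0.40, 0.30],
         [0.90, 0.80, 0.70]],
        index=["r1", "r2", "r3"],
        columns=["s1", "s2", "s3"],
    )
    groups = pd.Series(["tumour", "tumour", "normal"], index=values.columns)
    return BetaMatrix(values, groups)
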