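import numpy as np
import pandas as pd
import pytest

from lpamr.instruments import SummaryStatSet, harmonize
from lpamr.synthetic import CohortConfig, SummaryStatsConfig, generate_cohort, generate_summary_stats


def make_stat_set(seed: int = 0, **overrides) -> SummaryStatSet:
    """Generate and harmonize one synthetic summary-stat set."""
    cfg = SummaryStatsConfig(seed=seed, **overrides)
    exposure, outcome = generate_summary_stats(cfg)
    return harmonize(exposure, outcome)


def stat_set_from_arrays(beta_exp, se_exp, beta_out, se_out) -> SummaryStatSet:
    """Build a harmonized set directly from effect arrays (already oriented)."""
    n = len(beta_exp)
    return SummaryStatSet(pd.DataFrame({
        "rsid": [f"rs{i}" for i in range(n)],
        "effect_allele": ["A"] * n, "other_allele": ["G"] * n,
        "maf": np.full(n, 0.3),
        "beta_exp": np.asarray(beta_exp, float),
        "se_exp": np.asarray(se_exp, float),
        "beta_out": np.asarray(beta_out, float),
        "se_out": np.asarray(se_out, float),
    }))


@pytest.fixture(scope="session")
def default_stat_set() -> SummaryStatSet:
    return make_stat_set(seed=11)


@pytest.fixture(scope="session")
def default_weights(default_stat_set) -> pd.DataFrame:
    return default_stat_set.snps[["rsid", "maf", "beta_exp"]].rename(
        columns={"beta_exp": "beta"})


@pytest.fixture(scope="session")
def small_cohort(default_weights) -> pd.DataFrame:
    cfg = CohortConfig(n_subjects=4000, seed=5)
    return generate_cohort(cfg, default_weights)
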