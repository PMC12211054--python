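import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Small synthetic cohort shared across module tests."""
    from hepmicro import synthetic_data as sd

    cfg = sd.SimConfig(
        seed=42,
        samples_per_stage={s: 12 for s in sd.STAGES},
        n_genes=200,
        n_taxa=80,
        n_contaminants=16,
        n_de_genes=20,
        n_diff_taxa=8,
        n_interactions=5,
    )
    expr, abund, meta, truth = sd.simulate_expression_and_profile(cfg)
    return cfg, expr, abund, meta, truth


@pytest.fixture(scope="session")
def taxon_reports():
    from hepmicro import synthetic_data as sd

    cfg = sd.SimConfig(
        seed=7,
        samples_per_stage={s: 8 for s in sd.STAGES},
        n_taxa=80,
        n_contaminants=16,
        n_genes=50,
    )
    reports, meta, truth = sd.simulate_taxon_reports(cfg)
    return cfg, reports, meta, truth
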