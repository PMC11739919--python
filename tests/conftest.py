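"""Shared fixtures: small synthetic cohorts reused across test modules."""

import numpy as np
import pytest

from episcope.containers import CORRECTED_M
from episcope.preprocess import beta_to_m, precorrect_m_values, residualize_trait
from episcope.synthdata import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def bundle_small():
    """Confounded cohort: 500 samples x 1,500 CpGs, 25 causal CpGs."""
    cfg = SimConfig(
        n_samples=500, n_cpgs=1500, n_blocks=75, n_causal=25,
        target_variance_explained=0.4, seed=42,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def corrected_small(bundle_small):
    m = beta_to_m(bundle_small.methylation)
    return precorrect_m_values(m, bundle_small.phenotypes[["age", "sex", "batch"]])


@pytest.fixture(scope="session")
def resid_small(bundle_small):
    return residualize_trait(bundle_small.phenotypes, "trait", bundle_small.kinship)


@pytest.fixture(scope="session")
def bundle_plain():
    """Clean cohort (no confounding, independent CpGs): recovery oracles."""
    cfg = SimConfig.plain(
        n_samples=1000, n_cpgs=2000, n_blocks=2000, n_causal=20,
        target_variance_explained=0.4, seed=7,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def plain_m(bundle_plain):
    m = beta_to_m(bundle_plain.methylation)
    m.scale = CORRECTED_M  # clean design: correction would only remove noise df
    return m


@pytest.fixture(scope="session")
def resid_plain(bundle_plain):
    return residualize_trait(bundle_plain.phenotypes, "trait", bundle_plain.kinship)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
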