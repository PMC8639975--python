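import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sensigen import synthio

settings.register_profile(
    "ci",
    max_examples=25,
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_bundle():
    """One small full-featured cohort shared by read-only tests."""
    return synthio.simulate_cohort(synthio.small_config(seed=11))


@pytest.fixture(scope="session")
def triad_bundle():
    """Expression-signature substudy cohort (~47 usable subjects)."""
    return synthio.simulate_cohort(synthio.triad_study_config(seed=11))


def null_config(**overrides):
    """Generator configuration with every planted effect switched off,
    so the training response is i.i.d. Gaussian noise."""
    base = dict(
        n_families=30, offspring_per_family=(1, 2), n_snps=25, n_ld_blocks=5,
        n_genes=45, signature_genes=("G0001", "G0002", "G0003"),
        signature_coefficients=(0.0,) * 6, family_icc_delta=0.0,
        baseline_to_delta_slope=0.0, trait_latent_sd=0.0,
        expression_coupling=0.0, n_coupled_genes=0,
        covariate_effect_sizes={}, n_gene_sets=10,
    )
    base.update(overrides)
    return synthio.SimulationConfig(**base)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
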