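"""Shared fixtures: small synthetic cohorts generated at test time."""

import pytest

from popvar import simulate as sim


def balanced_probs():
    """Equal mass on the three quality classes in every MAF bin."""
    third = 1.0 / 3.0
    return tuple(
        {"true_poly_good": third, "true_poly_noisy": third, "monomorphic_smear": third}
        for _ in range(8)
    )


@pytest.fixture(scope="session")
def small_config():
    return sim.SimConfig(
        master_seed=7,
        n_samples=4000,
        n_variants=36,
        n_batches=8,
        maf_range=(2e-3, 1e-2),
        quality_class_probs=balanced_probs(),
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return sim.simulate_cohort(small_config)
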