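import numpy as np
import pytest

from vocfinger.faims import build_feature_matrix
from vocfinger.io_formats import GroupLabel
from vocfinger.synthetic import CohortConfig, generate_cohort


def equal_arm_config(n=8, **kwargs):
    kwargs.setdefault("seed", 0)
    return CohortConfig(n_per_group={g: n for g in GroupLabel}, **kwargs)


@pytest.fixture(scope="session")
def separable_cohort():
    """Small, strongly separated cohort (effect 3, nearly noiseless)."""
    return generate_cohort(
        equal_arm_config(6, effect_size=3.0, noise_sd=0.01, seed=42)
    )


@pytest.fixture(scope="session")
def separable_features(separable_cohort):
    labels = [g.value for _, g in separable_cohort.manifest]
    scans = [separable_cohort.faims_scans[s] for s, _ in separable_cohort.manifest]
    return build_feature_matrix(scans), labels


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no group signal at all."""
    return generate_cohort(
        equal_arm_config(8, effect_size=0.0, noise_sd=0.5, seed=7)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
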