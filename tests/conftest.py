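import pytest

from adhdtree.cohort_io import load_atlas
from adhdtree.synthetic_cohort import (
    GroupSpec,
    PlantedEffect,
    SimulationConfig,
    generate_cohort,
)


def balanced_groups(n_train_per_class=30, n_test_per_class=15, f_frac=0.5):
    def spec(n, age, iq):
        return GroupSpec(n, age[0], age[1], iq[0], iq[1], round(f_frac * n))

    return {
        ("TD", "training"): spec(n_train_per_class, (12.1, 3.1), (110.8, 13.8)),
        ("ADHD", "training"): spec(n_train_per_class, (11.3, 2.7), (107.0, 13.3)),
        ("TD", "test"): spec(n_test_per_class, (11.8, 3.0), (114.0, 13.4)),
        ("ADHD", "test"): spec(n_test_per_class, (10.3, 2.5), (103.3, 13.2)),
    }


@pytest.fixture(scope="session")
def atlas():
    return load_atlas()


@pytest.fixture(scope="session")
def planted_config():
    """Small cohort with strong variance effects: one global, one gender-scoped."""
    return SimulationConfig(
        seed=123,
        groups=balanced_groups(),
        planted_effects=(
            PlantedEffect(40, "both", 4.0),
            PlantedEffect(88, "F", 4.0),
        ),
    )


@pytest.fixture(scope="session")
def planted_train(planted_config):
    return generate_cohort(planted_config, "training")


@pytest.fixture(scope="session")
def planted_test(planted_config):
    return generate_cohort(planted_config, "test")
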