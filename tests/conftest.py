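"""Shared fixtures: seeded synthetic cohorts reused across test modules."""

from dataclasses import replace

import pytest
from hypothesis import HealthCheck, settings

from mirscreen import preprocess, simulate

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    database=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def planted_cohort():
    """Full-size cohort (904 probes, 24 cases / 15 controls) with one up-
    and three down-regulated probes planted at 2 glog units."""
    cfg = replace(
        simulate.GeneratorConfig(), n_up=1, n_down=3, effect_size=2.0, seed=11
    )
    probe_set, raw = simulate.simulate_from_config(cfg, 24, 15)
    matrix = preprocess.preprocess_raw(raw)
    return probe_set, raw, matrix


@pytest.fixture(scope="session")
def null_matrix_small():
    """Effect-free small cohort (150 probes, 12 cases / 8 controls)."""
    cfg = replace(simulate.GeneratorConfig(), n_probes=150, seed=5)
    _, raw = simulate.simulate_from_config(cfg, 12, 8)
    return preprocess.preprocess_raw(raw)


@pytest.fixture(scope="session")
def separable_matrix_small():
    """Strongly separable small cohort: 20 probes planted at 3 glog units
    out of 150, 12 cases / 8 controls."""
    cfg = replace(
        simulate.GeneratorConfig(),
        n_probes=150,
        n_up=10,
        n_down=10,
        effect_size=3.0,
        seed=21,
    )
    _, raw = simulate.simulate_from_config(cfg, 12, 8)
    return preprocess.preprocess_raw(raw)
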