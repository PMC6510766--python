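from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from remi import FCClassSpec, SampleSpec, ScenarioConfig, TFSpec

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def small_scenario(
    n_elements: int = 2_000,
    factors: tuple[TFSpec, ...] | None = None,
    **overrides,
) -> ScenarioConfig:
    """A light scenario for unit tests: 2 x 5 Mb, one TN + one RR sample."""
    if factors is None:
        factors = (
            TFSpec("EZH2", 0.1),
            TFSpec("SUZ12", 0.1),
            TFSpec("TFX", 0.15),
            TFSpec("TFY", 0.05),
        )
    base = dict(
        genome=(("chr1", 5_000_000), ("chr2", 5_000_000)),
        n_elements=n_elements,
        n_genes=400,
        samples=(
            SampleSpec("N1", "TN", (0, 56)),
            SampleSpec("R1", "RR", (0, 56)),
        ),
        subgroup_mixture={1: 0.1, 2: 0.1, 3: 0.1, 4: 0.1, 5: 0.1, 6: 0.1, 7: 0.4},
        tf_catalogue=factors,
        fc_classes=(
            FCClassSpec("increased", 0.2, 1.0),
            FCClassSpec("decreased", 0.2, -1.0),
            FCClassSpec("stable", 0.6, 0.0),
        ),
        seed=0,
    )
    base.update(overrides)
    return ScenarioConfig(**base)
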