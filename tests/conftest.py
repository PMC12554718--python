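import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from seedgerm import PipelineConfig, analyze_image, synth

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")

#: study conditions for the synthetic recovery suites
N_DISHES = 20
BASE_SEED = 42


def _generate_and_analyze(touching: float):
    config = PipelineConfig(counting_mode="rounded")
    out = []
    for k in range(N_DISHES):
        spec = synth.SynthSpec(
            n_seeds=(30, 60),
            germination_fraction=0.6,
            touching_probability=touching,
            random_seed=BASE_SEED + k,
        )
        image, truth = synth.generate_dish(spec)
        analysis = analyze_image(image, config, image_id=truth.image_name)
        out.append((truth, analysis))
    return out


@pytest.fixture(scope="session")
def analyzed_dishes_nontouching():
    """20 analyzed dishes, 30-60 seeds each, no touching (seeds 42..61)."""
    return _generate_and_analyze(touching=0.0)


@pytest.fixture(scope="session")
def analyzed_dishes_touching():
    """20 analyzed dishes with touching probability 0.2 (seeds 42..61)."""
    return _generate_and_analyze(touching=0.2)


@pytest.fixture()
def small_dish():
    """A quick 10-seed dish on a smaller frame for unit tests."""
    spec = synth.SynthSpec(
        height=640, width=960, n_seeds=10, germination_fraction=0.6, random_seed=3
    )
    return synth.generate_dish(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
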