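import numpy as np
import pytest

from epistage.graphs import GraphSample, complete_adjacency
from epistage.synthetic import GeneratorConfig, generate_recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def short_recordings():
    """One short surrogate recording per stage (10 s, 8 ch, 1 kHz)."""
    cfg = GeneratorConfig(duration=10.0, seed=7)
    return {
        stage: generate_recording(stage, cfg)
        for stage in ("normal", "acute", "chronic")
    }


def make_toy_samples(n_per_class=60, offset=3.0, noise=0.1, seed=0):
    """Trivially separable graph samples: class mean shifts much larger than noise."""
    rng = np.random.default_rng(seed)
    samples = []
    for label in range(3):
        for i in range(n_per_class):
            nf = rng.normal(size=(8, 5)) * noise + label * offset
            samples.append(
                GraphSample(complete_adjacency(), nf, label, "toy", i)
            )
    return samples
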