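import numpy as np
import pytest

from cmaf import PipelineParams, SyntheticSpec, generate


@pytest.fixture(scope="session")
def small_instance():
    """Planted-structure instance small enough for per-test pipeline runs."""
    spec = SyntheticSpec(m=20, n=14, r=3, density=0.18, similarity_noise=0.1, seed=7)
    return generate(spec)


@pytest.fixture(scope="session")
def pipeline_params():
    return PipelineParams.with_seed(7)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
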