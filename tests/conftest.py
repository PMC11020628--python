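import numpy as np
import pytest

from ltrscout import pipeline, repeat_profile
from ltrscout.synthetic_data import PlantSpec, demo_genome, generate_genome


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)




@pytest.fixture(scope="session")
def small_truth():
    """Five zero/low-divergence singles plus a solo, ~300 kb."""
    specs = [
        PlantSpec("famA", ltr_length=400, internal_length=1500,
                  ltr_divergence=0.02, family_divergence=0.02, copy_number=5),
        PlantSpec("famA", kind="solo_ltr", ltr_length=400, gap_before=(3000, 6000)),
    ]
    return generate_genome(specs, 300_000, seed=7)


@pytest.fixture(scope="session")
def small_profile(small_truth):
    return repeat_profile.train(small_truth.genome)


@pytest.fixture(scope="session")
def default_model():
    return pipeline.default_model()


@pytest.fixture(scope="session")
def demo_truth():
    return demo_genome(seed=1)


@pytest.fixture(scope="session")
def demo_detection(demo_truth):
    return pipeline.detect(demo_truth.genome)
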