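import numpy as np
import pytest

from microbeid.synthetic import (
    ImageSpec,
    TableSpec,
    generate_feature_table,
    generate_microbe_image,
)


@pytest.fixture(scope="session")
def ovoid_fixture():
    spec = ImageSpec(archetype="ovoid", count=3, size_px=60, seed=11)
    img, mask = generate_microbe_image(spec)
    return img, mask, spec


@pytest.fixture(scope="session")
def separable_table():
    """Widely separated 3-class table: trivially classifiable."""
    spec = TableSpec(
        class_names=("a", "b", "c"),
        n_per_class=(40, 40, 40),
        informative_dim=4,
        noise_dim=2,
        separable=True,
        seed=5,
    )
    return generate_feature_table(spec), spec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
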