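import numpy as np
import pytest

from punctapolarity import FieldSpec, ReferenceField, generate_field


@pytest.fixture(scope="session")
def biased_field():
    """A strongly midline-biased synthetic field, shared across read-only tests."""
    spec = FieldSpec(n_cells=60, bias_kappa=4.0, seed=42)
    image, mask, truth = generate_field(spec, ReferenceField.fixed(0.0))
    return spec, image, mask, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
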