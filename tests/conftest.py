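import numpy as np
import pytest

from denngap import ToyComplexSpec, make_toy_complex, read_structure


@pytest.fixture(scope="session")
def toy_complex():
    """Default planted-arginine fixture: (reference, predicted model)."""
    ref_text, model_text = make_toy_complex(ToyComplexSpec())
    return read_structure(ref_text), read_structure(model_text)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
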