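import numpy as np
import pytest

from predinfo.process_model import FormProcess


@pytest.fixture
def single_form_process() -> FormProcess:
    """The one-form language 'a': deterministic a#a#a#... cycle."""
    return FormProcess(forms=(("a",),), probs=np.array([1.0]))


@pytest.fixture
def two_bit_process() -> FormProcess:
    """Two equiprobable length-1 forms '0' and '1'."""
    return FormProcess(forms=(("0",), ("1",)), probs=np.array([0.5, 0.5]))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
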