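import numpy as np
import pytest

from dcetex import Lesion, PhantomSpec


@pytest.fixture
def small_spec() -> PhantomSpec:
    """A compact phantom (32x32x10) with one malignant and one benign lesion."""
    return PhantomSpec(
        shape=(32, 32, 10),
        lesions=(
            Lesion((12, 14, 5), (3, 3, 2), "malignant"),
            Lesion((20, 10, 4), (3, 3, 2), "benign"),
        ),
        seed=7,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
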