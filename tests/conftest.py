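import numpy as np
import pytest

from rymeralign.damage import DamageProfile, make_parametric_profile
from rymeralign.indexing import HaplotypePanel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def zero_profile():
    return make_parametric_profile("none")


@pytest.fixture
def high_profile():
    return make_parametric_profile("double_stranded_high")


@pytest.fixture
def small_panel(rng):
    seq = "".join(rng.choice(list("ACGT"), size=2000))
    return HaplotypePanel([("hap0", seq, False)])


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))
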