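import numpy as np
import pytest

from chondroclock import build_jtt


@pytest.fixture(scope="session")
def jtt():
    """Plain JTT+Gamma4 model shared across tests."""
    return build_jtt(alpha=0.8)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_aa(rng, n: int) -> str:
    from chondroclock.models import JTT_ORDER

    return "".join(rng.choice(list(JTT_ORDER), size=n))
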