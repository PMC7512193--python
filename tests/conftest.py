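import numpy as np
import pytest

from thermodecide import ActionSpace, Policy, UtilityEpoch, UtilityProtocol


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def random_instance(rng, n_actions=None, n_epochs=None, beta=None):
    """A random discrete protocol instance: (space, prior, protocol, beta)."""
    n = n_actions or int(rng.integers(2, 6))
    m = n_epochs or int(rng.integers(2, 5))
    space = ActionSpace(range(n))
    w = rng.dirichlet(np.ones(n))
    prior = Policy.from_probs(space, w)
    protocol = UtilityProtocol(space, [rng.uniform(-1, 1, size=n) for _ in range(m)])
    b = beta if beta is not None else float(rng.uniform(0.3, 3.0))
    return space, prior, protocol, b


@pytest.fixture
def two_action():
    """Uniform prior on two actions with dU = (1, 0): the closed-form workhorse."""
    space = ActionSpace(["a", "b"])
    return space, Policy.uniform(space), UtilityEpoch(np.array([1.0, 0.0]))
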