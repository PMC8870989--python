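import numpy as np
import pytest

from rkhsda import KernelSpec, ShiftScenario, combine, compute_gram, generate_shifted_gaussians


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_bundle(rng, Ns=18, Nt=12, D=4, C=3):
    """Small labeled two-domain problem with no particular structure."""
    Xs = rng.standard_normal((Ns, D))
    Xt = rng.standard_normal((Nt, D)) + 0.5
    ys = rng.integers(1, C + 1, size=Ns)
    # guarantee every class occupied
    ys[:C] = np.arange(1, C + 1)
    return combine(Xs, ys, Xt)


@pytest.fixture
def bundle(rng):
    return random_bundle(rng)


@pytest.fixture
def gram(bundle):
    return compute_gram(bundle.X, KernelSpec("rbf", 1.5))


@pytest.fixture
def shift_problem():
    return generate_shifted_gaussians(ShiftScenario(seed=7))
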