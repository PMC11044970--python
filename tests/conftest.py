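import numpy as np
import pytest

from mopcv.deeptda import StateDataset, TDATargets, TrainingConfig, train_cv
from mopcv.potentials import MullerBrown, ThermoParams


@pytest.fixture(scope="session")
def mb():
    return MullerBrown()


@pytest.fixture(scope="session")
def thermo():
    return ThermoParams(temperature=0.1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


class ZeroPotential:
    """Free particle in 2D."""

    dim = 2

    def energy(self, p):
        return np.zeros(np.asarray(p, dtype=float).shape[:-1])

    def gradient(self, p):
        return np.zeros_like(np.asarray(p, dtype=float))

    def hessian(self, p):
        shape = np.asarray(p, dtype=float).shape[:-1]
        return np.zeros(shape + (2, 2))

    def force(self, p):
        return -self.gradient(p)

    def derivs(self, p):
        return self.energy(p), self.gradient(p), self.hessian(p)


@pytest.fixture(scope="session")
def zero_potential():
    return ZeroPotential()


@pytest.fixture(scope="session")
def two_cluster_cv():
    """A 2-state CV trained on well-separated planted Gaussian clusters."""
    gen = np.random.default_rng(42)
    X = np.concatenate([gen.normal([-1.0, 0.0], 0.05, (400, 2)),
                        gen.normal([1.0, 1.0], 0.05, (400, 2))])
    y = np.repeat([0, 1], 400)
    model = train_cv(StateDataset(X, y), TDATargets.two_state(),
                     TrainingConfig(seed=5, max_epochs=600))
    return model
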