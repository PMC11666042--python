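import numpy as np
import pytest

from pinnode.normalization import NormalizationSpec
from pinnode.simulate import ObservationSet, integrate
from pinnode.systems import ODESystem, ParamSpec, lorenz_system, mosquito_system


def exponential_system(rate: float = 1.0) -> ODESystem:
    """du/dt = -rate * u: the 1-D desk-scale benchmark with closed form."""
    return ODESystem(
        "expdecay", 1,
        rhs=lambda t, u, th: -rate * u,
        jac_state=lambda t, u, th: np.full((u.shape[0], 1, 1), -rate),
        state_names=["u"],
    )


def exponential_inverse_system(rate: float = 0.5) -> ODESystem:
    """du/dt = -theta u with theta unknown (learnable constant)."""
    return ODESystem(
        "expdecay_inverse", 1,
        rhs=lambda t, u, th: -th[:, [0]] * u,
        jac_state=lambda t, u, th: -th[:, 0].reshape(-1, 1, 1),
        param_spec=[ParamSpec("theta", "learn_constant", rate, bounds=(0.0, 2.0))],
        state_names=["u"],
    )


def rotation_system() -> ODESystem:
    """du/dt = A u with A = [[0, 1], [-1, 0]]: circular rotation."""
    A = np.array([[0.0, 1.0], [-1.0, 0.0]])
    return ODESystem(
        "rotation", 2,
        rhs=lambda t, u, th: u @ A.T,
        jac_state=lambda t, u, th: np.broadcast_to(A, (u.shape[0], 2, 2)).copy(),
    )


@pytest.fixture(scope="session")
def exp_system():
    return exponential_system()


@pytest.fixture(scope="session")
def exp_spec():
    # state bounds from the closed form e^-t on [0, 2]
    return NormalizationSpec(0.0, 2.0, [np.exp(-2.0)], [1.0])


@pytest.fixture(scope="session")
def exp_initial_obs():
    return ObservationSet([0.0], [[1.0]])


@pytest.fixture(scope="session")
def lorenz():
    return lorenz_system()


@pytest.fixture(scope="session")
def lorenz_truth_t2(lorenz):
    return integrate(lorenz, [1.0, 1.0, 1.0], (0.0, 2.0), np.linspace(0, 2, 401))


@pytest.fixture(scope="session")
def mosquito():
    return mosquito_system()


@pytest.fixture(scope="session")
def mosquito_truth_1y(mosquito):
    u0 = np.array([1e4, 1e3, 1e2, 10.0, 10.0, 10.0, 10.0, 0.0, 0.0, 0.0])
    return integrate(mosquito, u0, (0.0, 365.0), np.linspace(0, 365, 366),
                     rtol=1e-8, atol=1e-8)


# desk-scale training configuration shared by the convergence tests
DESK_NET = dict(n_hidden_layers=3, width=32)
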