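"""Shared fixtures: the benchmark models and their (expensive) steady solves
are computed once per session and reused across test modules."""

import numpy as np
import pytest
from hypothesis import settings as _hsettings

_hsettings.register_profile("deterministic", derandomize=True, deadline=None)
_hsettings.load_profile("deterministic")

from eldscape import EnergyLandscape, make_example1, make_example2
from eldscape import fpe2d
from eldscape.models import Box, DifferentiationModel, PolynomialRate


@pytest.fixture(scope="session")
def ex1():
    return make_example1()


@pytest.fixture(scope="session")
def ou_model():
    """2-D Ornstein-Uhlenbeck: linear drift -x, no birth-death."""
    return DifferentiationModel(
        name="ou",
        dim=2,
        drift=lambda x: -np.asarray(x, dtype=float),
        rate=lambda x: np.zeros(np.asarray(x).shape[:-1]),
        epsilon=0.01,
        domain=Box((-1.0, -1.0), (1.0, 1.0)),
        jacobian=lambda x: -np.eye(2),
        hessian=lambda x: np.zeros((2, 2, 2)),
    )


@pytest.fixture(scope="session")
def gen_ou_model():
    """Linear drift with a quadratic death rate: the steady density and the
    growth rate have closed forms (Gaussian with modified variance)."""
    kappa = 5.0
    rate = PolynomialRate([(-kappa, (2, 0)), (-kappa, (0, 2))], dim=2)
    m = DifferentiationModel(
        name="gen_ou",
        dim=2,
        drift=lambda x: -np.asarray(x, dtype=float),
        rate=rate,
        epsilon=0.01,
        domain=Box((-1.0, -1.0), (1.0, 1.0)),
        jacobian=lambda x: -np.eye(2),
        hessian=lambda x: np.zeros((2, 2, 2)),
    )
    m.metadata["kappa"] = kappa
    return m


@pytest.fixture(scope="session")
def ex1_result():
    """Full PDE decomposition of the triple-well benchmark (201^2)."""
    return EnergyLandscape("example1").fit()


@pytest.fixture(scope="session")
def ex1_r0_result():
    """Same benchmark with the birth-death rate switched off."""
    return EnergyLandscape(make_example1().zero_rate()).fit()


@pytest.fixture(scope="session")
def ex2_r0_result():
    return EnergyLandscape(make_example2(0.0)).fit()


@pytest.fixture(scope="session")
def ex2_r30_result():
    return EnergyLandscape(make_example2(30.0)).fit()


@pytest.fixture(scope="session")
def ex1_grid(ex1):
    return fpe2d.build_grid(ex1, 201, 201)


@pytest.fixture(scope="session")
def stable_points_ex1(ex1):
    from eldscape import mfa

    fps = mfa.find_fixed_points(ex1, seed=0)
    return [fp for fp in fps if fp.stability == "stable"]


def tcell_synthetic_spec():
    """Synthetic four-gene cascade fixture: an upstream toggle (same kinetics
    class as the two-gene benchmark) driving two downstream genes, plus a
    quadratic rate favoring the first lineage.  The parameter values are this
    package's own choice (synthetic), not taken from any published network.
    """
    return {
        "genes": ["g1", "g2", "g3", "g4"],
        "degradation": [1.0, 1.0, 1.0, 1.0],
        "terms": [
            {"target": 0, "source": 0, "type": "activation", "amplitude": 0.3,
             "threshold": 0.5, "hill": 4},
            {"target": 1, "source": 1, "type": "activation", "amplitude": 0.3,
             "threshold": 0.5, "hill": 4},
            {"target": 0, "source": 1, "type": "inhibition", "amplitude": 0.5,
             "threshold": 0.5, "hill": 4},
            {"target": 1, "source": 0, "type": "inhibition", "amplitude": 0.5,
             "threshold": 0.5, "hill": 4},
            {"target": 2, "source": 0, "type": "activation", "amplitude": 0.6,
             "threshold": 0.5, "hill": 2},
            {"target": 3, "source": 2, "type": "activation", "amplitude": 0.6,
             "threshold": 0.5, "hill": 2},
            {"target": 3, "source": 1, "type": "inhibition", "amplitude": 0.3,
             "threshold": 0.5, "hill": 2},
        ],
        "rate": {"dim": 4, "terms": [
            {"coeff": -1.0, "powers": [2, 0, 0, 0]},
            {"coeff": 2.4, "powers": [1, 0, 0, 0]},
            {"coeff": -1.0, "powers": [0, 2, 0, 0]},
            {"coeff": -1.04, "powers": [0, 0, 0, 0]},
        ]},
    }
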