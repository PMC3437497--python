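import numpy as np
import pytest

from scfc.connectome import modular_sc, normalize_rows
from scfc.node_model import NodeParams

# the three reference parameter points on the bifurcation diagram:
# a and c lie where the synchronous state is unstable (H'(0) < 0),
# b where it is stable (H'(0) > 0)
POINT_A = (-2.5, -8.5)
POINT_B = (-1.5, -6.0)
POINT_C = (2.5, -3.5)


@pytest.fixture(scope="session")
def params_b() -> NodeParams:
    return NodeParams(P=POINT_B[0], Q=POINT_B[1])


@pytest.fixture(scope="session")
def two_node_sc():
    """Reciprocally connected pair, row-normalized."""
    return normalize_rows(np.array([[0, 1], [1, 0]]), label="pair")


@pytest.fixture(scope="session")
def modular_3x4():
    return modular_sc(3, 4)


@pytest.fixture(scope="session")
def limit_cycle_b(params_b):
    """Precision limit cycle at point b, shared across tests."""
    from scfc.phase_reduction import find_limit_cycle

    return find_limit_cycle(params_b)


@pytest.fixture(scope="session")
def adjoint_b(limit_cycle_b):
    from scfc.phase_reduction import adjoint

    return adjoint(limit_cycle_b)
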