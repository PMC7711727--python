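import numpy as np
import pytest

from fracldg.elements import Element, shifted_legendre_eval
from fracldg.solver import ProblemSpec


@pytest.fixture
def linear_benchmark() -> ProblemSpec:
    """Classical Malthusian benchmark: D^1 X = X, X(0) = 0.75 on [0, 2]."""
    return ProblemSpec(nu=1.0, sigma=1.0, x0=0.75, T=2.0, model="linear")


@pytest.fixture
def logistic_benchmark() -> ProblemSpec:
    """Classical logistic benchmark: D^1 X = X(1-X)/2, X(0) = 0.5 on [0, 1]."""
    return ProblemSpec(nu=1.0, sigma=0.5, x0=0.5, T=1.0, model="logistic")


def gauss_inner_product(f, g, element: Element, n_nodes: int = 40) -> float:
    """Dense Gauss-Legendre oracle for element inner products <f, g>_l."""
    s, w = np.polynomial.legendre.leggauss(n_nodes)
    ts = 0.5 * (element.left + element.right) + 0.5 * element.length * s
    return 0.5 * element.length * float(
        np.sum(w * np.array([f(t) * g(t) for t in ts]))
    )


def basis(i: int, element: Element):
    return lambda t: shifted_legendre_eval(i, element, t)
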