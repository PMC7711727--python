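"""Baseline fractional-ODE integrators: Adams-Bashforth-Moulton PECE and L1.

Both schemes integrate the scalar Caputo initial-value problem
``D^nu X = f(t, X)``, ``X(0) = x0`` on a uniform grid and serve as
comparison baselines for the LDG solver.  ``f`` is derived from the same
:class:`~fracldg.solver.ProblemSpec`: ``sigma**nu * X`` for the linear
growth model, ``sigma * X * (1 - X)`` for the logistic model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .solver import ConvergenceError, ProblemSpec

__all__ = ["Trajectory", "pece_abm", "l1_scheme"]


@dataclass(frozen=True)
class Trajectory:
    """Uniform-grid solution samples ``X_n`` at ``t_n = n h``."""

    times: np.ndarray
    values: np.ndarray

    @property
    def final_value(self) -> float:
        return float(self.values[-1])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"t": self.times, "X": self.values})


def _rhs(problem: ProblemSpec) -> Callable[[float, float], float]:
    if problem.model == "linear":
        lam = problem.rate
        return lambda t, x: lam * x
    sigma = problem.sigma
    return lambda t, x: sigma * x * (1.0 - x)


def pece_abm(problem: ProblemSpec, N: int) -> Trajectory:
    """Fractional Adams-Bashforth-Moulton predictor-corrector (PECE).

    One-step-memory-free form with the standard product-quadrature weights:
    the predictor uses the product-rectangle rule,

    ``X^P_{n+1} = x0 + (1/Gamma(nu)) * sum_{j<=n} b_{j,n+1} f_j``,
    ``b_{j,n+1} = (h^nu/nu) * ((n+1-j)^nu - (n-j)^nu)``,

    and a single corrector application uses the product-trapezoidal rule,

    ``X_{n+1} = x0 + (h^nu/Gamma(nu+2)) * (f(t_{n+1}, X^P) + sum_j a_{j,n+1} f_j)``

    with ``a_{0,n+1} = n^(nu+1) - (n-nu)(n+1)^nu`` and
    ``a_{j,n+1} = (n-j+2)^(nu+1) + (n-j)^(nu+1) - 2(n-j+1)^(nu+1)``.
    Exactly one correction per step (PECE, not PE(CE)^m).  At ``nu = 1``
    the weights collapse and the scheme is the classical one-step
    rectangle-predictor / trapezoid-corrector method.

    The full-memory sums cost O(N^2) overall, fine at desk scale.
    """
    if N < 1:
        raise ValueError(f"step count must be >= 1, got N={N}")
    nu = problem.nu
    f = _rhs(problem)
    h = problem.T / N
    t = np.arange(N + 1) * h
    x = np.empty(N + 1)
    x[0] = problem.x0
    fvals = np.empty(N + 1)
    fvals[0] = f(t[0], x[0])
    h_nu = h**nu
    c_pred = h_nu / (nu * math.gamma(nu))      # = h^nu / Gamma(nu+1)
    c_corr = h_nu / math.gamma(nu + 2)

    for n in range(N):
        j = np.arange(n + 1)
        b_w = (n + 1 - j) ** nu - (n - j) ** nu
        x_pred = x[0] + c_pred * float(b_w @ fvals[: n + 1])

        a_w = np.empty(n + 1)
        a_w[0] = n ** (nu + 1) - (n - nu) * (n + 1) ** nu
        if n >= 1:
            jj = np.arange(1, n + 1)
            a_w[1:] = (
                (n - jj + 2) ** (nu + 1)
                + (n - jj) ** (nu + 1)
                - 2.0 * (n - jj + 1) ** (nu + 1)
            )
        x[n + 1] = x[0] + c_corr * (
            f(t[n + 1], x_pred) + float(a_w @ fvals[: n + 1])
        )
        fvals[n + 1] = f(t[n + 1], x[n + 1])
    return Trajectory(times=t, values=x)


def l1_scheme(
    problem: ProblemSpec,
    N: int,
    treatment: str = "implicit",
    newton_tol: float = 1e-14,
    newton_max_iter: int = 50,
) -> Trajectory:
    """L1 scheme for the Caputo derivative.

    The derivative at ``t_{n+1}`` is replaced by the piecewise-linear
    product quadrature

    ``(h^-nu / Gamma(2-nu)) * sum_{k<=n} w_{n,k} (X_{k+1} - X_k) = f(t_*, X_*)``

    with ``w_{n,k} = (n+1-k)^(1-nu) - (n-k)^(1-nu)`` (``w_{n,n} = 1``).

    ``treatment`` picks where the right-hand side is evaluated:

    * ``"implicit"`` — ``f(t_{n+1}, X_{n+1})``; each step is solved in
      closed form for linear ``f`` and by scalar Newton (warm-started from
      the previous value) otherwise.  At ``nu = 1`` this is backward Euler.
    * ``"explicit"`` — ``f(t_n, X_n)``; each step is a direct update.  At
      ``nu = 1`` this is forward Euler.  This variant is the one that
      reproduces the published L1 benchmark column for the linear model
      (the implicit variant is noticeably more accurate at the same step).
    """
    if N < 1:
        raise ValueError(f"step count must be >= 1, got N={N}")
    if treatment not in ("implicit", "explicit"):
        raise ValueError(
            f"treatment must be 'implicit' or 'explicit', got {treatment!r}"
        )
    nu = problem.nu
    h = problem.T / N
    t = np.arange(N + 1) * h
    x = np.empty(N + 1)
    x[0] = problem.x0
    c = h ** (-nu) / math.gamma(2.0 - nu)
    linear = problem.model == "linear"
    lam = problem.rate
    sigma = problem.sigma
    f = _rhs(problem)

    for n in range(N):
        k = np.arange(n + 1)
        w = (n + 1 - k) ** (1.0 - nu) - (n - k) ** (1.0 - nu)
        # memory part: c * sum_{k<n} w_k (x_{k+1} - x_k); w_{n,n} is exactly 1
        mem = c * float(w[:-1] @ np.diff(x[: n + 1])) if n >= 1 else 0.0
        rhs_const = mem - c * x[n]  # so lhs = c*x_{n+1} + rhs_const
        if treatment == "explicit":
            x[n + 1] = x[n] + (f(t[n], x[n]) - mem) / c
        elif linear:
            denom = c - lam
            if denom == 0.0:
                raise ConvergenceError("L1 linear step is singular: c == rate")
            x[n + 1] = (c * x[n] - mem) / denom
        else:
            xn1 = x[n]
            for _ in range(newton_max_iter):
                g = c * xn1 + rhs_const - sigma * xn1 * (1.0 - xn1)
                if abs(g) < newton_tol:
                    break
                dg = c - sigma * (1.0 - 2.0 * xn1)
                xn1 -= g / dg
            else:
                raise ConvergenceError(
                    f"L1 Newton failed at step {n + 1}: residual {g:.3e}"
                )
            x[n + 1] = xn1
    return Trajectory(times=t, values=x)
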