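"""Shifted Legendre element bases and per-element operator matrices.

The discontinuous Galerkin discretisation works element by element on a
partition ``0 = t_0 < t_1 < ... < t_J = T``.  On each element the trial and
test space is spanned by Legendre polynomials mapped through the affine
change of variable ``s = (2t - t_{l-1} - t_l) / h_l`` onto [-1, 1], so that
``L_i(t_l) = 1`` and ``L_i(t_{l-1}) = (-1)^i``.

This module provides the basis evaluation (stable three-term recurrence),
its monomial representation (needed for term-wise fractional integration),
and all the per-element operators of the local algebraic system: the
diagonal mass matrix M, the stiffness matrix S, the all-ones flux matrix E
and flux load vector b, the fractional matrix D discretising the
Riemann-Liouville integral of order ``1 - nu``, and the triple-product
tensor used by the direct-computation nonlinear term.

Matrix convention: the TEST index is always the row index, so e.g.
``S[j, i] = <L_i, L_j'>`` on the element.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import mpmath
import numpy as np

__all__ = [
    "MAX_DEGREE",
    "Mesh",
    "Element",
    "MonomialRep",
    "ElementOperators",
    "shifted_legendre_eval",
    "monomial_coefficients",
    "mass_matrix",
    "stiffness_matrix",
    "flux_operators",
    "fractional_matrix",
    "triple_product_tensor",
    "build_element_operators",
]

#: Hard cap on the polynomial degree; the monomial representation used for
#: fractional integration is too ill-conditioned beyond this.
MAX_DEGREE = 12

#: Decimal digits used for extended-precision fractional-matrix assembly.
_FRAC_DPS = 50


@dataclass(frozen=True)
class Element:
    """One mesh element ``(t_{l-1}, t_l)``; ``index`` is 1-based."""

    index: int
    left: float
    right: float

    def __post_init__(self) -> None:
        if not self.right > self.left:
            raise ValueError(
                f"element {self.index}: right node {self.right} must exceed "
                f"left node {self.left}"
            )

    @property
    def length(self) -> float:
        return self.right - self.left

    def to_reference(self, t: float) -> float:
        """Map element time ``t`` to the reference coordinate ``s in [-1, 1]``."""
        return (2.0 * t - self.left - self.right) / self.length

    def contains(self, t: float, rtol: float = 1e-12) -> bool:
        pad = rtol * max(1.0, abs(self.right))
        return self.left - pad <= t <= self.right + pad


@dataclass(frozen=True)
class Mesh:
    """Partition of ``[0, T]`` into elements.

    ``nodes`` must be strictly increasing with ``nodes[0] == 0``.  Elements
    are 1-based to match the usual finite-element numbering.
    """

    nodes: tuple[float, ...]

    def __post_init__(self) -> None:
        nodes = tuple(float(t) for t in self.nodes)
        object.__setattr__(self, "nodes", nodes)
        if len(nodes) < 2:
            raise ValueError("mesh needs at least two nodes")
        if nodes[0] != 0.0:
            raise ValueError(f"mesh must start at t=0, got {nodes[0]}")
        if any(b <= a for a, b in zip(nodes, nodes[1:])):
            raise ValueError("mesh nodes must be strictly increasing")

    @classmethod
    def uniform(cls, T: float, J: int) -> "Mesh":
        if T <= 0:
            raise ValueError(f"horizon must be positive, got T={T}")
        if J < 1:
            raise ValueError(f"element count must be >= 1, got J={J}")
        return cls(tuple(T * l / J for l in range(J + 1)))

    @property
    def n_elements(self) -> int:
        return len(self.nodes) - 1

    @property
    def span(self) -> float:
        return self.nodes[-1]

    @property
    def max_length(self) -> float:
        return max(b - a for a, b in zip(self.nodes, self.nodes[1:]))

    def element(self, l: int) -> Element:
        """Return element ``l`` (1-based)."""
        if not 1 <= l <= self.n_elements:
            raise IndexError(f"element index {l} outside 1..{self.n_elements}")
        return Element(l, self.nodes[l - 1], self.nodes[l])

    def elements(self) -> list[Element]:
        return [self.element(l) for l in range(1, self.n_elements + 1)]

    def locate(self, t: float, side: str = "left") -> Element:
        """Element containing ``t``; at interior nodes ``side`` disambiguates.

        ``side='left'`` returns the element ending at ``t`` (the one-sided
        limit from below), ``side='right'`` the element starting at ``t``.
        """
        if side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {side!r}")
        if not 0.0 <= t <= self.span * (1 + 1e-12):
            raise ValueError(f"t={t} outside [0, {self.span}]")
        nodes = self.nodes
        for l in range(1, self.n_elements + 1):
            if nodes[l - 1] < t < nodes[l]:
                return self.element(l)
        # t coincides with a node
        for l, node in enumerate(nodes):
            if math.isclose(t, node, rel_tol=1e-12, abs_tol=1e-14):
                if l == 0:
                    return self.element(1)
                if l == self.n_elements:
                    return self.element(self.n_elements)
                return self.element(l if side == "left" else l + 1)
        return self.element(self.n_elements)


def shifted_legendre_eval(i: int, element: Element, t: float) -> float:
    """Evaluate the degree-``i`` shifted Legendre basis at ``t`` in the element.

    Uses the Bonnet three-term recurrence on the mapped coordinate, which is
    numerically stable for all degrees handled here.
    """
    if i < 0:
        raise ValueError(f"degree index must be >= 0, got {i}")
    if not element.contains(t):
        raise ValueError(
            f"t={t} outside element {element.index} = "
            f"[{element.left}, {element.right}]"
        )
    s = element.to_reference(t)
    return _legendre_recurrence(i, s)


def _legendre_recurrence(i: int, s: float) -> float:
    if i == 0:
        return 1.0
    p_prev, p = 1.0, s
    for n in range(1, i):
        p_prev, p = p, ((2 * n + 1) * s * p - n * p_prev) / (n + 1)
    return p


@lru_cache(maxsize=None)
def _legendre_monomial_rows(i: int) -> tuple[tuple[float, ...], ...]:
    """Rows 0..i of Legendre coefficients in powers of s (exact rationals cast
    to float); row n has length n+1."""
    from fractions import Fraction

    rows = [[Fraction(1)], [Fraction(0), Fraction(1)]]
    for n in range(1, i):
        a = [Fraction(0)] + rows[n]  # s * P_n
        new = [
            (Fraction(2 * n + 1, n + 1)) * a[m]
            - (Fraction(n, n + 1)) * (rows[n - 1][m] if m < len(rows[n - 1]) else 0)
            for m in range(n + 2)
        ]
        rows.append(new)
    return tuple(tuple(rows[n]) for n in range(i + 1))


@dataclass(frozen=True)
class MonomialRep:
    """Monomial form of a shifted Legendre basis function.

    ``coeffs[m]`` multiplies ``t^m`` in the global time variable.  Used only
    where the fractional integral must be applied term by term; evaluation
    elsewhere goes through the recurrence.
    """

    degree: int
    element: Element
    coeffs: tuple[float, ...]

    def __call__(self, t: float) -> float:
        return float(sum(c * t**m for m, c in enumerate(self.coeffs)))


def _monomial_coeffs_generic(i: int, a, b, one):
    """Coefficients of P_i((2t - a - b)/(b - a)) in powers of t.

    ``one`` fixes the arithmetic (Fraction/mpf/float); a, b are cast through
    multiplication with it.
    """
    if i > MAX_DEGREE:
        raise ValueError(f"degree {i} exceeds the supported maximum {MAX_DEGREE}")
    h = (b - a) * one
    u = 2 * one / h          # s = u*t + v
    v = -(a + b) * one / h
    srow = _legendre_monomial_rows(i)[i]
    out = [0 * one for _ in range(i + 1)]
    for p, c in enumerate(srow):
        if c == 0:
            continue
        # (u t + v)^p expanded binomially
        for q in range(p + 1):
            out[q] += (c * one) * math.comb(p, q) * u**q * v ** (p - q)
    return out


def monomial_coefficients(i: int, element: Element) -> MonomialRep:
    """Monomial representation of the degree-``i`` basis on the element."""
    from fractions import Fraction

    try:
        a = Fraction(element.left).limit_denominator(10**12)
        b = Fraction(element.right).limit_denominator(10**12)
        coeffs = _monomial_coeffs_generic(i, a, b, Fraction(1))
        return MonomialRep(i, element, tuple(float(c) for c in coeffs))
    except (OverflowError, ValueError):
        coeffs = _monomial_coeffs_generic(i, element.left, element.right, 1.0)
        return MonomialRep(i, element, tuple(float(c) for c in coeffs))


def mass_matrix(r: int, element: Element) -> np.ndarray:
    """Diagonal mass matrix ``M[i, i] = h_l / (2i + 1)`` for degrees 0..r."""
    if r < 0:
        raise ValueError(f"degree must be >= 0, got r={r}")
    return np.diag([element.length / (2 * i + 1) for i in range(r + 1)])


def stiffness_matrix(r: int, element: Element) -> np.ndarray:
    """Stiffness matrix ``S[j, i] = <L_i, L_j'>`` on the element (test = row).

    On the reference interval the integral telescopes through the Legendre
    derivative recurrence: the entry is exactly 2 when the differentiated
    (test) degree exceeds the trial degree and the index sum is odd, else
    exactly 0.  Element length drops out (derivative Jacobian cancels the
    measure).
    """
    if r < 0:
        raise ValueError(f"degree must be >= 0, got r={r}")
    S = np.zeros((r + 1, r + 1))
    for j in range(r + 1):
        for i in range(r + 1):
            if j > i and (i + j) % 2 == 1:
                S[j, i] = 2.0
    return S


def flux_operators(r: int, inflow_value: float) -> tuple[np.ndarray, np.ndarray]:
    """Upwind flux operators: all-ones matrix E and load vector b.

    ``E[j, i] = 1`` couples the downwind trace ``Z0(t_l^-) = sum_i alpha_i``
    into every test equation; ``b_j = (-1)^(j+1) * inflow`` carries the
    upwind trace from the previous element (the initial value on the first).
    """
    if r < 0:
        raise ValueError(f"degree must be >= 0, got r={r}")
    E = np.ones((r + 1, r + 1))
    b = np.array([(-1.0) ** (j + 1) * inflow_value for j in range(r + 1)])
    return E, b


def fractional_matrix(
    r: int, element: Element, nu: float, mode: str = "paper_literal"
) -> np.ndarray:
    """Fractional matrix ``D[j, i] = <I^(1-nu) L_i, L_j>`` on the element.

    ``mode='paper_literal'`` anchors the Riemann-Liouville integral at the
    global origin ``t = 0`` and applies it to the local basis as stated by
    the scheme's algebraic form; ``mode='history_corrected'`` anchors it at
    the element's left node (the cross-element memory is then supplied
    separately by the marcher as a load vector).  The two coincide on the
    first element and, trivially, for ``nu = 1`` where both reduce exactly
    to the mass matrix.

    Assembly is term-wise over the monomial representation; for ``nu < 1``
    it runs in 50-digit arithmetic because the node-power differences
    ``t_l^e - t_{l-1}^e`` cancel catastrophically on deep meshes.
    """
    if not 0 < nu <= 1:
        raise ValueError(f"order must lie in (0, 1], got nu={nu}")
    if mode not in ("paper_literal", "history_corrected"):
        raise ValueError(f"unknown mode {mode!r}")
    if r > MAX_DEGREE:
        raise ValueError(f"degree {r} exceeds the supported maximum {MAX_DEGREE}")
    if nu == 1.0:
        return mass_matrix(r, element)

    with mpmath.workdps(_FRAC_DPS):
        if mode == "paper_literal":
            a = mpmath.mpf(element.left)
            b = mpmath.mpf(element.right)
        else:
            # local anchor: work in u = t - t_{l-1}
            a = mpmath.mpf(0)
            b = mpmath.mpf(element.length)
        one = mpmath.mpf(1)
        reps = [_monomial_coeffs_generic(i, a, b, one) for i in range(r + 1)]
        mu = 1 - mpmath.mpf(nu)  # integral order
        # I^(1-nu) t^m = Gamma(m+1)/Gamma(m+2-nu) t^(m+1-nu)
        gfac = [
            mpmath.gamma(m + 1) / mpmath.gamma(m + 1 + mu) for m in range(r + 1)
        ]
        D = np.zeros((r + 1, r + 1))
        for j in range(r + 1):
            for i in range(r + 1):
                acc = mpmath.mpf(0)
                for m, cm in enumerate(reps[i]):
                    if cm == 0:
                        continue
                    for mp_, cmp in enumerate(reps[j]):
                        if cmp == 0:
                            continue
                        e = m + mp_ + 1 + mu
                        acc += cm * gfac[m] * cmp * (b**e - a**e) / e
                D[j, i] = float(acc)
    return D


def triple_product_tensor(r: int, element: Element) -> np.ndarray:
    """Tensor ``T[i, i2, j] = int_element L_i * L_i2 * L_j dt``.

    Computed by a Gauss-Legendre rule exact for the degree-``3r`` integrand;
    feeds the direct-computation quadratic term and its Jacobian.
    """
    if r < 0:
        raise ValueError(f"degree must be >= 0, got r={r}")
    n_nodes = math.ceil((3 * r + 1) / 2) + 2
    s, w = np.polynomial.legendre.leggauss(n_nodes)
    # basis values P_i(s_k) at all quadrature nodes
    P = np.array([[_legendre_recurrence(i, sk) for sk in s] for i in range(r + 1)])
    T = 0.5 * element.length * np.einsum("ik,mk,jk,k->imj", P, P, P, w)
    # symmetrise the first two indices against quadrature roundoff
    return 0.5 * (T + T.transpose(1, 0, 2))


@dataclass(frozen=True)
class ElementOperators:
    """All operators of one element's local algebraic system."""

    degree: int
    element: Element
    mass: np.ndarray = field(repr=False)
    stiffness: np.ndarray = field(repr=False)
    flux: np.ndarray = field(repr=False)
    fractional: np.ndarray = field(repr=False)
    triple: np.ndarray = field(repr=False)


def build_element_operators(
    r: int, element: Element, nu: float, history_mode: str = "paper_literal"
) -> ElementOperators:
    """Assemble M, S, E, D and the triple-product tensor for one element."""
    return ElementOperators(
        degree=r,
        element=element,
        mass=mass_matrix(r, element),
        stiffness=stiffness_matrix(r, element),
        flux=np.ones((r + 1, r + 1)),
        fractional=fractional_matrix(r, element, nu, history_mode),
        triple=triple_product_tensor(r, element),
    )
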