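"""Element bases and operator matrices against quadrature oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import basis, gauss_inner_product
from fracldg.elements import (
    MAX_DEGREE,
    Element,
    Mesh,
    flux_operators,
    fractional_matrix,
    mass_matrix,
    monomial_coefficients,
    shifted_legendre_eval,
    stiffness_matrix,
    triple_product_tensor,
)
from fracldg.special import fractional_integral_oracle


class TestMesh:
    def test_uniform_partition(self):
        mesh = Mesh.uniform(2.0, 4)
        assert mesh.n_elements == 4
        assert mesh.nodes == (0.0, 0.5, 1.0, 1.5, 2.0)
        assert mesh.max_length == pytest.approx(0.5)

    def test_locate_sides_at_interior_node(self):
        mesh = Mesh.uniform(1.0, 2)
        assert mesh.locate(0.5, side="left").index == 1
        assert mesh.locate(0.5, side="right").index == 2
        assert mesh.locate(0.0, side="left").index == 1
        assert mesh.locate(1.0, side="right").index == 2

    def test_invalid_meshes_rejected(self):
        with pytest.raises(ValueError):
            Mesh((0.0, 0.5, 0.5, 1.0))
        with pytest.raises(ValueError):
            Mesh((0.1, 1.0))
        with pytest.raises(ValueError):
            Mesh.uniform(1.0, 0)


class TestShiftedLegendre:
    @pytest.mark.parametrize("i", range(9))
    def test_node_values(self, i):
        """Right node value 1, left node value (-1)^i — the flux identities."""
        el = Element(1, 0.3, 1.1)
        assert shifted_legendre_eval(i, el, el.right) == pytest.approx(1.0, abs=1e-13)
        assert shifted_legendre_eval(i, el, el.left) == pytest.approx(
            (-1.0) ** i, abs=1e-13
        )

    def test_quadratic_midpoint(self):
        el = Element(1, 0.0, 2.0)
        assert shifted_legendre_eval(2, el, 1.0) == pytest.approx(-0.5, abs=1e-14)

    def test_outside_element_rejected(self):
        el = Element(1, 0.0, 1.0)
        with pytest.raises(ValueError):
            shifted_legendre_eval(2, el, 1.5)

    @pytest.mark.parametrize(
        "i, interval, expected",
        [
            (0, (0.0, 1.0), [1.0]),
            (1, (0.0, 2.0), [-1.0, 1.0]),          # t - 1
            (2, (0.0, 1.0), [1.0, -6.0, 6.0]),     # 6t^2 - 6t + 1
        ],
    )
    def test_monomial_coefficients_examples(self, i, interval, expected):
        rep = monomial_coefficients(i, Element(1, *interval))
        assert np.allclose(rep.coeffs, expected, atol=1e-12)

    @pytest.mark.parametrize("i", range(MAX_DEGREE - 3))
    def test_monomial_roundtrip(self, i):
        """Monomial form reproduces the recurrence evaluation on a sample.

        Tolerance scales with sum_m |c_m t^m|, the cancellation level
        inherent to the monomial representation; absolute accuracy beyond
        that is not achievable in double precision for high degrees.
        """
        el = Element(1, 0.7, 1.9)
        rep = monomial_coefficients(i, el)
        for t in np.linspace(el.left, el.right, 2 * i + 3):
            scale = max(1.0, sum(abs(c) * t**m for m, c in enumerate(rep.coeffs)))
            assert rep(t) == pytest.approx(
                shifted_legendre_eval(i, el, t), abs=1e-11 * scale
            )

    def test_degree_cap(self):
        with pytest.raises(ValueError):
            monomial_coefficients(MAX_DEGREE + 1, Element(1, 0.0, 1.0))


class TestOperatorMatrices:
    def test_mass_matrix_closed_form(self):
        assert np.allclose(mass_matrix(1, Element(1, 0.0, 2.0)), np.diag([2, 2 / 3]))
        assert np.allclose(
            mass_matrix(2, Element(1, 0.0, 1.0)), np.diag([1, 1 / 3, 1 / 5])
        )

    @pytest.mark.parametrize("r", [2, 5, 8])
    def test_mass_matrix_matches_quadrature(self, r):
        el = Element(1, 0.35, 1.6)
        M = mass_matrix(r, el)
        for i in range(r + 1):
            for j in range(r + 1):
                oracle = gauss_inner_product(basis(i, el), basis(j, el), el)
                assert M[i, j] == pytest.approx(oracle, abs=1e-11)

    def test_stiffness_examples(self):
        el = Element(1, 0.0, 1.0)
        assert np.array_equal(stiffness_matrix(1, el), [[0, 0], [2, 0]])
        assert np.array_equal(
            stiffness_matrix(2, el), [[0, 0, 0], [2, 0, 0], [0, 2, 0]]
        )

    @pytest.mark.parametrize("r", [3, 6, 8])
    def test_stiffness_matches_quadrature(self, r):
        """S[j,i] = <L_i, L_j'> checked against a Gauss oracle, with the
        test-function derivative from the stable Legendre-series route."""
        from numpy.polynomial import legendre as npleg

        el = Element(1, 0.2, 1.45)
        S = stiffness_matrix(r, el)

        def dbasis(j):
            dP = npleg.Legendre.basis(j).deriv()
            jac = 2.0 / el.length  # ds/dt of the affine map

            def d(t):
                return float(dP(el.to_reference(t))) * jac

            return d

        for j in range(r + 1):
            for i in range(r + 1):
                oracle = gauss_inner_product(basis(i, el), dbasis(j), el)
                assert S[j, i] == pytest.approx(oracle, abs=1e-11)

    @pytest.mark.parametrize("r", [1, 4, 8])
    def test_integration_by_parts_identity(self, r):
        """s_{j,i} + s_{i,j} = 1 - (-1)^(i+j), from the boundary values."""
        S = stiffness_matrix(r, Element(1, 0.0, 3.0))
        for i in range(r + 1):
            for j in range(r + 1):
                assert S[j, i] + S[i, j] == 1.0 - (-1.0) ** (i + j)

    def test_flux_operators(self):
        E, b = flux_operators(2, 0.75)
        assert np.array_equal(E, np.ones((3, 3)))
        assert np.allclose(b, [-0.75, 0.75, -0.75])
        _, b0 = flux_operators(3, 0.0)
        assert np.array_equal(b0, np.zeros(4))


class TestFractionalMatrix:
    @pytest.mark.parametrize("r", [0, 2, 4])
    def test_classical_order_reduces_to_mass(self, r):
        el = Element(3, 1.0, 1.5)
        for mode in ("paper_literal", "history_corrected"):
            assert np.allclose(
                fractional_matrix(r, el, 1.0, mode), mass_matrix(r, el), atol=1e-14
            )

    def test_scalar_entry_closed_form(self):
        # <I^0.5 1, 1> on [0,1] = int_0^1 t^0.5/Gamma(1.5) dt
        D = fractional_matrix(0, Element(1, 0.0, 1.0), 0.5, "paper_literal")
        assert D[0, 0] == pytest.approx(0.752252778063675, abs=1e-12)

    @pytest.mark.parametrize("nu", [0.25, 0.5, 0.75])
    def test_modes_coincide_on_first_element(self, nu):
        el = Element(1, 0.0, 0.8)
        Dp = fractional_matrix(3, el, nu, "paper_literal")
        Dh = fractional_matrix(3, el, nu, "history_corrected")
        assert np.allclose(Dp, Dh, atol=1e-12)

    @pytest.mark.parametrize("nu", [0.25, 0.5, 0.75])
    def test_matches_oracle_assembly_on_first_element(self, nu):
        """Entries equal the quadrature-oracle assembly of <I^(1-nu)L_i, L_j>.

        On the first element I^(1-nu)L_i = t^(1-nu) * (polynomial of degree
        i), so a Gauss-Jacobi rule with weight t^(1-nu) integrates the
        product against L_j exactly; only the oracle supplies the
        fractional-integral values.
        """
        from scipy.special import roots_jacobi

        r = 2
        h = 0.9
        el = Element(1, 0.0, h)
        D = fractional_matrix(r, el, nu, "paper_literal")
        mu = 1.0 - nu
        x, w = roots_jacobi(r + 2, 0.0, mu)
        ts = 0.5 * h * (x + 1.0)
        # Jacobi weight (1+x)^mu maps to (2t/h)^mu; undo it and rescale
        scale = 0.5 * h * (h / 2.0) ** mu
        reps = [monomial_coefficients(i, el) for i in range(r + 1)]
        for i in range(r + 1):
            smooth = np.array(
                [
                    fractional_integral_oracle([(0.0, h, reps[i].coeffs)], mu, t)
                    / t**mu
                    for t in ts
                ]
            )
            for j in range(r + 1):
                Lj = np.array([shifted_legendre_eval(j, el, t) for t in ts])
                oracle = scale * float(np.sum(w * smooth * Lj))
                assert D[j, i] == pytest.approx(oracle, abs=1e-10)

    def test_rejects_bad_order(self):
        with pytest.raises(ValueError):
            fractional_matrix(2, Element(1, 0.0, 1.0), 1.5)
        with pytest.raises(ValueError):
            fractional_matrix(2, Element(1, 0.0, 1.0), 0.5, "bogus")


class TestTripleProductTensor:
    def test_reference_entries(self):
        el = Element(1, 0.0, 2.0)
        T = triple_product_tensor(1, el)
        assert T[0, 0, 0] == pytest.approx(2.0, abs=1e-13)      # int 1 dt
        assert T[1, 1, 0] == pytest.approx(2.0 / 3.0, abs=1e-13)
        assert T[1, 1, 1] == pytest.approx(0.0, abs=1e-13)      # odd integrand

    @pytest.mark.parametrize("r", [1, 3, 5])
    def test_slice_with_constant_is_mass(self, r):
        el = Element(1, 0.4, 1.7)
        T = triple_product_tensor(r, el)
        M = mass_matrix(r, el)
        assert np.allclose(T[0], M, atol=1e-12)

    def test_full_symmetry(self):
        T = triple_product_tensor(4, Element(1, 0.0, 1.3))
        for perm in ((1, 0, 2), (2, 1, 0), (0, 2, 1)):
            assert np.allclose(T, T.transpose(perm), atol=1e-12)

    def test_matches_quadrature(self):
        el = Element(1, 0.25, 1.15)
        T = triple_product_tensor(3, el)
        for i, m, j in [(1, 2, 3), (2, 2, 2), (0, 3, 3), (3, 3, 2)]:
            oracle = gauss_inner_product(
                lambda t: shifted_legendre_eval(i, el, t)
                * shifted_legendre_eval(m, el, t),
                basis(j, el),
                el,
            )
            assert T[i, m, j] == pytest.approx(oracle, abs=1e-12)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    left=st.floats(0.0, 5.0),
    length=st.floats(0.05, 3.0),
    i=st.integers(0, 8),
)
def test_monomial_and_recurrence_agree_property(left, length, i):
    """The two basis-evaluation routes agree on arbitrary elements, to the
    cancellation level of the monomial form."""
    el = Element(1, left, left + length)
    rep = monomial_coefficients(i, el)
    t = left + 0.37 * length
    scale = max(1.0, sum(abs(c) * t**m for m, c in enumerate(rep.coeffs)))
    assert rep(t) == pytest.approx(
        shifted_legendre_eval(i, el, t), abs=1e-11 * scale
    )
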