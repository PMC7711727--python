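# Methods

## Models

The package integrates scalar Caputo-fractional initial-value problems on
[0, T]:

- linear growth `D^nu X = sigma^nu X` (the fractional Malthus model; the
  rate enters raised to the fractional power so that the exact solution is
  `X0 * E_nu(sigma^nu t^nu)`), and
- logistic `D^nu X = sigma X (1 - X)` with X normalised to carrying
  capacity 1.

`D^nu` is the Liouville–Caputo derivative, `I^(1-nu)` applied to the
classical derivative, so constants are annihilated and the classical
initial condition applies. For `sigma < 0` the linear model uses the plain
rate `sigma` (the fractional power of a negative rate is not real); that
is also the form under which the scheme's contractivity holds and is
tested. All forms coincide at `nu = 1` or `sigma = 1`.

## Discretisation

First-order system: `z1 = z0'`, `I^(1-nu) z1 = sigma z0 g(z0)`. Both
variables are approximated by discontinuous piecewise polynomials of
degree `r` (`r <= 12`) in shifted Legendre bases on each element, with
upwind fluxes: the trace entering element `l` is the left limit
`Z0(t_{l-1}^-)` from element `l-1` (the initial value on the first
element, imposed weakly — `Z0(0^+)` is generally not `X0`). The local
system per element is

    M beta + (S - E) alpha = b,
    D beta - lambda M alpha + sigma n(alpha) + H = 0,

test index as row throughout. `M` is diagonal (`h_l/(2i+1)`); `S[j,i] =
<L_i, L_j'>` equals exactly 2 when the test degree exceeds the trial
degree with odd index sum, else 0 (the closed form of the exact
quadrature; it satisfies the integration-by-parts identity
`s_{j,i} + s_{i,j} = 1 - (-1)^(i+j)` exactly); `E` is all ones and
`b_j = (-1)^(j+1) * inflow`; `lambda` is the effective rate above;
`n(alpha)` is the Galerkin quadratic term, absent in the linear model.

### Quadratic term

Two treatments, selectable per run:

- **dc** (direct computation, default): `n_j = sum_{i,i'} T[i,i',j]
  alpha_i alpha_{i'}` with the triple-product tensor
  `T[i,i',j] = int L_i L_{i'} L_j dt`, computed by a Gauss–Legendre rule
  of `ceil((3r+1)/2)+2` nodes (exact for the degree-3r integrand).
  Downwind superconvergence of order `2r+1` is retained.
- **pa** (product approximation): the square of the expansion is replaced
  by the expansion of squared coefficients, `n = M @ alpha**2`. Assembly
  is linear in `r` but accuracy drops to second order regardless of `r`.

Nonlinear local systems are solved by Newton with the analytic Jacobian
(`2 M diag(alpha)` for pa, `2 T . alpha` for dc), max-norm residual
tolerance 1e-13 (so 10-digit table values are limited by the method, not
the solver), at most 50 iterations. The initial guess is the inflow value
as a constant polynomial, with `beta` from the fractional block
linearised there; this O(h)-accurate predictor keeps every benchmark run
inside Newton's quadratic basin (3–5 iterations).

### Fractional matrix and memory

`D[j,i] = <I^(1-nu) L_i, L_j>` is assembled term by term through the
monomial representation of the basis (binomial expansion of the mapped
Legendre polynomial — the recurrence is used everywhere else, the
monomial form only where the fractional integral must act power by
power), using `I^mu t^m = Gamma(m+1)/Gamma(m+2-nu) t^(m+1-nu)`. For
`nu < 1` the entries involve differences `t_l^e - t_{l-1}^e` that cancel
catastrophically on deep meshes, so all `nu < 1` assembly runs in
50-digit mpmath arithmetic and is rounded once at the end; `nu = 1`
short-circuits exactly to the mass matrix. (This extends the
extended-precision guard to every fractional assembly rather than only
high degrees or extreme node/length ratios — at desk scale the cost is
negligible and one code path is safer.)

Two memory modes:

- **paper_literal** (default): the fractional integral in `D` is anchored
  at the global origin for every element and no explicit history term is
  added. This is the scheme's algebraic form as published; for `nu < 1`
  and more than one element it discards cross-element memory, and the
  marching error is observed to grow with refinement.
- **history_corrected**: `D` is anchored at the element's left node and
  the memory of all previous elements enters as an explicit load
  `H_j = <(1/Gamma(1-nu)) sum_{k<l} int_{L_k} (t-p)^(-nu) Z1|_{L_k}(p) dp, L_j>_l`.
  Substituting `u = t - p` and expanding binomially reduces every term to
  integrals `int t^p (t-c)^e dt`, which are evaluated in closed form —
  the load is exact to roundoff, with no quadrature even when `Z1` jumps
  across interfaces. With this mode the `nu < 1` linear benchmark error
  decreases monotonically under refinement (e.g. 2.8e-2 at J=1 down to
  4.1e-8 at J=32 for nu=0.6, r=2).

The two modes coincide when `nu = 1` or `J = 1`; every published
benchmark configuration is in that intersection, which is why the default
follows the published algebraic form.

## Reference schemes

- **PECE** (fractional Adams–Bashforth–Moulton): product-rectangle
  predictor, one product-trapezoidal correction per step, full-memory
  sums (O(N^2) total, fine for N <= 4096). At `nu = 1` it collapses to
  the classical full-memory rectangle/trapezoid PECE (note: equivalent to
  the one-step classical scheme only for linear right-hand sides).
- **L1**: piecewise-linear product quadrature of the Caputo derivative,
  weights `(n+1-k)^(1-nu) - (n-k)^(1-nu)`. The implicit variant
  (right-hand side at the new level; closed-form step for linear,
  scalar Newton otherwise) is the default and is backward Euler at
  `nu = 1`. An explicit variant (right-hand side at the previous level;
  forward Euler at `nu = 1`) is also provided — it is the variant that
  reproduces the published L1 benchmark column for the linear model, and
  the table-reproduction code uses it there; the implicit variant is
  noticeably more accurate at the same step size.

## Exact references and special functions

The Mittag-Leffler function is evaluated by direct series summation in
50-digit arithmetic with a 1e-20 term-ratio stopping rule, rounded to
double precision at the end; this is accurate far below 1e-12 for the
moderate arguments growth models produce (|z| <= 4, nu >= 0.25). No
global Padé/inversion algorithm is attempted, and complex arguments and
the two-parameter generalisation are out of scope. `E_1` short-circuits
to `exp`, and the `nu = 1` branches of the exact solutions use elementary
functions directly (also avoiding `0^0` at `t = 0`). Error tables use the
Mittag-Leffler closed form for the linear model at any order and the
logistic closed form only at `nu = 1`; the fractional logistic equation
has no known exact solution and error requests for it raise.

A quadrature-based fractional-integral oracle for piecewise polynomials
(tanh-sinh rule in 30-digit arithmetic, with the kernel singularity
removed exactly by the substitution `u = (t-p)^nu` on the adjacent
piece) backs the test suite as an independent route to every fractional
quantity; it shares no code with the monomial-formula assembly.

## Numerical choices

- Basis evaluation: Bonnet three-term recurrence (stable); degree cap
  `r <= 12` because the monomial representation's conditioning degrades
  as roughly `4^r` — the round-trip tests assert agreement at the
  cancellation level `sum |c_m t^m| * 1e-11`.
- Gauss rules: `(3r+1)/2 + 2` nodes for triple products, exactness
  verified against a 40-node oracle in the tests.
- Downwind values are reported as the left limit at the final node,
  `sum_i alpha_i^J`; the estimated order of convergence is
  `log2(Ea(h)/Ea(h/2))` computed from full-precision errors, never from
  rounded printed values.
- Meshes are uniform by default (`h = T/J`); the data model accepts
  arbitrary strictly increasing nodes.
- Degenerate rate `sigma = 0`: the local system decouples, the solution
  is the constant inflow and `Z1 = 0`; Newton converges immediately.

## Benchmark scope and known limitations

The convergence studies in `experiments` use J up to 128 (linear, r=2),
J in {1, 2, 4} (logistic, r = 1 and 2), degree 5 single-element runs for
the fractional linear model, and N = 1000 steps for the L1 column — the
configurations of the published comparison tables; all complete in a few
seconds on one core. Known limitations:

- The published single-element logistic downwind values differ from the
  exact roots of the corresponding local algebraic systems by 4e-10 to
  9e-9 (the exact roots were confirmed independently by multiprecision
  root finding); this package reports the converged roots, so its last
  one or two digits differ from those printed values. Its own error and
  EOC columns are self-consistent.
- At `nu = 1` the L1 scheme is a first-order method; its error halves
  (rather than better) per step halving.
- No systems of equations, no `nu > 1`, no adaptive meshing, and the
  stability (contractivity) property is verified numerically, not proved.
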