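# Methods

## Model

The package solves the dimensionless steady-state heat-conduction model of
the human head in spherical symmetry, generalized to fractional
Liouville–Caputo (LC) derivatives:

    D^gamma H(r) + (A/r) D^sigma H(r) + lam * exp(-m H(r)) = f(r),  0 < r < 1,
    H'(0) = 0,    H'(1) = Bi (1 - H(1)).

`H` is temperature relative to ambient, `r` the radial coordinate scaled by
the head radius. Parameters, with defaults chosen as the standard benchmark
configuration:

| symbol  | meaning                                        | admissible      | default |
|---------|------------------------------------------------|-----------------|---------|
| gamma   | LC order of the diffusion term                 | (1, 2]          | 2.0     |
| sigma   | LC order inside the singular term              | (0, 1]          | 1.0     |
| A       | singular-coefficient constant (A=2: sphere)    | real            | 2.0     |
| lam     | thermogenesis heat-production factor           | >= 0            | 1.0     |
| m       | metabolic thermogenesis slope                  | real            | 1.0     |
| Bi      | Biot number of the Robin boundary condition    | nonzero         | 1.0     |
| f       | optional source term (testing only)            | callable        | 0       |

Physically `Bi > 0`; the solver layer accepts any nonzero value because
manufactured exact solutions with `H(1) > 1` require `Bi < 0` through the
Robin condition, and restricting the range there would make the solver
untestable against exact solutions. The config/CLI layer, which is the
user-facing surface, enforces `Bi > 0`.

The integer-order case (gamma, sigma) = (2, 1) is routed through the same
Caputo power-rule formula, which reduces exactly to classical derivatives;
there is no special-cased numerics.

## Discretization

**Basis.** Shifted Vieta–Lucas functions `V_k(r) = 2 T_k(2r - 1)` (twice a
shifted Chebyshev polynomial, orthogonal on (0,1) under `(r - r^2)^(-1/2)`),
generalized by the substitution `r -> r^alpha` to span the fractional powers
`r^(l alpha)`, `l = 0..K`. Monomial coefficients are computed by an exact
integer factorial formula (they reach ~1e9 at k = 12; the integer arithmetic
avoids cancellation) and assembled into the upper-triangular change-of-basis
matrix `N_K`, so every operator row is formed in the fractional-monomial
basis and multiplied by `N_K` once.

**Caputo derivative rows.** The LC derivative of a power `r^w` of order `q`
is `Gamma(w+1)/Gamma(w+1-q) r^(w-q)` when `w` is an integer `>= ceil(q)` or a
non-integer `> floor(q)`; integer powers below `ceil(q)` (and constants) map
to zero. The gamma ratio is evaluated through the reciprocal gamma function,
so poles of the denominator give a zero coefficient instead of overflow.
Non-integer powers at or below `floor(q)` are outside the rule's validity:
they carry a `divergent_flag`, enter assembled systems as zeros with a logged
warning, and make residual evaluation an error. This convention keeps basis
exponents `alpha < 1` formally runnable (the operator rows exist) while
refusing to report a residual whose defining derivatives are undefined.

**Collocation and boundary rows.** The linearized equation is enforced at
the `K+1` roots of the degree-(K+1) FSVLF — all interior to (0,1), in
ascending order. Two rows of the square system are then replaced:

- the Robin row `(d/dr + Bi)|_{r=1}` replaces the row of the *largest* node;
- the `h'(0) = 0` row replaces the row of the *smallest* node, **unless** the
  row is identically zero. For `alpha > 1` every basis derivative vanishes at
  the origin, the condition holds automatically, and the collocation row is
  retained (substituting a zero row would make the system singular). For
  non-integer `alpha < 1` the `l = 1` entry is singular at 0; the row is then
  built from the admissible entries only and a warning is logged.

Which two rows to replace is a genuinely open design point — enforcing the
equation at a different node subset changes the computed solution at its own
truncation-error level (about 5e-8 at K = 6 for the integer benchmark, 2e-10
at K = 6, alpha = 1.7 for the fractional one) and leaves everything beyond
that level unchanged. The published reference tables this package reproduces
were evidently produced with a different (unstated) choice: their pointwise
values agree with this implementation to 8 significant digits at K = 6 and
to 12 at K = 10, while their printed K = 6 expansion *coefficients* and their
low-K residual-norm tables differ at exactly the truncation-artifact level
described above (their K = 2 residual norm is in fact below the sup-norm
floor attainable by any single-interior-node scheme of this family, and their
fractional sweep norms are ~20x larger than this implementation achieves at
equal K). Those artifacts are catalogued, compared side by side by
`reproduce()`, and not tuned toward.

**Quasilinearization.** Newton linearization of `G(H) = -lam exp(-m H)`
about the previous iterate: coefficient `xi1 = -lam m exp(-m H_prev)` and
right side `theta = -lam exp(-m H_prev)(1 + m H_prev) + f`. The initial
iterate is identically zero. Default `n_iters = 6` linear solves (iterates
labelled 0..5, matching the conventional superscript-6 labelling of the
final iterate) with early stop once the max coefficient change drops below
`tol = 1e-14`; every benchmark configuration reaches the round-off floor in
4–5 solves, the strongly nonlinear `lam = 5` case in 6. Convergence is
quadratic; the per-iteration coefficient change is exposed in
`SpectralSolution.changes`.

**Linear algebra.** Dense direct solve with partial pivoting after scaling
each column by its max absolute entry (the fractional-monomial basis is
ill-conditioned; scaling keeps the K = 16 systems solvable to ~1e-13
backward error in double precision). A `precision="extended"` toggle reruns
the whole pipeline (nodes, gamma functions, assembly, LU, residuals) in
mpmath with `dps` decimal digits (default 50). It matters only for K >= 14,
where the true truncation residual sits below the double round-off floor:
at K = 16 the integer benchmark's residual norm is ~9e-19 in extended
arithmetic, while double precision floors near 2e-15 — reference values
printed at that level are round-off readings, not truncation errors.

## Projections and error bounds

Expansion coefficients of a function `g` are computed by the weighted inner
product `beta_k = alpha/(pi eta_k) * int V^alpha_k g w_alpha dr`
(`eta_0 = 4`, else 2). The substitution `r^alpha = (1 + cos s)/2` removes the
endpoint singularity of the weight and collapses the integral to a cosine
transform; the equally weighted midpoint rule in `s` (= Gauss–Chebyshev
quadrature) is doubled from 64 to at most 4096 nodes until successive
coefficient vectors agree to 1e-12, and non-convergence is an error.

For `C^2` functions with `M = max |g''|` the closed-form bounds (valid for
alpha = 1) are exposed as data: `|beta_k| < 4M/(pi k^4)`, tail sup-norm
`< 8M/(3 pi K^3)`, weighted-L2 tail `< sqrt(8/(7 pi)) M K^(-7/2)`, and
successive-truncation gap `< 2 sqrt(2) M K^(-4) / sqrt(pi)`. The test suite
verifies them empirically for `g = e^r`; bounds for `alpha != 1` are not
asserted.

## Residual diagnostics

The REF inserts the computed monomial form into the original nonlinear
equation term by term via the power rule; `E_inf` is its maximum over a
uniform grid on (0, 1] with `n_grid = 2001` points by default (the value at
the singular endpoint r = 0 is reported as 0 by convention). 2001 points make
`E_inf` grid-stable to well under 1% at K <= 10; doubling the grid is part of
the test suite. The numerical order of convergence between truncations K and
2K is `(ln E_K - ln E_2K)/ln 2`.

The REF vanishes (to round-off) at retained collocation nodes of a converged
run — a useful self-check, and the reason residual plots show sharp dips
there. For `alpha != gamma` in fractional problems the REF does *not* vanish
as `r -> 0`: no basis power can balance the thermogenesis source at the
singular origin, the defect is O(1) there, and `E_inf` is dominated by the
smallest grid point. This is a property of the method family, not a bug;
choosing `alpha = gamma` removes the defect.

## Manufactured solutions

`manufactured_source` builds `f = D^gamma H* + (A/r) D^sigma H* +
lam exp(-m H*)` for a prescribed fractional polynomial `H*` and reports the
Biot number consistent with the Robin condition. With
`H* = 1 + r^(2 alpha) + r^(3 alpha)` the solver recovers `H*` to ~1e-15 for
K >= 3, exercising every pipeline stage against an exact solution. The
source hook exists purely for this purpose; `f = 0` is the physical model.

## Benchmark catalog

`fsvlf.catalog` stores the parameter sets and printed values of the eight
published benchmark tables (pointwise solution/REF tables and E_inf/order
sweeps) plus the two published least-squares comparator polynomials
(fixtures only — the comparator methods are never reimplemented).
`reproduce("tableN")` reruns every recomputable cell and reports relative
differences; published CPU-time columns are displayed but never compared.
Each full entry runs in well under ten seconds on one CPU in double
precision, and reruns are bit-identical (no randomness exists anywhere).

## Limitations

- Bounds of the basis approximation theory are asserted only for alpha = 1.
- Basis exponents alpha < 1 run with warnings but their residuals are
  undefined under the power-rule convention (see above); sweeps over alpha
  should stay above max(1, gamma - 1).
- The direct (non-quasilinearized) nonlinear collocation is deliberately not
  implemented; QLM is strictly better-conditioned here.
- Printed reference values at the K = 6 coefficient level and low-K residual
  norms embed the reference implementation's own unstated discretization
  choices and cannot be matched beyond the truncation-artifact level by any
  implementation of the stated algorithm (see "Collocation and boundary
  rows").
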