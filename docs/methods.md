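# Methods

## Phase-type representations

A phase-type distribution is stored as the pair `(alpha, A)`: `alpha` a
1-D probability vector over `k` transient states and `A` the `k × k`
transient rate block, in the row convention where entry `(i, j)` is the
rate `r_i p_{ij}` of moving from transient state `i` to `j`. The exit
vector is `a = -A·1` and the defect `α* = 1 - Σα` is an atom at time 0.
Construction validates: strictly negative diagonal, nonnegative
off-diagonals, nonnegative exit rates, `alpha` a (sub-)probability vector,
and invertibility of `A` (every transient state reaches absorption).
Validation uses an absolute tolerance of 1e-9, sized for double-precision
round-off in matrices assembled from user arithmetic; invertibility is
screened by a condition-number bound of 1e12. Representations are accepted
as-is — phase-type parameterizations are not unique and no canonicalization
is attempted.

Density and CDF use `pdf(t) = αᵀ e^{At} a`, `F(t) = 1 - αᵀ e^{At} 1` with
the matrix exponential from `scipy.linalg.expm` (scaling-and-squaring),
evaluated per time point; blocks here are small (k ≤ ~10) so no
eigendecomposition caching is needed. Moments `j! αᵀ(-A)^{-j} 1` are
computed by `j` successive linear solves, never explicit inversion.

Closure operations: the minimum of independent phase-type variables is
`(α₁ ⊗ α₂, A₁ ⊕ A₂)` (Kronecker product / sum), folded left for more than
two arguments; finite mixtures are block-diagonal with weight-scaled
alphas. Mixture components must carry no defect so that the defect of the
result has a single unambiguous reading at the top level. The
mortality-augmented representation `G = A - μI` is the minimum with an
independent exponential(μ) clock after dropping the trivial scalar
Kronecker factor; it adds μ to every exit rate and shifts the spectrum of
`A` by -μ.

## Absorbing-CTMC algebra

The embedded jump chain is `Q = D_r⁻¹A + I` (diagonal forced to zero),
with per-state absorption probabilities `q = a/r`, and the rate matrix is
recovered as `-A = D_r(I - Q)`. The Green matrix `U = -A⁻¹` holds expected
occupation times; expected rewards are `αᵀ(-A⁻¹)g`. When the absorbing
state is split into `m` labelled states by a routing matrix `C` (row `i`
the conditional exit distribution from transient state `i`), hitting
probabilities are `H = (-A⁻¹)D_a C` and the overall absorption vector is
`π = αᵀH`. Rows of `C` are validated only where the exit rate is positive
(elsewhere `D_a` zeroes them; they are stored as uniform). `π` is refused
when `Σα < 1`: mass absorbed at t = 0 has no transient path and hence no
defined destination, and we prefer an explicit error to a guessed
convention. The intermediate jump-chain matrix `R = D_q C` is not part of
the public surface; the two algebraic routes `(I-Q)⁻¹R` and `(-A⁻¹)D_a C`
are compared in the test suite instead.

## Model assembly

The generic GLCT stage is `dx = α·inflow + Aᵀx` with per-substate outflow
`a ∘ x`. The generalized SEIRS model chains three stages (latent,
infectious, immune) with uniform per-capita mortality μ applied inside
each stage, force of infection `λ = βᵀy`, and recruitment into S. The
birth term is pluggable (`birth(S, x, y, z)`); the default is a constant
Λ, the only case with a closed-form disease-free equilibrium S₀ = Λ/μ.
Closed populations (Λ = μ = 0) carry a user-supplied S₀. The latent block
must satisfy `Σα_E = 1`: the R₀ derivation presumes every new infection
enters E, and a defective entry into E has no derived correction. The
predator-prey model allows a defective maturation block — that fraction of
offspring dies before entering the immature stage, and the factor
`1 - α_x*` carries through R_pred explicitly. Offspring "skipping" the
immature stage directly into adulthood is not modelled.

State vectors are flat arrays, scalars first then substate vectors in
declaration order. Nonnegativity is enforced on initial conditions only;
the RHS tolerates the slightly negative probes adaptive integrators make.

There is no disease-induced mortality in the generalized SEIRS model (μ is
uniform across compartments); the classic SIR bookkeeping where a total
exit rate `(γ+μ+ν)I` splits proportionally into destination flows is
exercised in the tests through the absorption-probability machinery rather
than carried as model structure.

## Reproduction numbers

`F` and `V` blocks are assembled over the infected (or predator) substates
exactly in their block forms, `V⁻¹` via the block-lower-triangular formula
`[[A,0],[C,D]]⁻¹ = [[A⁻¹,0],[-D⁻¹CA⁻¹,D⁻¹]]` with per-block linear solves,
and the spectral radius is taken over the full eigenvalue set of `FV⁻¹`
(blocks are small dense matrices; exactness is preferred over iteration).
Since `FV⁻¹` is block upper-triangular with a zero lower-right diagonal
block, its nonzero spectrum comes from the upper-left block alone — used
as a structural test. Every NGM call also evaluates the factored closed
form (`R0 = R0,new · P(E→I)`, or the three-factor R_pred) and raises if
the two routes disagree beyond 1e-8 relative; the factorization rests on
the rank-one identity `ρ(uvᵀ) = |u·v|`.

Default evaluation points: SEIRS at S₀ = Λ/μ (or the user's S₀ for a
closed population); predator-prey at the prey-only equilibrium N = K, with
an override for arbitrary N. The immature-predation parameter η is
accepted but absent from R_pred — it affects neither adult fecundity nor
maturation, and the tests assert its absence. Threshold classification
treats |R - 1| ≤ 1e-9 as "marginal" rather than forcing a side.

## Verification machinery

The CTMC sampler draws the initial state from α (defects are refused),
exponential dwells per state, jumps from the embedded chain, and a final
absorbing label from the corresponding row of `C`; runs are
bit-reproducible under a fixed seed. Monte-Carlo comparisons use 20,000
samples and 3-standard-error acceptance bands (≲ 0.3% false-failure rate
per statistic); the standard error of the sampled coefficient of variation
is estimated by batch means (100 batches).

ODE trajectories use LSODA (stiff-capable) at rel_tol 1e-8 / abs_tol
1e-10; they are verification artifacts, not performance targets. The
equilibrium Jacobian is computed by central finite differences with step
`1e-6·max(1, |x_i|)` on the full right-hand side — the RHS is smooth
polynomial/rational, so the O(h²) error (~1e-12) is far below the
eigenvalue scales being classified, and one code path covers both model
families. Threshold concordance compares the sign of the leading Jacobian
eigenvalue at the DFE/prey-only equilibrium with the position of R
relative to 1; because R is linear in the transmission scale (β) and in
the conversion efficiency (χ), draws are placed at 0.9× and 1.1× the
critical value, and bisection on the eigenvalue sign is checked to land on
the closed-form critical parameter within 1e-6 relative.

## Random model generation

The fixture generator draws Erlang, hypoexponential, and Coxian blocks
with 1–5 substates, stage rates log-uniform on [0.2, 5] (dwell times of
order the time unit, spanning ~an order of magnitude each way), Coxian
continuation probabilities uniform on [0.3, 1], SEIRS mortality uniform on
[0.01, 0.3] (small to comparable against dwell rates, as for demographic
turnover against infection timescales), recruitment on [1, 10], and
transmission rates on [0.001, 0.05] per infectious substate; predator-prey
parameters sit in ranges (prey growth 0.5–2, K 50–500, predation 0.5–3,
half-saturation 20–200, conversion 0.05–0.8) that straddle R_pred = 1.
These draws emulate the structural variety of the theory — they are
synthetic parameterizations, not fits to any organism, so passing tests
establish the algebraic identities and threshold behaviour, not the
realism of any particular parameter set.

## Problem sizes

Equivalence sweeps use 100 random models per family, Erlang shape pairs up
to 6×6, 50 threshold draws, and 20,000 Monte-Carlo samples — sizes at
which the closed forms are exercised across the full structural variety
while the whole suite runs in seconds on one core.

## Known limitations

- Only the constant-recruitment disease-free equilibrium is built in;
  custom birth functions require a user-supplied equilibrium.
- Absorption probabilities and sampling refuse defective initial vectors
  rather than adopting a convention for mass absorbed at t = 0.
- No disease-induced mortality, spatial, or multi-host structure; no
  fitting of phase-type parameters to data; endemic equilibria and global
  stability are out of scope — only the R = 1 local threshold at the
  disease-free / prey-only equilibrium is analyzed.
- The stability verdict for closed populations (μ = 0) carries a neutral
  direction (total population is conserved), which reports as "marginal".
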