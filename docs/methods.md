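# Methods

## Model and assumptions

The package implements a two-species competition model in which density
dependence acts on immatures during maturation rather than on adults.
Offspring born at time `t − s` to adults of species `i` survive to
recruitment at time `t` with probability
`exp(−μ_i s − ∫ [a_i N_i + b_j N_j])`, where the competition integral runs
over the maturation interval; adults face only constant mortality `m_i`.
The maturation time `s` is random with a truncated-Erlang kernel: shape
`p_i ∈ ℕ⁺` (number of exponential maturation sub-stages), rate `β_i`, and a
hard cap `Δ_i` — individuals that have not matured by `Δ_i` never recruit.
The competition exposure of a cohort is approximated through the window
mean `f_i(t)`, the average adult density over the species' own maturation
window, scaled by `Δ_i`; the competitor's pressure therefore enters species
`i`'s recruitment as `Δ_i b_j f_j`, with `f_j` averaged over the
*competitor's* window `Δ_j`.

Because the kernel is Erlang, the delayed system converts exactly into a
finite chain of first-order stages (linear chain trick): per species, a
recruitment chain `x_{i,1..p_i}` at rate `(μ_i+β_i)/α_i` and a window-mean
chain `y_{i,1..p_i}` at rate `β_i/α_i`, where `α_i` is the Erlang mass
below `Δ_i` (the truncation renormalisation). State dimension is
`2(p_1+p_2+2)`.

Assumptions worth keeping in mind: adults do not compete; the birth rate is
density-independent at laying time; truncation removes (rather than
delays) the slowest maturers; and the cross-species competition window is
the focal species' own `Δ_i` applied to the competitor's window mean.

## Derived quantities and closed forms

All equilibrium structure reduces to three numbers per species:

* `α_i = 1 − e^{−β_iΔ_i} e_{p_i−1}(β_iΔ_i)` — kernel mass below the cap
  (identically the Erlang CDF at `Δ_i`);
* `τ_i = p_i α_i / β_i` — effective delay weight multiplying competition
  exposure;
* `A_i = ln(m_i/r_i) + p_i ln((β_i+μ_i)/β_i)` — log fitness deficit;
  survival in isolation requires `A_i < 0`, and the critical rate solving
  `A_i = 0` has the closed form `β* = μ/((r/m)^{1/p} − 1)`.

The growth nullclines are straight lines
`a_i τ_i N_i + ρ_{ij} b_j τ_j N_j = −A_i` with `ρ_{ij} = Δ_i/Δ_j`. The
window-ratio factor `ρ` is frequently dropped in quoted closed forms
(it is 1 in every symmetric worked example), but it is required for the
analytic equilibria to be fixed points of the chain ODEs when the two
truncation shifts differ, and the package keeps it throughout. Outcomes
follow textbook invasibility logic: species `i` invades the competitor's
boundary equilibrium iff `g_i > 0`, where `g_1 = ρ b_2 A_2 − a_2 A_1` and
`g_2 = b_1 A_1/ρ − a_1 A_2`; mutual invasibility under weak competition
(`a_1a_2 > b_1b_2`) gives a stable interior point, mutual non-invasibility
under strong competition gives bistability, one-sided invasibility gives
exclusion. The interior point itself is `N̄_i = g_i / (τ_i (a_1a_2 −
b_1b_2))`, which coincides with the 2×2 nullcline solve.

## Stability

The primary instrument is the analytic Jacobian of the chain system. Two
facts shape its use:

* The chain conserves `C_i = f_i − (α_i/(β_iΔ_i)) Σ_k y_{i,k}` per species
  — `f_i` is an integrator whose asymptotic value is selected by the
  initial history (both supported history conventions give `C_i = 0`,
  which is what pins `f̄_i = τ_i N̄_i/Δ_i`). Every equilibrium therefore
  carries two exact zero eigenvalues transverse to the invariant manifold.
  The stability decision discards the two eigenvalues nearest zero only if
  they are numerically zero (`|λ| < 1e−7`), so a genuinely marginal mode is
  never masked, and declares stability when the rest satisfy
  `Re λ < −1e−9`.
* The transcendental characteristic functions of the underlying delay
  system (extinction and boundary equilibria) are implemented for
  cross-verification only; their rightmost roots are located by a
  rectangular grid scan plus Newton polishing, with the structural root at
  `λ = 0` divided out. They represent the untruncated (`α → 1`) system, so
  they agree with the chain spectrum to `O(1 − α)` — about 1e−3 at the
  package's default 99th-percentile truncation — and sign agreement is what
  the tests assert.

## Numerical choices

* **Integration**: adaptive explicit Runge–Kutta of order 3
  (Bogacki–Shampine, scipy `RK23`), rtol 1e−6 / atol 1e−9 for
  trajectories. Steady-state detection integrates in windows (default 200
  time units) at rtol 1e−9 and stops when `‖rhs‖_∞ < 1e−8`; the tighter
  window tolerance is needed because solver wobble at 1e−6 sits above the
  convergence criterion. Extinction threshold on normalised density: 1e−6
  (three orders below the smallest equilibrium scales of interest, well
  above solver noise).
* **Kernels**: all hot-path formulas use the exponential-sum closed form
  for integer shape (Poisson-term recurrence, no overflow); the regularized
  incomplete gamma appears only in the truncated mean,
  `(p/β) P(p+1, βΔ)/P(p, βΔ)`, which is quadrature-verified. Percentile
  inversion is bracketed root finding on the Erlang CDF (tolerance 1e−10).
  Non-integer shapes are rejected: the chain needs an integer stage count.
* **Classification tolerances**: strict inequalities (survival, regime,
  invasibility) are evaluated with tolerance 1e−9; anything within
  tolerance of a frontier is labelled `degenerate` rather than silently
  assigned, so region-map pixels near boundaries are reproducible. The
  region scans share the exact same vectorised rule used by the scalar
  classifier.
* **Region maps**: default 200×200 grid over delay ratios [0.1, 8] with the
  truncation at the 99th percentile; purely analytic (no integration per
  cell), so a full scan takes well under a second. The discrete-delay
  companion map uses the limit values `α = 1`, `τ = p/β`,
  `A = ln(m/r) + μp/β`.

## Scenario fixtures and the interspecific-coefficient convention

`b_i` is stored on the species **exerting** the pressure (it multiplies
`f_i` in the competitor's equation). Published parameter sets are not
always quoted that way: the mosquito scenarios (`fig8*`) quote coefficients
per species experiencing the pressure, and the builtin fixtures swap them
accordingly — only that reading reproduces all the reported outcomes of
that example. Truncation shifts in the fixtures are always derived from the
percentile rule (99th unless the scenario varies it) rather than hard-coded.

## What the tests do and do not establish

The synthetic sweeps draw random valid parameter sets (r > m, shapes 1–3,
mean delays 0.5–6, competition coefficients up to 1.5) with the truncation
at the 99th percentile. Green tests establish internal consistency
(analytic equilibria are fixed points to 1e−10; stable-classified points
attract simulations to 1e−3; Jacobian, characteristic functions and
invasibility conditions agree) and reproduction of the published example
quantities. They do not validate the model against field data, nor cover
transient oscillations (visible after perturbations in the mosquito
example but deliberately not analysed), stochasticity, time-varying
parameters, or more than two species.

## Known limitations

* The characteristic-function route ignores truncation (`α = 1`); for
  shifts far below the 99th percentile its root locations drift from the
  chain spectrum.
* Bistable basins are probed with two mirrored initial conditions, not
  mapped.
* Near-degenerate settings (`|a_1a_2 − b_1b_2|` or an invasibility margin
  below ~1e−9, or `A_i ≈ 0`) are reported as `degenerate`; dynamics there
  are extremely slow and simulation-based labels may not converge within
  default horizons.
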