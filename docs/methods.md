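# Methods

## The model

`migrec` solves the discrete-time **migration–recombination equation
(MRE)**, a deterministic nonlinear dynamical system for the genetic
composition of a haploid population spread over a finite set of demes
`L`, in the law-of-large-numbers regime (infinite local populations, no
genetic drift, no selection or mutation). Genotypes are sequences over
sites `[n] = {1, …, n}` with a finite alphabet `A_i` per site; the state
is a metapopulation `μ_t = (μ_t(α))_{α∈L}`, one probability distribution
per deme on the product type space `A = A_1 × ⋯ × A_n`.

One generation is migration followed by recombination:

1. **Migration.** `μ_{t+1/2}(α) = Σ_β M(α,β) μ_t(β)`, where `M` is the
   *backward* migration matrix: `M(α,β)` is the probability that an
   individual now at `α` came from `β`. A forward matrix `M̃` with
   constant deme sizes `c` converts via `M(α,β) = c(β) M̃(β,α) / c(α)`;
   when the sizes are not constant under `M̃` the rows are renormalised
   (population regulation after migration) and a warning is logged.
2. **Recombination.** With probability `r_δ`, for `δ` a set partition of
   `[n]`, an offspring is pieced together from `|δ|` independent parents,
   inheriting the sites of each block from one parent; the deme's
   distribution becomes `Σ_δ r_δ ⊗_{d∈δ} ν^d`, a mixture of block-product
   measures of its own marginals. Partitions with more than two blocks
   are admitted (more than two parents); the distribution `r` is stored
   sparsely over its support.

Equivalently, one generation is a mixture of **labelled recombinators**:
`μ_{t+1}(α) = Σ_𝛅 p_𝛅(α) R_𝛅(μ_t)` where `𝛅` ranges over partitions with
a deme label per block, `R_𝛅(μ) = ⊗_{(d,λ)∈𝛅} μ^d(λ)`, and
`p_𝛅(α) = r_δ · Π_{(d,λ)} M(α,λ)`. Both forms are implemented
(`mre_step`, `mre_step_labelled`) and the tests assert their agreement —
the two independent code paths validate each other.

## Marginalisation consistency

The dynamics restricted to any site subset `U` is again an MRE, with
marginal recombination distribution `r^U_δ = Σ_{δ′: δ′|_U = δ} r_{δ′}`
and the same migration matrix. This consistency (step-then-marginalise =
marginalise-then-step) is the structural key to everything else and is
tested exhaustively over all site subsets on suites of random models.

## Haldane linearisation and the dual chain

Lifting the state to the vector `R(μ) = (R_𝛅(μ))_𝛅` of all labelled
recombinator values makes the evolution **linear**:
`R(μ_{t+1}) = T R(μ_t)` for a stochastic matrix `T` on labelled
partitions, so `μ_t` is read off the single-block components of
`T^t R(μ_0)`. `T` is the transition matrix of the **labelled
partitioning process (LPP)**: backward in time, each labelled block
`(d, λ)` independently splits according to `r^d` and every fragment is
relabelled by one step of `M(λ,·)` — splitting before relabelling,
because forward time runs migration before recombination. Because there
is no coalescence in this regime, the base partition only ever refines
and the ancestral graph is a tree.

The extracted source text displays the entries of `T` illegibly, so the
package constructs them in two independent ways and asserts entrywise
equality: the product over blocks of marginal migration–recombination
probabilities (`build_T`), and the factorisation into the unlabelled
matrix times migration entries,
`T_{𝛅𝛆} = T^ul_{δε} Π_{(d,λ)∈𝛅} Π_{(e,γ)∈𝛆|_d} M(λ,γ)`
(`build_T_factorised`), with
`T^ul_{δε} = Π_{d∈δ} r^d_{ε|_d}` for `ε ≼ δ` (`build_T_unlabelled`).

Duality gives the stochastic representation
`μ_t(α) = E[R_{Σ_t}(μ_0) | Σ_0 = {([n], α)}]`, which `duality_estimate`
evaluates by Monte Carlo; the recombinator value depends on a trajectory
only through its final state, so values are cached per visited state and
per-cell standard errors come from the empirical state distribution.

## Asymptotics

With `M` primitive (checked by boolean matrix powers up to the Wielandt
bound `(|L|−1)² + 1`) and a recombination support whose meet is the
all-singleton partition (separability), `μ_t` converges geometrically to
spatial stationarity and linkage equilibrium: every deme receives
`⊗_i Σ_β q(β) μ_0^{i}(β)` with `q` the stationary law of `M`. A
non-separating support raises by default; `collapse_clusters` merges
never-separated site clusters into super-sites (product alphabets),
restoring the hypothesis.

Conditioned on non-absorption, the unlabelled chain settles on the set
`F` of reachable states with maximal sojourn probability
`η = max_δ T^ul_{δδ}`. Sojourn probabilities are *not* monotone along
refinement paths — the shipped four-site fixture (`r` = 1/2 on
singletons, 1/10 on `{{1,2},{3,4}}`, 2/5 on the one-block partition) has
sojourns 2/5 → 1/4 → 1/2 along one path, with `F` the two partitions
{{1,2},{3},{4}} and {{1},{2},{3,4}} and quasi-limiting law (1/2, 1/2).
The law is computed exactly from hitting-time functionals
`h_δ(ε) = E_ε[η^{−τ_δ}; τ_δ < ∞]`: since the chain only refines, a
single sweep from finest to coarsest solves
`h_δ(ε)(1 − T^ul_{εε}/η) = η^{−1} Σ_{ε′≺ε} T^ul_{εε′} h_δ(ε′)`
explicitly; from an `F` state the chain can only stay or absorb (the
stay-or-absorb identity `T^ul_{δδ} + T^ul_{δ0} = 1`, verified on every
member), so distinct `F` states are never both hit and the normaliser is
a plain sum. The labelled quasi-limiting law is the unlabelled law times
independent stationary labels `Π q(λ)`. An exact finite-`t` oracle
(`conditional_law_exact`) powers the substochastic restriction of
`T^ul` and conditions on survival.

## Continuous time

The continuous-time variant replaces `r` by nonnegative rates `ϱ_δ` and
`M` by a Markov generator `N` over demes:
`ω̇_t(α) = Σ_β N(α,β) ω_t(β) + Σ_δ ϱ_δ (R_δ − Id) ω_t(α)`.
The dual LPP generator `Q` splits one labelled block at marginal rate
`ϱ^d` (fragments keep their label) or relabels one block at rate `N`;
`ω_t` is read off `exp(tQ)` applied to the recombinator vector. A rate
on the one-block partition is a no-op (`R_top = Id`) and is dropped with
a logged note. Two solvers (`expm` via `scipy.linalg.expm`, `ode` via
adaptive RK with rtol 1e-9) act as mutual oracles; a two-site closed
form integrates the exponential splitting time by adaptive quadrature
(`scipy.integrate.quad_vec`, abs. tol. 1e-9).

## Numerical choices

- **Canonical forms everywhere.** Blocks are sorted tuples, blocks sort
  by smallest element, enumeration follows restricted-growth-string
  order, labels follow declared deme order; all matrices share this
  stable indexing and runs are bit-reproducible.
- **Dual numeric modes.** Probability data is float64 by default;
  recombination weights may be `fractions.Fraction` (accepted as
  `"p/q"` strings in model files), in which case marginals, `T^ul`,
  sojourn probabilities and the quasi-limiting law are exact. Migration
  matrices are floats; entries exactly equal to 1 (forced labels) do not
  degrade Fraction weights, so single-deme quantities stay exact.
- **Per-step renormalisation.** Recombination forms products of block
  masses, so a float mass error `ε` becomes `≈ |δ|·ε` per generation and
  an orbit would lose all mass by `t ≈ 50`; each recombination step
  therefore renormalises each deme's table (exact mode is untouched).
  Singleton-block factors in `T^ul` are skipped — their marginal is the
  unit mass by construction — keeping the absorbing row exactly a unit
  vector.
- **Measure-valued vectors, not one giant matrix.** `T` (dimension
  `Σ_δ |L|^{|δ|}`, e.g. 94 for four sites and two demes) acts on an
  `(states × |A|)` array; nothing of size `|A| × |A|` is ever formed.
  Matrix powers are iterated multiplications — `t` is small and
  exactness beats eigendecompositions here.
- **RNG.** All samplers take integer seeds; replicate streams are
  spawned via `numpy.random.SeedSequence` (one child per trajectory) and
  block decisions within a step consume the stream in canonical block
  order, so results are reproducible regardless of replicate count.
- **Size caps.** Exhaustive enumeration is capped (10 sites for
  partitions, 2·10⁵ labelled states, 10⁶ product-space cells);
  exceeding a cap raises, never truncates.

## What the synthetic models emulate

`generate_random_model` draws Dirichlet recombination weights over a
random partition support, Dirichlet migration rows, and Dirichlet
initial tables, deterministically in the seed. Two standing assumptions
of the limit theory are enforced by construction: the all-singleton
partition always carries mass ≥ 0.05 (so recombination separates every
site pair) and migration rows are strictly positive (so `M` is primitive
with witness 1). These models exercise every code path at the scales the
exact linear algebra can verify (n ≤ 4, |L| ≤ 2, ≤ 94 labelled states);
they are *not* calibrated to any organism — real linkage maps
concentrate `r` on single-crossover partitions, real migration matrices
are sparse and nearly reducible, and real alphabets are larger. Passing
tests therefore demonstrate the mathematical identities (linearisation,
duality, marginal consistency, quasi-limits), not biological realism.

## Problem sizes used in the shipped checks

The verification suites use 25 random models (n ∈ {2,3,4}, 1–2 demes)
for the linearisation and marginalisation identities, 10⁴ replicates for
the duality Monte Carlo at t = 5 (4-SE cellwise criterion), 10⁵
trajectories with rejection on absorption at horizon t = 8 for the
conditional-law simulation (the horizon is set so that the exact
survival probability, 6.7·10⁻³, leaves ≈ 670 survivors — conditioning at
much larger horizons is unreachable by rejection sampling since survival
decays like η^t = 2⁻ᵗ on the fixture), and exact matrix powers at
t = 300 (unlabelled) and t = 60 (labelled) for the quasi-limiting
convergence statements.

## Known limitations

- Dense type-space tables: memory is `Π|A_i|` per deme; tens of sites
  are out of reach for the exact solvers (the Monte-Carlo simulator has
  no such limit on `n` through the partition states it visits, but
  recombinator evaluation is still dense).
- Quasi-limiting laws are computed for a single start partition;
  mixtures of starts are not supported.
- No selection, mutation, drift, or coalescence; overlapping
  generations and continuous site spaces are out of scope.
- The continuous-time module has no quasi-stationary analysis.
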