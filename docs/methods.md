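# Methods

## Model

The package simulates communities of `S` consumers coupled to `M`
substitutable resources. All interactions are resource-mediated: species
import energy, pay a maintenance cost, grow on the surplus, and leak a
fraction of imported energy back into the environment as byproducts. The
dynamical law is assembled from three independent mode selectors:

- **response** — how uptake depends on concentration: `type1` (linear,
  `σ(x) = x`), `type2` (Monod, `x/(1 + x/σ_max)`), `type3` (Hill,
  `xⁿ/(1 + xⁿ/σ_max)`, `n > 1`). For type3 with non-integer `n` we define
  `0ⁿ = 0`, keeping `σ` continuous at the origin.
- **regulation** — optional reweighting of import capacity toward the
  currently richest resource: `energy` weights `∝ (w_α c_iα R_α)^n_reg`,
  `biomass` weights `∝ (c_iα R_α)^n_reg`, both normalized per species using
  that species' own uptake row; `off` applies no reweighting (weights are
  identically 1, not 1/M). If the environment is entirely empty the weights
  are taken uniform by convention.
- **supply** — `external` (linearized chemostat, timescale `τ_α`, supply
  point `R⁰_α`), `self_renewing` (logistic, rate `r_α`), or `off` (closed
  community).

Energy accounting is the structural core: per species,
`J^in_total = J^grow + J^out_total` holds identically because the metabolic
matrix `D` is column-stochastic. A direct consequence (used as a test
invariant) is that with supply off the Lyapunov-like quantity
`Σ_i N_i/g_i + Σ_α w_α R_α` decays at rate `Σ_i m_i N_i ≥ 0`: secretion
cannot create energy.

`σ` is applied elementwise to `c_iα R_α` — uptake pathways are independent;
there is no cross-resource saturation. Per-well parameter heterogeneity is
supported by passing a list of parameter sets, and fully custom dynamics by
passing an `rhs(N, R, params)` callable with a dictionary declaring each
parameter's dimensions (`S`, `M`, `SxM`, `SxS`, `MxM`) so extinct-species
compression can slice the species axis.

## Random ecosystems

The sampler draws the uptake matrix `c` (one row-major block) and then the
metabolic matrix `D` (column by column) from numpy's PCG64 generator, so a
seed fixes the ecosystem bit-for-bit. Layout conventions: resources ordered
by class (class 0 first), species ordered by family with generalists last,
waste class defaulting to the last class; labels carry these identities
(`T2_R5`, `F0_S3`, `GEN_S1`).

Uptake rows are parameterized by the mean `μ_c` and variance `σ_c²` of the
row sum, with a specialism parameter `q ∈ [0, 1]` shifting both mean and
variance onto the family's preferred class (factor `1 + q(M−M_A)/M_A`
on-class, `1 − q` off-class). Three distribution families share these
moments: gaussian (entries may be negative; kept as sampled, with an
optional clip-at-zero flag defaulting to off), gamma (two-moment match,
shape `mean²/var`, scale `var/mean`; requires strictly positive target
means, so `q = 1` specialists are rejected), and binary (`c₀/M` or
`c₀/M + c₁` with Bernoulli probabilities matching the same structure;
probabilities above 1 are rejected as an inconsistent `μ_c, c₁, M`
combination).

Columns of `D` are Dirichlet draws whose concentrations implement a
three-tier secretion structure: a fraction `f_w` of secreted flux goes on
average to a designated waste class, `f_s` to the input's own class, the
remainder elsewhere; the overall concentration scale is `1/s`, so `s → 0`
gives dense near-expected allocations and `s → 1` concentrates each column
on few products. Columns whose input is itself in the waste class merge the
first two tiers. Tiers with zero Dirichlet concentration produce exact
zeros; a nonzero tier fraction pointing at an empty tier is an error.

Initial plates seed each well with a uniformly random subset of exactly `S`
species at abundance 1 and a single supplied carbon source (identity and
quantity configurable per well). The supplied quantity defaults to the same
`R0_food` that defines the supply point of that resource; both are
overridable.

### Defaults for non-sampled parameters

The non-sampled parameters carry package defaults, uniform across species
and resources and all overridable: `g = 1` (1/energy), `m = 1`
(energy/time), `w = 1` (energy/mass), `τ = 1` (time), `r = 1`
(volume/mass/time), `l = 0` (no leakage unless requested), `n = 2`,
`n_reg = 10`, `σ_max` unset (required only for type2/type3). These are
conventions, not fitted values; every scenario that ships with the package
states its own values.

## Propagation and passaging

`Propagate` integrates each well independently with LSODA
(stiff/non-stiff switching), default tolerances rtol 1e-8 / atol 1e-10,
configurable. Before integration, species at exactly zero abundance are
removed together with the matching slices of every parameter array and
restored as exact zeros afterwards; this prevents solver round-off from
letting an extinct species with positive invasion fitness "self-seed". Small
negative values within tolerance are clipped to zero; larger ones raise an
error naming the well. Wells are processed serially; results are independent
of well order by construction.

`Passage` converts abundances to cell counts with a conversion factor
`scale` (default 1e6), forms the expected transferred counts
`scale · Σ_ν f_μν N_iν` for transfer matrix `f`, and draws one multinomial
per destination well with total count equal to the rounded total expected
count and probabilities proportional to the per-species expectations. This
contract preserves the total cell count exactly and each species'
expectation, and fixes populations with expected counts well below one cell
at zero — the only demographic noise in the simulator (none is added during
propagation). Resources are treated as continuous: they mix linearly through
`f` and are not discretized. With `refresh_resource` on, the stored
fresh-medium profile of the destination well (the plate's initial resource
table) is added on top of the transferred resources — batch-culture
semantics: fresh medium plus inoculum.

The stepping-stone transfer matrix places `f₀(1−m)` on the diagonal and
`f₀·m/2` on both off-diagonals; edge wells keep `f₀(1−m)` and send `f₀·m/2`
to their single neighbor, the other half being lost (absorbing boundary).

`run_experiment` alternates passage → propagate for `np` rounds, recording a
timestamped snapshot after each propagation.

## Direct equilibrium computation

For type-I response without regulation, noninvadable steady states coincide
with constrained minima of an environmental dissimilarity `d(R⁰, R)` over
the convex region where every species' per-capita growth rate is ≤ 0, with
the equilibrium abundances appearing as the Lagrange multipliers of the
growth constraints. For external supply `d` is the weighted KL divergence
`Σ_β w_β τ_β⁻¹ [R⁰_β ln(R⁰_β/R_β) − (R⁰_β − R_β)]`; for self-renewing supply
it is `Σ_β w_β r_β (R⁰_β − R_β)²`. In the quadratic case the multipliers of
this objective are `2N*` (the gradient carries a factor 2), so the solver
rescales the duals by 1/2; the self-renewing path is implemented for
`l = 0` only, where no effective-supply correction is needed.

With leakage, byproducts break the symmetry the duality requires. It is
restored by the matrix `Q_αβ = δ_αβ − l_β D_αβ w_β/w_α`: substituting the
steady-state resource balance `Σ_β Q_αβ φ_β = τ_α⁻¹(R⁰_α − R_α)` (where
`φ_β` is the total uptake of resource β) into the stationarity conditions
gives a KL objective in an effective supply point

    R̃⁰_α = R⁰_α + Σ_{β≠α} (Q⁻¹_αβ τ_β⁻¹)/(Q⁻¹_αα τ_α⁻¹) (R⁰_β − R*_β)

with weights `w̃_α = Q⁻¹_αα (1−l_α) w_α / τ_α`, for which the duals are
exactly `N*`. (The ratio uses the row diagonal `Q⁻¹_αα`, and the weights
`w̃` already include the `τ⁻¹` factor — both facts fall out of the
derivation above and are verified end-to-end by the solver-vs-integration
equivalence tests.) A singular `Q` means the leakage-weighted recycling
amplifies energy and is rejected as unphysical. With `l = 0`, `Q` is the
identity, `R̃⁰ = R⁰`, and the whole correction disappears.

Since `R̃⁰` depends on the unknown `R*`, the solver runs an
expectation-maximization loop: E-step `R̃⁰ ← α R̃⁰(R*) + (1−α) R̃⁰_prev`
(learning rate `α`, default 0.5 — the damping keeps the KL arguments
positive at low supply, where the undamped update can go transiently
negative), M-step: minimize `d(R̃⁰, ·)` over the noninvadable region.
Convergence is declared when the max-norm change of both `R̃⁰` and `R*`
falls below the tolerance `δ` (default 1e-7); with `l = 0` the loop
terminates after one iteration. Hitting the iteration cap (default 1000)
returns a flagged non-converged result rather than raising, so batch sweeps
survive pathological draws.

### The constrained step

The package solves the M-step through its explicit Lagrangian dual rather
than a generic conic solver. Minimizing the Lagrangian over `R` at fixed
multipliers `λ ≥ 0` has a closed form — `R_β(λ) = R̃⁰_β / (1 + (Gᵀλ)_β/w̃_β)`
for the KL objective, `R_β(λ) = max(0, R⁰_β − (Gᵀλ)_β/(2 w_β r_β))` for the
quadratic one, where `G_iβ = (1−l_β) w_β c_iβ` — leaving a smooth concave
dual whose gradient is simply the vector of growth rates at `R(λ)`. The
dual is maximized by projected L-BFGS-B and then polished by an active-set
Newton iteration on the stationarity conditions `growth_i(R(λ)) = 0` (the
dual Hessian is closed-form and negative definite on the active set), which
drives complementary slackness `N_i · growth_i` to near machine precision.
Only species present in the well enter the constraint set, so absent species
cannot acquire positive duals. A positivity floor of 1e-12 is applied inside
KL logarithms as a numerical guard; components with `R̃⁰_β ≤ 0`
(transiently possible mid-loop) are treated as zero-supply and pinned at
`R_β = 0` during that M-step.

### Initialization and bistability

When external supply cannot directly sustain any consumer, the model is
bistable: a consumer-free equilibrium (`R* = R̃⁰ = R⁰`) coexists with a
byproduct-sustained community. The EM fixed point found depends on the
initial `R̃⁰`. The default initialization is the E-step evaluated at
`R* = 0` — the "depleted environment" supply point
`R⁰ + offdiag-ratio · R⁰` — which is deterministic, reduces to exactly `R⁰`
when `l = 0`, and generically lands in the surviving-community basin.
Initializing explicitly at `R⁰` (`R0_eff_init=params.R0`) selects the
consumer-free branch. A small random perturbation of `R⁰` is *not* a
workable generic initialization: if all growth rates at `R⁰` are negative,
the M-step returns no survivors and the damped E-step contracts straight
back to the extinct fixed point.

Equilibrium abundances do not depend on `g_i` (it rescales rates, not fixed
points), and the reported residual is the RMS per-capita growth rate
(`g`-scaled) over survivors.

## Analysis

`alpha_diversity` reports per well: richness above a threshold (default 0 —
exact zeros exist after passaging by construction), Shannon entropy of
relative abundances (natural log by default, base exposed), Simpson index
`Σ p²`, and the effective species number `exp(H)`. Empty wells report
richness 0, Shannon 0 and Simpson 0 by convention. All measures except
richness are invariant under abundance rescaling. `flux_network` evaluates
the energy-flux bookkeeping at a state and returns a directed graph with
resource→species uptake edges and species→resource secretion edges
(population-level fluxes `N_i J^in_iα`, `N_i J^out_iβ`), exportable as an
edge-list table.

## Scenario suite and what the tests show

Shipped scenarios pin every unprinted choice: the structured-families
scenario (3 specialist families of 25 + 25 generalists, 90 resources in 3
classes, `q = 0.9`, `s = 0.05`, `f_w = f_s = 0.49`); the equilibrium
benchmark (binary uptake, `S = S_tot = M`, single supplied resource with
supply point `10·M`, `μ_c = 5` so uptake probabilities stay below 1 at
`M = 10`, leakage 0.8); the range-expansion scenario (stepping stone,
`f₀ = 0.1`, `m = 0.25`, one inoculated well); and a hand-built two-resource
bistable cross-feeder (supply `1.5` with maintenance 1 and leakage 0.5, so
direct growth is impossible while a byproduct-sustained state exists).

The solver-vs-integration equivalence suite runs `M = S ∈ {10, 20, 40}` with
10 scenario seeds each, comparing the EM equilibrium against `T = 10⁴`
integration broken into 10 rounds separated by identity passages (scale
1e12, so dying species are zeroed while demographic noise stays negligible).
Survivors are defined as ODE abundances above 1e-4: true survivors in these
scenarios are O(1e-2) and larger, while finite-time integration leaves
residues of slowly dying species (decay rates down to ~1e-3) up to a few
1e-5. Agreement is required to 1e-3 relative on surviving abundances and all
resource concentrations; measured deviations are at the 1e-6 level, and the
EM residual (≲1e-15) sits far below the integrator's own growth-rate
residual.

The synthetic generator emulates block-structured uptake preferences,
tiered secretion, and single-carbon-source batch culture. It does not
emulate phylogenetic trait correlation beyond the family/class blocks,
fitted genome-scale metabolism, within-propagation demographic noise, or
spatial structure beyond well-to-well transfer — so passing tests certify
the simulator's internal contracts (conservation laws, duality, sampling
moments, passage statistics), not the fidelity of any particular biological
system.

## Known limitations

- Direct equilibration covers type-I response without regulation only
  (elsewhere the feasible region is non-convex); use propagation for
  type-II/III or regulated models. Self-renewing equilibration additionally
  requires `l = 0`.
- The multinomial passaging contract (one joint draw per destination well,
  total fixed to the rounded expected total) is one of several defensible
  discretizations; expectations match in either case, but exact random
  streams differ from implementations that draw species independently.
- Gaussian uptake sampling can produce negative rates; they are kept unless
  clipping is requested, and the gamma family is the positivity-safe choice.
- No eigenvalue-based stability classification is performed; returned
  equilibria are certified noninvadable, not asymptotically stable in the
  Jacobian sense.
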