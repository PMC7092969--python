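# microcrm

Simulation of microbial community dynamics with cross-feeding, built around
the Microbial Consumer Resource Model (MicroCRM) and the experimental logic
of multi-well batch culture. The package is aimed at microbial ecologists who
want reproducible *in silico* analogues of serial-dilution and plate
experiments: structured random ecosystems, propagation and passaging of
virtual plates, and a fast solver that finds noninvadable equilibria directly
instead of integrating through long transients.

## The model

`S` consumer species interact with `M` substitutable resources only through
uptake and secretion. Species `i` imports energy from resource `α` at rate
`J^in_iα = w_α u_iα σ(c_iα R_α)`, where `c_iα` is its uptake rate, `w_α` the
resource's energy density, `σ` a linear (type-I), Monod (type-II) or Hill
(type-III) response, and `u_iα` optional metabolic-regulation weights. A
fraction `l_α` of the imported energy leaks back out as byproducts,
partitioned among resources by a column-stochastic metabolic matrix `D`; the
rest drives growth against a maintenance cost `m_i`:

    dN_i/dt = g_i N_i [ Σ_α (1−l_α) w_α u_iα σ(c_iα R_α) − m_i ]
    dR_α/dt = h_α(R_α) − Σ_j N_j u_jα σ(c_jα R_α)
              + Σ_jβ N_j u_jβ σ(c_jβ R_β) l_β D_αβ w_β / w_α

with intrinsic resource dynamics `h` either chemostat-like
(`(R⁰_α − R_α)/τ_α`), logistic (`r_α R_α (R⁰_α − R_α)`), or off (a closed
community). Because columns of `D` sum to one, energy is conserved per
species (`J^in = J^grow + J^out`), so closed communities can only dissipate —
no bootstrapping from secretion loops. With type-I response and `l = 0` the
model reduces exactly to MacArthur's classic consumer resource model.

Random ecosystems are generated from a compact assumptions ledger: resources
fall into `T` classes, species into specialist families (specialism `q`) plus
generalists, and `D` follows a three-tiered secretion structure (waste class
fraction `f_w`, same-class fraction `f_s`, sparsity `s`) with Dirichlet
columns.

## Direct equilibration

For type-I response without regulation, every stable noninvadable state
minimizes a dissimilarity `d(R⁰, R)` — a weighted KL divergence for external
supply, a weighted squared distance for self-renewing supply — over the
convex region where no species can grow; the equilibrium abundances `N*` are
the Lagrange multipliers of the growth constraints. Byproducts shift the
relevant supply point to an effective `R̃⁰(R*)` through the matrix
`Q = I − l_β D_αβ w_β/w_α`, and the solver iterates an expectation-
maximization loop (damped `R̃⁰` update, then constrained minimization) until
self-consistent. The constrained step is solved through its explicit
Lagrangian dual, so complementary slackness holds to solver precision.

## Worked example

```python
import numpy as np
from microcrm import *

a = Assumptions(M=12, T=3, S_tot=30, F=3, S=10, S_gen=3, S_A=[9, 9, 9],
                muc=4.0, sigc=1.0, c1=1.0, q=0.7, s=0.2, fw=0.4, fs=0.3,
                l=0.6, R0_food=50.0, sampling_family="binary")
params = make_params(a, rng_seed=0)
state = make_initial_state(a, n_wells=2, rng_seed=1)

plate = Plate(state, params, DynamicsSpec(), seed=2)
snaps = plate.run_experiment(f=0.02 * np.eye(2), T=24.0, np_iter=6)
print(alpha_diversity(plate.state).round(3))

results = plate.steady_state()
for well, res in zip(plate.state.wells, results):
    print(f"{well}: {int((res.N_star > 0).sum())} survivors, "
          f"{res.iterations} iterations, residual {res.residual:.2e}")
```

Output:

    well  richness  shannon  simpson  effective_species
    W0           5    1.057    0.418              2.876
    W1           3    0.689    0.613              1.991
    W0: 4 survivors, 25 iterations, residual 1.57e-16
    W1: 3 survivors, 25 iterations, residual 1.28e-16

Each of the two wells starts from 10 random colonists on a single carbon
source and is diluted 1:50 into fresh medium every 24 h for six rounds.
Competitive exclusion prunes the communities to 5 and 3 species with the
reported Shannon/Simpson diversity; the equilibrium solver then identifies
the true long-term survivors (4 and 3) directly, with root-mean-square
per-capita growth rates of the survivors at the 1e-16 level — far below what
ODE integration reaches.

A command-line interface mirrors the library
(`microcrm init | propagate | passage | run | steady-state | fixtures`);
state moves between calls as labeled CSV/JSON files.

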