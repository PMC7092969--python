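"""Direct equilibrium computation via convex duality and expectation-maximization.

For the MicroCRM with linear (type1) uptake and no metabolic regulation,
every stable, noninvadable steady state minimizes a dissimilarity d(R0, R)
between the resource environment R and the unperturbed supply point R0,
subject to every species' per-capita growth rate being <= 0; the equilibrium
abundances N* are the Lagrange multipliers of the growth constraints.  For
externally supplied resources d is a weighted KL divergence, for
self-renewing resources a weighted squared distance.

Byproduct secretion (leakage l > 0) breaks the symmetry this duality needs.
It is restored by replacing R0 with an effective supply point R~0(R*) that
absorbs the byproduct flux, computed through the matrix
Q = I - l_b D_ab w_b / w_a.  Since R~0 depends on the unknown equilibrium,
the solver iterates an EM loop: the E-step updates R~0 from the current R*
(with a damped/learning-rate update that keeps the KL arguments positive),
and the M-step solves the constrained minimization at fixed R~0.

The M-step is solved through its explicit Lagrangian dual: the inner minimum
over R is available in closed form, leaving a smooth concave maximization
over the nonnegative multipliers, handled by projected quasi-Newton ascent
plus an active-set Newton polish that drives complementary slackness to
solver precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .dynamics import DynamicsSpec
from .params import ModelParams

__all__ = [
    "QMatrix",
    "EquilibriumResult",
    "q_matrix",
    "dissimilarity",
    "effective_supply",
    "effective_weights",
    "constrained_minimize",
    "steady_state",
    "plate_steady_state",
]

_LOG_FLOOR = 1e-12  # positivity floor inside KL logarithms (numerical guard)


@dataclass
class QMatrix:
    """Byproduct bookkeeping matrix Q_ab = delta_ab - l_b D_ab w_b / w_a and its inverse."""

    Q: np.ndarray
    Q_inv: np.ndarray


def q_matrix(params: ModelParams) -> QMatrix:
    """Build Q and its inverse; with l = 0, Q is the identity.

    A singular Q signals that recycling amplifies energy (spectral radius of
    l*D weighting >= 1), which energy conservation forbids for l < 1.
    """
    p = params
    M = p.n_resources
    A = (1.0 / p.w)[:, None] * p.D * (p.l * p.w)[None, :]
    Q = np.eye(M) - A
    try:
        Q_inv = np.linalg.inv(Q)
    except np.linalg.LinAlgError as e:
        raise ValueError(
            "Q is singular: byproduct recycling l*D amplifies energy"
        ) from e
    if not np.all(np.isfinite(Q_inv)) or np.linalg.cond(Q) > 1e12:
        raise ValueError("Q is numerically singular")
    return QMatrix(Q=Q, Q_inv=Q_inv)


def dissimilarity(
    R0: np.ndarray,
    R: np.ndarray,
    weights: np.ndarray,
    supply_mode: str = "external",
) -> float:
    """Environmental dissimilarity d(R0, R).

    external: sum_b weights_b [R0_b ln(R0_b/R_b) - (R0_b - R_b)], a weighted
    KL divergence (weights typically w_b / tau_b); self_renewing:
    sum_b weights_b (R0_b - R_b)^2.  Both are >= 0, vanishing iff R == R0.
    """
    R0 = np.asarray(R0, dtype=float)
    R = np.asarray(R, dtype=float)
    weights = np.broadcast_to(np.asarray(weights, dtype=float), R0.shape)
    if supply_mode == "self_renewing":
        return float(weights @ (R0 - R) ** 2)
    if supply_mode != "external":
        raise ValueError(f"no dissimilarity defined for supply mode {supply_mode!r}")
    if np.any(R0 < 0):
        raise ValueError("KL dissimilarity requires nonnegative R0")
    if np.any(R[R0 > 0] <= 0) or np.any(R < 0):
        raise ValueError("KL dissimilarity requires positive R where R0 > 0")
    terms = np.zeros_like(R0)
    pos = R0 > 0
    terms[pos] = R0[pos] * np.log(R0[pos] / np.maximum(R[pos], _LOG_FLOOR))
    terms -= R0 - R
    return float(weights @ terms)


def effective_supply(
    R_star: np.ndarray,
    R0: np.ndarray,
    Q: QMatrix,
    tau: np.ndarray | None = None,
) -> np.ndarray:
    """Effective unperturbed supply point R~0(R*) absorbing byproduct flux.

    R~0_a = R0_a + sum_{b != a} [Qinv_ab / tau_b] / [Qinv_aa / tau_a] (R0_b - R*_b).
    With l = 0 (Q = I) this is exactly R0; at R* = R0 it is R0 for any Q.
    """
    R0 = np.asarray(R0, dtype=float)
    R_star = np.asarray(R_star, dtype=float)
    M = R0.size
    tau = np.ones(M) if tau is None else np.asarray(tau, dtype=float)
    A = Q.Q_inv / tau[None, :]
    diag = np.diag(A)
    if np.any(np.abs(diag) < 1e-300):
        raise ValueError("vanishing diagonal in Q inverse")
    ratio = A / diag[:, None]
    delta = R0 - R_star
    # ratio has unit diagonal, so subtract the diagonal term from the full product
    return R0 + ratio @ delta - delta


def effective_weights(params: ModelParams, Q: QMatrix) -> np.ndarray:
    """Objective weights w~_a = Qinv_aa (1 - l_a) w_a / tau_a for the byproduct KL."""
    p = params
    return np.diag(Q.Q_inv) * (1.0 - p.l) * p.w / p.tau


def _growth_matrix(params: ModelParams, species_idx: np.ndarray) -> np.ndarray:
    """Rows G_i = (1 - l) * w * c_i: per-capita energy-uptake gradient wrt R."""
    p = params
    return (1.0 - p.l)[None, :] * p.w[None, :] * p.c[species_idx, :]


def _dual_R_external(lam, G, R0_eff, a):
    """Closed-form inner minimizer R(lambda) of the Lagrangian, KL case."""
    load = (G.T @ lam) / a
    return np.maximum(R0_eff, 0.0) / (1.0 + load)


def _dual_R_quadratic(lam, G, R0_eff, a):
    """Closed-form inner minimizer, squared-distance case (R clipped at 0)."""
    return np.maximum(R0_eff - (G.T @ lam) / (2.0 * a), 0.0)


def constrained_minimize(
    R0_eff: np.ndarray,
    params: ModelParams,
    weights: np.ndarray | None = None,
    species_idx: np.ndarray | None = None,
    supply_mode: str = "external",
    tol: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray]:
    """Minimize d(R0_eff, R) subject to all per-capita growth rates <= 0.

    Solved in the dual: the Lagrangian minimum over R is closed-form, and the
    resulting concave dual of the multipliers lambda >= 0 is maximized by
    L-BFGS-B followed by an active-set Newton polish so that complementary
    slackness N_i* . growth_i holds to near machine precision.  Returns
    (R_star, N_star) with N_star the equilibrium abundances (the multipliers;
    halved in the quadratic case, whose gradient carries a factor 2).

    Only defined for type1 response without regulation (the convex case).
    """
    p = params
    R0_eff = np.asarray(R0_eff, dtype=float)
    if species_idx is None:
        species_idx = np.arange(p.n_species)
    species_idx = np.asarray(species_idx, dtype=int)
    if supply_mode == "external":
        if weights is None:
            weights = effective_weights(p, q_matrix(p))
        dual_R = _dual_R_external
    elif supply_mode == "self_renewing":
        if np.any(p.l > 0):
            raise ValueError(
                "self-renewing equilibria are only supported without leakage"
            )
        if weights is None:
            weights = p.w * p.r
        dual_R = _dual_R_quadratic
    else:
        raise ValueError(f"unsupported supply mode {supply_mode!r}")
    a = np.asarray(weights, dtype=float)
    if np.any(a <= 0):
        raise ValueError("objective weights must be positive")
    G = _growth_matrix(p, species_idx)
    m = p.m[species_idx]
    S_a = species_idx.size
    if S_a == 0:
        return np.maximum(R0_eff, 0.0), np.zeros(p.n_species)

    R0c = np.maximum(R0_eff, 0.0)

    def d_of(R):
        if supply_mode == "self_renewing":
            return float(a @ (R0c - R) ** 2)
        pos = R0c > 0
        terms = np.zeros_like(R0c)
        terms[pos] = R0c[pos] * np.log(R0c[pos] / np.maximum(R[pos], _LOG_FLOOR))
        terms -= R0c - R
        return float(a @ terms)

    def growth(R):
        return G @ R - m

    def neg_dual(lam):
        R = dual_R(lam, G, R0c, a)
        val = d_of(R) + lam @ growth(R)
        return -val, -growth(R)

    res = minimize(
        neg_dual,
        np.zeros(S_a),
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * S_a,
        options={"maxiter": 2000, "ftol": 1e-16, "gtol": 1e-10},
    )
    lam = np.maximum(res.x, 0.0)

    lam = _newton_polish(lam, G, m, R0c, a, dual_R, supply_mode, tol)

    R_star = dual_R(lam, G, R0c, a)
    N_star = np.zeros(p.n_species)
    N_star[species_idx] = lam / 2.0 if supply_mode == "self_renewing" else lam
    return R_star, N_star


def _newton_polish(lam, G, m, R0c, a, dual_R, supply_mode, tol, max_iter=100):
    """Active-set Newton on the dual stationarity conditions growth_i = 0.

    The dual Hessian is available in closed form and negative definite on the
    active set; inactive multipliers stay pinned at zero and are reactivated
    if their constraint turns violated.
    """
    S_a = lam.size
    for _ in range(max_iter):
        R = dual_R(lam, G, R0c, a)
        g = G @ R - m
        active = (lam > 1e-12) | (g > tol)
        if not active.any():
            break
        if np.max(np.abs(g[active])) <= tol and np.all(g <= tol):
            break
        idx = np.flatnonzero(active)
        Ga = G[idx]
        if supply_mode == "external":
            load = (G.T @ lam) / a
            # dR_b/dlam_j = -R0c_b G_jb / (a_b (1 + load_b)^2)
            w_b = R0c / (a * (1.0 + load) ** 2)
        else:
            free = R > 0
            w_b = np.where(free, 1.0 / (2.0 * a), 0.0)
        H = -(Ga * w_b[None, :]) @ Ga.T
        try:
            step = np.linalg.solve(H, -g[idx])
        except np.linalg.LinAlgError:
            reg = H - 1e-12 * np.eye(idx.size)
            step = np.linalg.solve(reg, -g[idx])
        new = lam.copy()
        new[idx] = lam[idx] + step
        # backtrack onto the nonnegative orthant
        if (new < 0).any():
            new = np.maximum(new, 0.0)
        lam = new
    return lam


@dataclass
class EquilibriumResult:
    """Noninvadable equilibrium of one well.

    N_star are the dual variables of the growth constraints (equilibrium
    abundances); residual is the RMS per-capita growth rate over survivors.
    """

    R_star: np.ndarray
    N_star: np.ndarray
    R0_eff: np.ndarray
    iterations: int
    converged: bool
    residual: float


def steady_state(
    N: np.ndarray,
    params: ModelParams,
    spec: DynamicsSpec | None = None,
    delta: float = 1e-7,
    learning_rate: float = 0.5,
    R0_eff_init: np.ndarray | None = None,
    max_iter: int = 1000,
) -> EquilibriumResult:
    """Find a noninvadable equilibrium for one well by the EM loop.

    Only species present in the well (N > 0) enter the constraint set, so
    absent species cannot appear at the equilibrium.  The E-step computes the
    effective supply point at the current R* with a damped update
    R~0 <- learning_rate * R~0(R*) + (1 - learning_rate) * R~0_prev, which
    keeps the KL arguments positive at low supply; the M-step solves the
    constrained minimization.  Convergence: max-norm change of (R~0, R*)
    below delta.  With l = 0, R~0(R*) = R0 identically and one outer
    iteration suffices.

    By default R~0 is initialized at the depleted-environment supply point
    (the E-step evaluated at R* = 0), a generic starting point that finds
    the surviving-community branch in bistable scenarios; pass
    ``R0_eff_init=params.R0`` to select the consumer-free branch instead.
    """
    p = params
    spec = spec or DynamicsSpec()
    if spec.response != "type1" or spec.regulation != "off":
        raise ValueError(
            "direct equilibration is only implemented for type1 response "
            "without metabolic regulation (the convex case)"
        )
    if spec.supply == "off":
        raise ValueError("no supply point exists with supply off")
    N = np.asarray(N, dtype=float)
    present = np.flatnonzero(N > 0)

    if spec.supply == "self_renewing":
        R_star, N_star = constrained_minimize(
            p.R0, p, species_idx=present, supply_mode="self_renewing"
        )
        res = _residual(p, R_star, N_star)
        return EquilibriumResult(
            R_star=R_star, N_star=N_star, R0_eff=p.R0.copy(),
            iterations=1, converged=True, residual=res,
        )

    Q = q_matrix(p)
    w_eff = effective_weights(p, Q)
    if R0_eff_init is None:
        R0_eff = effective_supply(np.zeros(p.n_resources), p.R0, Q, p.tau)
    else:
        R0_eff = np.asarray(R0_eff_init, dtype=float).copy()

    R_star_prev = None
    converged = False
    iterations = 0
    for t in range(1, max_iter + 1):
        iterations = t
        R_star, N_star = constrained_minimize(
            R0_eff, p, weights=w_eff, species_idx=present, supply_mode="external"
        )
        R0_eff_new = (
            learning_rate * effective_supply(R_star, p.R0, Q, p.tau)
            + (1.0 - learning_rate) * R0_eff
        )
        dR0 = np.max(np.abs(R0_eff_new - R0_eff))
        dR = np.inf if R_star_prev is None else np.max(np.abs(R_star - R_star_prev))
        R0_eff = R0_eff_new
        R_star_prev = R_star
        if max(dR0, dR) < delta or (t == 1 and np.all(p.l == 0) and dR0 < delta):
            converged = True
            break

    res = _residual(p, R_star, N_star)
    return EquilibriumResult(
        R_star=R_star,
        N_star=N_star,
        R0_eff=R0_eff,
        iterations=iterations,
        converged=converged,
        residual=res,
    )


def _residual(p: ModelParams, R_star: np.ndarray, N_star: np.ndarray) -> float:
    """RMS per-capita growth rate over surviving species."""
    surv = N_star > 0
    if not surv.any():
        return 0.0
    rates = p.g[surv] * (
        _growth_matrix(p, np.flatnonzero(surv)) @ R_star - p.m[surv]
    )
    return float(np.sqrt(np.mean(rates**2)))


def plate_steady_state(plate, update_state: bool = True, **kwargs):
    """Equilibrate every well of a Plate; optionally write (N*, R*) back."""
    import pandas as pd

    results = []
    Nmat = plate.state.N.to_numpy()
    for k in range(plate.state.n_wells):
        results.append(
            steady_state(Nmat[:, k], plate._well_params(k), plate.spec, **kwargs)
        )
    if update_state:
        from .plate import PlateState

        N_new = np.column_stack([r.N_star for r in results])
        R_new = np.column_stack([r.R_star for r in results])
        plate.state = PlateState(
            N=pd.DataFrame(N_new, index=plate.state.N.index, columns=plate.state.wells),
            R=pd.DataFrame(
                np.maximum(R_new, 0.0), index=plate.state.R.index, columns=plate.state.wells
            ),
        )
    return results
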