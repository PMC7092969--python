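"""Assembly of the MicroCRM right-hand side from mode selectors.

The model is specified by three orthogonal choices: the uptake response
(type1 linear, type2 Monod, type3 Hill), metabolic regulation of import
weights (off / energy-based / biomass-based), and the intrinsic resource
supply (external chemostat-like, self-renewing logistic, or off for a closed
community).

All variants share one energy bookkeeping: the energy imported by species i
from resource alpha is J_in[i, a] = w_a * u[i, a] * sigma(c[i, a] R_a); a
fraction l_a leaks out as byproducts partitioned by the column-stochastic
matrix D, and the remainder drives growth.  Because columns of D sum to one,
J_in = J_grow + J_out holds identically per species, which prevents closed
communities from gaining energy through secretion loops.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .params import ModelParams

__all__ = [
    "DynamicsSpec",
    "FluxBreakdown",
    "response_fn",
    "regulation_weights",
    "supply_fn",
    "make_rhs",
    "flux_breakdown",
]


@dataclass(frozen=True)
class DynamicsSpec:
    """Mode selectors for the built-in dynamics."""

    response: str = "type1"
    regulation: str = "off"
    supply: str = "external"

    def __post_init__(self):
        if self.response not in ("type1", "type2", "type3"):
            raise ValueError(f"unknown response {self.response!r}")
        if self.regulation not in ("off", "energy", "biomass"):
            raise ValueError(f"unknown regulation {self.regulation!r}")
        if self.supply not in ("external", "self_renewing", "off"):
            raise ValueError(f"unknown supply {self.supply!r}")


def response_fn(spec: DynamicsSpec, x, sigma_max: float | None = None, n: float = 2.0):
    """Uptake response sigma(x) for x = c*R >= 0 (elementwise).

    type1: sigma(x) = x; type2: x / (1 + x/sigma_max);
    type3: x^n / (1 + x^n/sigma_max) with n > 1.  Types 2-3 saturate at
    sigma_max.  0^n is taken as 0 so type3 is continuous at the origin.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("response argument x must be nonnegative")
    if spec.response == "type1":
        return x.copy()
    if sigma_max is None or sigma_max <= 0:
        raise ValueError("sigma_max > 0 required for type2/type3 response")
    if spec.response == "type2":
        return x / (1.0 + x / sigma_max)
    if not n > 1:
        raise ValueError("type3 response requires n > 1")
    with np.errstate(invalid="ignore"):
        xn = np.where(x > 0, x**n, 0.0)
    return xn / (1.0 + xn / sigma_max)


def regulation_weights(
    spec: DynamicsSpec,
    c_row: np.ndarray,
    R: np.ndarray,
    w: np.ndarray,
    n_reg: float = 10.0,
) -> np.ndarray:
    """Import-allocation weights u for one species.

    energy mode: u_a proportional to (w_a c_a R_a)^n_reg; biomass mode drops
    the energy density w.  Weights are normalized to sum to 1.  With
    regulation off, u = 1 for every resource (no reweighting).  An all-zero
    environment under active regulation returns uniform weights by
    convention.
    """
    c_row = np.asarray(c_row, dtype=float)
    R = np.asarray(R, dtype=float)
    if np.any(R < 0):
        raise ValueError("resource concentrations must be nonnegative")
    if spec.regulation == "off":
        return np.ones_like(c_row)
    base = c_row * R
    if spec.regulation == "energy":
        base = np.asarray(w, dtype=float) * base
    with np.errstate(invalid="ignore"):
        score = np.where(base > 0, base**n_reg, 0.0)
    tot = score.sum()
    if tot <= 0:
        return np.full_like(c_row, 1.0 / c_row.size)
    return score / tot


def _regulation_matrix(spec, c, R, w, n_reg):
    """Vectorized regulation weights, one row per species."""
    if spec.regulation == "off":
        return np.ones_like(c)
    base = c * R[None, :]
    if spec.regulation == "energy":
        base = base * w[None, :]
    with np.errstate(invalid="ignore"):
        score = np.where(base > 0, base**n_reg, 0.0)
    tot = score.sum(axis=1, keepdims=True)
    uniform = np.full_like(c, 1.0 / c.shape[1])
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.where(tot > 0, score / np.where(tot > 0, tot, 1.0), uniform)
    return u


def supply_fn(
    spec: DynamicsSpec,
    R: np.ndarray,
    R0: np.ndarray,
    tau: np.ndarray,
    r: np.ndarray,
) -> np.ndarray:
    """Intrinsic resource dynamics h(R) in the absence of consumers."""
    R = np.asarray(R, dtype=float)
    if spec.supply == "external":
        return (np.asarray(R0) - R) / np.asarray(tau)
    if spec.supply == "self_renewing":
        return np.asarray(r) * R * (np.asarray(R0) - R)
    return np.zeros_like(R)


@dataclass
class FluxBreakdown:
    """Energy and mass fluxes at one state.

    J_in[i, a]: energy flux into species i from resource a; J_grow[i]: energy
    retained for growth; J_out[i, b]: energy secreted as resource b.
    nu_in/nu_out are the corresponding mass fluxes J/w.  Energy conservation:
    J_in.sum(1) == J_grow + J_out.sum(1).
    """

    J_in: np.ndarray
    J_grow: np.ndarray
    J_out: np.ndarray
    nu_in: np.ndarray
    nu_out: np.ndarray


def flux_breakdown(
    N: np.ndarray, R: np.ndarray, spec: DynamicsSpec, params: ModelParams
) -> FluxBreakdown:
    """Evaluate the per-species energy/mass flux bookkeeping at (N, R)."""
    p = params
    R = np.asarray(R, dtype=float)
    u = _regulation_matrix(spec, p.c, R, p.w, p.n_reg)
    sigma = response_fn(spec, p.c * R[None, :], p.sigma_max, p.n)
    nu_in = u * sigma
    J_in = p.w[None, :] * nu_in
    J_grow = J_in @ (1.0 - p.l)
    J_out = (p.l[None, :] * J_in) @ p.D.T
    nu_out = J_out / p.w[None, :]
    return FluxBreakdown(J_in=J_in, J_grow=J_grow, J_out=J_out, nu_in=nu_in, nu_out=nu_out)


def make_rhs(
    spec: DynamicsSpec, params: ModelParams
) -> Callable[[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]:
    """Build the pure function (N, R) -> (dN/dt, dR/dt) for one well.

    dN_i/dt = g_i N_i [sum_a (1-l_a) w_a u_ia sigma(c_ia R_a) - m_i]
    dR_a/dt = h_a(R_a) - sum_j N_j u_ja sigma(c_ja R_a)
              + sum_{j,b} N_j u_jb sigma(c_jb R_b) l_b D_ab w_b / w_a
    """
    p = params
    S, M = p.c.shape
    if spec.response in ("type2", "type3") and p.sigma_max is None:
        raise ValueError(f"sigma_max required for {spec.response} response")

    def rhs(N: np.ndarray, R: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        N = np.asarray(N, dtype=float)
        R = np.asarray(R, dtype=float)
        if N.shape != (S,) or R.shape != (M,):
            raise ValueError(f"state shapes must be ({S},) and ({M},)")
        fb = flux_breakdown(N, np.maximum(R, 0.0), spec, p)
        dN = p.g * N * (fb.J_grow - p.m)
        h = supply_fn(spec, R, p.R0, p.tau, p.r)
        dR = h - N @ fb.nu_in + N @ fb.nu_out
        return dN, dR

    return rhs
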