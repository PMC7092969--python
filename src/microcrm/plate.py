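"""Virtual multi-well plate: state container and the two experimental actions.

A plate holds n independent well-mixed communities (no interaction except
through explicit transfer matrices).  ``propagate`` integrates the dynamics of
each well for a time T, compressing away extinct species so that solver noise
cannot resurrect them; ``passage`` pipettes fractions of old wells into fresh
wells, discretizing cell counts by multinomial sampling so that vanishing
populations go extinct exactly; ``run_experiment`` alternates the two, the
discrete-time backbone of serial-dilution batch culture.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, NamedTuple

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .dynamics import DynamicsSpec, make_rhs
from .params import ModelParams

__all__ = [
    "PlateState",
    "TransferMatrix",
    "Snapshot",
    "Plate",
    "propagate",
    "passage",
    "run_experiment",
    "stepping_stone_transfer",
]


@dataclass
class PlateState:
    """Species abundances (S_tot x n) and resource concentrations (M x n)."""

    N: pd.DataFrame
    R: pd.DataFrame

    def __post_init__(self):
        if list(self.N.columns) != list(self.R.columns):
            raise ValueError("N and R must share well labels")
        if (self.N.to_numpy() < 0).any() or (self.R.to_numpy() < 0).any():
            raise ValueError("negative entries in plate state")

    @property
    def wells(self) -> list[str]:
        return list(self.N.columns)

    @property
    def n_wells(self) -> int:
        return self.N.shape[1]

    def copy(self) -> "PlateState":
        return PlateState(N=self.N.copy(), R=self.R.copy())

    def to_csv(self, n_path, r_path) -> None:
        self.N.to_csv(n_path)
        self.R.to_csv(r_path)

    @classmethod
    def from_csv(cls, n_path, r_path) -> "PlateState":
        return cls(
            N=pd.read_csv(n_path, index_col=0),
            R=pd.read_csv(r_path, index_col=0),
        )


@dataclass
class TransferMatrix:
    """Dilution/mixing fractions: f[mu, nu] of old well nu goes to new well mu."""

    f: np.ndarray

    def __post_init__(self):
        self.f = np.atleast_2d(np.asarray(self.f, dtype=float))
        if (self.f < 0).any() or (self.f > 1).any():
            raise ValueError("transfer fractions must lie in [0, 1]")
        colsums = self.f.sum(axis=0)
        if (colsums > 1 + 1e-9).any():
            warnings.warn(
                "transfer matrix column sums exceed 1: wells are overdrawn",
                stacklevel=2,
            )

    @property
    def n_new(self) -> int:
        return self.f.shape[0]

    @property
    def n_old(self) -> int:
        return self.f.shape[1]

    def to_csv(self, path) -> None:
        pd.DataFrame(self.f).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TransferMatrix":
        return cls(pd.read_csv(path).to_numpy())


def stepping_stone_transfer(n_wells: int, f0: float, m: float) -> TransferMatrix:
    """Nearest-neighbor migration on a row of wells.

    Each well keeps a fraction f0*(1-m) in place and sends f0*m split equally
    between its two neighbors.  End wells have a single neighbor and send it
    f0*m/2, the other half being lost off the edge (absorbing boundary).
    """
    if not 0 <= m <= 1:
        raise ValueError("migration fraction m must be in [0, 1]")
    if f0 <= 0:
        raise ValueError("dilution factor f0 must be positive")
    f = np.zeros((n_wells, n_wells))
    np.fill_diagonal(f, f0 * (1 - m))
    for k in range(n_wells - 1):
        f[k, k + 1] = f0 * m / 2
        f[k + 1, k] = f0 * m / 2
    return TransferMatrix(f)


class Snapshot(NamedTuple):
    time: float
    state: PlateState


def _compress_custom_params(params: dict, dims: dict, idx: np.ndarray) -> dict:
    """Slice the species dimension of a custom parameter dictionary."""
    out = {}
    for k, v in params.items():
        d = dims.get(k)
        if d == "S":
            out[k] = np.asarray(v)[idx]
        elif d == "SxM":
            out[k] = np.asarray(v)[idx, :]
        elif d == "SxS":
            out[k] = np.asarray(v)[np.ix_(idx, idx)]
        else:  # scalars, M, MxM
            out[k] = v
    return out


class Plate:
    """An n-well plate with its dynamical law, parameters and RNG.

    Parameters may be a single :class:`ModelParams` shared by all wells or a
    list with one entry per well.  Custom dynamics are supported by passing a
    callable ``rhs(N, R, params) -> (dN, dR)`` together with a parameter
    dictionary and a ``dimensions`` ledger mapping parameter names to one of
    {"S", "M", "SxM", "SxS", "MxM", "scalar"}, which lets extinct-species
    compression slice the species axis correctly.
    """

    def __init__(
        self,
        state: PlateState,
        params: ModelParams | list[ModelParams] | dict,
        spec: DynamicsSpec | None = None,
        rhs: Callable | None = None,
        dimensions: dict | None = None,
        seed: int | None = None,
        rtol: float = 1e-8,
        atol: float = 1e-10,
        neg_tol: float = 1e-6,
    ):
        if spec is None and rhs is None:
            raise ValueError("provide either a DynamicsSpec or a custom rhs")
        if rhs is not None and not isinstance(params, (dict, list)):
            raise ValueError("custom dynamics require a parameter dictionary")
        self.state = state.copy()
        self.params = params
        self.spec = spec
        self.custom_rhs = rhs
        self.dimensions = dimensions or {}
        self.rng = np.random.default_rng(seed)
        self.rtol = rtol
        self.atol = atol
        self.neg_tol = neg_tol
        self.time = 0.0
        # fresh-medium profile used by refresh_resource at each passage
        self.R_init = state.R.copy()
        if spec is not None:
            for p in self._well_params_list():
                if p.c.shape[0] != state.N.shape[0] or p.c.shape[1] != state.R.shape[0]:
                    raise ValueError("params dimensions do not match plate state")

    def _well_params(self, k: int):
        if isinstance(self.params, list):
            return self.params[k]
        return self.params

    def _well_params_list(self):
        if isinstance(self.params, list):
            return self.params
        return [self.params]

    # -- propagation ------------------------------------------------------

    def _propagate_well(self, N, R, params, T, compress_species):
        if compress_species:
            alive = np.flatnonzero(N > 0)
        else:
            alive = np.arange(N.size)
        if self.custom_rhs is not None:
            p = (
                _compress_custom_params(params, self.dimensions, alive)
                if compress_species
                else params
            )
            rhs = lambda Na, Ra: self.custom_rhs(Na, Ra, p)
        else:
            p = params.subset_species(alive) if compress_species else params
            rhs = make_rhs(self.spec, p)
        S_a, M = alive.size, R.size

        def ode(t, y):
            dN, dR = rhs(y[:S_a], y[S_a:])
            return np.concatenate([dN, dR])

        y0 = np.concatenate([N[alive], R])
        sol = solve_ivp(
            ode, (0.0, T), y0, method="LSODA", rtol=self.rtol, atol=self.atol
        )
        if not sol.success:
            raise RuntimeError(f"ODE integration failed: {sol.message}")
        y = sol.y[:, -1]
        if (y < -self.neg_tol).any():
            raise RuntimeError(
                f"integration produced negative values below -{self.neg_tol}"
            )
        y = np.maximum(y, 0.0)
        N_out = np.zeros_like(N)
        N_out[alive] = y[:S_a]
        return N_out, y[S_a:]

    def propagate(self, T: float, compress_species: bool = True) -> PlateState:
        """Integrate every well independently for a duration T."""
        if not T > 0:
            raise ValueError("propagation time T must be positive")
        Nmat = self.state.N.to_numpy()
        Rmat = self.state.R.to_numpy()
        N_new = np.empty_like(Nmat)
        R_new = np.empty_like(Rmat)
        for k, well in enumerate(self.state.wells):
            try:
                N_new[:, k], R_new[:, k] = self._propagate_well(
                    Nmat[:, k], Rmat[:, k], self._well_params(k), T, compress_species
                )
            except RuntimeError as e:
                raise RuntimeError(f"well {well}: {e}") from e
        self.state = PlateState(
            N=pd.DataFrame(N_new, index=self.state.N.index, columns=self.state.wells),
            R=pd.DataFrame(R_new, index=self.state.R.index, columns=self.state.wells),
        )
        self.time += T
        return self.state

    # -- passaging --------------------------------------------------------

    def passage(
        self,
        f: TransferMatrix | np.ndarray,
        refresh_resource: bool = True,
        scale: float = 1e6,
    ) -> PlateState:
        """Transfer diluted well contents to a fresh plate.

        Expected cell counts scale * sum_nu f[mu, nu] N[i, nu] are realized by
        one multinomial draw per destination well (total = rounded total
        expected count, probabilities proportional to per-species expected
        contributions), then divided by ``scale``.  Resources mix linearly
        and, with ``refresh_resource``, the stored fresh-medium profile of the
        destination well is added on top.
        """
        if scale <= 0:
            raise ValueError("scale must be positive")
        if not isinstance(f, TransferMatrix):
            f = TransferMatrix(f)
        if f.n_old != self.state.n_wells:
            raise ValueError(
                f"transfer matrix expects {f.n_old} source wells, plate has "
                f"{self.state.n_wells}"
            )
        Nmat = self.state.N.to_numpy()
        Rmat = self.state.R.to_numpy()
        expected = scale * (Nmat @ f.f.T)  # S x n_new
        N_new = np.zeros_like(expected)
        for mu in range(f.n_new):
            total = int(round(expected[:, mu].sum()))
            if total > 0:
                p = expected[:, mu] / expected[:, mu].sum()
                N_new[:, mu] = self.rng.multinomial(total, p)
        N_new /= scale

        R_new = Rmat @ f.f.T
        wells_new = (
            self.state.wells
            if f.n_new == self.state.n_wells
            else [f"W{k}" for k in range(f.n_new)]
        )
        if refresh_resource:
            if self.R_init.shape[1] != f.n_new:
                raise ValueError(
                    "refresh_resource needs a fresh-medium profile per destination well"
                )
            R_new = R_new + self.R_init.to_numpy()
        self.state = PlateState(
            N=pd.DataFrame(N_new, index=self.state.N.index, columns=wells_new),
            R=pd.DataFrame(R_new, index=self.state.R.index, columns=wells_new),
        )
        return self.state

    # -- experiment loop --------------------------------------------------

    def run_experiment(
        self,
        f: TransferMatrix | np.ndarray,
        T: float,
        np_iter: int,
        refresh_resource: bool = True,
        scale: float = 1e6,
        compress_species: bool = True,
    ) -> list[Snapshot]:
        """Alternate passage then propagate for np_iter rounds.

        Returns one timestamped snapshot per round, taken after propagation.
        """
        if np_iter < 1:
            raise ValueError("np_iter must be at least 1")
        snapshots = []
        for _ in range(np_iter):
            self.passage(f, refresh_resource=refresh_resource, scale=scale)
            self.propagate(T, compress_species=compress_species)
            snapshots.append(Snapshot(time=self.time, state=self.state.copy()))
        return snapshots

    def steady_state(self, **kwargs):
        """Equilibrate every well directly; see :func:`microcrm.steadystate.steady_state`."""
        from .steadystate import plate_steady_state

        return plate_steady_state(self, **kwargs)


# -- functional wrappers ---------------------------------------------------


def propagate(
    plate: PlateState,
    params,
    spec: DynamicsSpec,
    T: float,
    compress_species: bool = True,
    **plate_kwargs,
) -> PlateState:
    """One-shot propagation of a plate state (stateless convenience)."""
    return Plate(plate, params, spec, **plate_kwargs).propagate(T, compress_species)


def passage(
    plate: PlateState,
    f: TransferMatrix | np.ndarray,
    refresh_resource: bool = False,
    scale: float = 1e6,
    seed: int | None = None,
    R_init: pd.DataFrame | None = None,
) -> PlateState:
    """One-shot passaging of a plate state (stateless convenience).

    Without ``R_init``, refresh_resource defaults to off since no
    fresh-medium profile is attached to a bare state.
    """
    dummy_params = ModelParams(
        c=np.zeros((plate.N.shape[0], plate.R.shape[0])),
        D=np.eye(plate.R.shape[0]) ,
    )
    p = Plate(plate, dummy_params, DynamicsSpec(), seed=seed)
    if R_init is not None:
        p.R_init = R_init.copy()
    return p.passage(f, refresh_resource=refresh_resource, scale=scale)


def run_experiment(
    plate: PlateState,
    params,
    spec: DynamicsSpec,
    f: TransferMatrix | np.ndarray,
    T: float,
    np_iter: int,
    seed: int | None = None,
    **kwargs,
) -> list[Snapshot]:
    """One-shot experiment loop on a plate state."""
    return Plate(plate, params, spec, seed=seed).run_experiment(f, T, np_iter, **kwargs)


def snapshots_to_csv(snapshots: list[Snapshot], path) -> None:
    """Write snapshots as one long-format CSV (time, well, entity_type, entity_id, value)."""
    rows = []
    for snap in snapshots:
        for kind, table in (("species", snap.state.N), ("resource", snap.state.R)):
            long = table.stack()
            for (entity, well), value in long.items():
                rows.append((snap.time, well, kind, entity, value))
    pd.DataFrame(
        rows, columns=["time", "well", "entity_type", "entity_id", "value"]
    ).to_csv(path, index=False)
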