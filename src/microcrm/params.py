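"""Parameter container for the microbial consumer-resource model (MicroCRM).

The model couples ``S`` consumer species to ``M`` substitutable resources.
Each species imports energy from resources through an uptake matrix ``c``,
spends a maintenance power ``m`` and converts the surplus to growth with
efficiency ``g``.  A fraction ``l`` of the energy imported from each resource
is leaked back into the environment as metabolic byproducts, partitioned among
resources by the column-stochastic metabolic matrix ``D``.  Resources carry an
energy density ``w`` and are replenished either externally (supply point
``R0``, turnover time ``tau``) or logistically (rate ``r``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields

import numpy as np


def _as_vector(x, size: int, name: str) -> np.ndarray:
    """Broadcast a scalar to a vector of the given size, or validate shape."""
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 0:
        return np.full(size, float(arr))
    if arr.shape != (size,):
        raise ValueError(f"{name} must be scalar or length-{size}, got shape {arr.shape}")
    return arr.copy()


@dataclass
class ModelParams:
    """All per-well parameters of the MicroCRM.

    Parameters
    ----------
    c : (S, M) array
        Uptake rate of resource alpha by species i, per unit concentration
        (volume/time).
    D : (M, M) array
        Column-stochastic byproduct allocation: ``D[alpha, beta]`` is the
        fraction of energy leaked while consuming ``beta`` that reappears as
        resource ``alpha``.
    g : (S,) array or scalar
        Conversion factor from net energy uptake to growth rate (1/energy).
    m : (S,) array or scalar
        Maintenance power per cell (energy/time).
    w : (M,) array or scalar
        Energy density of each resource (energy/mass).
    l : (M,) array or scalar
        Leakage fraction in [0, 1).
    R0 : (M,) array or scalar
        Intrinsic (unperturbed) equilibrium resource abundance (mass/volume).
    tau : (M,) array or scalar
        Turnover timescale for externally supplied resources (time).
    r : (M,) array or scalar
        Self-renewal rate for logistic resources (volume/mass/time).
    sigma_max : float, optional
        Saturating flux for Monod (type2) / Hill (type3) uptake.
    n : float
        Hill coefficient for type3 uptake (must exceed 1 when used).
    n_reg : float
        Hill coefficient for metabolic regulation weights.
    """

    c: np.ndarray
    D: np.ndarray
    g: np.ndarray | float = 1.0
    m: np.ndarray | float = 1.0
    w: np.ndarray | float = 1.0
    l: np.ndarray | float = 0.0
    R0: np.ndarray | float = 10.0
    tau: np.ndarray | float = 1.0
    r: np.ndarray | float = 1.0
    sigma_max: float | None = None
    n: float = 2.0
    n_reg: float = 10.0
    species_names: list[str] = field(default_factory=list)
    resource_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.c = np.atleast_2d(np.asarray(self.c, dtype=float))
        S, M = self.c.shape
        self.D = np.asarray(self.D, dtype=float)
        if self.D.shape != (M, M):
            raise ValueError(f"D must be {M}x{M}, got {self.D.shape}")
        self.g = _as_vector(self.g, S, "g")
        self.m = _as_vector(self.m, S, "m")
        self.w = _as_vector(self.w, M, "w")
        self.l = _as_vector(self.l, M, "l")
        self.R0 = _as_vector(self.R0, M, "R0")
        self.tau = _as_vector(self.tau, M, "tau")
        self.r = _as_vector(self.r, M, "r")
        if np.any(self.l < 0) or np.any(self.l >= 1):
            raise ValueError("leakage fractions l must lie in [0, 1)")
        if np.any(self.w <= 0):
            raise ValueError("energy densities w must be positive")
        if not self.species_names:
            self.species_names = [f"S{i}" for i in range(S)]
        if not self.resource_names:
            self.resource_names = [f"R{a}" for a in range(M)]
        if len(self.species_names) != S or len(self.resource_names) != M:
            raise ValueError("label lengths inconsistent with c")

    @property
    def n_species(self) -> int:
        return self.c.shape[0]

    @property
    def n_resources(self) -> int:
        return self.c.shape[1]

    def subset_species(self, idx: np.ndarray) -> "ModelParams":
        """Return a copy restricted to the species rows in ``idx``.

        Resource-indexed arrays are shared unchanged; used by extinct-species
        compression during propagation.
        """
        idx = np.asarray(idx)
        return ModelParams(
            c=self.c[idx],
            D=self.D,
            g=self.g[idx],
            m=self.m[idx],
            w=self.w,
            l=self.l,
            R0=self.R0,
            tau=self.tau,
            r=self.r,
            sigma_max=self.sigma_max,
            n=self.n,
            n_reg=self.n_reg,
            species_names=[self.species_names[i] for i in idx],
            resource_names=list(self.resource_names),
        )

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            out[f.name] = v.tolist() if isinstance(v, np.ndarray) else v
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ModelParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def __eq__(self, other) -> bool:
        if not isinstance(other, ModelParams):
            return NotImplemented
        for f in fields(self):
            a, b = getattr(self, f.name), getattr(other, f.name)
            if isinstance(a, np.ndarray):
                if not np.array_equal(a, np.asarray(b, dtype=float)):
                    return False
            elif a != b:
                return False
        return True
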