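"""Structured random ecosystem generation.

Builds the two large random matrices of the MicroCRM — the consumer
preference matrix ``c`` and the metabolic (byproduct stoichiometry) matrix
``D`` — plus default parameter vectors and initial plate states, from a flat
ledger of modeling assumptions.

Taxonomic/metabolic structure is a block model: the ``M`` resources are
partitioned into ``T`` classes and the ``S_tot`` species into ``F`` specialist
families (one per preferred resource class) plus an optional generalist
family.  A specialism parameter ``q`` shifts consumption capacity onto the
preferred class; a three-tiered secretion model (waste class / same class /
everything else, with fractions ``fw`` and ``fs``) shapes ``D``, whose columns
are Dirichlet samples and therefore sum to one exactly.

Draw order is fixed (``c`` in one row-major block, then ``D`` column by
column) so a given seed reproduces the same ecosystem on any platform.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .params import ModelParams
from .plate import PlateState

__all__ = [
    "Assumptions",
    "make_consumer_matrix",
    "make_metabolic_matrix",
    "make_params",
    "make_initial_state",
]

_FAMILIES = ("gaussian", "gamma", "binary")
_RESPONSES = ("type1", "type2", "type3")
_REGULATIONS = ("off", "energy", "biomass")
_SUPPLIES = ("external", "self_renewing", "off")


@dataclass
class Assumptions:
    """Global knobs for constructing a random ecosystem.

    Counts: ``M`` resources in ``T`` classes (sizes ``M_A``), ``S_tot``
    species split into ``F`` specialist families (sizes ``S_A``) plus
    ``S_gen`` generalists; ``S`` species are seeded per well.  ``muc`` and
    ``sigc`` are the mean and standard deviation of the row sums of ``c``;
    ``c0``/``c1`` the low/high binary consumption levels; ``q`` the
    specialization fraction; ``s`` the metabolic sparsity; ``fw``/``fs`` the
    waste-tier and same-class-tier secretion fractions.

    The remaining scalars (``l``, ``m``, ``g``, ``w``, ``tau``, ``r``,
    ``R0_food``, ``food``, ``sigma_max``, ``n``, ``n_reg``) fill the
    non-sampled model parameters uniformly; the defaults below are package
    conventions, overridable per run.
    """

    M: int = 10
    T: int = 1
    S_tot: int = 10
    F: int = 1
    S: int = 5
    muc: float = 10.0
    sigc: float = 3.0
    c0: float = 0.0
    c1: float = 1.0
    q: float = 0.0
    s: float = 0.2
    fw: float = 0.45
    fs: float = 0.45
    M_A: list[int] | None = None
    S_A: list[int] | None = None
    S_gen: int = 0
    sampling_family: str = "binary"
    response: str = "type1"
    regulation: str = "off"
    supply: str = "external"
    waste_class_index: int | None = None
    # uniform defaults for the non-sampled parameters
    l: float = 0.0
    m: float = 1.0
    g: float = 1.0
    w: float = 1.0
    tau: float = 1.0
    r: float = 1.0
    R0_food: float = 10.0
    food: int = 0
    sigma_max: float | None = None
    n: float = 2.0
    n_reg: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.M_A is None:
            base, extra = divmod(self.M, self.T)
            self.M_A = [base + (1 if a < extra else 0) for a in range(self.T)]
        if self.S_A is None:
            n_spec = self.S_tot - self.S_gen
            base, extra = divmod(n_spec, self.F)
            self.S_A = [base + (1 if a < extra else 0) for a in range(self.F)]
        if self.waste_class_index is None:
            self.waste_class_index = self.T - 1
        self.validate()

    def validate(self) -> None:
        for name in ("M", "T", "S_tot", "F", "S"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if sum(self.M_A) != self.M:
            raise ValueError(f"sum(M_A)={sum(self.M_A)} must equal M={self.M}")
        if self.S_gen + sum(self.S_A) != self.S_tot:
            raise ValueError("S_gen + sum(S_A) must equal S_tot")
        if len(self.S_A) != self.F:
            raise ValueError("S_A must have F entries")
        if self.F > self.T:
            raise ValueError("F must not exceed T")
        if not 0.0 <= self.q <= 1.0:
            raise ValueError(f"q must be in [0, 1], got {self.q}")
        if not 0.0 < self.s <= 1.0:
            raise ValueError(f"s must be in (0, 1], got {self.s}")
        if self.fw < 0 or self.fs < 0 or self.fw + self.fs > 1 + 1e-12:
            raise ValueError("need fw, fs >= 0 and fw + fs <= 1")
        if self.S > self.S_tot:
            raise ValueError("S cannot exceed S_tot")
        if self.sampling_family not in _FAMILIES:
            raise ValueError(f"sampling_family must be one of {_FAMILIES}")
        if self.response not in _RESPONSES:
            raise ValueError(f"response must be one of {_RESPONSES}")
        if self.regulation not in _REGULATIONS:
            raise ValueError(f"regulation must be one of {_REGULATIONS}")
        if self.supply not in _SUPPLIES:
            raise ValueError(f"supply must be one of {_SUPPLIES}")
        if not 0 <= self.waste_class_index < self.T:
            raise ValueError("waste_class_index out of range")

    # -- derived layout ---------------------------------------------------

    def resource_classes(self) -> np.ndarray:
        """Class index of each resource; resources are ordered by class."""
        return np.repeat(np.arange(self.T), self.M_A)

    def species_families(self) -> np.ndarray:
        """Family index of each species; -1 marks generalists (placed last)."""
        fams = np.repeat(np.arange(self.F), self.S_A)
        return np.concatenate([fams, -np.ones(self.S_gen, dtype=int)])

    def resource_names(self) -> list[str]:
        names = []
        for a, ma in enumerate(self.M_A):
            for j in range(ma):
                names.append(f"T{a}_R{j}")
        return names

    def species_names(self) -> list[str]:
        names = []
        for a, sa in enumerate(self.S_A):
            for i in range(sa):
                names.append(f"F{a}_S{i}")
        for i in range(self.S_gen):
            names.append(f"GEN_S{i}")
        return names

    # -- serialization (flat ledger with the canonical key names) ---------

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "Assumptions":
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "Assumptions":
        """Read a flat JSON or YAML assumptions ledger."""
        text = open(path).read()
        try:
            d = json.loads(text)
        except json.JSONDecodeError:
            import yaml

            d = yaml.safe_load(text)
        return cls.from_dict(d)


def _preference_moments(a: Assumptions) -> tuple[np.ndarray, np.ndarray]:
    """Per-entry mean and variance of c for gaussian/gamma families.

    Specialist family A has inflated moments on its preferred class
    (factor 1 + q (M - M_A)/M_A) and deflated ones (factor 1 - q) elsewhere;
    generalists are uniform.  Row sums then have mean muc and variance sigc^2
    for every species.
    """
    M, q = a.M, a.q
    classes = a.resource_classes()
    fams = a.species_families()
    mean = np.empty((a.S_tot, M))
    var = np.empty((a.S_tot, M))
    M_A = np.asarray(a.M_A, dtype=float)
    for i, fam in enumerate(fams):
        if fam < 0:
            mean[i] = a.muc / M
            var[i] = a.sigc**2 / M
        else:
            on = classes == fam
            boost = 1.0 + q * (M - M_A[fam]) / M_A[fam]
            mean[i] = np.where(on, a.muc / M * boost, a.muc / M * (1 - q))
            var[i] = np.where(on, a.sigc**2 / M * boost, a.sigc**2 / M * (1 - q))
    return mean, var


def make_consumer_matrix(
    assumptions: Assumptions, rng_seed: int, clip_negative: bool = False
) -> pd.DataFrame:
    """Sample the S_tot x M consumer preference matrix c.

    Three sampling families: ``gaussian`` (two-moment parameterization; may
    produce negative entries, kept as sampled unless ``clip_negative``),
    ``gamma`` (same moments, strictly positive), and ``binary`` (entries
    c0/M or c0/M + c1 with block-structured Bernoulli probabilities).

    Returns a labeled DataFrame: row index carries family identity
    (``F<fam>_S<i>`` / ``GEN_S<i>``), columns carry resource class
    (``T<class>_R<j>``).
    """
    a = assumptions
    a.validate()
    rng = np.random.default_rng(rng_seed)
    fam = a.sampling_family

    if fam in ("gaussian", "gamma"):
        mean, var = _preference_moments(a)
        if fam == "gaussian":
            c = rng.normal(mean, np.sqrt(var))
            if clip_negative:
                c = np.clip(c, 0.0, None)
        else:
            if np.any(mean <= 0):
                raise ValueError(
                    "gamma family requires strictly positive target means; "
                    "q=1 specialist off-class entries have mean 0"
                )
            shape = mean**2 / var
            scale = var / mean
            c = rng.gamma(shape, scale)
    else:  # binary
        classes = a.resource_classes()
        fams = a.species_families()
        M_A = np.asarray(a.M_A, dtype=float)
        base = a.muc / (a.M * a.c1)
        p = np.empty((a.S_tot, a.M))
        for i, f in enumerate(fams):
            if f < 0:
                p[i] = base
            else:
                on = classes == f
                boost = 1.0 + a.q * (a.M - M_A[f]) / M_A[f]
                p[i] = np.where(on, base * boost, base * (1 - a.q))
        if np.any(p > 1 + 1e-12):
            raise ValueError(
                "binary family: Bernoulli probability exceeds 1 "
                "(muc too large for the chosen c1 and M)"
            )
        x = rng.random((a.S_tot, a.M)) < p
        c = a.c0 / a.M + a.c1 * x

    return pd.DataFrame(c, index=a.species_names(), columns=a.resource_names())


def _dirichlet_concentrations(a: Assumptions, beta_class: int) -> np.ndarray:
    """Concentration parameters d[:, beta] of the three-tiered secretion model.

    A fraction fw of secreted flux goes on average to the waste class, fs to
    the input's own class, and the remainder everywhere else; sparsity s sets
    the Dirichlet scale (s -> 0: dense, near-expected allocations; s -> 1:
    each column concentrates on few outputs).  Columns whose input is itself
    in the waste class merge the first two tiers.
    """
    classes = a.resource_classes()
    wc = a.waste_class_index
    M_w = int(np.sum(classes == wc))
    d = np.empty(a.M)
    if beta_class == wc:
        rest = a.M - M_w
        for alpha in range(a.M):
            if classes[alpha] == wc:
                d[alpha] = (a.fw + a.fs) / (a.s * M_w)
            else:
                frac = 1.0 - a.fw - a.fs
                d[alpha] = frac / (a.s * rest) if rest > 0 else _empty_tier(frac)
    else:
        M_b = int(np.sum(classes == beta_class))
        rest = a.M - M_b - M_w
        for alpha in range(a.M):
            if classes[alpha] == wc:
                d[alpha] = a.fw / (a.s * M_w) if M_w > 0 else _empty_tier(a.fw)
            elif classes[alpha] == beta_class:
                d[alpha] = a.fs / (a.s * M_b)
            else:
                frac = 1.0 - a.fw - a.fs
                d[alpha] = frac / (a.s * rest) if rest > 0 else _empty_tier(frac)
    return d


def _empty_tier(frac: float) -> float:
    if frac > 1e-12:
        raise ValueError(
            f"secretion fraction {frac} allocated to an empty resource tier"
        )
    return 0.0


def make_metabolic_matrix(assumptions: Assumptions, rng_seed: int) -> pd.DataFrame:
    """Sample the M x M column-stochastic metabolic matrix D.

    Each column beta is a Dirichlet draw with the three-tiered concentration
    parameters, so every column sums to 1 exactly.  Entries whose
    concentration parameter is zero (an empty secretion tier) are exact
    zeros.
    """
    a = assumptions
    a.validate()
    rng = np.random.default_rng(rng_seed)
    classes = a.resource_classes()
    wc = a.waste_class_index
    if a.fw > 1e-12 and not np.any(classes == wc):
        raise ValueError("waste class is empty but fw > 0")

    D = np.zeros((a.M, a.M))
    for beta in range(a.M):
        d = _dirichlet_concentrations(a, classes[beta])
        if np.any(d < 0):
            raise ValueError("negative Dirichlet concentration parameter")
        pos = d > 0
        if not np.any(pos):
            raise ValueError(f"column {beta}: all concentration parameters are zero")
        D[pos, beta] = rng.dirichlet(d[pos])
    names = a.resource_names()
    return pd.DataFrame(D, index=names, columns=names)


def make_params(assumptions: Assumptions, rng_seed: int) -> ModelParams:
    """Assemble a complete ModelParams for one well.

    ``c`` and ``D`` are sampled (c first, then D, from a single seed); all
    other parameters are filled uniformly from the assumptions-level scalars.
    The supply point R0 implements the single-supplied-carbon-source
    scenario: R0[food] = R0_food and 0 elsewhere for external supply, and
    uniformly R0_food for self-renewing supply.
    """
    a = assumptions
    if a.response in ("type2", "type3") and a.sigma_max is None:
        raise ValueError(f"sigma_max is required for response={a.response}")
    if a.response == "type3" and not a.n > 1:
        raise ValueError("type3 response requires Hill coefficient n > 1")
    c = make_consumer_matrix(a, rng_seed)
    D = make_metabolic_matrix(a, rng_seed + 1)
    if a.supply == "self_renewing":
        R0 = np.full(a.M, a.R0_food)
    else:
        R0 = np.zeros(a.M)
        R0[a.food] = a.R0_food
    return ModelParams(
        c=c.to_numpy(),
        D=D.to_numpy(),
        g=a.g,
        m=a.m,
        w=a.w,
        l=a.l,
        R0=R0,
        tau=a.tau,
        r=a.r,
        sigma_max=a.sigma_max,
        n=a.n,
        n_reg=a.n_reg,
        species_names=list(c.index),
        resource_names=list(c.columns),
    )


def make_initial_state(
    assumptions: Assumptions,
    n_wells: int,
    rng_seed: int,
    food: int | list[int] | None = None,
    R0_food: float | list[float] | None = None,
) -> PlateState:
    """Build an initial plate: random species subsets on a single carbon source.

    Each well receives a uniformly random subset of exactly S distinct
    species from the regional pool, at abundance 1; resources start at the
    single supplied carbon source (identity/quantity per well via ``food`` /
    ``R0_food``, defaulting to the assumptions-level values).
    """
    a = assumptions
    a.validate()
    rng = np.random.default_rng(rng_seed)
    wells = [f"W{k}" for k in range(n_wells)]
    N = np.zeros((a.S_tot, n_wells))
    for k in range(n_wells):
        chosen = rng.choice(a.S_tot, size=a.S, replace=False)
        N[chosen, k] = 1.0

    food = a.food if food is None else food
    R0_food = a.R0_food if R0_food is None else R0_food
    foods = np.broadcast_to(np.asarray(food, dtype=int), (n_wells,))
    amounts = np.broadcast_to(np.asarray(R0_food, dtype=float), (n_wells,))
    R = np.zeros((a.M, n_wells))
    for k in range(n_wells):
        R[foods[k], k] = amounts[k]

    return PlateState(
        N=pd.DataFrame(N, index=a.species_names(), columns=wells),
        R=pd.DataFrame(R, index=a.resource_names(), columns=wells),
    )
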