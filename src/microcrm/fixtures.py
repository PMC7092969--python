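"""Pinned-seed scenario generators for tests, docs and benchmarks.

Every scenario is fully regenerable from (name, seed): all randomness flows
through numpy's seeded PCG64 generator with a fixed draw order, so the
serialized bundle is byte-identical across runs and platforms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import ModelParams
from .plate import PlateState, TransferMatrix, stepping_stone_transfer
from .sampling import (
    Assumptions,
    make_consumer_matrix,
    make_initial_state,
    make_params,
)

__all__ = [
    "Scenario",
    "structured_families_scenario",
    "em_benchmark_scenario",
    "range_expansion_scenario",
    "bistable_crossfeeding_scenario",
]


@dataclass
class Scenario:
    """A named, seed-pinned bundle of assumptions, parameters and initial state."""

    name: str
    assumptions: Assumptions | None
    params: ModelParams
    plate: PlateState
    transfer: TransferMatrix | None = None
    seed: int = 0
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "seed": self.seed,
            "assumptions": self.assumptions.to_dict() if self.assumptions else None,
            "params": self.params.to_dict(),
            "N": self.plate.N.to_dict(orient="split"),
            "R": self.plate.R.to_dict(orient="split"),
            "transfer": self.transfer.f.tolist() if self.transfer else None,
        }
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)


def structured_families_scenario(
    sampling_family: str = "binary", seed: int = 0
) -> Scenario:
    """Three specialist families plus generalists on three resource classes.

    100 species (3 families of 25 plus 25 generalists), 90 resources in 3
    classes of 30, specialism q = 0.9, metabolic sparsity s = 0.05 with
    secretion tiers f_s = f_w = 0.49.  The consumer matrices for all three
    sampling families (same seed) are attached under
    ``extras["consumer_variants"]``.
    """
    a = Assumptions(
        M=90,
        T=3,
        S_tot=100,
        F=3,
        S=20,
        S_A=[25, 25, 25],
        S_gen=25,
        q=0.9,
        s=0.05,
        fw=0.49,
        fs=0.49,
        muc=10.0,
        sigc=3.0,
        c0=0.0,
        c1=1.0,
        sampling_family=sampling_family,
        l=0.8,
        R0_food=200.0,
        seed=seed,
    )
    params = make_params(a, seed)
    plate = make_initial_state(a, n_wells=3, rng_seed=seed + 100)
    variants = {
        fam: make_consumer_matrix(
            Assumptions(**{**a.to_dict(), "sampling_family": fam}), seed
        )
        for fam in ("gaussian", "gamma", "binary")
    }
    return Scenario(
        name=f"structured_families_{sampling_family}",
        assumptions=a,
        params=params,
        plate=plate,
        seed=seed,
        extras={"consumer_variants": variants},
    )


def em_benchmark_scenario(M: int, seed: int = 0) -> Scenario:
    """Single externally supplied resource, binary uptake, S = M species.

    The supply point of the supplied resource is 10*M (all other resources
    are supplied at 0 and exist only as byproducts); used for the
    equilibrium-solver vs ODE-integration equivalence suite.
    """
    if M < 2:
        raise ValueError("need at least two resources")
    a = Assumptions(
        M=M,
        T=1,
        S_tot=M,
        F=1,
        S=M,
        muc=5.0,
        sigc=3.0,
        c0=0.0,
        c1=1.0,
        q=0.0,
        s=0.2,
        fw=0.7,
        fs=0.2,
        sampling_family="binary",
        l=0.8,
        m=1.0,
        tau=1.0,
        R0_food=10.0 * M,
        food=0,
        supply="external",
        response="type1",
        regulation="off",
        seed=seed,
    )
    params = make_params(a, seed)
    plate = make_initial_state(a, n_wells=1, rng_seed=seed + 100)
    return Scenario(
        name=f"em_benchmark_M{M}", assumptions=a, params=params, plate=plate, seed=seed
    )


def range_expansion_scenario(n_wells: int, seed: int = 0) -> Scenario:
    """Stepping-stone migration from a single inoculated well.

    Nearest-neighbor transfer matrix (dilution f0 = 0.1, migration m = 0.25),
    one supplied carbon source in every well, and only well 0 populated.
    """
    if n_wells < 3:
        raise ValueError("need at least three wells")
    a = Assumptions(
        M=8,
        T=1,
        S_tot=8,
        F=1,
        S=8,
        muc=4.0,
        sigc=1.0,
        c0=0.0,
        c1=1.0,
        sampling_family="binary",
        l=0.8,
        s=0.2,
        fw=0.7,
        fs=0.2,
        R0_food=80.0,
        seed=seed,
    )
    params = make_params(a, seed)
    wells = [f"W{k}" for k in range(n_wells)]
    rng = np.random.default_rng(seed + 100)
    N = np.zeros((a.S_tot, n_wells))
    chosen = rng.choice(a.S_tot, size=a.S, replace=False)
    N[chosen, 0] = 1.0
    R = np.zeros((a.M, n_wells))
    R[a.food, :] = a.R0_food
    plate = PlateState(
        N=pd.DataFrame(N, index=a.species_names(), columns=wells),
        R=pd.DataFrame(R, index=a.resource_names(), columns=wells),
    )
    transfer = stepping_stone_transfer(n_wells, f0=0.1, m=0.25)
    return Scenario(
        name=f"range_expansion_{n_wells}",
        assumptions=a,
        params=params,
        plate=plate,
        transfer=transfer,
        seed=seed,
    )


def bistable_crossfeeding_scenario() -> Scenario:
    """A two-resource cross-feeder whose supply cannot directly sustain it.

    One species consumes the supplied resource weakly (c = 1) and its own
    secreted byproduct strongly (c = 20); all leaked energy flows to the
    byproduct.  At the bare supply point R0 = (1.5, 0) the growth rate is
    (1 - l) * c1 * R0_1 - m = 0.5 * 1.5 - 1 < 0, so the consumer-free state
    is stable; a second, byproduct-sustained equilibrium with the consumer
    persisting also exists.
    """
    params = ModelParams(
        c=np.array([[1.0, 20.0]]),
        D=np.array([[0.0, 0.0], [1.0, 1.0]]),
        g=1.0,
        m=1.0,
        w=1.0,
        l=0.5,
        R0=np.array([1.5, 0.0]),
        tau=1.0,
        species_names=["F0_S0"],
        resource_names=["T0_R0", "T0_R1"],
    )
    plate = PlateState(
        N=pd.DataFrame([[1.0]], index=params.species_names, columns=["W0"]),
        R=pd.DataFrame(
            params.R0.reshape(-1, 1), index=params.resource_names, columns=["W0"]
        ),
    )
    return Scenario(
        name="bistable_crossfeeding",
        assumptions=None,
        params=params,
        plate=plate,
        seed=0,
    )


_SCENARIOS = {
    "structured_families": lambda seed: structured_families_scenario(seed=seed),
    "em_benchmark": lambda seed: em_benchmark_scenario(M=10, seed=seed),
    "range_expansion": lambda seed: range_expansion_scenario(n_wells=10, seed=seed),
    "bistable_crossfeeding": lambda seed: bistable_crossfeeding_scenario(),
}


def get_scenario(name: str, seed: int = 0) -> Scenario:
    if name not in _SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; choices: {sorted(_SCENARIOS)}")
    return _SCENARIOS[name](seed)
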