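"""Summaries of simulation output: alpha diversity and energy-flux networks."""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx

from .dynamics import DynamicsSpec, flux_breakdown
from .params import ModelParams
from .plate import PlateState

__all__ = ["alpha_diversity", "flux_network", "flux_edge_list"]


def alpha_diversity(
    plate: PlateState, threshold: float = 0.0, base: float = np.e
) -> pd.DataFrame:
    """Per-well alpha diversity of the species table.

    richness: number of species with N > threshold; shannon: entropy of
    relative abundances (natural log by default); simpson: sum p_i^2;
    effective_species: exp(shannon), the number of equally abundant species
    with the same entropy.  Empty wells get richness 0, shannon 0 and
    simpson 0 by convention.
    """
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    rows = []
    for well in plate.wells:
        N = plate.N[well].to_numpy()
        present = N > threshold
        richness = int(present.sum())
        tot = N[present].sum()
        if tot > 0:
            p = N[present] / tot
            shannon = float(-(p * np.log(p)).sum() / np.log(base))
            simpson = float((p**2).sum())
        else:
            shannon, simpson = 0.0, 0.0
        rows.append(
            {
                "well": well,
                "richness": richness,
                "shannon": shannon,
                "simpson": simpson,
                "effective_species": float(np.exp(shannon * np.log(base))) if tot > 0 else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("well")


def flux_network(
    N: np.ndarray,
    R: np.ndarray,
    params: ModelParams,
    spec: DynamicsSpec | None = None,
    tol: float = 0.0,
) -> nx.DiGraph:
    """Directed energy-flux graph of one well at state (N, R).

    Nodes are species and resources; an edge resource -> species carries the
    population-level input flux N_i * J_in[i, a], an edge species -> resource
    the secreted flux N_i * J_out[i, b].  Edges with weight <= tol are
    omitted (with l = 0 there are no secretion edges at all).
    """
    spec = spec or DynamicsSpec()
    N = np.asarray(N, dtype=float)
    fb = flux_breakdown(N, R, spec, params)
    g = nx.DiGraph()
    for name in params.species_names:
        g.add_node(name, kind="species")
    for name in params.resource_names:
        g.add_node(name, kind="resource")
    for i, sp in enumerate(params.species_names):
        g.nodes[sp]["J_grow"] = float(N[i] * fb.J_grow[i])
        for a, rs in enumerate(params.resource_names):
            w_in = N[i] * fb.J_in[i, a]
            if w_in > tol:
                g.add_edge(rs, sp, weight=float(w_in), edge_type="uptake")
            w_out = N[i] * fb.J_out[i, a]
            if w_out > tol:
                g.add_edge(sp, rs, weight=float(w_out), edge_type="secretion")
    return g


def flux_edge_list(graph: nx.DiGraph) -> pd.DataFrame:
    """Edge-list table (source, target, weight, edge_type) for a flux network."""
    rows = [
        {"source": u, "target": v, "weight": d["weight"], "edge_type": d["edge_type"]}
        for u, v, d in graph.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["source", "target", "weight", "edge_type"])
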