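import numpy as np
import pandas as pd
import pytest

from microcrm import Assumptions, DynamicsSpec, ModelParams, PlateState


@pytest.fixture
def small_assumptions():
    """A small structured ecosystem: 3 classes, 2 specialist families + generalists."""
    return Assumptions(
        M=12,
        T=3,
        S_tot=20,
        F=2,
        S=5,
        S_A=[9, 9],
        S_gen=2,
        muc=3.0,
        sigc=1.0,
        c0=0.1,
        c1=1.0,
        q=0.5,
        s=0.2,
        fw=0.4,
        fs=0.3,
        l=0.4,
        R0_food=20.0,
        sampling_family="binary",
    )


@pytest.fixture
def tiny_params():
    """Hand-sized two-resource model with leakage and full bookkeeping."""
    return ModelParams(
        c=[[0.3, 0.7], [0.5, 0.2]],
        D=[[0.6, 0.1], [0.4, 0.9]],
        g=[2.0, 1.0],
        m=[0.5, 0.3],
        w=[1.0, 2.0],
        l=[0.2, 0.4],
        R0=[2.0, 1.0],
        tau=[1.0, 2.0],
    )


@pytest.fixture
def single_well_state():
    def _make(N, R, species=None, resources=None):
        N = np.atleast_1d(np.asarray(N, dtype=float))
        R = np.atleast_1d(np.asarray(R, dtype=float))
        return PlateState(
            N=pd.DataFrame(N.reshape(-1, 1), index=species, columns=["W0"]),
            R=pd.DataFrame(R.reshape(-1, 1), index=resources, columns=["W0"]),
        )

    return _make


def macarthur_rhs_oracle(N, R, c, g, m, w, R0, tau, supply="external", r=None):
    """Independently coded MacArthur consumer-resource RHS (plain loops).

    dN_i/dt = g_i N_i (sum_a w_a c_ia R_a - m_i)
    dR_a/dt = h_a(R_a) - sum_j N_j c_ja R_a
    """
    S, M = len(N), len(R)
    dN = np.zeros(S)
    for i in range(S):
        uptake = 0.0
        for a in range(M):
            uptake += w[a] * c[i][a] * R[a]
        dN[i] = g[i] * N[i] * (uptake - m[i])
    dR = np.zeros(M)
    for a in range(M):
        if supply == "external":
            h = (R0[a] - R[a]) / tau[a]
        elif supply == "self_renewing":
            h = r[a] * R[a] * (R0[a] - R[a])
        else:
            h = 0.0
        cons = 0.0
        for j in range(S):
            cons += N[j] * c[j][a] * R[a]
        dR[a] = h - cons
    return dN, dR
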