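"""Reduction of a converged community to an effective Lotka-Volterra model.

In the fast-resource-equilibration regime the resource concentrations
track the populations, R(N) = A(N)^-1 kappa with
A = tau^-1 I + Q diag(phi), phi_b = sum_i N_i c_ib and
Q = I - D (w_b l_b / w_a).  Linearizing the resource-eliminated growth
rates around the computed fixed point yields generalized Lotka-Volterra
dynamics

    dN_i/dt = (r_i / K_i) N_i [ K_i - sum_j alpha_ij N_j ],  alpha_ii = 1,

whose parameters (carrying capacities K, interactions alpha, intrinsic
rates r) are computed here from the mechanistic quantities.  The sign
conventions are fixed so that the Jacobian of the effective model at
the fixed point equals the exact Jacobian of the reduced dynamics,
which can be checked directly by finite differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import SteadyStateResult, steady_state_resources
from .sampling import Environment, RegionalPool

__all__ = [
    "EffectiveLV",
    "reduce_to_lv",
    "k_variability",
    "pair_variability_table",
    "PairVariability",
]


@dataclass
class EffectiveLV:
    """Effective Lotka-Volterra parameters of one community's survivors."""

    survivors: np.ndarray        # pool indices, in the order of the arrays below
    alpha_matrix: np.ndarray     # interactions, alpha_ii = 1
    K: np.ndarray                # carrying capacities
    r: np.ndarray                # intrinsic growth rates
    N_bar: np.ndarray            # equilibrium abundances of the survivors
    # intermediates of the reduction
    w_tilde: np.ndarray          # effective energy per uptake, w (1 - l)
    Q: np.ndarray                # byproduct-corrected consumption operator
    A: np.ndarray                # resource-equilibrium response matrix
    dRdN: np.ndarray             # M x S' sensitivity of R to survivor abundances
    W: np.ndarray                # resource-mediated interaction kernel

    def K_series(self) -> dict[int, float]:
        return dict(zip(self.survivors.tolist(), self.K.tolist()))


@dataclass
class PairVariability:
    """Normalized RMS difference of shared-survivor carrying capacities."""

    pair: tuple
    variability: float
    n_shared: int


def reduce_to_lv(
    result: SteadyStateResult, pool: RegionalPool, env: Environment
) -> EffectiveLV:
    """Compute effective LV parameters at a converged fixed point.

    Restricted to the surviving species; all resources are retained in
    the linear algebra (the dilution term keeps A well conditioned even
    for depleted resources).
    """
    if not result.converged:
        raise ValueError("effective LV reduction requires a converged result")
    p = pool.params
    M = p.M
    surv = result.survivors
    if surv.size == 0:
        raise ValueError("no surviving species to reduce")
    w = np.full(M, p.w)
    l = np.full(M, p.l)
    w_tilde = w * (1.0 - l)
    Q = np.eye(M) - pool.D * (w * l)[None, :] / w[:, None]
    c_s = pool.c[surv]                     # S' x M
    N_s = result.N_bar[surv]
    R_bar = steady_state_resources(pool, env, result.N_bar)

    phi = result.N_bar @ pool.c
    A = np.eye(M) / env.tau_R + Q * phi[None, :]
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError as err:
        raise ValueError("degenerate resource equilibrium: A is singular") from err

    # dR_a/dN_j = -(A^-1 Q diag(R) c^T)_{aj}
    dRdN = -Ainv @ (Q * R_bar[None, :]) @ c_s.T
    # resource-mediated kernel: (c W c^T)_ij = -sum_a w~_a c_ia dR_a/dN_j
    W = (w_tilde[:, None] * Ainv) @ (Q * R_bar[None, :])
    G = c_s @ W @ c_s.T                    # S' x S'
    diag = np.diag(G)
    if np.any(diag == 0):
        raise ValueError("degenerate self-interaction in the reduction")
    alpha = G / diag[:, None]
    K = alpha @ N_s                        # equilibrium consistency for survivors
    r = K * p.g * diag
    return EffectiveLV(
        survivors=surv.copy(),
        alpha_matrix=alpha,
        K=K,
        r=r,
        N_bar=N_s.copy(),
        w_tilde=w_tilde,
        Q=Q,
        A=A,
        dRdN=dRdN,
        W=W,
    )


def lv_jacobian(lv: EffectiveLV) -> np.ndarray:
    """Jacobian of the effective LV dynamics at the fixed point."""
    return -(lv.r / lv.K)[:, None] * lv.N_bar[:, None] * lv.alpha_matrix


def reduced_jacobian_fd(
    result: SteadyStateResult,
    pool: RegionalPool,
    env: Environment,
    rel_step: float = 1e-6,
) -> np.ndarray:
    """Finite-difference Jacobian of the exact resource-eliminated dynamics.

    The reduced dynamics are F_i(N) = g N_i [sum_a w~_a c_ia R_a(N) - m_i]
    with R(N) the resource equilibrium at fixed N; central differences
    are taken in the surviving species' abundances.
    """
    p = pool.params
    surv = result.survivors
    w_tilde = np.full(p.M, p.w) * (1.0 - np.full(p.M, p.l))
    m_eff = pool.m_base + env.m_env

    def F(N_s: np.ndarray) -> np.ndarray:
        N_full = np.zeros(pool.S_tot)
        N_full[surv] = N_s
        R = steady_state_resources(pool, env, N_full)
        growth = pool.c[surv] @ (w_tilde * R) - m_eff[surv]
        return p.g * N_s * growth

    N0 = result.N_bar[surv]
    n = N0.size
    J = np.zeros((n, n))
    for j in range(n):
        h = rel_step * max(abs(N0[j]), 1e-8)
        up, dn = N0.copy(), N0.copy()
        up[j] += h
        dn[j] -= h
        J[:, j] = (F(up) - F(dn)) / (2 * h)
    return J


def pair_variability_table(lvs, ids=None):
    """All-pairs carrying-capacity variability as a tidy table.

    Takes a sequence of per-community reductions (and optional sample
    ids) and returns one record per unordered pair with the shared
    survivor count and normalized RMS K-difference; suitable for
    writing as TSV.
    """
    import pandas as pd

    if ids is None:
        ids = list(range(len(lvs)))
    records = []
    for i in range(len(lvs)):
        for j in range(i + 1, len(lvs)):
            v = k_variability(lvs[i], lvs[j], pair=(ids[i], ids[j]))
            records.append(
                {
                    "sample_mu": ids[i],
                    "sample_nu": ids[j],
                    "n_shared": v.n_shared,
                    "variability": v.variability,
                }
            )
    return pd.DataFrame(records)


def k_variability(lv_mu: EffectiveLV, lv_nu: EffectiveLV, pair=("mu", "nu")) -> PairVariability:
    """Normalized RMS difference in carrying capacities over shared survivors.

    The RMS of K differences over the shared survivor set, divided by
    the mean of all shared K values across the two communities.
    Returns NaN variability if the communities share no survivors.
    """
    K_mu = lv_mu.K_series()
    K_nu = lv_nu.K_series()
    shared = sorted(set(K_mu) & set(K_nu))
    if not shared:
        return PairVariability(pair=tuple(pair), variability=float("nan"), n_shared=0)
    a = np.array([K_mu[i] for i in shared])
    b = np.array([K_nu[i] for i in shared])
    rms = np.sqrt(np.mean((a - b) ** 2))
    mean_K = np.mean(a + b) / 2.0
    return PairVariability(
        pair=tuple(pair), variability=float(rms / mean_K), n_shared=len(shared)
    )
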