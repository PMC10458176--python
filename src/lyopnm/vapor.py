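"""Quasi-steady vapor transport on the vapor-connected subnetwork.

Vapor flows through *empty* pores only.  A pore conductance combines
viscous (Poiseuille) flow with a Knudsen correction for the transition
regime,

    K_ij = d_ij^2 P_ij / (32 eta) * (1 + 8.88 Kn_ij + 4.96 Kn_ij^2),

where the Knudsen number ``Kn = Lambda / d`` uses the mean free path
``Lambda = (eta / P) sqrt(pi R T / (2 M))``; temperatures and pressures in
a pore are arithmetic means of its end-node values.  The mass conductance
is ``g_ij = A_ij M K_ij / (R T_ij L_ij)`` and node mass balances
``sum g_ij (P_i - P_j) = 0`` yield a sparse linear system.

Boundary conditions: top-layer nodes couple to the chamber pressure
``P_inf`` through the constant coefficient ``g_inf``; sublimation-front
nodes (vapor-active nodes still touching ice) are pinned at the local
equilibrium pressure ``P_eq(T_i)`` over ice.  Partially saturated pores do
not conduct through-flow; they enter only as front anchors and sublimation
sources.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import breadth_first_order

from .conditions import BoundaryConditions
from .network import PoreNetwork
from .properties import MaterialProps, p_sat_ice, vapor_viscosity

__all__ = [
    "VaporSystem",
    "PressureField",
    "pore_transport_coefficient",
    "active_nodes",
    "build_vapor_system",
    "solve_pressure",
]


class SingularSystemError(RuntimeError):
    """Pressure system is singular (disconnected vapor component)."""


def pore_transport_coefficient(d, T_i, T_j, P_i, P_j, mat: MaterialProps):
    """Transition-regime transport coefficient of a cylindrical pore.

    Returns ``(K, Kn, Lambda)`` with K in m^2/s, the Knudsen number and
    the vapor mean free path in m.  Vectorised over pores.
    """
    d = np.asarray(d, dtype=float)
    T_ij = 0.5 * (np.asarray(T_i, dtype=float) + np.asarray(T_j, dtype=float))
    P_ij = 0.5 * (np.asarray(P_i, dtype=float) + np.asarray(P_j, dtype=float))
    if np.any(d <= 0) or np.any(T_ij <= 0) or np.any(P_ij <= 0):
        raise ValueError("pore diameter, temperature and pressure must be positive")
    eta = vapor_viscosity(T_ij)
    lam_mfp = eta / P_ij * np.sqrt(np.pi * mat.R * T_ij / (2.0 * mat.M_v))
    Kn = lam_mfp / d
    K = d**2 * P_ij / (32.0 * eta) * (1.0 + 8.88 * Kn + 4.96 * Kn**2)
    return K, Kn, lam_mfp


def active_nodes(net: PoreNetwork, empty: np.ndarray) -> np.ndarray:
    """Vapor-active node mask: top-layer nodes plus every node reachable
    from the top through empty pores.

    At the start of drying (no empty pores) only the top layer is active:
    sublimation is seeded there through the chamber coupling.
    """
    top = net.top
    if not empty.any():
        return top.copy()
    N = net.n_nodes
    src = np.concatenate([net.pore_i[empty], net.pore_j[empty], np.flatnonzero(top)])
    dst = np.concatenate(
        [net.pore_j[empty], net.pore_i[empty], np.full(int(top.sum()), N)]
    )
    ones = np.ones(src.size)
    adj = csr_matrix(
        (np.concatenate([ones, ones]),
         (np.concatenate([src, dst]), np.concatenate([dst, src]))),
        shape=(N + 1, N + 1),
    )
    reached, _ = breadth_first_order(adj, N, directed=False, return_predecessors=True)
    mask = np.zeros(N, dtype=bool)
    mask[reached[reached < N]] = True
    mask |= top
    return mask


@dataclass
class VaporSystem:
    """Assembled pressure problem on the vapor-active subgraph.

    The conductance matrix ``A`` couples only lattice neighbours; because
    free nodes keep their relative ordering, the coupling stays within
    ``bandwidth`` indices of the diagonal and ``A`` is kept in LAPACK
    banded storage (shape ``(2 bandwidth + 1, n_free)``).
    """

    net: PoreNetwork
    bc: BoundaryConditions
    active: np.ndarray          # (N,) bool
    front: np.ndarray           # (N,) bool: active nodes touching ice (Dirichlet)
    free: np.ndarray            # (N,) bool: active, non-front (unknowns)
    empty_pores: np.ndarray     # pore indices with zero ice
    g: np.ndarray               # conductances of empty pores [kg/(s Pa)]
    K: np.ndarray               # transport coefficients of empty pores [m^2/s]
    Kn: np.ndarray              # Knudsen numbers of empty pores
    mfp: np.ndarray             # mean free paths of empty pores [m]
    P_dirichlet: np.ndarray     # (N,) equilibrium pressure at front nodes (0 elsewhere)
    A: np.ndarray               # banded (2B+1, n_free) conductance matrix
    b: np.ndarray               # (n_free,) boundary vector
    free_index: np.ndarray      # (N,) global -> local free index (-1 elsewhere)
    bandwidth: int = 0


@dataclass
class PressureField:
    """Solved pressures and the resulting vapor mass flows."""

    P: np.ndarray               # (N,) node pressures (inactive nodes keep input)
    pore_flow: np.ndarray       # (P,) mass flow i -> j through empty pores [kg/s]
    top_outflow: np.ndarray     # (N,) g_inf (P_i - P_inf) for active top nodes
    node_net_outflow: np.ndarray  # (N,) net vapor leaving each node [kg/s]


def build_vapor_system(
    net: PoreNetwork,
    state,
    bc: BoundaryConditions,
    mat: MaterialProps,
    active: np.ndarray | None = None,
) -> VaporSystem:
    """Assemble the quasi-steady pressure system for the current state.

    ``state`` needs attributes ``T`` (node temperatures, K), ``P`` (node
    pressures from the previous solve, used to evaluate the
    pressure-dependent conductances) and ``pore_ice`` (per-pore ice
    volume, m^3).  ``active`` may supply a precomputed vapor-active mask
    (the engine tracks it incrementally); omitted, it is recomputed by
    flood fill from the top.
    """
    icy = state.pore_ice > 0.0
    empty = ~icy
    act = active_nodes(net, empty) if active is None else active
    has_ice = net.node_sum(icy.astype(float)) > 0
    front = act & has_ice
    free = act & ~front

    P_work = np.array(state.P, dtype=float)
    P_dir = np.zeros(net.n_nodes)
    if front.any():
        P_dir[front] = p_sat_ice(state.T[front])
        P_work[front] = P_dir[front]

    ep = np.flatnonzero(empty)
    u, v = net.pore_i[ep], net.pore_j[ep]
    if ep.size:
        K, Kn, mfp = pore_transport_coefficient(
            net.d[ep], state.T[u], state.T[v], P_work[u], P_work[v], mat
        )
        T_ij = 0.5 * (state.T[u] + state.T[v])
        g = net.A[ep] * mat.M_v * K / (mat.R * T_ij * net.L)
    else:
        K = Kn = mfp = g = np.empty(0)

    # banded assembly on the free nodes (relative order of free nodes is
    # preserved, so couplings stay within the lattice bandwidth)
    free_ids = np.flatnonzero(free)
    nf = free_ids.size
    B = net.bandwidth
    free_index = np.full(net.n_nodes, -1, dtype=int)
    free_index[free_ids] = np.arange(nf)
    A = np.zeros((2 * B + 1, nf))
    b = np.zeros(nf)
    if nf and ep.size:
        lu, lv = free_index[u], free_index[v]
        both = (lu >= 0) & (lv >= 0)
        if both.any():
            np.add.at(A[B], lu[both], g[both])
            np.add.at(A[B], lv[both], g[both])
            np.add.at(A, (B + lu[both] - lv[both], lv[both]), -g[both])
            np.add.at(A, (B + lv[both] - lu[both], lu[both]), -g[both])
        # free node connected to a Dirichlet front node
        for lf, other in ((lu, v), (lv, u)):
            mask = (lf >= 0) & front[other]
            if mask.any():
                np.add.at(A[B], lf[mask], g[mask])
                np.add.at(b, lf[mask], g[mask] * P_dir[other[mask]])
    if nf:
        ftop = np.flatnonzero(net.top[free_ids])
        A[B, ftop] += bc.g_inf
        b[ftop] += bc.g_inf * bc.P_inf

    return VaporSystem(
        net=net, bc=bc, active=act, front=front, free=free,
        empty_pores=ep, g=g, K=K, Kn=Kn, mfp=mfp,
        P_dirichlet=P_dir, A=A, b=b, free_index=free_index, bandwidth=B,
    )


def solve_pressure(system: VaporSystem, P_prev: np.ndarray | None = None) -> PressureField:
    """Solve the node mass balances and evaluate all vapor flows.

    Interior balances close to the solver tolerance; the total sublimation
    influx at the front equals the total outflow across the top surface.
    """
    from scipy.linalg import lapack

    net, bc = system.net, system.bc
    nf = system.A.shape[1]
    B = system.bandwidth
    P = (
        np.array(P_prev, dtype=float)
        if P_prev is not None
        else np.full(net.n_nodes, bc.P_inf)
    )
    P[system.front] = system.P_dirichlet[system.front]
    if nf:
        diag = np.abs(system.A[B])
        if np.any(diag <= 0):
            bad = np.flatnonzero(system.free)[diag <= 0]
            raise SingularSystemError(
                f"free nodes {bad.tolist()} have no path to a pressure boundary"
            )
        abw = np.zeros((3 * B + 1, nf))
        abw[B:] = system.A
        _, _, x, info = lapack.dgbsv(B, B, abw, system.b)
        if info != 0:  # pragma: no cover
            raise SingularSystemError(f"LAPACK gbsv info={info}")
        P[np.flatnonzero(system.free)] = x

    pore_flow = np.zeros(net.n_pores)
    ep = system.empty_pores
    if ep.size:
        pore_flow[ep] = system.g * (P[net.pore_i[ep]] - P[net.pore_j[ep]])

    top_outflow = np.zeros(net.n_nodes)
    toplayer = net.top & system.active
    top_outflow[toplayer] = bc.g_inf * (P[toplayer] - bc.P_inf)

    net_out = np.zeros(net.n_nodes)
    if ep.size:
        np.add.at(net_out, net.pore_i[ep], pore_flow[ep])
        np.add.at(net_out, net.pore_j[ep], -pore_flow[ep])
    net_out += top_outflow

    # interior (free) node balances must close to solver precision; the
    # round-off floor of a balance term is eps * g * P
    if nf:
        P_scale = float(np.abs(P[system.active]).max()) if system.active.any() else 1.0
        g_scale = max(float(system.g.max()) if system.g.size else 0.0, bc.g_inf)
        worst = float(np.abs(net_out[system.free]).max())
        if worst > 1e-8 * g_scale * P_scale:  # pragma: no cover
            raise SingularSystemError(
                f"pressure solve violates mass balance ({worst:.2e})"
            )

    return PressureField(
        P=P, pore_flow=pore_flow, top_outflow=top_outflow, node_net_outflow=net_out
    )
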