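"""Primary-drying simulation loop: sequential heat/mass coupling.

Each step performs, in order: update of the saturation-dependent CV
properties, quasi-steady pressure solve on the vapor-connected subgraph,
apportioning of the front mass flows to sublimating pores, adaptive time
step selection, one implicit heat step, and the ice bookkeeping.  The loop
runs until all ice is gone.

The time step is the minimum of a heat scale

    dt_h = min_cv  V_cv (rho cp)_cv L_cv / sum_j (lam_if A_cv)

and a mass scale ``dt_m = min over subliming pores of m_ice / M_sub`` (the
time for the fastest pore to empty), so pores empty exactly at step
boundaries and properties never lag behind a topology change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .conditions import BoundaryConditions
from .heat import step_temperature
from .network import CvGeometry, PoreNetwork, compute_cv_geometry
from .properties import (
    MaterialProps,
    cv_saturation,
    effective_cv_properties,
)
from .vapor import (
    PressureField,
    VaporSystem,
    active_nodes,
    build_vapor_system,
    solve_pressure,
)

__all__ = [
    "SimulationState",
    "SolverOptions",
    "DryingRecord",
    "sublimation_rates",
    "sublimation_heat_sinks",
    "compute_time_step",
    "update_ice",
    "run_primary_drying",
]


class StallError(RuntimeError):
    """All sublimation rates vanished while ice remains."""


class ConsistencyError(RuntimeError):
    """Internal bookkeeping violated an invariant."""


@dataclass
class SimulationState:
    """Mutable per-step state of a drying run."""

    t: float                 # clock [s]
    T: np.ndarray            # (N,) node temperatures [K]
    P: np.ndarray            # (N,) node pressures [Pa]
    pore_ice: np.ndarray     # (P,) ice volume per pore [m^3]

    def saturation(self, net: PoreNetwork) -> float:
        return float(self.pore_ice.sum() / net.V.sum())


@dataclass(frozen=True)
class SolverOptions:
    """Numerical knobs of the drying loop."""

    safety: float = 1.0          # multiplies the heat time-step bound
    dt_floor: float = 1e-12      # [s], guards against a vanishing step
    snapshot_ds: float = 0.05    # saturation spacing of full-state snapshots
    max_steps: int = 5_000_000
    s_end: float = 1e-12         # terminate when overall saturation drops below
    validate_active: bool = False  # cross-check the incremental active set


@dataclass
class DryingRecord:
    """Per-step time series, snapshots and audits of one drying run.

    Scalar series are recorded at every step.  Full state snapshots
    (temperature, pressure, pore saturation, slice profiles) are stored
    each time the overall saturation crosses a multiple of
    ``snapshot_ds``; front structure summaries quoted per saturation are
    taken from these windows.
    """

    L_cv_um: float
    series: dict = field(default_factory=dict)
    snapshots: list = field(default_factory=list)
    events: list = field(default_factory=list)      # (t, pore_id) emptying log
    audit: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    # -- convenience views ---------------------------------------------------
    def __getitem__(self, key: str) -> np.ndarray:
        return self.series[key]

    @property
    def drying_time(self) -> float:
        return float(self.series["t"][-1])

    @property
    def final_T(self) -> np.ndarray:
        """Temperature field at the end of the run (last snapshot, S = 0)."""
        return self.snapshots[-1]["T"]

    def to_dataframe(self):
        import pandas as pd

        cols = [
            "t", "S", "rate", "top_outflow", "mfp_um", "map_um", "lap_um",
            "width_um", "T_front", "Q_bot", "Q_top_enthalpy",
        ]
        return pd.DataFrame({c: self.series[c] for c in cols})

    def max_front_width(self, window: float = 0.05) -> float:
        """Maximum prevailing front width [um] over the drying run.

        The width series is binned into saturation windows of size
        ``window`` and the *median* width of each window is taken before
        maximising, so that the reported figure reflects the sustained
        front structure at each stage of drying rather than single-step
        pore-emptying transients (front structure, like the slice
        snapshots, is characterised per saturation interval).
        """
        S = self.series["S"]
        w = self.series["width_um"]
        ok = np.isfinite(w)
        if not ok.any():
            return float("nan")
        bins = np.floor((1.0 - S[ok]) / window).astype(int)
        widths = w[ok]
        best = 0.0
        for b in np.unique(bins):
            best = max(best, float(np.median(widths[bins == b])))
        return best

    def value_at_saturation(self, key: str, S_target: float) -> float:
        """Interpolate a recorded series at a given overall saturation."""
        S = self.series["S"]
        v = self.series[key]
        return float(np.interp(S_target, S[::-1], v[::-1]))

    def mass_closure(self) -> float:
        """|initial ice mass - integrated top outflow| / initial ice mass."""
        return abs(self.audit["mass_initial"] - self.audit["mass_out_top"]) / (
            self.audit["mass_initial"]
        )

    def energy_closure(self) -> float:
        """Relative defect of the integrated discrete energy balance."""
        a = self.audit
        num = abs(a["E_bot"] + a["E_adv"] - a["E_sub"] - a["E_storage"])
        den = max(abs(a["E_bot"]), abs(a["E_sub"]), abs(a["E_storage"]), 1e-300)
        return num / den


def sublimation_rates(
    net: PoreNetwork,
    system: VaporSystem,
    flows: PressureField,
    icy: np.ndarray | None = None,
) -> np.ndarray:
    """Apportion front-node vapor production to ice-containing pores.

    Each front node's *positive* net vapor outflow is distributed over its
    incident ice-containing pores in proportion to their cross sections;
    negative nodal balances (condensation) are disregarded.  A pore may
    collect contributions from both of its end nodes.
    """
    if icy is None:
        icy = ~np.isin(np.arange(net.n_pores), system.empty_pores)
    q = np.where(system.front, np.maximum(flows.node_net_outflow, 0.0), 0.0)
    sumA = net.node_sum(np.where(icy, net.A, 0.0))
    active_src = q > 0
    if np.any(active_src & (sumA <= 0)):
        raise ConsistencyError("front node produces vapor but touches no ice pore")
    rates = np.zeros(net.n_pores)
    inc_node, inc_pore = net.incidence
    take = icy[inc_pore] & active_src[inc_node]
    if take.any():
        n_, p_ = inc_node[take], inc_pore[take]
        np.add.at(rates, p_, q[n_] * net.A[p_] / sumA[n_])
    return rates


def sublimation_heat_sinks(
    net: PoreNetwork, rates: np.ndarray, mat: MaterialProps
) -> np.ndarray:
    """Latent-heat sink per CV: half of each pore's rate to each end CV."""
    return 0.5 * mat.dh_sub * net.node_sum(rates)


def compute_time_step(
    net: PoreNetwork,
    cv: CvGeometry,
    props,
    rates: np.ndarray,
    state: SimulationState,
    mat: MaterialProps,
    options: SolverOptions,
) -> tuple[float, float, float]:
    """Adaptive step ``dt = min(safety * dt_h, dt_m)``; returns (dt, dt_h, dt_m)."""
    lam_i = props.lam[net.pore_i]
    lam_j = props.lam[net.pore_j]
    lam_if = 2.0 * lam_i * lam_j / (lam_i + lam_j)
    denom = net.node_sum(lam_if) * cv.A_cv
    with np.errstate(divide="ignore"):
        dt_h_nodes = cv.V_cv * props.rho_cp * net.L / denom
    dt_h = float(dt_h_nodes.min())

    subliming = rates > 0.0
    if subliming.any():
        dt_m = float(
            (state.pore_ice[subliming] * mat.rho_ice / rates[subliming]).min()
        )
    else:
        if state.pore_ice.sum() > 0:
            raise StallError("no pore is subliming although ice remains")
        dt_m = math.inf
    dt = max(min(options.safety * dt_h, dt_m), options.dt_floor)
    return dt, dt_h, dt_m


def update_ice(
    net: PoreNetwork,
    state: SimulationState,
    rates: np.ndarray,
    dt: float,
    mat: MaterialProps,
) -> list[int]:
    """Remove sublimated ice; returns the pores that emptied this step.

    Volumes within one part in 1e12 of empty are snapped to zero so that
    a pore drained over exactly ``dt_m`` leaves the ice inventory rather
    than lingering as a numerical residue.
    """
    removed = rates * dt / mat.rho_ice
    new = state.pore_ice - removed
    if np.any(new < -1e-9 * net.V - 1e-30):
        raise ConsistencyError("negative ice volume beyond numerical tolerance")
    new = np.maximum(new, 0.0)
    snap = new <= 1e-12 * net.V
    newly_empty = np.flatnonzero(snap & (state.pore_ice > 0))
    new[snap] = 0.0
    state.pore_ice = new
    return newly_empty.tolist()


def run_primary_drying(
    net: PoreNetwork,
    bc: BoundaryConditions | None = None,
    mat: MaterialProps | None = None,
    options: SolverOptions | None = None,
) -> DryingRecord:
    """Run primary drying to completion and return the full record.

    The network starts fully saturated at the uniform initial temperature
    and pressure; at t = 0 the top node layer forms the initial front
    (pinned at its local equilibrium pressure against the chamber through
    ``g_inf``), which produces the characteristic high initial rate that
    collapses once the surface pores dry out.
    """
    bc = bc or BoundaryConditions()
    mat = mat or MaterialProps()
    options = options or SolverOptions()
    cv = compute_cv_geometry(net)
    if float(net.V.sum()) <= 0:
        raise ValueError("network has no pore volume")

    state = SimulationState(
        t=0.0,
        T=np.full(net.n_nodes, bc.T_init),
        P=np.full(net.n_nodes, bc.P_init),
        pore_ice=net.V.copy(),
    )
    # vapor-active node set, grown incrementally as pores empty
    active = net.top.copy()
    adjacency = [[] for _ in range(net.n_nodes)]
    for p in range(net.n_pores):
        u, v = int(net.pore_i[p]), int(net.pore_j[p])
        adjacency[u].append((p, v))
        adjacency[v].append((p, u))
    total_void = float(net.V.sum())
    mass_initial = total_void * mat.rho_ice

    keys = (
        "t", "S", "rate", "top_outflow", "mfp_um", "map_um", "lap_um",
        "width_um", "T_front", "Q_bot", "Q_top_enthalpy", "dt", "dt_h", "dt_m",
    )
    series = {k: [] for k in keys}
    rec = DryingRecord(L_cv_um=net.spec.L_cv_um, series=series)
    E_bot = E_adv = E_sub = E_storage = 0.0
    mass_out = 0.0
    mass_sublimated = 0.0
    max_resid = 0.0
    next_snap = 1.0 - options.snapshot_ds
    layer_um = net.pore_layer * net.spec.L_cv_um

    S = 1.0
    step = 0
    while S > options.s_end and step < options.max_steps:
        step += 1
        # 1. saturation-dependent CV properties
        ice_cv = 0.5 * net.node_sum(state.pore_ice)
        S_cv = cv_saturation(ice_cv, cv.void_cv)
        props = effective_cv_properties(cv.eps, S_cv, mat)

        # 2. quasi-steady vapor transport
        icy_mask = state.pore_ice > 0
        if options.validate_active:
            ref = active_nodes(net, ~icy_mask)
            if not np.array_equal(ref, active):  # pragma: no cover
                raise ConsistencyError("incremental active set diverged")
        system = build_vapor_system(net, state, bc, mat, active=active)
        flows = solve_pressure(system, P_prev=state.P)

        # 3. sublimation apportioning and latent sinks
        rates = sublimation_rates(net, system, flows, icy=icy_mask)
        sinks = sublimation_heat_sinks(net, rates, mat)

        # 4. time step
        dt, dt_h, dt_m = compute_time_step(
            net, cv, props, rates, state, mat, options
        )

        # 5. implicit heat step
        T_new, audit = step_temperature(
            net, props, state.T, flows, sinks, bc, mat, dt
        )

        if not np.all(np.isfinite(T_new)):
            raise ConsistencyError(
                f"non-finite temperature at t={state.t:.6g} s (step {step}, S={S:.6g})"
            )

        # 6. ice bookkeeping and incremental vapor-connectivity growth
        ice_before = state.pore_ice.copy()
        emptied = update_ice(net, state, rates, dt, mat)
        if emptied:
            empty_now = state.pore_ice <= 0.0
            stack = []
            for p in emptied:
                rec.events.append((state.t + dt, int(p)))
                u, v = int(net.pore_i[p]), int(net.pore_j[p])
                if active[u] and not active[v]:
                    stack.append(v)
                elif active[v] and not active[u]:
                    stack.append(u)
            while stack:
                n = stack.pop()
                if active[n]:
                    continue
                active[n] = True
                for p2, m in adjacency[n]:
                    if empty_now[p2] and not active[m]:
                        stack.append(m)

        # 7. advance
        state.T = T_new
        state.P = flows.P
        state.t += dt
        S = state.pore_ice.sum() / total_void

        # audits (terms exactly as exchanged by the discrete scheme)
        E_bot += audit["Q_bot"] * dt
        E_adv += audit["Q_adv"] * dt
        E_sub += audit["Q_sub"] * dt
        E_storage += audit["dE"]
        max_resid = max(max_resid, audit["residual_rel"])
        mass_out += float(flows.top_outflow.sum()) * dt
        mass_sublimated += float(rates.sum()) * dt

        # record scalars
        fp = icy_mask & (system.active[net.pore_i] | system.active[net.pore_j])
        if fp.any():
            z = layer_um[fp]
            w = ice_before[fp]
            mfp = float(np.average(z, weights=w))
            map_, lap = float(z.min()), float(z.max())
            width = lap - map_ + net.spec.L_cv_um
            T_front = float(state.T[system.front].mean()) if system.front.any() else np.nan
        else:
            mfp = map_ = lap = width = T_front = np.nan
        vals = (
            state.t, S, float(rates.sum()),
            float(flows.top_outflow.sum()), mfp, map_, lap, width, T_front,
            audit["Q_bot"], audit["Q_top_enthalpy"], dt, dt_h, dt_m,
        )
        for k, v in zip(keys, vals):
            series[k].append(v)

        # state snapshots on the saturation grid
        if S <= next_snap + 1e-15 or S <= options.s_end:
            rec.snapshots.append(
                {
                    "t": state.t,
                    "S": float(S),
                    "T": state.T.copy(),
                    "P": state.P.copy(),
                    "pore_saturation": state.pore_ice / net.V,
                }
            )
            while next_snap >= S - 1e-15:
                next_snap -= options.snapshot_ds

    if S > options.s_end:
        raise StallError(f"run did not finish within {options.max_steps} steps")

    for k in keys:
        series[k] = np.asarray(series[k])
    rec.audit = {
        "mass_initial": mass_initial,
        "mass_out_top": mass_out,
        "mass_sublimated": mass_sublimated,
        "E_bot": E_bot,
        "E_adv": E_adv,
        "E_sub": E_sub,
        "E_storage": E_storage,
        "max_step_residual": max_resid,
        "n_steps": step,
    }
    rec.meta = {
        "spec": net.spec.__dict__ | {},
        "bc": bc.__dict__ | {},
        "mat": mat.__dict__ | {},
        "options": options.__dict__ | {},
    }
    rec.audit["mass_closure"] = rec.mass_closure()
    rec.audit["energy_closure"] = rec.energy_closure()
    return rec
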