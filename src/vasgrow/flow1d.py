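"""1D blood flow in vessel networks.

With rigid walls, the 1D mass balance dQ/dz = 0 makes flow uniform along a
segment, and the steady momentum balance reduces to a Poiseuille pressure
drop dp = R_seg Q with R_seg = 8 mu l / (pi r^4).  The steady solver
therefore assembles a linear resistance network with mass conservation and
pressure continuity at junctions.  The transient solver integrates the
lumped momentum equation per segment,

    (rho l / S) dQ/dt + R_seg Q = p_prox - p_dist,

together with the junction constraints and the terminal resistance /
three-element Windkessel (RCR) boundary models, using the generalized-alpha
method for first-order systems parameterized by a single spectral radius.
Within a rigid uniform segment the advective flux difference
(1+delta) Q^2/S vanishes identically (dQ/dz = 0) and junctions use pressure
continuity, so the advective term does not enter the assembled network
system; delta is retained in the parameter set.

Internal assembly is CGS (lengths cm, flows ml/s, pressures dyn/cm^2);
pressures are converted to mmHg at the interface (1 mmHg = 1333.22 Ba).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from vasgrow.vascular_forest import VascularForest

MMHG = 1333.22  # dyn/cm^2 per mmHg


@dataclass
class FlowParams1D:
    """Blood and profile parameters for the 1D equations.

    blood_density : g/cm^3
    kinematic_viscosity : cm^2/s
    delta : momentum-flux profile parameter (parabolic: 1/3)
    friction_N : cm^2/s; None selects the parabolic-profile value 8 pi nu
    """

    blood_density: float = 1.06
    kinematic_viscosity: float = 0.0377  # mu=0.04 poise / rho=1.06
    delta: float = 1.0 / 3.0
    friction_N: float | None = None
    external_force: float = 0.0

    def __post_init__(self):
        if self.blood_density <= 0 or self.kinematic_viscosity <= 0:
            raise ValueError("density and viscosity must be positive")

    @property
    def N(self) -> float:
        return 8.0 * np.pi * self.kinematic_viscosity if self.friction_N is None \
            else self.friction_N

    @property
    def mu(self) -> float:
        return self.blood_density * self.kinematic_viscosity


@dataclass
class TerminalBC:
    """Terminal boundary model: pure resistance or RCR Windkessel.

    Resistances in mmHg s/ml, compliance in ml/mmHg, pressures in mmHg.
    """

    kind: str = "resistance"  # or "windkessel_rcr"
    R: float = 0.0
    Rp: float = 0.0
    C: float = 0.0
    Rd: float = 0.0
    distal_pressure: float = 0.0

    def __post_init__(self):
        if self.kind not in ("resistance", "windkessel_rcr"):
            raise ValueError(f"unknown terminal BC kind {self.kind!r}")
        if self.kind == "resistance" and self.R < 0:
            raise ValueError("terminal resistance must be >= 0")
        if self.kind == "windkessel_rcr" and (self.Rp < 0 or self.Rd < 0 or self.C <= 0):
            raise ValueError("RCR requires Rp, Rd >= 0 and C > 0")


@dataclass
class Solution1D:
    """Flow per segment (ml/s) and pressure per segment endpoint (mmHg)."""

    flow: dict[int, float]
    pressure_proximal: dict[int, float]
    pressure_distal: dict[int, float]
    times: np.ndarray | None = None
    flow_series: dict[int, np.ndarray] = field(default_factory=dict)
    pressure_series: dict[int, np.ndarray] = field(default_factory=dict)

    def terminal_pressures(self, forest: VascularForest) -> dict[int, float]:
        return {t: self.pressure_distal[t] for t in forest.terminal_ids}

    def to_frame(self) -> pd.DataFrame:
        ids = sorted(self.flow)
        return pd.DataFrame({
            "segment": ids,
            "Q_ml_s": [self.flow[i] for i in ids],
            "p_in_mmHg": [self.pressure_proximal[i] for i in ids],
            "p_out_mmHg": [self.pressure_distal[i] for i in ids],
        })


def segment_resistance(forest: VascularForest, mu: float) -> dict[int, float]:
    """Poiseuille resistance 8 mu l/(pi r^4) per segment, in mmHg s/ml."""
    out = {}
    for s in forest.segments.values():
        if s.radius <= 0:
            raise ValueError(f"segment {s.id} has zero radius")
        out[s.id] = 8.0 * mu * s.length / (np.pi * s.radius**4) / MMHG
    return out


# ---------------------------------------------------------------------------
# node numbering: one pressure node per segment distal end + one per root
# proximal end; children share the parent's distal node (pressure continuity)


def _build_nodes(forest: VascularForest):
    """Returns (node index per ("root",rid)/("distal",sid), count)."""
    nodes: dict[tuple[str, int], int] = {}
    for r in sorted(forest.roots):
        nodes[("root", r)] = len(nodes)
    for sid in sorted(forest.segments):
        nodes[("distal", sid)] = len(nodes)
    return nodes


def _prox_node(forest: VascularForest, nodes, sid: int) -> int:
    seg = forest.segments[sid]
    if seg.parent is None:
        return nodes[("root", sid)]
    return nodes[("distal", seg.parent)]


def solve_steady(
    forest: VascularForest,
    params: FlowParams1D,
    inflow: dict[int, float] | None = None,
    inlet_pressure: dict[int, float] | float | None = None,
    terminal_bcs: dict[int, TerminalBC] | None = None,
    terminal_flows: dict[int, float] | None = None,
) -> Solution1D:
    """Steady network solve (Poiseuille drops + junction conservation).

    Two consistent BC patterns:

    * ``terminal_flows`` prescribed (perfusion mode, flow set by metabolic
      demand) together with ``inlet_pressure`` (mmHg, scalar or per root) as
      the pressure datum;
    * ``inflow`` per root (ml/s) together with ``terminal_bcs`` (resistance
      or RCR, whose steady resistance is Rp + Rd) which carry the distal
      pressure datum.
    """
    if terminal_flows is not None and inlet_pressure is None:
        raise ValueError("prescribed terminal flows need an inlet_pressure datum")
    if terminal_flows is None and (inflow is None or terminal_bcs is None):
        raise ValueError("need either terminal_flows+inlet_pressure or inflow+terminal_bcs")

    R = segment_resistance(forest, params.mu)
    nodes = _build_nodes(forest)
    seg_ids = sorted(forest.segments)
    seg_index = {sid: i for i, sid in enumerate(seg_ids)}
    n_seg, n_nod = len(seg_ids), len(nodes)
    n = n_seg + n_nod
    A = sp.lil_matrix((n, n))
    rhs = np.zeros(n)

    def pcol(node_i: int) -> int:
        return n_seg + node_i

    # momentum rows: R Q - p_prox + p_dist = 0
    for sid in seg_ids:
        i = seg_index[sid]
        A[i, i] = R[sid]
        A[i, pcol(_prox_node(forest, nodes, sid))] = -1.0
        A[i, pcol(nodes[("distal", sid)])] = 1.0

    # node rows
    for (kind, sid), ni in nodes.items():
        row = n_seg + ni
        if kind == "root":
            if inflow is not None:
                A[row, seg_index[sid]] = 1.0
                rhs[row] = inflow.get(sid, 0.0) if isinstance(inflow, dict) else inflow
            else:
                A[row, pcol(ni)] = 1.0
                if isinstance(inlet_pressure, dict):
                    rhs[row] = inlet_pressure[sid]
                else:
                    rhs[row] = float(inlet_pressure)
        else:
            seg = forest.segments[sid]
            if seg.children:
                A[row, seg_index[sid]] = 1.0
                for c in seg.children:
                    A[row, seg_index[c]] = -1.0
            elif terminal_flows is not None:
                A[row, seg_index[sid]] = 1.0
                if sid not in terminal_flows:
                    raise ValueError(f"terminal {sid} missing a prescribed flow")
                rhs[row] = terminal_flows[sid]
            else:
                bc = terminal_bcs.get(sid) if terminal_bcs else None
                if bc is None:
                    raise ValueError(f"terminal {sid} missing a boundary condition; "
                                     "no pressure datum")
                r_t = bc.R if bc.kind == "resistance" else bc.Rp + bc.Rd
                # Q - (p_node - p_dist)/r_t = 0  (r_t=0: p_node = p_dist)
                if r_t > 0:
                    A[row, seg_index[sid]] = r_t
                    A[row, pcol(ni)] = -1.0
                    rhs[row] = -bc.distal_pressure
                else:
                    A[row, pcol(ni)] = 1.0
                    rhs[row] = bc.distal_pressure

    A = A.tocsr()
    try:
        y = spla.spsolve(A, rhs)
    except Exception as e:
        raise ValueError(f"singular 1D network system: {e}") from e
    if not np.all(np.isfinite(y)):
        raise ValueError("singular 1D network system (disconnected network or "
                         "all-flow boundary conditions without a pressure datum)")
    res = np.linalg.norm(A @ y - rhs) / max(np.linalg.norm(rhs), 1e-300)
    if res > 1e-10:
        raise ValueError(f"1D steady solve residual {res:.2e} exceeds 1e-10")

    flow = {sid: float(y[seg_index[sid]]) for sid in seg_ids}
    p_node = y[n_seg:]
    pp = {sid: float(p_node[_prox_node(forest, nodes, sid)]) for sid in seg_ids}
    pd_ = {sid: float(p_node[nodes[("distal", sid)]]) for sid in seg_ids}
    return Solution1D(flow, pp, pd_)


def generalized_alpha_parameters(rho_inf: float) -> tuple[float, float, float]:
    """(alpha_m, alpha_f, gamma) for first-order generalized-alpha."""
    if not 0.0 <= rho_inf <= 1.0:
        raise ValueError("spectral radius must be in [0, 1]")
    alpha_m = 0.5 * (3.0 - rho_inf) / (1.0 + rho_inf)
    alpha_f = 1.0 / (1.0 + rho_inf)
    gamma = 0.5 + alpha_m - alpha_f
    return alpha_m, alpha_f, gamma


def solve_transient(
    forest: VascularForest,
    params: FlowParams1D,
    inflow_waveform,
    terminal_bcs: dict[int, TerminalBC],
    dt: float,
    T: float,
    rho_inf: float = 0.5,
    flow_tolerance: float = 1e-6,
    max_inner_iterations: int = 20,
    store_every: int = 1,
) -> Solution1D:
    """Transient 1D solve with generalized-alpha time integration.

    ``inflow_waveform(t)`` gives the root inflow in ml/s (scalar networks
    with one root, or a dict per root id via ``inflow_waveform(t)[rid]``).
    Each step is iterated until the flow change between consecutive
    iterations drops below ``flow_tolerance`` (relative); exceeding
    ``max_inner_iterations`` raises with the residual.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    R = segment_resistance(forest, params.mu)
    nodes = _build_nodes(forest)
    seg_ids = sorted(forest.segments)
    seg_index = {sid: i for i, sid in enumerate(seg_ids)}
    n_seg, n_nod = len(seg_ids), len(nodes)
    term_ids = sorted(t for t in forest.terminal_ids)
    wk_ids = [t for t in term_ids if terminal_bcs[t].kind == "windkessel_rcr"]
    wk_index = {t: n_seg + n_nod + i for i, t in enumerate(wk_ids)}
    n = n_seg + n_nod + len(wk_ids)

    def pcol(ni):
        return n_seg + ni

    # M y' + K y = f(t)
    M = sp.lil_matrix((n, n))
    K = sp.lil_matrix((n, n))
    f_rows_root = {}
    for sid in seg_ids:
        i = seg_index[sid]
        s = forest.segments[sid]
        S = np.pi * s.radius**2
        M[i, i] = params.blood_density * s.length / S / MMHG  # mmHg units
        K[i, i] = R[sid]
        K[i, pcol(_prox_node(forest, nodes, sid))] = -1.0
        K[i, pcol(nodes[("distal", sid)])] = 1.0
    rhs0 = np.zeros(n)
    for (kind, sid), ni in nodes.items():
        row = n_seg + ni
        if kind == "root":
            K[row, seg_index[sid]] = 1.0
            f_rows_root[row] = sid
        else:
            seg = forest.segments[sid]
            if seg.children:
                K[row, seg_index[sid]] = 1.0
                for c in seg.children:
                    K[row, seg_index[c]] = -1.0
            else:
                bc = terminal_bcs[sid]
                if bc.kind == "resistance":
                    if bc.R > 0:
                        K[row, seg_index[sid]] = bc.R
                        K[row, pcol(ni)] = -1.0
                        rhs0[row] = -bc.distal_pressure
                    else:
                        K[row, pcol(ni)] = 1.0
                        rhs0[row] = bc.distal_pressure
                else:
                    # p_node = p_c + Rp Q
                    K[row, pcol(ni)] = -1.0
                    K[row, seg_index[sid]] = bc.Rp
                    K[row, wk_index[sid]] = 1.0
                    # C dp_c/dt = Q - (p_c - p_dist)/Rd
                    wrow = wk_index[sid]
                    M[wrow, wrow] = bc.C
                    K[wrow, seg_index[sid]] = -1.0
                    K[wrow, wrow] = 1.0 / bc.Rd
                    rhs0[wrow] = bc.distal_pressure / bc.Rd
    M = M.tocsr()
    K = K.tocsr()

    def f_of(t):
        f = rhs0.copy()
        q = inflow_waveform(t)
        for row, rid in f_rows_root.items():
            f[row] = q[rid] if isinstance(q, dict) else float(q)
        return f

    alpha_m, alpha_f, gamma = generalized_alpha_parameters(rho_inf)
    # initial state: steady solve at t=0 inflow; consistent ydot = 0
    q0 = inflow_waveform(0.0)
    y = _steady_from_operators(K, f_of(0.0))
    ydot = np.zeros(n)

    lhs = (alpha_m * M + alpha_f * gamma * dt * K).tocsc()
    solve = spla.factorized(lhs)
    n_steps = int(round(T / dt))
    times = [0.0]
    flows = [y[:n_seg].copy()]
    pressures = [y[n_seg:n_seg + n_nod].copy()]
    t = 0.0
    for step in range(n_steps):
        t_af = t + alpha_f * dt
        f = f_of(t_af)
        ydot_new = ydot.copy()
        prev_q = None
        for it in range(max_inner_iterations):
            rhs = f - M @ ((1 - alpha_m) * ydot) \
                - K @ (y + alpha_f * (1 - gamma) * dt * ydot)
            ydot_new = solve(rhs)
            y_new = y + dt * ((1 - gamma) * ydot + gamma * ydot_new)
            qn = y_new[:n_seg]
            if prev_q is not None:
                delta = np.linalg.norm(qn - prev_q) / max(np.linalg.norm(qn), 1e-300)
                if delta < flow_tolerance:
                    break
            prev_q = qn.copy()
        else:
            delta = np.linalg.norm(qn - prev_q) / max(np.linalg.norm(qn), 1e-300)
            raise RuntimeError(f"1D transient step {step}: inner iteration residual "
                               f"{delta:.2e} > {flow_tolerance:.1e}")
        y = y + dt * ((1 - gamma) * ydot + gamma * ydot_new)
        ydot = ydot_new
        t += dt
        if (step + 1) % store_every == 0:
            times.append(t)
            flows.append(y[:n_seg].copy())
            pressures.append(y[n_seg:n_seg + n_nod].copy())

    flow_series = {sid: np.array([fr[seg_index[sid]] for fr in flows]) for sid in seg_ids}
    p_series = {sid: np.array([pr[nodes[("distal", sid)]] for pr in pressures])
                for sid in seg_ids}
    flow = {sid: float(flow_series[sid][-1]) for sid in seg_ids}
    p_node = pressures[-1]
    pp = {sid: float(p_node[_prox_node(forest, nodes, sid)]) for sid in seg_ids}
    pd_ = {sid: float(p_node[nodes[("distal", sid)]]) for sid in seg_ids}
    return Solution1D(flow, pp, pd_, times=np.array(times),
                      flow_series=flow_series, pressure_series=p_series)


def _steady_from_operators(K, f):
    y = spla.spsolve(K.tocsc(), f)
    if not np.all(np.isfinite(y)):
        raise ValueError("singular steady initialization")
    return y
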