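"""Explicit 1D-network / Darcy-tissue coupling and run reporting.

The two solvers exchange interface data until a fixed point: the 1D solver,
driven by the current terminal flows, yields terminal pressures; each
terminal's pressure becomes the Darcy source pressure on the tissue
partition it perfuses; the Darcy solve returns per-element tissue inflows,
which are summed per partition and fed back as the 1D terminal flows
(under-relaxed).  Iteration stops when both the terminal pressures and
flows change less than the configured tolerances.  beta_sink may be
rescaled slightly (bounded, default within 2%) to match a prescribed total
flow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import log as math_log

import numpy as np
import pandas as pd

from vasgrow.tissue_domain import ClaimMap, DemandField, TissueMesh, UNCLAIMED, element_flow
from vasgrow.vascular_forest import VascularForest, tree_volume
from vasgrow.flow1d import FlowParams1D, Solution1D, solve_steady
from vasgrow.darcy_perfusion import (
    CouplingCoefficients, DarcyOperator, DarcyParams, DarcySolution,
)

logger = logging.getLogger(__name__)


@dataclass
class CouplingConfig:
    """Fixed-point controls.

    pressure_tolerance : mmHg, max terminal-pressure change per sweep
    flow_tolerance : relative max terminal-flow change per sweep
    max_iterations : coupling sweeps before declaring non-convergence
    beta_sink_adjustment_bound : fractional bound on beta_sink rescaling
    relaxation : under-relaxation factor on the flow update (0, 1]
    inlet_pressure : mmHg pressure datum at the tree roots
    """

    pressure_tolerance: float = 1e-6
    flow_tolerance: float = 1e-8
    max_iterations: int = 200
    beta_sink_adjustment_bound: float = 0.02
    relaxation: float = 0.5
    inlet_pressure: float = 100.0

    def __post_init__(self):
        if self.pressure_tolerance <= 0 or self.flow_tolerance <= 0:
            raise ValueError("tolerances must be positive")
        if not 0 < self.relaxation <= 1:
            raise ValueError("relaxation must be in (0, 1]")


def run_coupled_perfusion(
    forest: VascularForest,
    mesh: TissueMesh,
    demand: DemandField,
    claim: ClaimMap,
    flow_params: FlowParams1D | None = None,
    darcy_params: DarcyParams | None = None,
    coupling: CouplingCoefficients | None = None,
    config: CouplingConfig | None = None,
    prescribed_total_flow: float | None = None,
) -> tuple[Solution1D, DarcySolution, pd.DataFrame]:
    """Iterate the explicit 1D/Darcy coupling to its fixed point.

    Terminal flows are initialized from the metabolic demand of each
    terminal's partition.  Returns the converged 1D and Darcy solutions and
    a convergence log (iteration, max pressure change, max relative flow
    change, total source flow).
    """
    flow_params = flow_params or FlowParams1D()
    darcy_params = darcy_params or DarcyParams()
    config = config or CouplingConfig()
    n_el = mesh.n_elements
    terminals = sorted(forest.terminal_ids)
    part = {t: claim.partition(t) for t in terminals}
    uncovered = [t for t in terminals if len(part[t]) == 0]
    if uncovered:
        raise ValueError(f"terminals without a tissue partition: {uncovered[:5]}")

    e_flow = element_flow(mesh, demand)
    q = {t: float(e_flow[part[t]].sum()) for t in terminals}

    if coupling is None:
        m_bar = float(np.mean(demand.metabolic_demand * demand.density)) / 60.0
        p_bar = 15.0
        bsnk = m_bar / p_bar
        bsrc = m_bar / (config.inlet_pressure * 0.75 - p_bar)
        coupling = CouplingCoefficients(np.full(n_el, bsrc), np.full(n_el, bsnk),
                                        np.zeros(n_el), np.zeros(n_el))
    cpl = coupling.broadcast(n_el)
    beta_sink0 = cpl.beta_sink.copy()
    operator = DarcyOperator(mesh, darcy_params, cpl.beta_source, cpl.beta_sink)

    rows = []
    p_term_prev = None
    sol1d = None
    darcy = None
    sink_scale = 1.0          # current multiplicative beta_sink adjustment
    adj_prev = None           # (log scale, log flow) for the secant update
    pinned = False
    for it in range(1, config.max_iterations + 1):
        sol1d = solve_steady(forest, flow_params, terminal_flows=q,
                             inlet_pressure=config.inlet_pressure)
        p_term = {t: sol1d.pressure_distal[t] for t in terminals}
        # terminal pressures -> piecewise-constant Darcy source pressures
        for t in terminals:
            cpl.p_source[part[t]] = p_term[t]
        darcy = operator.solve(cpl.p_source, cpl.p_sink)
        q_part = {t: float(darcy.source_flow[part[t]].sum()) for t in terminals}

        dq = max(abs(q_part[t] - q[t]) / max(abs(q[t]), 1e-300) for t in terminals)
        dp = (max(abs(p_term[t] - p_term_prev[t]) for t in terminals)
              if p_term_prev is not None else np.inf)
        total_src = float(darcy.source_flow.sum())
        rows.append({"iteration": it, "max_dp_mmHg": dp, "max_dq_rel": dq,
                     "total_source_flow_ml_s": total_src})
        flow_matched = True
        if prescribed_total_flow is not None and not pinned:
            flow_matched = abs(total_src - prescribed_total_flow) \
                <= max(config.flow_tolerance, 1e-10) * prescribed_total_flow
        if dq < config.flow_tolerance and dp < config.pressure_tolerance \
                and flow_matched:
            break
        w = config.relaxation
        q = {t: (1 - w) * q[t] + w * q_part[t] for t in terminals}
        p_term_prev = p_term

        if prescribed_total_flow is not None and total_src > 0 and not pinned:
            # secant step on log(beta_sink scale) vs log(total flow)
            bound = config.beta_sink_adjustment_bound
            if adj_prev is not None and adj_prev[0] != math_log(sink_scale):
                slope = (math_log(total_src) - adj_prev[1]) \
                    / (math_log(sink_scale) - adj_prev[0])
                step = (math_log(prescribed_total_flow) - math_log(total_src)) \
                    / max(slope, 1e-3)
            else:
                step = math_log(prescribed_total_flow / total_src)
            adj_prev = (math_log(sink_scale), math_log(total_src))
            new_scale = float(np.clip(sink_scale * np.exp(step),
                                      1.0 - bound, 1.0 + bound))
            if new_scale in (1.0 - bound, 1.0 + bound) and new_scale == sink_scale:
                pinned = True
                logger.warning("beta_sink adjustment pinned at the %.1f%% bound",
                               100 * bound)
            if new_scale != sink_scale:
                sink_scale = new_scale
                cpl.beta_sink = beta_sink0 * sink_scale
                operator = DarcyOperator(mesh, darcy_params,
                                         cpl.beta_source, cpl.beta_sink)
    else:
        hist = pd.DataFrame(rows)
        raise RuntimeError(
            "1D/Darcy coupling did not converge within "
            f"{config.max_iterations} iterations; last residuals "
            f"dp={rows[-1]['max_dp_mmHg']:.3e} mmHg, dq={rows[-1]['max_dq_rel']:.3e}\n"
            f"{hist.tail().to_string(index=False)}")

    return sol1d, darcy, pd.DataFrame(rows)


def report(
    forest: VascularForest,
    mesh: TissueMesh,
    demand: DemandField,
    claim: ClaimMap,
    execution_time_s: float | None = None,
    method: str = "GBO",
) -> pd.DataFrame:
    """Per-source summary: tissue volume, total flow, tree volume.

    One row per source root (plus ratio columns when there are exactly two
    sources, mirroring the benchmark tables).
    """
    from vasgrow.gbo_growth import map_perfusion_territories

    rows = []
    if len(forest.roots) == 0:
        return pd.DataFrame(columns=["method", "source", "n_terminals",
                                     "tissue_volume_ml", "total_flow_ml_s",
                                     "tree_volume_ml", "execution_time_s"])
    label = map_perfusion_territories(forest, claim)
    e_flow = element_flow(mesh, demand)
    vols = mesh.element_volume
    for r in sorted(forest.roots):
        sid = forest.segments[r].source_id
        in_territory = label == r
        sub = forest.subtree_ids(r)
        n_term = sum(1 for i in sub if forest.segments[i].is_terminal)
        rows.append({
            "method": method,
            "source": sid,
            "n_terminals": n_term,
            "tissue_volume_ml": float(vols[in_territory].sum()),
            "total_flow_ml_s": float(e_flow[in_territory].sum()),
            "tree_volume_ml": tree_volume(forest, source_id=sid),
            "execution_time_s": execution_time_s,
        })
    df = pd.DataFrame(rows)
    if len(rows) == 2:
        a, b = df.iloc[0], df.iloc[1]
        for col in ("tissue_volume_ml", "total_flow_ml_s", "tree_volume_ml"):
            df[f"{col}_ratio"] = a[col] / b[col] if b[col] else np.nan
    return df
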