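"""Explicit 1D/Darcy coupling: fixed point, conservation, reporting."""

import numpy as np
import pytest

from vasgrow.coupled_driver import CouplingConfig, report, run_coupled_perfusion
from vasgrow.darcy_perfusion import CouplingCoefficients
from vasgrow.flow1d import FlowParams1D, segment_resistance
from vasgrow.tissue_domain import ClaimMap, DemandField, TissueMesh
from vasgrow.vascular_forest import VascularForest


@pytest.fixture
def minimal_system():
    """One source segment perfusing a single-tet tissue."""
    mesh = TissueMesh(np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]]),
                      np.array([[0, 1, 2, 3]]))
    demand = DemandField(np.array([1.0]), np.array([1.05]))
    f = VascularForest()
    s = f.new_segment([0, 0, 0], [0.25, 0.25, 0.25])
    s.radius, s.flow = 0.1, 1.0
    claim = ClaimMap(np.array([0]))
    cpl = CouplingCoefficients(np.array([0.000281]), np.array([0.00117]),
                               np.array([0.0]), np.array([0.0]))
    return mesh, demand, f, claim, cpl


class TestCoupling:
    def test_minimal_fixed_point_matches_hand_algebra(self, minimal_system):
        mesh, demand, forest, claim, cpl = minimal_system
        fp = FlowParams1D()
        cfg = CouplingConfig(inlet_pressure=100.0, flow_tolerance=1e-10,
                             pressure_tolerance=1e-8)
        sol1d, darcy, log = run_coupled_perfusion(
            forest, mesh, demand, claim, flow_params=fp, coupling=cpl,
            config=cfg)
        # hand algebra: p_term = P_in - R Q; equilibrium tissue pressure
        # p* = bs p_term/(bs+bk); Q = V bs (p_term - p*) = G p_term with
        # G = V bs bk/(bs+bk)  =>  Q = G P_in / (1 + G R)
        R = segment_resistance(forest, fp.mu)[0]
        V = mesh.element_volume[0]
        bs, bk = 0.000281, 0.00117
        G = V * bs * bk / (bs + bk)
        q_exact = G * 100.0 / (1 + G * R)
        assert sol1d.flow[0] == pytest.approx(q_exact, rel=1e-8)

    def test_fixed_point_independent_of_relaxation(self, minimal_system):
        mesh, demand, forest, claim, cpl = minimal_system
        flows = []
        for w in (0.3, 1.0):
            sol1d, _, _ = run_coupled_perfusion(
                forest, mesh, demand, claim, coupling=cpl,
                config=CouplingConfig(relaxation=w, flow_tolerance=1e-12,
                                      pressure_tolerance=1e-10))
            flows.append(sol1d.flow[0])
        assert flows[0] == pytest.approx(flows[1], rel=1e-8)

    def test_converged_interface_and_global_conservation(self, gbo567):
        bm, forest, claim, _ = gbo567
        n = bm.mesh.n_elements
        cpl = CouplingCoefficients(np.full(n, 0.000281), np.full(n, 0.00117),
                                   np.zeros(n), np.zeros(n))
        cfg = CouplingConfig(inlet_pressure=100.0, flow_tolerance=1e-9,
                             pressure_tolerance=1e-7)
        sol1d, darcy, log = run_coupled_perfusion(
            forest, bm.mesh, bm.demand, claim, coupling=cpl, config=cfg)
        # per-terminal interface agreement at convergence
        for t in forest.terminal_ids:
            q_darcy = float(darcy.source_flow[claim.partition(t)].sum())
            assert abs(sol1d.flow[t] - q_darcy) <= max(
                1e-6 * abs(q_darcy), 1e-12)
        # total 1D inflow equals total Darcy sink outflow (p_sink = 0)
        inflow = sum(sol1d.flow[r] for r in forest.roots)
        assert abs(inflow - darcy.sink_flow.sum()) / inflow < 1e-6
        # tissue flow nearly uniform, slightly reduced far from the sources
        qv = darcy.source_flow / bm.mesh.element_volume
        d = np.minimum(
            np.linalg.norm(bm.mesh.element_centroid - [0, 0, -10.0], axis=1),
            np.linalg.norm(bm.mesh.element_centroid - [0, 0, 10.0], axis=1))
        assert qv[d < 7].mean() > qv[d > 13].mean()
        assert qv.std() / qv.mean() < 0.1

    def test_beta_sink_adjustment_matches_prescribed_flow(self, minimal_system):
        # the 2% beta_sink authority moves the total flow by only
        # ~ bs/(bs+bk) * 2% here, so ask for a target inside that range
        mesh, demand, forest, claim, cpl = minimal_system
        sol0, _, _ = run_coupled_perfusion(forest, mesh, demand, claim,
                                           coupling=cpl)
        target = sol0.flow[0] * 1.002
        sol1, darcy1, _ = run_coupled_perfusion(
            forest, mesh, demand, claim, coupling=cpl,
            prescribed_total_flow=target)
        assert darcy1.source_flow.sum() == pytest.approx(target, rel=1e-6)

    def test_beta_sink_adjustment_stops_at_bound(self, minimal_system):
        # an unreachable target pins the adjustment at the bound (warned)
        mesh, demand, forest, claim, cpl = minimal_system
        sol0, _, _ = run_coupled_perfusion(forest, mesh, demand, claim,
                                           coupling=cpl)
        sol1, darcy1, _ = run_coupled_perfusion(
            forest, mesh, demand, claim, coupling=cpl,
            prescribed_total_flow=sol0.flow[0] * 1.5)
        got = darcy1.source_flow.sum()
        assert sol0.flow[0] < got < sol0.flow[0] * 1.01  # moved, but bounded

    def test_nonconvergence_raises_with_history(self, minimal_system):
        mesh, demand, forest, claim, cpl = minimal_system
        cfg = CouplingConfig(max_iterations=2, flow_tolerance=1e-14,
                             pressure_tolerance=1e-14)
        with pytest.raises(RuntimeError, match="did not converge"):
            run_coupled_perfusion(forest, mesh, demand, claim, coupling=cpl,
                                  config=cfg)


class TestReport:
    def test_two_source_report_ratios(self, gbo567):
        bm, forest, claim, _ = gbo567
        df = report(forest, bm.mesh, bm.demand, claim)
        assert len(df) == 2
        for col in ("tissue_volume_ml_ratio", "total_flow_ml_s_ratio",
                    "tree_volume_ml_ratio"):
            assert 0.9 <= df[col].iloc[0] <= 1.1
        # volumes recomputed from the forest agree with the report
        from vasgrow.vascular_forest import tree_volume
        for _, row in df.iterrows():
            assert row["tree_volume_ml"] == pytest.approx(
                tree_volume(forest, source_id=int(row["source"])))

    def test_empty_run_gives_header_only(self):
        df = report(VascularForest(),
                    TissueMesh(np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0],
                                         [0, 0, 1.0]]),
                               np.array([[0, 1, 2, 3]])),
                    DemandField(np.array([1.0]), np.array([1.0])),
                    ClaimMap(np.array([-1])))
        assert len(df) == 0 and "tree_volume_ml" in df.columns
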