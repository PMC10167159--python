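"""Forest data model: binary identity, power-law radii, loss, round trips."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize_scalar

from vasgrow.fixtures import random_binary_forest
from vasgrow.vascular_forest import (
    GeometricParams, OptimizationParams, VascularForest,
    assign_flows_and_radii, count_segments, forest_to_frame, loss,
    read_forest, segment_loss, tree_volume, validate_binary, write_forest,
)


class TestCountSegments:
    def test_brain_scale_counts(self):
        assert count_segments(58, 9713) == 19368

    @pytest.mark.parametrize("roots,terms,expected", [(1, 1, 1), (1, 2, 3)])
    def test_small_cases(self, roots, terms, expected):
        assert count_segments(roots, terms) == expected

    def test_invalid(self):
        with pytest.raises(ValueError):
            count_segments(5, 3)
        with pytest.raises(ValueError):
            count_segments(0, 3)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(1, 4), st.integers(0, 30), st.integers(0, 10**6))
    def test_identity_on_random_forests(self, n_roots, extra, seed):
        n_terminals = n_roots + extra
        forest = random_binary_forest(np.random.default_rng(seed),
                                      n_roots, n_terminals)
        assert validate_binary(forest) == 2 * n_terminals - n_roots


class TestFlowsAndRadii:
    def test_qmin_terminal_gets_rmin(self):
        geo = GeometricParams(r_min=0.05, q_min=0.02)
        f = VascularForest()
        f.new_segment([0, 0, 0], [1, 0, 0])
        assign_flows_and_radii(f, {0: geo.q_min}, geo)
        assert f.segments[0].radius == pytest.approx(geo.r_min)

    def test_symmetric_bifurcation_murray(self):
        geo = GeometricParams(power_law_exponent=3.0, r_min=0.1, q_min=1.0)
        f = VascularForest()
        f.new_segment([0, 0, 0], [0, 0, 1])
        f.new_segment([0, 0, 1], [1, 0, 2], parent=0)
        f.new_segment([0, 0, 1], [-1, 0, 2], parent=0)
        assign_flows_and_radii(f, {1: 1.0, 2: 1.0}, geo)
        assert f.segments[0].radius == pytest.approx(
            2 ** (1 / 3) * f.segments[1].radius)

    def test_three_terminal_root_radius(self):
        # flows q_min, q_min, 2q_min sum to 4 q_min at the root: r = 4^(1/3) r_min
        geo = GeometricParams(power_law_exponent=3.0, r_min=0.05, q_min=0.01)
        f = VascularForest()
        f.new_segment([0, 0, 0], [0, 0, 1])              # root
        f.new_segment([0, 0, 1], [0, 1, 2], parent=0)    # inner
        f.new_segment([0, 0, 1], [0, -1, 2], parent=0)   # terminal 2q
        f.new_segment([0, 1, 2], [1, 1, 3], parent=1)
        f.new_segment([0, 1, 2], [-1, 1, 3], parent=1)
        assign_flows_and_radii(f, {2: 2 * geo.q_min, 3: geo.q_min,
                                   4: geo.q_min}, geo)
        assert f.segments[0].radius == pytest.approx(4 ** (1 / 3) * geo.r_min)

    def test_missing_terminal_flow_raises(self):
        f = VascularForest()
        f.new_segment([0, 0, 0], [1, 0, 0])
        with pytest.raises(ValueError):
            assign_flows_and_radii(f, {}, GeometricParams())

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(0, 10**6), st.floats(2.0, 4.0))
    def test_bifurcation_law_holds_everywhere(self, seed, k):
        geo = GeometricParams(power_law_exponent=k)
        forest = random_binary_forest(np.random.default_rng(seed), 2, 12, geo)
        for seg in forest.segments.values():
            if len(seg.children) == 2:
                r0 = forest.segments[seg.id].radius
                r1, r2 = (forest.segments[c].radius for c in seg.children)
                assert abs(r0**k - (r1**k + r2**k)) <= 1e-9 * r0**k
            if seg.children:
                q_c = sum(forest.segments[c].flow for c in seg.children)
                assert seg.flow == pytest.approx(q_c, rel=1e-14)


class TestTreeVolume:
    def test_single_segment(self):
        f = VascularForest()
        s = f.new_segment([0, 0, 0], [1, 0, 0])
        s.radius = 0.1
        assert tree_volume(f) == pytest.approx(math.pi * 0.01)

    def test_empty_and_per_source_additivity(self):
        assert tree_volume(VascularForest()) == 0.0
        forest = random_binary_forest(np.random.default_rng(5), 3, 9)
        per_source = sum(tree_volume(forest, source_id=s) for s in range(3))
        assert per_source == pytest.approx(tree_volume(forest))

    def test_unknown_source(self):
        forest = random_binary_forest(np.random.default_rng(5), 1, 3)
        with pytest.raises(KeyError):
            tree_volume(forest, source_id=99)


class TestLoss:
    def test_viscous_term_only(self):
        val = segment_loss(1.0, 0.1, 1.0, mu=0.04, beta=0.0)
        assert val == pytest.approx(8 * 0.04 / (math.pi * 0.1**4), rel=1e-12)
        assert val == pytest.approx(1018.59, rel=1e-4)

    def test_metabolic_term_only(self):
        assert segment_loss(1.0, 0.1, 0.0, mu=0.04, beta=1.0) == pytest.approx(
            math.pi * 0.01, rel=1e-12)

    def test_zero_radius_raises(self):
        with pytest.raises(ValueError):
            segment_loss(1.0, 0.0, 1.0, 0.04, 1.0)

    def test_optimal_radius_closed_form(self):
        # dL/dr = 0 at r* = (16 mu q^2 / (pi^2 beta))^(1/6)
        mu, beta, q, length = 0.04, 500.0, 0.8, 2.0
        r_star = (16 * mu * q**2 / (math.pi**2 * beta)) ** (1 / 6)
        res = minimize_scalar(lambda r: segment_loss(length, r, q, mu, beta),
                              bounds=(1e-3, 10.0), method="bounded",
                              options={"xatol": 1e-10})
        assert res.x == pytest.approx(r_star, rel=1e-6)

    def test_matches_bruteforce_sum(self):
        geo = GeometricParams()
        opt = OptimizationParams(viscosity_mu=0.04, metabolic_coefficient_beta=3.0)
        forest = random_binary_forest(np.random.default_rng(11), 2, 15, geo)
        brute = sum(segment_loss(s.length, s.radius, s.flow, 0.04, 3.0)
                    for s in forest.segments.values())
        assert loss(forest, opt, geo) == pytest.approx(brute, rel=1e-14)


class TestSerialization:
    def test_round_trip_identity(self, tmp_path):
        forest = random_binary_forest(np.random.default_rng(3), 2, 20)
        path = tmp_path / "forest.csv"
        write_forest(forest, path)
        back = read_forest(path)
        assert forest_to_frame(forest).equals(forest_to_frame(back))

    def test_cycle_detected(self, tmp_path):
        forest = random_binary_forest(np.random.default_rng(3), 1, 3)
        df = forest_to_frame(forest)
        # make the root a child of a terminal: creates a cycle
        df.loc[df["parent"] == -1, "parent"] = int(df["id"].iloc[-1])
        path = tmp_path / "cyclic.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError):
            read_forest(path)

    def test_flow_violation_strictness(self, tmp_path):
        forest = random_binary_forest(np.random.default_rng(3), 1, 3)
        df = forest_to_frame(forest)
        df.loc[0, "flow"] = df.loc[0, "flow"] * 3.0
        path = tmp_path / "bad_flow.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError):
            read_forest(path, strict=True)
        read_forest(path, strict=False)  # tolerated when not strict

    def test_malformed_file(self, tmp_path):
        path = tmp_path / "junk.csv"
        path.write_text("id,parent\n1,0\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_forest(path)
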