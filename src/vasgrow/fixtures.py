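"""Self-generated benchmark inputs: the two-source perfused sphere.

The idealized benchmark is a ball of radius 10 cm centred at the origin
with two source outlets of segmented radius 0.4 cm at the poles (0, 0, -10)
and (0, 0, 10), uniform metabolic demand 1.0 ml/min/g and tissue density
1.05 g/cm^3 (radially varying demand profiles are available for the
non-uniform studies).  Tree resolution is controlled by the target terminal
count n: the terminal flow quantum is q_min = Q_total/n and the minimum
radius follows from requiring the source radius r_min (Q/q_min)^(1/k) to
reach the segmented 0.4 cm when a source supplies half the total flow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from vasgrow.tissue_domain import (
    DemandField, TissueMesh, generate_sphere_tissue, make_demand_field,
    total_metabolic_flow,
)
from vasgrow.vascular_forest import GeometricParams, OptimizationParams
from vasgrow.gbo_growth import Source

SPHERE_RADIUS = 10.0       # cm
SOURCE_RADIUS = 0.4        # cm, both polar outlets
UNIFORM_DEMAND = 1.0       # ml/min/g
TISSUE_DENSITY = 1.05      # g/cm^3


@dataclass
class SphereBenchmark:
    mesh: TissueMesh
    demand: DemandField
    sources: list[Source]
    geo: GeometricParams
    opt: OptimizationParams
    growth_step: float
    n_terminals_target: int


def default_edge_length(n_terminals: int) -> float:
    """Mesh edge length giving roughly 2.5 elements per target terminal.

    The tessellation produces ~12 tets per edge_length^3 of volume, so
    a = (12 V / n_elements)^(1/3), floored so coarse runs stay resolvable.
    """
    n_elements = max(1500, int(2.5 * n_terminals))
    v = 4.0 / 3.0 * np.pi * SPHERE_RADIUS**3
    return float(min(2.2, (12.0 * v / n_elements) ** (1.0 / 3.0)))


def sphere_benchmark(
    n_terminals: int = 567,
    edge_length: float | None = None,
    demand_profile: str = "uniform",
    power_law_exponent: float = 3.0,
    viscosity_mu: float = 0.04,
) -> SphereBenchmark:
    """Build the two-source sphere benchmark at a given tree resolution.

    ``demand_profile`` is "uniform" (1.0 ml/min/g), "radial_decreasing"
    (3.0 at the centre to 0.3 at the periphery) or "radial_increasing"
    (0.1 to 1.5); the radial profiles are renormalized to the uniform
    profile's total flow so all cases demand the same total supply.
    """
    if edge_length is None:
        edge_length = default_edge_length(n_terminals)
    mesh = generate_sphere_tissue(SPHERE_RADIUS, edge_length)
    uniform = make_demand_field(mesh, "uniform", value=UNIFORM_DEMAND,
                                density=TISSUE_DENSITY)
    q_total = total_metabolic_flow(mesh, uniform)
    if demand_profile == "uniform":
        demand = uniform
    elif demand_profile == "radial_decreasing":
        demand = make_demand_field(mesh, "radial_linear", center_value=3.0,
                                   periphery_value=0.3, outer_radius=SPHERE_RADIUS,
                                   density=TISSUE_DENSITY, renormalize_to=q_total)
    elif demand_profile == "radial_increasing":
        demand = make_demand_field(mesh, "radial_linear", center_value=0.1,
                                   periphery_value=1.5, outer_radius=SPHERE_RADIUS,
                                   density=TISSUE_DENSITY, renormalize_to=q_total)
    else:
        raise ValueError(f"unknown demand profile {demand_profile!r}")

    q_min = q_total / n_terminals
    k = power_law_exponent
    r_min = SOURCE_RADIUS * (q_min / (q_total / 2.0)) ** (1.0 / k)
    growth_step = 2.0 * float(np.mean(mesh.element_volume)) ** (1.0 / 3.0)
    geo = GeometricParams(power_law_exponent=k, r_min=r_min, q_min=q_min,
                          l_min=3.0 * growth_step,
                          source_distance_criterion=2.0 * growth_step)
    opt = OptimizationParams(viscosity_mu=viscosity_mu)
    sources = [
        Source(id=0, location=np.array([0.0, 0.0, -SPHERE_RADIUS]),
               segmented_radius=SOURCE_RADIUS),
        Source(id=1, location=np.array([0.0, 0.0, SPHERE_RADIUS]),
               segmented_radius=SOURCE_RADIUS),
    ]
    return SphereBenchmark(mesh, demand, sources, geo, opt, growth_step,
                           n_terminals)


def random_binary_forest(rng, n_roots: int, n_terminals: int,
                         geo: GeometricParams | None = None):
    """A random strictly binary forest with power-law flows and radii.

    Built by repeatedly splitting a random segment and attaching a new
    terminal (no optimization); useful for structural and serialization
    tests.  ``rng`` is a numpy Generator; terminal flows are uniform in
    [0.5, 3] x q_min.
    """
    from vasgrow.vascular_forest import VascularForest, assign_flows_and_radii

    geo = geo or GeometricParams()
    forest = VascularForest()
    for r in range(n_roots):
        base = rng.standard_normal(3)
        forest.new_segment(base, base + rng.standard_normal(3) * 0.5 + 1.0,
                           source_id=r)
    n_term = n_roots
    while n_term < n_terminals:
        sid = int(rng.integers(forest._next_id))  # ids are contiguous
        seg = forest.segments[sid]
        t = rng.uniform(0.2, 0.8)
        x_j = seg.proximal + t * (seg.distal - seg.proximal)
        x_t = x_j + rng.standard_normal(3) * 0.3 + 0.2
        prox = forest.new_segment(seg.proximal, x_j, parent=None,
                                  source_id=seg.source_id)
        forest.roots.remove(prox.id)
        prox.parent = seg.parent
        if seg.parent is None:
            forest.roots[forest.roots.index(sid)] = prox.id
        else:
            pc = forest.segments[seg.parent].children
            pc[pc.index(sid)] = prox.id
        seg.parent = prox.id
        seg.proximal = x_j
        prox.children = [sid]
        forest.new_segment(x_j, x_t, parent=prox.id, source_id=seg.source_id)
        n_term += 1
    flows = {t: float(rng.uniform(0.5, 3.0)) * geo.q_min
             for t in forest.terminal_ids}
    assign_flows_and_radii(forest, flows, geo)
    return forest


def mirror_symmetric_mesh() -> TissueMesh:
    """A tiny exactly z-mirror-symmetric tet mesh (for symmetry tests).

    An octahedron-like arrangement split into tets that map onto each other
    under z -> -z.
    """
    verts = np.array([
        [0.0, 0.0, 0.0],
        [1.0, 0.0, 0.0], [-1.0, 0.0, 0.0],
        [0.0, 1.0, 0.0], [0.0, -1.0, 0.0],
        [0.0, 0.0, 1.0], [0.0, 0.0, -1.0],
    ])
    tets = np.array([
        [0, 1, 3, 5], [0, 3, 2, 5], [0, 2, 4, 5], [0, 4, 1, 5],
        [0, 3, 1, 6], [0, 2, 3, 6], [0, 4, 2, 6], [0, 1, 4, 6],
    ])
    return TissueMesh(verts, tets)
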