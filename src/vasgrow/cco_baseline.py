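"""Constrained constructive optimization (CCO) baseline tree generator.

Classical single-source CCO: terminal locations are sampled at random from
the tissue (here, uniformly over element centroids not yet used), accepted
if they respect an adaptive distance criterion to the existing tree, and
connected to the candidate segment and bifurcation point that minimize the
work-loss increase.  Radii follow the same power law q ~ r^k as the
growth-based generator, so bifurcations satisfy r0^k = r1^k + r2^k by
construction and the two algorithms are compared at identical parameters.

The generator is fully reproducible: an identical seed yields an identical
forest.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from vasgrow.tissue_domain import ClaimMap, DemandField, TissueMesh, element_flow
from vasgrow.vascular_forest import (
    GeometricParams, OptimizationParams, VascularForest, assign_flows_and_radii,
)
from vasgrow.gbo_growth import (
    Source, _point_segment_distance, _path_delta, optimize_bifurcation,
)

logger = logging.getLogger(__name__)


@dataclass
class CCOParams:
    """Controls for the CCO loop.

    n_terminals : target terminal count
    seed : RNG seed (identical seed => identical forest)
    distance_factor : initial separation criterion as a multiple of the
        current mean supply radius (V_domain / n_current)^(1/3)
    shrink : multiplicative schedule applied after max_rejections failures
    max_candidates : nearest segments evaluated per accepted location
    """

    n_terminals: int = 100
    seed: int = 0
    distance_factor: float = 0.9
    shrink: float = 0.9
    max_rejections: int = 50
    max_candidates: int = 8

    def __post_init__(self):
        if self.n_terminals < 1:
            raise ValueError("n_terminals must be >= 1")


def run_cco(
    mesh: TissueMesh,
    demand: DemandField,
    source: Source,
    cco: CCOParams,
    geo: GeometricParams,
    opt: OptimizationParams,
    domain_elements: np.ndarray | None = None,
    refine_3d: bool = True,
) -> tuple[VascularForest, ClaimMap]:
    """Generate one CCO tree from a single source outlet.

    ``domain_elements`` restricts the perfused domain to a subset of mesh
    elements (e.g. one hemisphere when emulating per-source runs).  Each
    terminal carries an equal share Q_domain / n_terminals of the domain's
    metabolic flow.  Returns the forest and a claim map assigning every
    domain element to its nearest terminal.
    """
    rng = np.random.default_rng(cco.seed)
    if domain_elements is None:
        domain_elements = np.arange(mesh.n_elements)
    domain_elements = np.asarray(domain_elements, dtype=np.int64)
    e_flow = element_flow(mesh, demand)
    q_total = float(e_flow[domain_elements].sum())
    if q_total <= 0:
        raise ValueError("domain has zero metabolic demand")
    q_term = q_total / cco.n_terminals
    v_domain = float(mesh.element_volume[domain_elements].sum())
    centroids = mesh.element_centroid[domain_elements]
    mu = opt.viscosity_mu
    beta = opt.beta(geo)

    forest = VascularForest()
    free = np.ones(len(domain_elements), dtype=bool)

    # first terminal: the domain centroid region seeds a single root segment
    d0 = np.linalg.norm(centroids - centroids.mean(axis=0), axis=1)
    first = int(np.argmin(d0))
    root = forest.new_segment(source.location, centroids[first], parent=None,
                              source_id=source.id, flow=q_term)
    free[first] = False
    source.root_segment = root.id

    n_placed = 1
    d_crit = cco.distance_factor * (v_domain / max(n_placed, 1)) ** (1.0 / 3.0)
    rejections = 0
    while n_placed < cco.n_terminals:
        free_idx = np.nonzero(free)[0]
        if len(free_idx) == 0:
            logger.warning("CCO: element centroids exhausted at %d terminals", n_placed)
            break
        pick = int(rng.integers(len(free_idx)))
        x_t = centroids[free_idx[pick]]
        segs = sorted(forest.segments.values(), key=lambda s: s.id)
        a = np.array([s.proximal for s in segs])
        b = np.array([s.distal for s in segs])
        dist = _point_segment_distance(x_t, a, b)
        if dist.min() < d_crit:
            rejections += 1
            if rejections >= cco.max_rejections:
                d_crit *= cco.shrink  # scale the search bound back
                rejections = 0
                logger.debug("CCO: distance criterion shrunk to %.3f cm", d_crit)
            continue
        rejections = 0
        order = np.argsort(dist, kind="stable")[:cco.max_candidates]
        best = (math.inf, -1, None)
        for i in order.tolist():
            sid = segs[i].id
            pdelta = _path_delta(forest, sid, q_term, mu, beta, geo)
            x_j, local = optimize_bifurcation(a[i], b[i], x_t, segs[i].flow,
                                              q_term, mu, beta, geo,
                                              refine_3d=refine_3d)
            if local + pdelta < best[0]:
                best = (local + pdelta, sid, x_j)
        _, sid, x_j = best
        _insert_terminal(forest, sid, x_j, x_t, source)
        free[free_idx[pick]] = False
        n_placed += 1
        _bump_path_flows(forest, q_term)  # keeps candidate costs current
        d_crit = cco.distance_factor * (v_domain / n_placed) ** (1.0 / 3.0)

    terminals = forest.terminal_ids
    assign_flows_and_radii(forest, {t: q_term for t in terminals}, geo)
    forest.validate(strict=True)

    # claim map: each domain element goes to its nearest terminal
    term_pos = np.array([forest.segments[t].distal for t in terminals])
    claim = ClaimMap.empty(mesh.n_elements)
    from scipy.spatial import cKDTree
    _, nearest = cKDTree(term_pos).query(centroids)
    claim.owner[domain_elements] = np.asarray(terminals)[nearest]
    return forest, claim


def _insert_terminal(forest: VascularForest, sid: int, x_j: np.ndarray,
                     x_t: np.ndarray, source: Source) -> int:
    """Split segment sid at x_j and attach a new terminal at x_t."""
    seg = forest.segments[sid]
    a, b = seg.proximal, seg.distal
    if np.linalg.norm(x_j - a) < 1e-6 or np.linalg.norm(b - x_j) < 1e-6:
        ab = b - a
        t = float(np.clip(np.dot(x_j - a, ab) / max(np.dot(ab, ab), 1e-300),
                          0.05, 0.95))
        x_j = a + t * ab
    prox = forest.new_segment(a, x_j, parent=None, source_id=seg.source_id)
    forest.roots.remove(prox.id)
    prox.parent = seg.parent
    if seg.parent is None:
        forest.roots[forest.roots.index(sid)] = prox.id
        if source.root_segment == sid:
            source.root_segment = prox.id
    else:
        pc = forest.segments[seg.parent].children
        pc[pc.index(sid)] = prox.id
    seg.parent = prox.id
    seg.proximal = x_j
    prox.children = [sid]
    prox.flow = seg.flow
    term = forest.new_segment(x_j, x_t, parent=prox.id, source_id=seg.source_id)
    term.flow = 0.0
    return term.id


def _bump_path_flows(forest: VascularForest, q_term: float) -> None:
    """Add the newest terminal's flow along its rootward path."""
    newest = max(forest.segments)
    forest.segments[newest].flow = q_term
    cur = forest.segments[newest].parent
    while cur is not None:
        forest.segments[cur].flow += q_term
        cur = forest.segments[cur].parent
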