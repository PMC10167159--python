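"""Growth-based synthetic tree generation (GBO).

Tissue and vessels grow in tandem.  Starting from each eligible source
outlet (scaled down to the minimum radius r_min and supplying q_min), the
claimed tissue expands each iteration into the unclaimed elements within
the growth reach of the nearest terminal (an anisotropic-distance Voronoi
competition between all live terminals).  The metabolic demand of the newly
claimed tissue determines how many new terminal segments are created
(half-up rounding of the flow increment over q_min); each new terminal is
placed at an element centroid of the newly claimed region and connected to
its source's tree at the attachment segment and bifurcation point that
minimize the work-loss increase, searched over candidate segments within
the search length l_min.  The radius at a source grows with its accumulated
flow, r = r_min (Q/q_min)^(1/k), and the source is complete once that
radius reaches its segmented radius.

The algorithm contains no randomness.  Candidate evaluation within one
iteration is a pure function of the iteration-start snapshot, so it can be
farmed out to workers; mutations are applied at a barrier in canonical
terminal order, which makes the output bit-identical for any worker count.
"""

from __future__ import annotations

import logging
import math
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from vasgrow.tissue_domain import (
    ClaimMap, DemandField, TissueMesh, UNCLAIMED, element_flow,
)
from vasgrow.vascular_forest import (
    GeometricParams, OptimizationParams, VascularForest,
    assign_flows_and_radii, loss as forest_loss, tree_volume,
)

logger = logging.getLogger(__name__)

_GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


@dataclass
class Source:
    """A segmented outlet from which a synthetic tree grows."""

    id: int
    location: np.ndarray
    segmented_radius: float
    current_radius: float = 0.0
    eligible: bool = True
    complete: bool = False
    root_segment: int | None = None

    def __post_init__(self):
        self.location = np.asarray(self.location, dtype=float)


@dataclass
class GrowthState:
    """The iterate of the growth loop: claimed tissue + current forest."""

    mesh: TissueMesh
    demand: DemandField
    geo: GeometricParams
    opt: OptimizationParams
    sources: list[Source]
    forest: VascularForest
    claim: ClaimMap
    growth_step: float  # cm; reach 1/c of the isotropic growth-rate vector
    iteration: int = 0
    growth_vectors: dict[int, np.ndarray] = field(default_factory=dict)
    reach_multiplier: float = 1.0  # per-iteration growth-rate escalation
    fallback_connections: int = 0

    def terminal_positions(self, terminal_ids: list[int]) -> np.ndarray:
        return np.array([self.forest.segments[t].distal for t in terminal_ids])

    def live_terminal_ids(self) -> list[int]:
        """Terminals of incomplete sources, in canonical (id) order."""
        incomplete = {s.id for s in self.sources if s.eligible and not s.complete}
        return sorted(t for t in self.forest.terminal_ids
                      if self.forest.segments[t].source_id in incomplete)

    def growth_vector(self, terminal_id: int) -> np.ndarray:
        """Per-axis growth rate c (1/cm); isotropic 1/h unless overridden.

        The per-iteration reach h may be escalated (reach_multiplier) when a
        coarse tree cannot advance its front within the base reach.
        """
        if terminal_id in self.growth_vectors:
            return self.growth_vectors[terminal_id] / self.reach_multiplier
        return np.full(3, 1.0 / (self.growth_step * self.reach_multiplier))

    def source_flow(self, source_id: int) -> float:
        """Accumulated flow of a source = demand of its claimed territory."""
        e_flow = element_flow(self.mesh, self.demand)
        ids = {t for t in self.forest.segments
               if self.forest.segments[t].source_id == source_id}
        mask = np.isin(self.claim.owner, list(ids))
        return float(e_flow[mask].sum())


# ---------------------------------------------------------------------------
# initialization


def init_sources(
    outlets: list[Source],
    mesh: TissueMesh,
    demand: DemandField,
    geo: GeometricParams,
    opt: OptimizationParams,
    growth_step: float | None = None,
) -> GrowthState:
    """Define eligible sources, their initial claims and terminal segments.

    Each eligible outlet starts at radius r_min with flow q_min; its initial
    tissue is claimed nearest-first (by centroid distance) until the claimed
    metabolic flow reaches the outlet flow, and one terminal segment is
    created from the outlet into the claimed region.
    """
    e_flow = element_flow(mesh, demand)
    if e_flow.sum() <= 0:
        raise ValueError("tissue demand is zero everywhere; nothing to perfuse")
    if growth_step is None:
        growth_step = 2.0 * float(np.mean(mesh.element_volume)) ** (1.0 / 3.0)
    # work on copies: growth mutates radius/completion/root bookkeeping
    outlets = [Source(o.id, o.location.copy(), o.segmented_radius) for o in outlets]

    centroids = mesh.element_centroid
    forest = VascularForest()
    claim = ClaimMap.empty(mesh.n_elements)

    any_eligible = False
    for src in outlets:
        d_near = float(np.min(np.linalg.norm(centroids - src.location, axis=1)))
        src.eligible = d_near <= geo.source_distance_criterion
        if not src.eligible:
            logger.warning("source %d at %s excluded: %.2f cm from tissue",
                           src.id, src.location, d_near)
            continue
        any_eligible = True
    if not any_eligible:
        raise ValueError("no eligible source outlet within the distance criterion")

    for src in sorted((s for s in outlets if s.eligible), key=lambda s: s.id):
        src.current_radius = geo.r_min
        dist = np.linalg.norm(centroids - src.location, axis=1)
        order = np.lexsort((np.arange(mesh.n_elements), dist))
        picked = []
        q_acc = 0.0
        for e in order:
            if claim.owner[e] != UNCLAIMED:
                continue
            picked.append(e)
            q_acc += e_flow[e]
            if q_acc >= geo.q_min:
                break
        if not picked:
            raise ValueError(f"source {src.id}: no unclaimed tissue to start from")
        w = e_flow[picked]
        target = np.average(centroids[picked], axis=0,
                            weights=w if w.sum() > 0 else None)
        snap = picked[int(np.argmin(np.linalg.norm(centroids[picked] - target, axis=1)))]
        distal = centroids[snap]
        if np.linalg.norm(distal - src.location) < 1e-9:
            distal = distal + np.array([0.0, 0.0, 1e-6])
        seg = forest.new_segment(src.location, distal, parent=None,
                                 source_id=src.id)
        src.root_segment = seg.id
        claim.owner[picked] = seg.id

    state = GrowthState(mesh, demand, geo, opt,
                        [s for s in outlets], forest, claim, growth_step)
    _reassign_flows(state)
    for src in state.sources:
        if src.eligible:
            update_source_radius(state, src.id)
    return state


# ---------------------------------------------------------------------------
# tissue growth: scaled-distance Voronoi competition


def _assignments(state: GrowthState, terminal_ids: list[int]) -> np.ndarray:
    """Owner (index into terminal_ids, or -1) for every unclaimed element.

    An unclaimed element x is claimed by terminal p iff its scaled distance
    d_p(x) = ||c_p o (x - x_p)|| is < 1 and <= d_k(x) for all competitors k;
    ties go to the lowest terminal id.
    """
    unclaimed = state.claim.unclaimed_indices
    out = np.full(len(unclaimed), -1, dtype=np.int64)
    if len(unclaimed) == 0 or not terminal_ids:
        return out
    x = state.mesh.element_centroid[unclaimed]
    pos = state.terminal_positions(terminal_ids)
    vectors = [state.growth_vector(t) for t in terminal_ids]
    isotropic = (not state.growth_vectors) or all(
        np.allclose(v, vectors[0]) for v in vectors)

    if isotropic and len(terminal_ids) > 8:
        h = 1.0 / vectors[0][0]
        tree = cKDTree(pos)
        k = min(2, len(terminal_ids))
        d, idx = tree.query(x, k=k)
        d = np.atleast_2d(d.reshape(len(x), -1))
        idx = np.atleast_2d(idx.reshape(len(x), -1))
        best = idx[:, 0].copy()
        if k == 2:
            tie = d[:, 0] == d[:, 1]
            best[tie] = np.minimum(idx[tie, 0], idx[tie, 1])
        within = d[:, 0] / h < 1.0
        out[within] = best[within]
        return out

    # general (anisotropic / small) path: exact brute force
    d = np.empty((len(x), len(terminal_ids)))
    for j, (p, c) in enumerate(zip(pos, vectors)):
        d[:, j] = np.linalg.norm((x - p) * c, axis=1)
    best = np.argmin(d, axis=1)  # argmin takes the first (lowest id) on ties
    within = d[np.arange(len(x)), best] < 1.0
    out[within] = best[within]
    return out


def growth_region(state: GrowthState, terminal_id: int) -> np.ndarray:
    """Element indices this terminal would claim in the current iteration."""
    live = state.live_terminal_ids()
    if terminal_id not in live:
        raise ValueError(f"{terminal_id} is not a live terminal")
    unclaimed = state.claim.unclaimed_indices
    assign = _assignments(state, live)
    j = live.index(terminal_id)
    return unclaimed[assign == j]


def grow_tissue(state: GrowthState) -> dict[int, np.ndarray]:
    """Claim the union of all growth regions; returns {terminal: new elems}.

    Mutates state.claim (monotone: only UNCLAIMED elements change owner).
    """
    live = state.live_terminal_ids()
    unclaimed = state.claim.unclaimed_indices
    assign = _assignments(state, live)
    newly: dict[int, np.ndarray] = {}
    for j, t in enumerate(live):
        elems = unclaimed[assign == j]
        if len(elems):
            state.claim.owner[elems] = t
            newly[t] = elems
    return newly


# ---------------------------------------------------------------------------
# terminal accounting


def new_terminal_count(q_new: float, q_old: float, q_min: float) -> int:
    """Number of new terminals: half-up rounding of (Q_new - Q_old)/q_min."""
    dq = q_new - q_old
    if dq < 0:
        raise ValueError("flow increment must be non-negative")
    return int(math.floor(dq / q_min + 0.5))


def update_source_radius(state: GrowthState, source_id: int) -> None:
    """Grow the source radius with its accumulated flow; flag completion."""
    src = next(s for s in state.sources if s.id == source_id)
    q = state.source_flow(source_id)
    if q > 0:
        src.current_radius = state.geo.r_min * (q / state.geo.q_min) ** (
            1.0 / state.geo.power_law_exponent)
    if src.current_radius >= src.segmented_radius:
        src.complete = True


# ---------------------------------------------------------------------------
# vessel creation: loss-minimizing connection of new terminals


def _seg_L(length: float, q: float, mu: float, beta: float, geo: GeometricParams) -> float:
    """Work rate of a segment carrying flow q at the power-law radius r(q)."""
    q = max(q, 1e-9 * geo.q_min)  # keep r^4 representable for vanishing flows
    r = geo.r_min * (q / geo.q_min) ** (1.0 / geo.power_law_exponent)
    return (8.0 * mu * length / (math.pi * r**4)) * q * q \
        + beta * math.pi * r * r * length


def _path_delta(forest: VascularForest, seg_id: int, q_t: float,
                mu: float, beta: float, geo: GeometricParams) -> float:
    """Loss change on the rootward path of seg when its flow gains q_t."""
    total = 0.0
    cur = forest.segments[seg_id].parent
    while cur is not None:
        s = forest.segments[cur]
        total += _seg_L(s.length, s.flow + q_t, mu, beta, geo) \
            - _seg_L(s.length, s.flow, mu, beta, geo)
        cur = s.parent
    return total


def _connection_cost(a, b, x_j, x_t, q_seg, q_t, mu, beta, geo) -> float:
    """Local loss delta of splitting (a->b) at x_j and attaching x_t."""
    la = float(np.linalg.norm(x_j - a))
    lb = float(np.linalg.norm(b - x_j))
    lt = float(np.linalg.norm(x_t - x_j))
    if la < 1e-9 or lb < 1e-9 or lt < 1e-9:
        return math.inf
    lab = float(np.linalg.norm(b - a))
    return (_seg_L(la, q_seg + q_t, mu, beta, geo)
            + _seg_L(lb, q_seg, mu, beta, geo)
            + _seg_L(lt, q_t, mu, beta, geo)
            - _seg_L(lab, q_seg, mu, beta, geo))


def optimize_bifurcation(a: np.ndarray, b: np.ndarray, x_t: np.ndarray,
                         q_seg: float, q_t: float, mu: float, beta: float,
                         geo: GeometricParams, refine_3d: bool = True
                         ) -> tuple[np.ndarray, float]:
    """Best junction point for attaching a terminal at x_t to segment (a,b).

    Golden-section search of the split parameter along the segment, then a
    short pattern-search refinement of the junction position in 3D.
    Returns (x_j, local loss delta).
    """
    def cost_s(s: float) -> float:
        return _connection_cost(a, b, a + s * (b - a), x_t, q_seg, q_t, mu, beta, geo)

    lo, hi = 0.02, 0.98
    c1 = hi - _GOLDEN * (hi - lo)
    c2 = lo + _GOLDEN * (hi - lo)
    f1, f2 = cost_s(c1), cost_s(c2)
    for _ in range(24):
        if f1 <= f2:
            hi, c2, f2 = c2, c1, f1
            c1 = hi - _GOLDEN * (hi - lo)
            f1 = cost_s(c1)
        else:
            lo, c1, f1 = c1, c2, f2
            c2 = lo + _GOLDEN * (hi - lo)
            f2 = cost_s(c2)
    s_best = c1 if f1 <= f2 else c2
    x_j = a + s_best * (b - a)
    f_best = min(f1, f2)

    if refine_3d:
        step = 0.25 * float(np.linalg.norm(b - a))
        dirs = np.vstack([np.eye(3), -np.eye(3)])
        for _ in range(12):
            improved = False
            for d in dirs:
                cand = x_j + step * d
                fc = _connection_cost(a, b, cand, x_t, q_seg, q_t, mu, beta, geo)
                if fc < f_best:
                    x_j, f_best = cand, fc
                    improved = True
            if not improved:
                step *= 0.5
                if step < 1e-4:
                    break
    return x_j, f_best


def _point_segment_distance(x: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distances from point x to segments with endpoint arrays a, b."""
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    t = np.clip(np.einsum("ij,ij->i", x - a, ab) / np.maximum(denom, 1e-300), 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(x - proj, axis=1)


@dataclass
class _Placement:
    """One planned new terminal (pure evaluation result)."""

    order_key: tuple
    source_id: int
    position: np.ndarray
    elements: np.ndarray
    flow: float
    chosen_segment: int = -1
    junction: np.ndarray | None = None
    cost: float = math.inf
    candidate_costs: list[tuple[int, float]] = field(default_factory=list)
    fallback: bool = False


def _plan_placements(state: GrowthState, newly: dict[int, np.ndarray]) -> list[_Placement]:
    """Apportion new terminals over grown partitions and pick their positions.

    The per-source terminal budget is the half-up-rounded increment of the
    source's claimed flow over the flow already covered by its existing
    terminals (n * q_min), so rounding residues from earlier iterations are
    never lost.  The budget is apportioned over the partitions that grew,
    proportional to their claimed flow increment (largest-remainder method,
    deterministic tie-breaks).
    """
    e_flow = element_flow(state.mesh, state.demand)
    centroids = state.mesh.element_centroid
    by_source: dict[int, list[int]] = {}
    for t in sorted(newly):
        by_source.setdefault(state.forest.segments[t].source_id, []).append(t)

    n_terms_of = {}
    for t in state.forest.terminal_ids:
        s = state.forest.segments[t].source_id
        n_terms_of[s] = n_terms_of.get(s, 0) + 1

    placements: list[_Placement] = []
    for sid in sorted(by_source):
        terms = by_source[sid]
        dq = {t: float(e_flow[newly[t]].sum()) for t in terms}
        dq_total = sum(dq.values())
        q_claimed = state.source_flow(sid)
        q_covered = n_terms_of[sid] * state.geo.q_min
        budget = new_terminal_count(max(q_claimed, q_covered), q_covered,
                                    state.geo.q_min)
        capacity = {t: len(newly[t]) for t in terms}
        if budget <= 0 or dq_total <= 0:
            continue
        # largest-remainder apportionment, clamped to per-partition capacity
        quota = {t: budget * dq[t] / dq_total for t in terms}
        m = {t: min(int(math.floor(quota[t])), capacity[t]) for t in terms}
        remaining = budget - sum(m.values())
        frac_order = sorted(terms, key=lambda t: (-(quota[t] - math.floor(quota[t])), t))
        while remaining > 0:
            progressed = False
            for t in frac_order:
                if remaining == 0:
                    break
                if m[t] < capacity[t]:
                    m[t] += 1
                    remaining -= 1
                    progressed = True
            if not progressed:
                break  # region exhausted; the cumulative budget re-emerges later

        for t in terms:
            if m[t] == 0:
                continue
            elems = np.sort(newly[t])
            pts = centroids[elems]
            x_p = state.forest.segments[t].distal
            # farthest-point sampling of m[t] positions among new centroids
            chosen = [int(np.argmax(np.round(np.linalg.norm(pts - x_p, axis=1), 12)))]
            dmin = np.linalg.norm(pts - pts[chosen[0]], axis=1)
            while len(chosen) < m[t]:
                nxt = int(np.argmax(np.round(dmin, 12)))
                chosen.append(nxt)
                dmin = np.minimum(dmin, np.linalg.norm(pts - pts[nxt], axis=1))
            # assign each newly claimed element to the nearest new position
            d = np.stack([np.linalg.norm(pts - pts[c], axis=1) for c in chosen])
            owner_idx = np.argmin(d, axis=0)
            for j, c in enumerate(chosen):
                sub = elems[owner_idx == j]
                placements.append(_Placement(
                    order_key=(sid, t, j), source_id=sid,
                    position=pts[c].copy(), elements=sub,
                    flow=float(e_flow[sub].sum())))
    placements.sort(key=lambda p: p.order_key)
    return placements


def _evaluate_connection(state: GrowthState, pl: _Placement,
                         seg_ids: np.ndarray, seg_a: np.ndarray, seg_b: np.ndarray,
                         refine_3d: bool, max_candidates: int = 6) -> _Placement:
    """Pure candidate evaluation against the iteration-start snapshot."""
    mu = state.opt.viscosity_mu
    beta = state.opt.beta(state.geo)
    geo = state.geo
    dist = _point_segment_distance(pl.position, seg_a, seg_b)
    within = np.nonzero(dist <= geo.l_min)[0]
    if len(within) == 0:
        within = np.array([int(np.argmin(dist))])
        pl.fallback = True
    elif len(within) > max_candidates:
        within = within[np.argsort(dist[within], kind="stable")[:max_candidates]]
    best = (math.inf, -1, None)
    for i in sorted(within.tolist()):
        sid = int(seg_ids[i])
        seg = state.forest.segments[sid]
        pdelta = _path_delta(state.forest, sid, pl.flow, mu, beta, geo)
        x_j, local = optimize_bifurcation(seg_a[i], seg_b[i], pl.position,
                                          seg.flow, pl.flow, mu, beta, geo,
                                          refine_3d=refine_3d)
        total = local + pdelta
        pl.candidate_costs.append((sid, total))
        if total < best[0]:
            best = (total, sid, x_j)
    pl.cost, pl.chosen_segment, pl.junction = best
    return pl


def _split_and_attach(state: GrowthState, pl: _Placement,
                      split_map: dict[int, tuple[int, int]]) -> int:
    """Apply one planned connection; returns the new terminal's segment id."""
    forest = state.forest
    sid = pl.chosen_segment
    x_j = pl.junction
    # resolve splits applied earlier this iteration: descend to the piece
    # nearest the planned junction (the distal piece keeps the original id)
    while sid in split_map:
        lo, hi = split_map[sid]
        d_lo = _point_segment_distance(x_j, forest.segments[lo].proximal[None],
                                       forest.segments[lo].distal[None])[0]
        d_hi = _point_segment_distance(x_j, forest.segments[hi].proximal[None],
                                       forest.segments[hi].distal[None])[0]
        choice = lo if d_lo <= d_hi else hi
        if choice == sid:
            break
        sid = choice
    seg = forest.segments[sid]
    a, b = seg.proximal, seg.distal
    # guard degenerate pieces: if the junction (possibly refined off the
    # segment line) collapses onto an endpoint, fall back to an interior
    # projection onto the segment
    if np.linalg.norm(x_j - a) < 1e-6 or np.linalg.norm(b - x_j) < 1e-6:
        ab = b - a
        t = float(np.clip(np.dot(x_j - a, ab) / max(np.dot(ab, ab), 1e-300),
                          0.05, 0.95))
        x_j = a + t * ab

    prox = forest.new_segment(a, x_j, parent=None, source_id=seg.source_id)
    # rewire: prox takes seg's parent; seg becomes the distal piece
    forest.roots.remove(prox.id)
    prox.parent = seg.parent
    if seg.parent is None:
        forest.roots[forest.roots.index(sid)] = prox.id
        src = next(s for s in state.sources if s.root_segment == sid)
        src.root_segment = prox.id
    else:
        pc = forest.segments[seg.parent].children
        pc[pc.index(sid)] = prox.id
    seg.parent = prox.id
    seg.proximal = x_j
    prox.children = [sid]
    prox.flow = seg.flow
    prox.radius = seg.radius
    split_map[sid] = (prox.id, sid)

    term = forest.new_segment(x_j, pl.position, parent=prox.id,
                              source_id=seg.source_id)
    state.claim.owner[pl.elements] = term.id
    if pl.fallback:
        state.fallback_connections += 1
        logger.debug("terminal %d: no candidate within l_min, nearest-segment fallback",
                     term.id)
    return term.id


def place_and_connect_terminals(
    state: GrowthState, newly: dict[int, np.ndarray],
    n_workers: int = 1, refine_3d: bool = True,
) -> list[_Placement]:
    """Create and connect the new terminals for one growth iteration.

    Candidate evaluation runs read-only against the iteration-start forest
    (optionally on a worker pool); connections are then applied sequentially
    in canonical order, so results do not depend on n_workers.
    """
    placements = _plan_placements(state, newly)
    if not placements:
        _reassign_flows(state)
        return placements

    # snapshot geometry per source
    per_source: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for sid in sorted({p.source_id for p in placements}):
        segs = sorted(state.forest.source_segments(sid), key=lambda s: s.id)
        per_source[sid] = (
            np.array([s.id for s in segs]),
            np.array([s.proximal for s in segs]),
            np.array([s.distal for s in segs]),
        )

    def work(pl: _Placement) -> _Placement:
        ids, a, b = per_source[pl.source_id]
        return _evaluate_connection(state, pl, ids, a, b, refine_3d)

    if n_workers > 1 and len(placements) > 1:
        with ThreadPoolExecutor(max_workers=n_workers) as pool:
            placements = list(pool.map(work, placements))
    else:
        placements = [work(pl) for pl in placements]

    split_map: dict[int, tuple[int, int]] = {}
    for pl in placements:  # canonical order (already sorted by order_key)
        _split_and_attach(state, pl, split_map)
    _reassign_flows(state)
    return placements


def _reassign_flows(state: GrowthState) -> None:
    """Terminal flows := metabolic demand of owned partitions; radii follow."""
    e_flow = element_flow(state.mesh, state.demand)
    owned = {t: 0.0 for t in state.forest.terminal_ids}
    owners = state.claim.owner
    mask = owners != UNCLAIMED
    np_owned = np.bincount(owners[mask], weights=e_flow[mask],
                           minlength=state.forest._next_id)
    for t in owned:
        owned[t] = float(np_owned[t]) if t < len(np_owned) else 0.0
    assign_flows_and_radii(state.forest, owned, state.geo)


# ---------------------------------------------------------------------------
# the full loop


def run_gbo(
    mesh: TissueMesh,
    demand: DemandField,
    sources: list[Source],
    geo: GeometricParams,
    opt: OptimizationParams,
    n_workers: int = 1,
    growth_step: float | None = None,
    max_iterations: int = 10_000,
    refine_3d: bool = True,
) -> tuple[VascularForest, ClaimMap, pd.DataFrame]:
    """Run growth-based tree generation to completion.

    Iterates {grow tissue -> count new terminals -> place & connect ->
    update radii} until every source is complete or the tissue is exhausted.
    Output is independent of ``n_workers``.

    Returns (forest, claim map, per-iteration log).
    """
    if n_workers < 1:
        raise ValueError("n_workers must be >= 1")
    state = init_sources(sources, mesh, demand, geo, opt, growth_step=growth_step)
    rows = []
    e_vol = mesh.element_volume
    max_reach = 64.0
    for _ in range(max_iterations):
        state.iteration += 1
        newly = grow_tissue(state)
        if not newly:
            if all(s.complete or not s.eligible for s in state.sources):
                break
            if len(state.claim.unclaimed_indices) == 0:
                logger.info("tissue exhausted at iteration %d", state.iteration)
                break
            # front cannot advance within the base reach (coarse trees):
            # escalate the per-iteration growth rate and retry
            if state.reach_multiplier < max_reach:
                state.reach_multiplier *= 2.0
                continue
            logger.warning(
                "no growth at iteration %d with incomplete sources; "
                "remaining tissue is out of reach", state.iteration)
            break
        state.reach_multiplier = 1.0
        place_and_connect_terminals(state, newly, n_workers=n_workers,
                                    refine_3d=refine_3d)
        for src in state.sources:
            if src.eligible and not src.complete:
                update_source_radius(state, src.id)
        rows.append({
            "iteration": state.iteration,
            "claimed_volume_ml": float(e_vol[state.claim.claimed].sum()),
            "Q_ml_s": float(sum(s.flow for r in state.forest.roots
                                for s in [state.forest.segments[r]])),
            "n_terminals": len(state.forest.terminal_ids),
            "loss": forest_loss(state.forest, opt, geo),
            "tree_volume_ml": tree_volume(state.forest),
        })
        if all(s.complete or not s.eligible for s in state.sources):
            break
    log = pd.DataFrame(rows)
    state.forest.validate(strict=True)
    return state.forest, state.claim, log


def map_perfusion_territories(forest: VascularForest, claim: ClaimMap) -> np.ndarray:
    """Per-element label = root outlet whose subtree perfuses the element.

    Unclaimed elements keep the UNCLAIMED label.  The labels partition the
    claimed tissue: every claimed element maps to exactly one root.
    """
    root_of = np.full(forest._next_id, UNCLAIMED, dtype=np.int64)
    for r in forest.roots:
        for i in forest.subtree_ids(r):
            root_of[i] = r
    label = np.full(len(claim.owner), UNCLAIMED, dtype=np.int64)
    mask = claim.owner != UNCLAIMED
    label[mask] = root_of[claim.owner[mask]]
    return label
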