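"""Binary-bifurcating vascular forests: geometry, Murray-law radii, work loss.

A forest is a set of trees, one per source outlet.  Segments are straight
lines with radius r (cm), length l (cm) and flow q (ml/s).  Radii follow the
power law q ~ r^k anchored at (r_min, q_min):

    r(q) = r_min * (q / q_min)^(1/k)

which makes the bifurcation law r0^k = r1^k + r2^k hold exactly wherever
flow is conserved (q0 = q1 + q2).  The work rate of maintaining and driving
blood through the network is

    L = sum_p [ 8 mu l_p q_p^2 / (pi r_p^4)  +  beta_p pi r_p^2 l_p ]

(viscous Poiseuille dissipation + metabolic cost of blood volume).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class GeometricParams:
    """Geometric constraint set for tree generation.

    power_law_exponent : k in r0^k = r1^k + r2^k (Murray: 3)
    allometric_exponent : p in Q ~ V^p for initial volumes (default 1)
    r_min : cm, minimum (terminal) vessel radius
    q_min : ml/s, flow of a minimum-radius terminal; fixes q ~ r^k constant
    l_min : cm, search length bounding candidate attachment segments
    source_distance_criterion : cm, outlet eligibility distance to tissue
    """

    power_law_exponent: float = 3.0
    allometric_exponent: float = 1.0
    r_min: float = 0.05
    q_min: float = 0.01
    l_min: float = 4.0
    source_distance_criterion: float = 2.0

    def __post_init__(self):
        if self.power_law_exponent <= 0:
            raise ValueError("power_law_exponent must be positive")
        for name in ("r_min", "q_min", "l_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def radius_of_flow(self, q) -> float | np.ndarray:
        return self.r_min * (np.asarray(q) / self.q_min) ** (1.0 / self.power_law_exponent)


@dataclass
class OptimizationParams:
    """Work-loss parameter set.

    viscosity_mu : poise (dyn s/cm^2); 0.04 is a common whole-blood value
    metabolic_coefficient_beta : scalar beta_p, energy per unit blood volume
        per unit time (consistent internal units).  None selects the
        self-consistent default for which the single-segment optimum radius
        of a q_min terminal equals r_min: beta = 16 mu q_min^2/(pi^2 r_min^6).
    """

    viscosity_mu: float = 0.04
    metabolic_coefficient_beta: float | None = None

    def __post_init__(self):
        if self.viscosity_mu <= 0:
            raise ValueError("viscosity must be positive")
        if self.metabolic_coefficient_beta is not None and self.metabolic_coefficient_beta < 0:
            raise ValueError("metabolic coefficient must be non-negative")

    def beta(self, geo: GeometricParams) -> float:
        if self.metabolic_coefficient_beta is not None:
            return self.metabolic_coefficient_beta
        return 16.0 * self.viscosity_mu * geo.q_min**2 / (math.pi**2 * geo.r_min**6)


@dataclass
class Segment:
    """One straight vessel segment."""

    id: int
    proximal: np.ndarray
    distal: np.ndarray
    radius: float = 0.0
    flow: float = 0.0
    parent: int | None = None
    children: list[int] = field(default_factory=list)
    source_id: int = 0

    def __post_init__(self):
        self.proximal = np.asarray(self.proximal, dtype=float)
        self.distal = np.asarray(self.distal, dtype=float)

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.distal - self.proximal))

    @property
    def is_terminal(self) -> bool:
        return len(self.children) == 0


class VascularForest:
    """A forest of binary vessel trees, one root per source outlet."""

    def __init__(self):
        self.segments: dict[int, Segment] = {}
        self.roots: list[int] = []
        self._next_id = 0

    # -- construction -----------------------------------------------------
    def new_segment(self, proximal, distal, parent: int | None = None,
                    source_id: int = 0, **kw) -> Segment:
        seg = Segment(self._next_id, proximal, distal, parent=parent,
                      source_id=source_id, **kw)
        self._next_id += 1
        self.segments[seg.id] = seg
        if parent is None:
            self.roots.append(seg.id)
        else:
            self.segments[parent].children.append(seg.id)
        return seg

    # -- queries ----------------------------------------------------------
    def __len__(self) -> int:
        return len(self.segments)

    @property
    def terminal_ids(self) -> list[int]:
        return [s.id for s in self.segments.values() if s.is_terminal]

    def source_segments(self, source_id: int) -> list[Segment]:
        segs = [s for s in self.segments.values() if s.source_id == source_id]
        if not segs:
            raise KeyError(f"unknown source_id {source_id}")
        return segs

    def path_to_root(self, seg_id: int) -> list[int]:
        path = []
        cur: int | None = seg_id
        while cur is not None:
            path.append(cur)
            cur = self.segments[cur].parent
        return path

    def subtree_ids(self, seg_id: int) -> list[int]:
        out, stack = [], [seg_id]
        while stack:
            i = stack.pop()
            out.append(i)
            stack.extend(self.segments[i].children)
        return out

    def root_of(self, seg_id: int) -> int:
        return self.path_to_root(seg_id)[-1]

    # -- validation -------------------------------------------------------
    def validate(self, strict: bool = True) -> None:
        """Check acyclicity, reachability, binary structure, conservation."""
        seen: set[int] = set()
        for r in self.roots:
            stack = [r]
            while stack:
                i = stack.pop()
                if i in seen:
                    raise ValueError(f"segment {i} reachable twice (cycle or shared child)")
                seen.add(i)
                seg = self.segments[i]
                for c in seg.children:
                    if self.segments[c].parent != i:
                        raise ValueError(f"parent/child mismatch at {i}->{c}")
                stack.extend(seg.children)
        if seen != set(self.segments):
            raise ValueError("segments unreachable from any root")
        for seg in self.segments.values():
            if seg.length <= 0:
                raise ValueError(f"segment {seg.id} has non-positive length")
            if strict and len(seg.children) == 1:
                raise ValueError(f"segment {seg.id} has a single child (non-binary)")
            if len(seg.children) > 2:
                raise ValueError(f"segment {seg.id} has >2 children")
            if seg.children and seg.flow > 0:
                qc = sum(self.segments[c].flow for c in seg.children)
                if strict and abs(seg.flow - qc) > 1e-9 * max(seg.flow, 1e-300):
                    raise ValueError(f"flow not conserved at segment {seg.id}")


def validate_binary(forest: VascularForest) -> int:
    """Assert the strictly binary forest identity and return segment count.

    A strictly binary forest with t terminals and r roots has 2t - r
    segments.
    """
    forest.validate(strict=True)
    n_t = len(forest.terminal_ids)
    n_r = len(forest.roots)
    n = len(forest)
    expected = count_segments(n_r, n_t)
    if n != expected:
        raise ValueError(f"binary-forest identity violated: {n} segments, expected {expected}")
    return n


def count_segments(n_roots: int, n_terminals: int) -> int:
    """Segment count of a strictly binary forest: 2*terminals - roots."""
    if n_roots < 1 or n_terminals < n_roots:
        raise ValueError("need n_terminals >= n_roots >= 1")
    return 2 * n_terminals - n_roots


def assign_flows_and_radii(
    forest: VascularForest, terminal_flows: dict[int, float], geo: GeometricParams
) -> VascularForest:
    """Set flows by rootward summation of terminal flows, radii via q ~ r^k.

    Mutates and returns ``forest``.  Every terminal must appear in
    ``terminal_flows`` with a non-negative flow.
    """
    for t in forest.terminal_ids:
        if t not in terminal_flows:
            raise ValueError(f"terminal {t} has no assigned flow")
        if terminal_flows[t] < 0:
            raise ValueError(f"terminal {t} has negative flow")
    # post-order accumulation
    for r in forest.roots:
        order = forest.subtree_ids(r)
        for i in reversed(order):
            seg = forest.segments[i]
            if seg.is_terminal:
                seg.flow = float(terminal_flows[i])
            else:
                seg.flow = sum(forest.segments[c].flow for c in seg.children)
    for seg in forest.segments.values():
        seg.radius = float(geo.radius_of_flow(seg.flow)) if seg.flow > 0 else geo.r_min
    return forest


def tree_volume(forest: VascularForest, source_id: int | None = None) -> float:
    """Total blood volume sum(pi r^2 l) in ml, optionally for one source."""
    if source_id is None:
        segs = forest.segments.values()
    else:
        segs = forest.source_segments(source_id)
    return float(sum(math.pi * s.radius**2 * s.length for s in segs))


def segment_loss(length: float, radius: float, flow: float, mu: float, beta: float) -> float:
    """Work rate of one segment: viscous + metabolic term."""
    if radius <= 0:
        raise ValueError("zero radius in loss evaluation")
    return (8.0 * mu * length / (math.pi * radius**4)) * flow**2 \
        + beta * math.pi * radius**2 * length


def loss(forest: VascularForest, opt: OptimizationParams,
         geo: GeometricParams | None = None) -> float:
    """Total work rate of the forest (sum of per-segment losses)."""
    beta = opt.beta(geo) if geo is not None else (opt.metabolic_coefficient_beta or 0.0)
    return float(sum(
        segment_loss(s.length, s.radius, s.flow, opt.viscosity_mu, beta)
        for s in forest.segments.values()
    ))


# ---------------------------------------------------------------------------
# serialization

_COLUMNS = ["id", "parent", "px", "py", "pz", "dx", "dy", "dz",
            "radius", "flow", "source", "terminal"]


def forest_to_frame(forest: VascularForest) -> pd.DataFrame:
    rows = []
    for s in sorted(forest.segments.values(), key=lambda s: s.id):
        rows.append([s.id, -1 if s.parent is None else s.parent,
                     *s.proximal, *s.distal, s.radius, s.flow,
                     s.source_id, int(s.is_terminal)])
    return pd.DataFrame(rows, columns=_COLUMNS)


def write_forest(forest: VascularForest, path) -> None:
    """Write a forest as a CSV table, one row per segment."""
    forest_to_frame(forest).to_csv(path, index=False, float_format="%.17g")


def read_forest(path, strict: bool = True) -> VascularForest:
    """Read a forest CSV written by :func:`write_forest` and validate it."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as e:  # pragma: no cover - pandas message passthrough
        raise ValueError(f"malformed forest file {path}: {e}") from e
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"forest file {path} missing columns {sorted(missing)}")
    forest = VascularForest()
    for i, row in enumerate(df.itertuples(index=False)):
        seg = Segment(int(row.id), np.array([row.px, row.py, row.pz]),
                      np.array([row.dx, row.dy, row.dz]),
                      radius=float(row.radius), flow=float(row.flow),
                      parent=None if row.parent < 0 else int(row.parent),
                      source_id=int(row.source))
        if seg.id in forest.segments:
            raise ValueError(f"duplicate segment id {seg.id} at line {i + 2}")
        forest.segments[seg.id] = seg
    for seg in forest.segments.values():
        if seg.parent is None:
            forest.roots.append(seg.id)
        else:
            if seg.parent not in forest.segments:
                raise ValueError(f"segment {seg.id} references unknown parent {seg.parent}")
            forest.segments[seg.parent].children.append(seg.id)
    for seg in forest.segments.values():
        seg.children.sort()
    forest._next_id = max(forest.segments) + 1 if forest.segments else 0
    forest.roots.sort()
    forest.validate(strict=strict)
    return forest
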