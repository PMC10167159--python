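"""Perfused tissue domain: tetrahedral meshes, metabolic demand fields, claims.

The tissue domain Omega is a tetrahedral mesh with per-element volume,
centroid, metabolic demand m_t (ml/min/g) and density rho (g/cm^3).  The
required blood flow of a set of elements is

    Q = sum_p m_p * rho_p * V_p / 60        [ml/s]

(the 1/60 converts the per-minute demand to per-second flow).  A ClaimMap
records which terminal vessel segment currently perfuses each element;
claims are monotone: once claimed, an element is never unclaimed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay

DEFAULT_DENSITY = 1.05  # g/cm^3, used when a demand field omits density

UNCLAIMED = -1

# Local vertex index pairs/faces of a tetrahedron; face i is opposite vertex i.
_TET_FACES = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])


@dataclass
class TissueMesh:
    """Tetrahedral tissue mesh.

    vertices : (n_v, 3) float array, cm
    elements : (n_e, 4) int array, tetrahedral connectivity
    """

    vertices: np.ndarray
    elements: np.ndarray
    _volumes: np.ndarray | None = field(default=None, repr=False)
    _centroids: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.elements = np.asarray(self.elements, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.elements.ndim != 2 or self.elements.shape[1] != 4:
            raise ValueError("elements must be (m, 4) tetrahedra")

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def element_volume(self) -> np.ndarray:
        """Per-element volume in ml."""
        if self._volumes is None:
            v = self.vertices[self.elements]
            d1 = v[:, 1] - v[:, 0]
            d2 = v[:, 2] - v[:, 0]
            d3 = v[:, 3] - v[:, 0]
            self._volumes = np.abs(np.einsum("ij,ij->i", np.cross(d1, d2), d3)) / 6.0
        return self._volumes

    @property
    def element_centroid(self) -> np.ndarray:
        if self._centroids is None:
            self._centroids = self.vertices[self.elements].mean(axis=1)
        return self._centroids

    @property
    def total_volume(self) -> float:
        return float(self.element_volume.sum())

    def boundary_faces(self) -> tuple[np.ndarray, np.ndarray]:
        """Faces on the boundary Gamma and their outward unit normals.

        Returns (faces, normals): faces is (n_f, 3) vertex indices oriented so
        the right-hand normal points out of the mesh; normals is (n_f, 3).
        """
        faces = self.elements[:, _TET_FACES].reshape(-1, 3)
        owner = np.repeat(np.arange(self.n_elements), 4)
        key = np.sort(faces, axis=1)
        _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
        on_boundary = counts[inv] == 1
        bfaces = faces[on_boundary]
        bowner = owner[on_boundary]
        # orient outward: normal must point away from the owning tet centroid
        p = self.vertices[bfaces]
        n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        to_cent = self.element_centroid[bowner] - p.mean(axis=1)
        flip = np.einsum("ij,ij->i", n, to_cent) > 0
        bfaces[flip] = bfaces[flip][:, [0, 2, 1]]
        n[flip] *= -1.0
        n /= np.linalg.norm(n, axis=1, keepdims=True)
        return bfaces, n

    def validate(self) -> None:
        if np.any(self.element_volume <= 0):
            raise ValueError("degenerate tetrahedra with non-positive volume")


@dataclass
class DemandField:
    """Per-element metabolic demand (ml/min/g) and tissue density (g/cm^3)."""

    metabolic_demand: np.ndarray
    density: np.ndarray

    def __post_init__(self):
        self.metabolic_demand = np.asarray(self.metabolic_demand, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if np.any(self.metabolic_demand < 0):
            raise ValueError("metabolic demand must be non-negative")
        if np.any(self.density <= 0):
            raise ValueError("density must be positive")


@dataclass
class ClaimMap:
    """Ownership of tissue elements by terminal segments.

    owner[e] is the terminal segment id perfusing element e, or UNCLAIMED.
    """

    owner: np.ndarray

    def __post_init__(self):
        self.owner = np.asarray(self.owner, dtype=np.int64)

    @classmethod
    def empty(cls, n_elements: int) -> "ClaimMap":
        return cls(np.full(n_elements, UNCLAIMED, dtype=np.int64))

    @property
    def claimed(self) -> np.ndarray:
        return self.owner != UNCLAIMED

    @property
    def unclaimed_indices(self) -> np.ndarray:
        return np.nonzero(self.owner == UNCLAIMED)[0]

    def partition(self, terminal_id: int) -> np.ndarray:
        """Element indices of the partition perfused by one terminal."""
        return np.nonzero(self.owner == terminal_id)[0]

    def copy(self) -> "ClaimMap":
        return ClaimMap(self.owner.copy())


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n nearly uniform unit-sphere directions (golden-spiral lattice)."""
    i = np.arange(n, dtype=float)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - 2.0 * (i + 0.5) / n
    theta = 2.0 * np.pi * i / phi
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def generate_sphere_tissue(radius: float, edge_length: float) -> TissueMesh:
    """Tetrahedral mesh of a ball of given radius centred at the origin.

    Interior points come from a body-centred-cubic lattice of spacing
    ``edge_length``; surface points from a golden-spiral lattice with
    comparable spacing.  Because the ball is convex, the Delaunay
    tetrahedralization of the point cloud tessellates it; total volume
    converges to (4/3) pi r^3 from below as edge_length -> 0 (inscribed
    polyhedron).

    Parameters
    ----------
    radius : cm
    edge_length : cm, target lattice spacing (0 < edge_length < radius)
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if edge_length <= 0 or edge_length >= radius:
        raise ValueError("edge_length must satisfy 0 < edge_length < radius")

    a = float(edge_length)
    n = int(np.ceil(radius / a))
    g = np.arange(-n, n + 1) * a
    g_half = (np.arange(-n, n) + 0.5) * a  # symmetric half-offset layer
    xx, yy, zz = np.meshgrid(g, g, g, indexing="ij")
    cubic = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    xo, yo, zo = np.meshgrid(g_half, g_half, g_half, indexing="ij")
    offset = np.column_stack([xo.ravel(), yo.ravel(), zo.ravel()])
    lattice = np.vstack([cubic, offset])  # BCC, mirror-symmetric about z=0
    rr = np.linalg.norm(lattice, axis=1)
    interior = lattice[rr < radius - 0.45 * a]

    # mirror-symmetric surface: golden-spiral hemisphere reflected in z
    n_surf = max(32, int(np.ceil(4.0 * np.pi * radius**2 / (0.8 * a) ** 2)))
    dirs = _fibonacci_sphere(n_surf)
    upper = dirs[dirs[:, 2] > 1e-12]
    surface = radius * np.vstack([upper, upper * [1.0, 1.0, -1.0]])

    pts = np.vstack([interior, surface])
    # tiny deterministic jitter breaks lattice/cospherical qhull
    # degeneracies; mirrored so the point set stays z-symmetric
    rng = np.random.default_rng(1234567)
    jit = (1e-4 * a) * rng.standard_normal(pts.shape)
    up = pts[:, 2] > 1e-12
    down = pts[:, 2] < -1e-12
    key_up = pts[up] * [1.0, 1.0, 1.0]
    # match each lower point to its mirror image's jitter
    lookup = {tuple(np.round(p, 9)): i for i, p in enumerate(key_up)}
    jit_up = jit[up]
    for i in np.nonzero(down)[0]:
        m = lookup.get(tuple(np.round(pts[i] * [1.0, 1.0, -1.0], 9)))
        if m is not None:
            jit[i] = jit_up[m] * [1.0, 1.0, -1.0]
    jit[np.abs(pts[:, 2]) <= 1e-12, 2] = 0.0  # keep the z=0 plane planar
    pts = pts + jit

    tri = Delaunay(pts)
    mesh = TissueMesh(pts, tri.simplices)
    # drop slivers that qhull may emit on near-degenerate configurations
    keep = mesh.element_volume > 1e-10 * a**3
    mesh = TissueMesh(pts, tri.simplices[keep])
    mesh.validate()
    return mesh


def make_demand_field(
    mesh: TissueMesh,
    profile: str = "uniform",
    value: float = 1.0,
    center_value: float | None = None,
    periphery_value: float | None = None,
    center: np.ndarray | None = None,
    outer_radius: float | None = None,
    density: float | np.ndarray = DEFAULT_DENSITY,
    renormalize_to: float | None = None,
) -> DemandField:
    """Build a demand field sampled at element centroids.

    profile "uniform": constant demand ``value`` everywhere.
    profile "radial_linear": demand varies linearly with distance from
    ``center`` (default origin), from ``center_value`` at r=0 to
    ``periphery_value`` at r=``outer_radius`` (default: max centroid radius).

    If ``renormalize_to`` is given (a total flow in ml/s), the demand is
    rescaled multiplicatively so the total metabolic flow of the mesh matches
    that target (used to compare non-uniform profiles at equal total flow).
    """
    n = mesh.n_elements
    dens = np.broadcast_to(np.asarray(density, dtype=float), (n,)).copy()
    if profile == "uniform":
        if value < 0:
            raise ValueError("demand must be non-negative")
        demand = np.full(n, float(value))
    elif profile == "radial_linear":
        if center_value is None or periphery_value is None:
            raise ValueError("radial_linear requires center_value and periphery_value")
        if center_value < 0 or periphery_value < 0:
            raise ValueError("demand must be non-negative")
        c = np.zeros(3) if center is None else np.asarray(center, dtype=float)
        r = np.linalg.norm(mesh.element_centroid - c, axis=1)
        r_out = float(r.max()) if outer_radius is None else float(outer_radius)
        frac = np.clip(r / r_out, 0.0, 1.0)
        demand = center_value + (periphery_value - center_value) * frac
    else:
        raise ValueError(f"unknown demand profile: {profile!r}")

    fld = DemandField(demand, dens)
    if renormalize_to is not None:
        current = total_metabolic_flow(mesh, fld)
        if current <= 0:
            raise ValueError("cannot renormalize a zero-demand field")
        fld = DemandField(demand * (renormalize_to / current), dens)
    return fld


def total_metabolic_flow(
    mesh: TissueMesh, demand: DemandField, subset: np.ndarray | None = None
) -> float:
    """Required blood flow of a set of elements, ml/s.

    Q = sum_p m_p [ml/min/g] * rho_p [g/cm^3] * V_p [ml] / 60.
    ``subset=None`` means the whole mesh; an empty subset yields 0.
    """
    m = demand.metabolic_demand
    rho = demand.density
    v = mesh.element_volume
    if subset is not None:
        subset = np.asarray(subset, dtype=np.int64)
        m, rho, v = m[subset], rho[subset], v[subset]
    return float(np.sum(m * rho * v) / 60.0)


def element_flow(mesh: TissueMesh, demand: DemandField) -> np.ndarray:
    """Per-element required flow in ml/s (vectorized Q contribution)."""
    return demand.metabolic_demand * demand.density * mesh.element_volume / 60.0


def mesh_summary_frame(
    mesh: TissueMesh, demand: DemandField | None = None, claim: ClaimMap | None = None
) -> pd.DataFrame:
    """Per-element summary table (id, volume, centroid, demand, owner)."""
    c = mesh.element_centroid
    data = {
        "element": np.arange(mesh.n_elements),
        "volume_ml": mesh.element_volume,
        "cx": c[:, 0], "cy": c[:, 1], "cz": c[:, 2],
    }
    if demand is not None:
        data["demand_ml_min_g"] = demand.metabolic_demand
        data["density_g_ml"] = demand.density
    if claim is not None:
        data["owner"] = claim.owner
    return pd.DataFrame(data)
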