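"""Single-compartment Darcy perfusion of the capillary bed.

The tissue is a porous medium: Darcy velocity v = -K grad(p) (gravity term
available but off by default), with distributed sources and sinks

    div(v) = beta_source (p_source - p) - beta_sink (p - p_sink)

and zero normal flux psi = 0 on the boundary.  K is the combined mobility
(kappa/mu) taken directly as the scalar "permeability coefficient" in
1/(mmHg s) units with lengths in cm, so v is cm/s for p in mmHg.  The
pressure-coupling coefficients beta (1/(mmHg s)) are volumetric flow per
tissue volume per pressure difference, and are initialized from average
demand and pressures:

    beta_source = m_bar / (p_source_bar - p_bar)
    beta_sink   = m_bar / (p_bar - p_sink_bar)

with m_bar the average volumetric demand rate in 1/s (ml/min/g x g/cm^3
/ 60).

Discretization: stabilized equal-order (P1/P1) mixed Galerkin on
tetrahedra.  The Galerkin form (velocity equation tested directly, mass
equation integrated by parts so the flux BC is natural) is augmented with a
consistent least-squares term on the Darcy-law residual with tau = K/2,
which yields the pressure-Laplacian stabilization of equal-order mixed
methods.  A primal P1 discretization of the equivalent pressure Poisson
problem is provided as an independent oracle for testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from vasgrow.tissue_domain import TissueMesh


@dataclass
class DarcyParams:
    """mobility K in 1/(mmHg s); gravity off by default (rho g / g_c term)."""

    mobility: float = 0.000107
    blood_density: float = 1.06
    gravity: np.ndarray | None = None  # cm/s^2 vector when enabled
    gravity_conversion: float = 1.0
    boundary_flux_psi: float = 0.0

    def __post_init__(self):
        if self.mobility <= 0:
            raise ValueError("mobility must be positive")


@dataclass
class CouplingCoefficients:
    """Per-element beta_source/beta_sink (1/(mmHg s)) and pressures (mmHg)."""

    beta_source: np.ndarray
    beta_sink: np.ndarray
    p_source: np.ndarray
    p_sink: np.ndarray

    def __post_init__(self):
        for name in ("beta_source", "beta_sink", "p_source", "p_sink"):
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name), float)))
        if np.any(self.beta_source < 0) or np.any(self.beta_sink < 0):
            raise ValueError("coupling coefficients must be non-negative")

    def broadcast(self, n: int) -> "CouplingCoefficients":
        return CouplingCoefficients(
            np.broadcast_to(self.beta_source, (n,)).copy(),
            np.broadcast_to(self.beta_sink, (n,)).copy(),
            np.broadcast_to(self.p_source, (n,)).copy(),
            np.broadcast_to(self.p_sink, (n,)).copy(),
        )


@dataclass
class DarcySolution:
    """Nodal capillary pressure (mmHg), element velocity (cm/s), flows (ml/s)."""

    pressure: np.ndarray
    velocity: np.ndarray
    element_pressure: np.ndarray
    source_flow: np.ndarray
    sink_flow: np.ndarray


def init_coupling_coefficients(
    m_bar: float, p_source_bar: float, p_bar: float, p_sink_bar: float = 0.0
) -> tuple[float, float]:
    """Initialize (beta_source, beta_sink) from average demand and pressures.

    ``m_bar`` is the average volumetric demand rate in 1/s (i.e. demand in
    ml/min/g times density in g/cm^3, divided by 60).  Requires
    p_source_bar > p_bar > p_sink_bar unless m_bar is zero.
    """
    if m_bar < 0:
        raise ValueError("average demand must be non-negative")
    if m_bar == 0:
        return 0.0, 0.0
    if not (p_source_bar > p_bar > p_sink_bar):
        raise ValueError("need p_source_bar > p_bar > p_sink_bar")
    return m_bar / (p_source_bar - p_bar), m_bar / (p_bar - p_sink_bar)


def _grad_ops(mesh: TissueMesh):
    """Per-element P1 shape-function gradients (n_e, 4, 3) and volumes."""
    v = mesh.vertices[mesh.elements]
    J = np.stack([v[:, 1] - v[:, 0], v[:, 2] - v[:, 0], v[:, 3] - v[:, 0]], axis=2)
    Jinv = np.linalg.inv(J)
    # gradients of reference shape functions
    gref = np.array([[-1.0, -1.0, -1.0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
    grads = np.einsum("aj,eji->eai", gref, np.transpose(Jinv, (0, 2, 1)))
    return grads, mesh.element_volume


class DarcyOperator:
    """Assembled, factorized stabilized-mixed Darcy operator.

    The system matrix depends on the mesh, mobility and the beta fields;
    the source/sink pressures enter only the right-hand side, so repeated
    solves with updated pressures (the coupling loop) reuse one
    factorization.
    """

    def __init__(self, mesh: TissueMesh, params: DarcyParams,
                 beta_source: np.ndarray, beta_sink: np.ndarray):
        n_el = mesh.n_elements
        self.mesh = mesh
        self.params = params
        self.beta_source = np.broadcast_to(np.atleast_1d(beta_source), (n_el,)).copy()
        self.beta_sink = np.broadcast_to(np.atleast_1d(beta_sink), (n_el,)).copy()
        if np.all(self.beta_source == 0) and np.all(self.beta_sink == 0):
            raise ValueError("both beta fields are zero: no pressure datum, "
                             "singular system")
        self._assemble()

    def _assemble(self):
        mesh, params = self.mesh, self.params
        n_nod = len(mesh.vertices)
        n_el = mesh.n_elements
        K = params.mobility
        grads, vol = _grad_ops(mesh)
        self._grads, self._vol = grads, vol
        el = mesh.elements
        mloc = (np.ones((4, 4)) + np.eye(4)) / 20.0
        bsum = self.beta_source + self.beta_sink

        # vectorized element contributions; dofs [vx, vy, vz, p] blocks
        Me = mloc[None] * vol[:, None, None]                      # (n_el,4,4)
        lap = 0.5 * K * vol[:, None, None] * np.einsum("eai,ebi->eab", grads, grads)
        react = bsum[:, None, None] * Me
        pa = np.broadcast_to(el[:, :, None], (n_el, 4, 4))        # test idx
        pb = np.broadcast_to(el[:, None, :], (n_el, 4, 4))        # trial idx

        rows = [(3 * n_nod + pa).ravel()]
        cols = [(3 * n_nod + pb).ravel()]
        vals = [(lap + react).ravel()]
        # gcpl[e,a,b,c] = V/4 * g[e,b,c]  (a = test phi, b = trial dphi)
        gcpl = vol[:, None, None, None] / 4.0 * np.broadcast_to(
            grads[:, None, :, :], (n_el, 4, 4, 3))
        for c in range(3):
            # velocity row block c: 3/2 K^-1 mass + 3/2 (w, dp/dx_c)
            rows.append((c * n_nod + pa).ravel())
            cols.append((c * n_nod + pb).ravel())
            vals.append((1.5 / K * Me).ravel())
            rows.append((c * n_nod + pa).ravel())
            cols.append((3 * n_nod + pb).ravel())
            vals.append(1.5 * gcpl[:, :, :, c].ravel())
            # pressure row: -1/2 (dq/dx_c, v_c) -> -V/4 g[a,c] phi_b
            rows.append((3 * n_nod + pa).ravel())
            cols.append((c * n_nod + pb).ravel())
            vals.append(-0.5 * np.transpose(gcpl[:, :, :, c], (0, 2, 1)).ravel())
        A = sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(4 * n_nod, 4 * n_nod))
        self._A = A
        self._solve = spla.factorized(A.tocsc())
        self._n_nod = n_nod

    def solve(self, p_source: np.ndarray, p_sink: np.ndarray) -> DarcySolution:
        mesh, params = self.mesh, self.params
        n_nod, n_el = self._n_nod, mesh.n_elements
        p_source = np.broadcast_to(np.atleast_1d(p_source), (n_el,))
        p_sink = np.broadcast_to(np.atleast_1d(p_sink), (n_el,))
        f_el = self.beta_source * p_source + self.beta_sink * p_sink
        rhs = np.zeros(4 * n_nod)
        np.add.at(rhs, 3 * n_nod + mesh.elements.ravel(),
                  np.repeat(f_el * self._vol / 4.0, 4))
        if params.gravity is not None:
            gvec = params.blood_density / params.gravity_conversion \
                * np.asarray(params.gravity, float)
            gv = -1.5 * self._vol / 4.0
            for c in range(3):
                np.add.at(rhs, c * n_nod + mesh.elements.ravel(),
                          np.repeat(gv * gvec[c], 4))
            np.add.at(rhs, 3 * n_nod + mesh.elements.ravel(),
                      np.repeat(-0.5 * params.mobility * self._vol, 4)
                      * np.einsum("eai,i->ea", self._grads, gvec).ravel())
        y = self._solve(rhs)
        if not np.all(np.isfinite(y)):
            raise ValueError("singular Darcy system")
        y += self._solve(rhs - self._A @ y)  # one iterative-refinement sweep
        res = np.linalg.norm(self._A @ y - rhs) / max(np.linalg.norm(rhs), 1e-300)
        if res > 1e-10:
            raise ValueError(f"Darcy solve residual {res:.2e} exceeds 1e-10")
        el = mesh.elements
        vx, vy, vz = y[:n_nod], y[n_nod:2 * n_nod], y[2 * n_nod:3 * n_nod]
        p = y[3 * n_nod:]
        vel = np.column_stack([vx[el].mean(1), vy[el].mean(1), vz[el].mean(1)])
        p_el = p[el].mean(axis=1)
        q_src = self.beta_source * (p_source - p_el) * self._vol
        q_snk = self.beta_sink * (p_el - p_sink) * self._vol
        return DarcySolution(p, vel, p_el, q_src, q_snk)


def solve_darcy(
    mesh: TissueMesh,
    params: DarcyParams,
    coupling: CouplingCoefficients,
) -> DarcySolution:
    """Steady stabilized mixed (P1/P1) solve of the Darcy perfusion problem.

    Unknowns are nodal velocity (3 dof) and pressure (1 dof).  The discrete
    mass balance is exact for the constant test function, so the global
    source/sink balance holds to solver precision.
    """
    cpl = coupling.broadcast(mesh.n_elements)
    op = DarcyOperator(mesh, params, cpl.beta_source, cpl.beta_sink)
    return op.solve(cpl.p_source, cpl.p_sink)


def element_tissue_flow(solution: DarcySolution) -> np.ndarray:
    """Per-element inflow from the vascular sources, ml/s (Fig.-3 style map)."""
    return solution.source_flow


def solve_darcy_primal(
    mesh: TissueMesh, params: DarcyParams, coupling: CouplingCoefficients
) -> np.ndarray:
    """Primal P1 pressure discretization (independent oracle, not public).

    Solves -div(K grad p) + (beta_s + beta_k) p = beta_s p_s + beta_k p_k
    with natural zero-flux boundary; returns nodal pressures.
    """
    n_nod = len(mesh.vertices)
    grads, vol = _grad_ops(mesh)
    elements = mesh.elements
    cpl = coupling.broadcast(mesh.n_elements)
    mloc = (np.ones((4, 4)) + np.eye(4)) / 20.0
    rows, cols, vals = [], [], []
    rhs = np.zeros(n_nod)
    bsum = cpl.beta_source + cpl.beta_sink
    f_el = cpl.beta_source * cpl.p_source + cpl.beta_sink * cpl.p_sink
    for e in range(mesh.n_elements):
        nd = elements[e]
        loc = params.mobility * vol[e] * (grads[e] @ grads[e].T) + bsum[e] * mloc * vol[e]
        for a in range(4):
            rows.extend(nd); cols.extend([nd[a]] * 4); vals.extend(loc[:, a])
        np.add.at(rhs, nd, f_el[e] * vol[e] / 4.0)
    A = sp.csr_matrix((vals, (rows, cols)), shape=(n_nod, n_nod))
    return spla.spsolve(A.tocsc(), rhs)
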