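"""Compliant lesion mechanics and partitioned fluid-structure coupling.

The lesion is a 2D plane-strain, small-strain linear elastic continuum
(near-incompressible, so the volumetric stiffness is integrated with
selective reduced integration on bilinear quads to avoid locking), clamped at
its attachment root, advanced in time with Newmark average acceleration.

Coupling to the fluid is partitioned and strongly coupled: each time step
fixed-point iterates fluid solve -> interface traction -> solid solve ->
interface displacement, under Aitken dynamic under-relaxation, until the
interface displacement increment falls below tolerance.  A prescribed-motion
fallback (sinusoidal flapping) lets endpoint analytics run without FSI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.spatial import cKDTree

from .geometry import LVGeometry, TAG_LESION
from .solver import ALEFlowSolver, ConvergenceError
from . import _fem

__all__ = ["LesionMaterial", "LesionState", "LesionSolid", "FSICoupler",
           "prescribed_flap"]

log = logging.getLogger(__name__)


@dataclass
class LesionMaterial:
    """Nearly incompressible linear elastic lesion tissue."""

    density: float = 1100.0           # kg/m^3
    youngs_modulus: float = 0.37e6    # Pa
    poisson_ratio: float = 0.49

    def __post_init__(self):
        if not (0.0 < self.poisson_ratio < 0.5):
            raise ValueError("poisson_ratio must lie in (0, 0.5)")
        if self.youngs_modulus <= 0 or self.density <= 0:
            raise ValueError("modulus and density must be positive")

    @property
    def lame(self):
        e, nu = self.youngs_modulus, self.poisson_ratio
        lam = e * nu / ((1 + nu) * (1 - 2 * nu))
        mu = e / (2 * (1 + nu))
        return lam, mu


@dataclass
class LesionState:
    """Dynamic state of the lesion solid."""

    d: np.ndarray          # nodal displacement (n, 2), m, local frame
    v: np.ndarray          # nodal velocity
    a: np.ndarray          # nodal acceleration
    time: float = 0.0

    def copy(self) -> "LesionState":
        return LesionState(self.d.copy(), self.v.copy(), self.a.copy(),
                           self.time)


class LesionSolid:
    """Plane-strain Q4 cantilever tab, clamped at the root (x=0).

    The local frame has x along the protrusion direction and y across the
    thickness, with the tab occupying [0, length] x [-t/2, t/2] (metres).
    """

    def __init__(self, length: float, thickness: float,
                 material: LesionMaterial, nx: int = 12, ny: int = 4,
                 rayleigh_alpha: float = 0.0):
        self.length = length
        self.thickness = thickness
        self.material = material
        xs = np.linspace(0, length, nx + 1)
        ys = np.linspace(-thickness / 2, thickness / 2, ny + 1)
        X, Y = np.meshgrid(xs, ys, indexing="xy")
        self.nodes = np.column_stack([X.ravel(), Y.ravel()])
        quads = []
        for j in range(ny):
            for i in range(nx):
                n0 = j * (nx + 1) + i
                quads.append([n0, n0 + 1, n0 + nx + 2, n0 + nx + 1])
        self.quads = np.asarray(quads, int)
        self.nx, self.ny = nx, ny
        self.n_nodes = len(self.nodes)
        self.clamped = np.where(np.isclose(self.nodes[:, 0], 0.0))[0]
        self.rayleigh_alpha = rayleigh_alpha
        self._assemble()
        self._interface_path()

    # ------------------------------------------------------------- assembly
    def _assemble(self):
        lam, mu = self.material.lame
        # deviatoric/shear part integrated 2x2, volumetric (lambda) 1-point
        d_mu = np.array([[2 * mu, 0, 0], [0, 2 * mu, 0], [0, 0, mu]])
        d_lam = np.array([[lam, lam, 0], [lam, lam, 0], [0, 0, 0.0]])

        gp2 = np.array([-1, 1]) / np.sqrt(3.0)
        pts2 = [(xi, eta) for xi in gp2 for eta in gp2]

        ndof = 2 * self.n_nodes
        rows, cols, vals = [], [], []
        mass = np.zeros(ndof)
        rho = self.material.density

        def bmat(xi, eta, xe):
            dn = 0.25 * np.array([
                [-(1 - eta), (1 - eta), (1 + eta), -(1 + eta)],
                [-(1 - xi), -(1 + xi), (1 + xi), (1 - xi)],
            ])
            jac = dn @ xe
            det = np.linalg.det(jac)
            dndx = np.linalg.solve(jac, dn)
            b = np.zeros((3, 8))
            b[0, 0::2] = dndx[0]
            b[1, 1::2] = dndx[1]
            b[2, 0::2] = dndx[1]
            b[2, 1::2] = dndx[0]
            return b, det

        for q in self.quads:
            xe = self.nodes[q]
            ke = np.zeros((8, 8))
            area = 0.0
            for xi, eta in pts2:
                b, det = bmat(xi, eta, xe)
                ke += b.T @ d_mu @ b * det
                area += det
            b0, det0 = bmat(0.0, 0.0, xe)
            ke += b0.T @ d_lam @ b0 * (4.0 * det0)
            dofs = np.repeat(2 * q, 2) + np.tile([0, 1], 4)
            rows.append(np.repeat(dofs, 8))
            cols.append(np.tile(dofs, 8))
            vals.append(ke.ravel())
            mass[dofs] += rho * area / 4.0

        self.K = sp.csr_matrix((np.concatenate(vals),
                                (np.concatenate(rows), np.concatenate(cols))),
                               shape=(ndof, ndof))
        self.M = mass
        cd = np.zeros(ndof, bool)
        cd[2 * self.clamped] = True
        cd[2 * self.clamped + 1] = True
        self.fixed = np.where(cd)[0]
        self.free = np.where(~cd)[0]
        self._newmark_cache = {}

    def _interface_path(self):
        """Wetted boundary path: root(+y) -> tip -> root(-y); param in metres."""
        nx, ny = self.nx, self.ny
        top = [ny * (nx + 1) + i for i in range(nx + 1)]
        right = [j * (nx + 1) + nx for j in range(ny, -1, -1)]
        bot = [i for i in range(nx, -1, -1)]
        path = top + right[1:] + bot[1:]
        # deduplicate corners, keep order
        seen, ordered = set(), []
        for nd in path:
            if nd not in seen:
                ordered.append(nd)
                seen.add(nd)
        self.interface_nodes = np.asarray(ordered, int)
        pts = self.nodes[self.interface_nodes]
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        self.interface_param = np.concatenate([[0.0], np.cumsum(seg)])
        trib = np.zeros(len(pts))
        trib[:-1] += 0.5 * seg
        trib[1:] += 0.5 * seg
        self.interface_tributary = trib

    # --------------------------------------------------------------- solves
    def static_solve(self, force: np.ndarray) -> np.ndarray:
        """Displacement under a nodal force vector (n, 2); root clamped."""
        f = np.asarray(force, float).ravel()
        K = self.K[self.free][:, self.free]
        d = np.zeros(2 * self.n_nodes)
        d[self.free] = spla.spsolve(K.tocsc(), f[self.free])
        return d.reshape(-1, 2)

    def newmark_step(self, state: LesionState, force: np.ndarray, dt: float,
                     beta: float = 0.25, gamma: float = 0.5,
                     extra_mass: Optional[np.ndarray] = None,
                     extra_accel: Optional[np.ndarray] = None) -> LesionState:
        """Implicit Newmark (average acceleration) step under ``force``.

        ``extra_mass``/``extra_accel`` implement iterate-corrected artificial
        added mass for partitioned coupling:  (M + Ma) a1 + K d1 = F + Ma a*
        with ``a*`` the previous coupling iterate's acceleration — at the
        converged fixed point (a1 = a*) the extra terms cancel exactly, while
        the iteration gain is reduced by M / (M + Ma).
        """
        f = np.asarray(force, float).ravel()
        d0 = state.d.ravel()
        v0 = state.v.ravel()
        a0 = state.a.ravel()
        ma = np.zeros_like(self.M) if extra_mass is None \
            else np.asarray(extra_mass, float).ravel()
        m_eff = self.M + ma
        key = (dt, beta, gamma, float(ma.sum()))
        if key not in self._newmark_cache:
            A = self.K + sp.diags(m_eff / (beta * dt * dt))
            Af = A[self.free][:, self.free].tocsc()
            self._newmark_cache = {key: spla.splu(Af)}
        lu = self._newmark_cache[key]
        pred_d = d0 + dt * v0 + dt * dt * (0.5 - beta) * a0
        pred_v = v0 + dt * (1 - gamma) * a0
        rhs = f + m_eff / (beta * dt * dt) * pred_d
        if extra_accel is not None:
            rhs = rhs + ma * np.asarray(extra_accel, float).ravel()
        d1 = np.zeros_like(d0)
        d1[self.free] = lu.solve(rhs[self.free])
        a1 = (d1 - pred_d) / (beta * dt * dt)
        v1 = pred_v + gamma * dt * a1
        return LesionState(d1.reshape(-1, 2), v1.reshape(-1, 2),
                           a1.reshape(-1, 2), state.time + dt)

    def initial_state(self) -> LesionState:
        z = np.zeros((self.n_nodes, 2))
        return LesionState(z.copy(), z.copy(), z.copy(), 0.0)

    # ------------------------------------------------------------ quantities
    def tip_deflection(self, d: np.ndarray) -> float:
        """Transverse (local-y) displacement of the tip mid-node."""
        tip = np.argmin(np.abs(self.nodes[:, 0] - self.length)
                        + np.abs(self.nodes[:, 1]))
        return float(d[tip, 1])

    def von_mises(self, d: np.ndarray) -> np.ndarray:
        """Von Mises stress per element at the centroid (plane strain)."""
        lam, mu = self.material.lame
        nu = self.material.poisson_ratio
        D = np.array([[lam + 2 * mu, lam, 0],
                      [lam, lam + 2 * mu, 0],
                      [0, 0, mu]])
        out = np.empty(len(self.quads))
        dn = 0.25 * np.array([[-1.0, 1, 1, -1], [-1.0, -1, 1, 1]])
        for e, q in enumerate(self.quads):
            xe = self.nodes[q]
            jac = dn @ xe
            dndx = np.linalg.solve(jac, dn)
            de = d[q]
            ex = dndx[0] @ de[:, 0]
            ey = dndx[1] @ de[:, 1]
            gxy = dndx[1] @ de[:, 0] + dndx[0] @ de[:, 1]
            sx, sy, txy = D @ np.array([ex, ey, gxy])
            sz = nu * (sx + sy)
            out[e] = np.sqrt(0.5 * ((sx - sy) ** 2 + (sy - sz) ** 2
                                    + (sz - sx) ** 2) + 3 * txy ** 2)
        return out

    def uniform_pressure_load(self, q_pressure: float) -> np.ndarray:
        """Consistent nodal load for pressure on the +y face (N/m per depth),
        acting in -y.  Used by the beam-theory verification oracle."""
        nxp = self.nx + 1
        top = np.array([self.ny * nxp + i for i in range(nxp)])
        h = self.length / self.nx
        f = np.zeros((self.n_nodes, 2))
        f[top, 1] = -q_pressure * h
        f[top[0], 1] *= 0.5
        f[top[-1], 1] *= 0.5
        return f


def prescribed_flap(amplitude: float, frequency: float):
    """Fallback lesion motion: tip-weighted sinusoidal flapping.

    Returns ``f(t, param_norm) -> transverse displacement (m)`` with
    ``param_norm`` the normalized interface path coordinate in [0, 1]
    (0 and 1 at the root, 0.5 at the tip).
    """
    def flap(t, q):
        shape = np.sin(np.pi * np.asarray(q, float)) ** 2
        return amplitude * shape * np.sin(2 * np.pi * frequency * t)
    return flap


# ---------------------------------------------------------------------------
# partitioned coupling
# ---------------------------------------------------------------------------

class FSICoupler:
    """Strongly coupled partitioned stepping of fluid and lesion.

    The lesion solid lives in a local frame rooted on the septal LVOT wall:
    local x is the protrusion direction (geometry ``n_hat``), local y the
    wall direction (``d_hat``).
    """

    def __init__(self, fluid: ALEFlowSolver, solid: LesionSolid,
                 geometry: LVGeometry, tol: float = 1e-6,
                 max_iters: int = 80, omega0: float = 0.2,
                 relax_max: float = 0.9, trust_step: float = 1e-3):
        self.fluid = fluid
        self.solid = solid
        self.geometry = geometry
        self.tol = tol
        self.max_iters = max_iters
        self.omega0 = omega0
        self.relax_max = relax_max
        self.trust_step = trust_step

        # artificial added mass on the wetted interface (flat-plate estimate
        # rho_f * pi/4 * span^2 per unit depth), distributed by tributary
        # length; iterate-corrected in the solid solve, exact at convergence
        rho_f = fluid.props.rho
        ma_tot = rho_f * 0.25 * np.pi * solid.length ** 2
        trib = solid.interface_tributary
        ma_nodes = ma_tot * trib / trib.sum()
        self.ma_vec = np.zeros(2 * solid.n_nodes)
        for c in (0, 1):
            self.ma_vec[2 * solid.interface_nodes + c] = ma_nodes
        self.solid_state = solid.initial_state()
        self.history: list = []        # (t, tip_deflection, max_von_mises)

        # local frame: origin at tab root centre on the wall
        mm = 1e-3
        les = geometry.lesion
        crest = geometry.crest_xy * mm
        d, n = geometry.d_hat, geometry.n_hat
        self.origin = crest + les.attachment_arc_position * mm * d
        self.R = np.column_stack([n, d])   # local (x, y) -> global

        # fluid lesion boundary nodes and their interface-path parameters
        mesh = fluid.mesh
        lesion_edges = np.where(mesh.btags == TAG_LESION)[0]
        nd = np.unique(mesh.bedges[lesion_edges])
        self.fluid_nodes = nd
        base_local = (mesh.points[nd] - self.origin) @ self.R
        # nearest point on the solid interface path
        dense_q = np.linspace(0, solid.interface_param[-1], 400)
        dense_pts = np.column_stack([
            np.interp(dense_q, solid.interface_param,
                      solid.nodes[solid.interface_nodes, 0]),
            np.interp(dense_q, solid.interface_param,
                      solid.nodes[solid.interface_nodes, 1])])
        tree = cKDTree(dense_pts)
        _, idx = tree.query(base_local)
        self.fluid_param = dense_q[idx]

        # traction extraction support: wall-adjacent element per lesion edge
        self.lesion_edges = lesion_edges
        self._mesh_id = id(mesh)
        self._build_edge_tri(mesh)
        mids_local = ((0.5 * (mesh.points[mesh.bedges[lesion_edges, 0]]
                              + mesh.points[mesh.bedges[lesion_edges, 1]]))
                      - self.origin) @ self.R
        _, idx = tree.query(mids_local)
        self.edge_param = dense_q[idx]

    def _build_edge_tri(self, mesh):
        edge_to_tri = {}
        for it, tr in enumerate(mesh.tris):
            for kk in range(3):
                e = (min(tr[kk], tr[(kk + 1) % 3]),
                     max(tr[kk], tr[(kk + 1) % 3]))
                edge_to_tri.setdefault(e, []).append(it)
        self.edge_tri = np.array([
            edge_to_tri[(min(i, j), max(i, j))][0]
            for i, j in mesh.bedges[self.lesion_edges]])

    def _sync_mesh(self):
        """Interior remeshing keeps boundary-node numbering (walk order), so
        only the wall-adjacent element map needs rebuilding."""
        mesh = self.fluid.mesh
        if id(mesh) != self._mesh_id:
            self._build_edge_tri(mesh)
            self._mesh_id = id(mesh)

    # ---------------------------------------------------------------- pieces
    def _interface_traction(self) -> np.ndarray:
        """Fluid traction (global frame, Pa) at lesion edge midpoints."""
        f = self.fluid
        mesh = f.mesh
        st = f.state
        area, grads = _fem.tri_geometry(mesh.points, mesh.tris)
        tr = self.edge_tri
        gu = np.einsum("ejd,ej->ed", grads[tr], st.u[mesh.tris[tr], 0])
        gv = np.einsum("ejd,ej->ed", grads[tr], st.u[mesh.tris[tr], 1])
        p_e = st.p[mesh.tris[tr]].mean(axis=1)
        mu = f.props.mu
        # force on the solid uses the solid-outward normal, i.e. minus the
        # fluid-domain outward normal stored for the boundary edges
        nrm = -f._bnormal[self.lesion_edges]
        sxx = -p_e + 2 * mu * gu[:, 0]
        syy = -p_e + 2 * mu * gv[:, 1]
        sxy = mu * (gu[:, 1] + gv[:, 0])
        tx = sxx * nrm[:, 0] + sxy * nrm[:, 1]
        ty = sxy * nrm[:, 0] + syy * nrm[:, 1]
        return np.column_stack([tx, ty])

    def _solid_load(self, traction_mid: np.ndarray) -> np.ndarray:
        """Map edge-midpoint tractions to consistent solid nodal forces."""
        s = self.solid
        order = np.argsort(self.edge_param)
        qs = self.edge_param[order]
        t_loc = traction_mid[order] @ self.R      # global -> local components
        f = np.zeros((s.n_nodes, 2))
        qi = s.interface_param
        for c in range(2):
            ti = np.interp(qi, qs, t_loc[:, c])
            f[s.interface_nodes, c] = ti * s.interface_tributary
        return f

    def _fluid_offsets(self, d_solid: np.ndarray) -> dict:
        """Displacement of fluid lesion boundary nodes from the solid state."""
        s = self.solid
        qi = s.interface_param
        di = d_solid[s.interface_nodes]           # local frame
        dx = np.interp(self.fluid_param, qi, di[:, 0])
        dy = np.interp(self.fluid_param, qi, di[:, 1])
        disp_global = np.column_stack([dx, dy]) @ self.R.T
        return {int(nd): disp_global[i]
                for i, nd in enumerate(self.fluid_nodes)}

    # ------------------------------------------------------------------ step
    def step(self, dt: float):
        """Advance the coupled system one time step (strong coupling)."""
        fluid, solid = self.fluid, self.solid
        snap = fluid.snapshot()
        solid0 = self.solid_state

        d_guess = solid0.d.copy()
        converged = False
        a_star = solid0.a
        rmax_prev = None
        relax = 1.0          # added-mass stabilization makes 1.0 contractive
        amp_limit = 0.6 * self.solid.length
        for it in range(self.max_iters):
            fluid.restore(snap)
            fluid.extra_boundary_offset = self._fluid_offsets(d_guess)
            try:
                fluid.step(dt)
            except ConvergenceError as err:
                raise ConvergenceError(
                    "fluid solve diverged inside FSI iteration; reduce dt or "
                    "strengthen relaxation", err.history) from err
            self._sync_mesh()
            traction = self._interface_traction()
            force = self._solid_load(traction)
            trial = solid.newmark_step(solid0, force, dt,
                                       extra_mass=self.ma_vec,
                                       extra_accel=a_star)
            a_star = trial.a
            res = trial.d - d_guess
            rmax = float(np.abs(res[solid.interface_nodes]).max())
            if rmax < self.tol:
                d_guess = trial.d
                self.solid_state = trial
                converged = True
                break
            if rmax_prev is not None and rmax > rmax_prev:
                relax = max(0.3, 0.6 * relax)     # damp if not contracting
            d_guess = d_guess + relax * res
            if float(np.abs(d_guess).max()) > amp_limit:
                raise ConvergenceError(
                    "FSI interface displacement exceeded the physical "
                    "amplitude guard; reduce dt or the flow forcing")
            rmax_prev = rmax
        if not converged:
            raise ConvergenceError(
                f"FSI coupling did not converge in {self.max_iters} "
                f"iterations (last interface residual {rmax:.3e} m); reduce "
                "dt or strengthen under-relaxation")

        tip = solid.tip_deflection(self.solid_state.d)
        vm = float(self.solid.von_mises(self.solid_state.d).max())
        self.history.append((fluid.state.time, tip, vm))
        return self.fluid.diagnostics[-1]
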