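"""Vectorized P1 finite-element assembly on triangle meshes.

Internal helpers shared by the flow solver and the turbulence transport:
element geometry, lumped mass, stiffness with scalar or streamline-tensor
diffusivity, Galerkin convection, divergence/gradient operators and Dirichlet
row elimination.  All operators are assembled fresh on the current (possibly
moved) node coordinates.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = [
    "tri_geometry", "lumped_mass", "assemble_stiffness",
    "assemble_convection", "assemble_supg", "divergence", "gradient_rhs",
    "node_gradient", "apply_dirichlet", "element_mean",
]


def tri_geometry(points: np.ndarray, tris: np.ndarray):
    """Areas (m,) and P1 basis gradients (m, 3, 2) of each triangle."""
    p0 = points[tris[:, 0]]
    p1 = points[tris[:, 1]]
    p2 = points[tris[:, 2]]
    d1 = p1 - p0
    d2 = p2 - p0
    det = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
    area = 0.5 * det
    grads = np.empty((len(tris), 3, 2))
    inv = 1.0 / det
    grads[:, 1, 0] = d2[:, 1] * inv
    grads[:, 1, 1] = -d2[:, 0] * inv
    grads[:, 2, 0] = -d1[:, 1] * inv
    grads[:, 2, 1] = d1[:, 0] * inv
    grads[:, 0] = -grads[:, 1] - grads[:, 2]
    return area, grads


def _scatter(tris, ke, n):
    """Assemble per-element 3x3 blocks into a CSR matrix."""
    rows = np.repeat(tris, 3, axis=1).ravel()
    cols = np.tile(tris, (1, 3)).ravel()
    return sp.csr_matrix((ke.ravel(), (rows, cols)), shape=(n, n))


def lumped_mass(points, tris, area=None) -> np.ndarray:
    """Row-sum lumped mass vector (m^2 weights per node)."""
    if area is None:
        area, _ = tri_geometry(points, tris)
    ml = np.zeros(len(points))
    np.add.at(ml, tris.ravel(), np.repeat(area / 3.0, 3))
    return ml


def element_mean(tris, nodal: np.ndarray) -> np.ndarray:
    """Average of a nodal field over each element's vertices."""
    return nodal[tris].mean(axis=1)


def assemble_stiffness(points, tris, diff_e: np.ndarray, area=None, grads=None):
    """Stiffness matrix with per-element scalar diffusivity ``diff_e``."""
    if area is None:
        area, grads = tri_geometry(points, tris)
    ke = np.einsum("e,eid,ejd->eij", diff_e * area, grads, grads)
    return _scatter(tris, ke, len(points))


def assemble_convection(points, tris, a_e: np.ndarray, area=None, grads=None):
    """Galerkin convection  C[i,j] = sum_e (area/3) * (a_e . grad phi_j).

    ``a_e`` is the element-mean convective velocity (m, 2).
    """
    if area is None:
        area, grads = tri_geometry(points, tris)
    adotg = np.einsum("ed,ejd->ej", a_e, grads)       # (m, 3)
    ke = (area / 3.0)[:, None, None] * adotg[:, None, :] * np.ones((1, 3, 1))
    return _scatter(tris, ke, len(points))


def assemble_supg(points, tris, a_e: np.ndarray, area=None, grads=None):
    """Streamline-upwind stabilization: tensor diffusivity tau * a (x) a with
    tau = h_e / (2|a|), i.e. streamline diffusivity |a| h_e / 2."""
    if area is None:
        area, grads = tri_geometry(points, tris)
    amag = np.linalg.norm(a_e, axis=1)
    h_e = np.sqrt(2.0 * np.abs(area))
    tau = np.where(amag > 1e-14, h_e / (2.0 * np.maximum(amag, 1e-14)), 0.0)
    adotg = np.einsum("ed,ejd->ej", a_e, grads)
    ke = np.einsum("e,ei,ej->eij", tau * area, adotg, adotg)
    return _scatter(tris, ke, len(points))


def divergence(points, tris, u: np.ndarray, area=None, grads=None) -> np.ndarray:
    """Nodal residual of continuity:  r_i = int phi_i div(u) dx."""
    if area is None:
        area, grads = tri_geometry(points, tris)
    div_e = np.einsum("ejd,ejd->e", grads, u[tris])
    r = np.zeros(len(points))
    np.add.at(r, tris.ravel(), np.repeat(area * div_e / 3.0, 3))
    return r


def gradient_rhs(points, tris, phi: np.ndarray, area=None, grads=None
                 ) -> np.ndarray:
    """Nodal vector  g_i = int phi_i grad(phi_h) dx  for a P1 scalar field."""
    if area is None:
        area, grads = tri_geometry(points, tris)
    grad_e = np.einsum("ejd,ej->ed", grads, phi[tris])     # (m, 2)
    g = np.zeros((len(points), 2))
    w = (area / 3.0)[:, None] * grad_e
    np.add.at(g, tris.ravel(), np.repeat(w, 3, axis=0))
    return g


def node_gradient(points, tris, f: np.ndarray, area=None, grads=None
                  ) -> np.ndarray:
    """Area-weighted recovery of grad(f) at nodes from element gradients."""
    if area is None:
        area, grads = tri_geometry(points, tris)
    grad_e = np.einsum("ejd,ej->ed", grads, f[tris])
    g = np.zeros((len(points), 2))
    w = np.zeros(len(points))
    np.add.at(g, tris.ravel(), np.repeat(area[:, None] * grad_e, 3, axis=0))
    np.add.at(w, tris.ravel(), np.repeat(area, 3))
    return g / w[:, None]


def apply_dirichlet(A: sp.csr_matrix, rhs: np.ndarray, nodes: np.ndarray,
                    values: np.ndarray):
    """Impose Dirichlet rows in place (identity row, prescribed rhs).

    ``rhs`` may be (n,) or (n, k); values broadcast accordingly.  Returns the
    modified matrix (CSR) and rhs.
    """
    n = A.shape[0]
    free = np.ones(n)
    free[nodes] = 0.0
    A = sp.diags(free) @ A + sp.diags(1.0 - free)
    rhs = np.array(rhs, copy=True)
    rhs[nodes] = values
    return A.tocsr(), rhs
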