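"""SST k-omega closure: two transport equations with blended constants.

The closure carries turbulence kinetic energy ``k`` and specific dissipation
rate ``omega`` with production from the mean strain rate, blended dissipation
and diffusion constants, a cross-diffusion term, and the shear-stress
transport eddy-viscosity limiter.  Reynolds stresses are never stored;
they are modeled through the eddy viscosity (Boussinesq closure).

Constants are Menter's standard set; the source terms S_k and S_omega default
to zero.  ``force_blend`` pins the blending function F1 to a constant, which
the reduced-equation (decaying turbulence) verification tests use to select
one constant set analytically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import _fem

__all__ = ["TurbulenceClosure", "SSTStepper"]


@dataclass
class TurbulenceClosure:
    """Model selection and SST closure coefficients."""

    model: str = "sst_k_omega"         # or "laminar"
    beta_star: float = 0.09
    a1: float = 0.31
    kappa: float = 0.41
    # set 1 (near wall)
    sigma_k1: float = 0.85
    sigma_w1: float = 0.5
    beta1: float = 0.075
    gamma1: float = 5.0 / 9.0
    # set 2 (free shear)
    sigma_k2: float = 1.0
    sigma_w2: float = 0.856
    beta2: float = 0.0828
    gamma2: float = 0.44
    omega_min: float = 1e-4
    production_limit: float = 10.0     # P_k <= limit * beta* rho k omega
    force_blend: Optional[float] = None
    s_k: Optional[Callable] = None     # user source terms S_k, S_omega
    s_w: Optional[Callable] = None

    @property
    def active(self) -> bool:
        return self.model == "sst_k_omega"

    def blend(self, f1: np.ndarray, name1: float, name2: float) -> np.ndarray:
        return f1 * name1 + (1.0 - f1) * name2


class SSTStepper:
    """Advances k and omega one time step on the current mesh.

    The transport equations are solved segregated and semi-implicitly:
    implicit Euler in time with Galerkin + streamline-upwind convection,
    implicit (linearized) destruction and explicit limited production and
    cross diffusion.
    """

    def __init__(self, closure: TurbulenceClosure, rho: float, mu: float):
        self.c = closure
        self.rho = rho
        self.mu = mu

    # -- pointwise model algebra ------------------------------------------

    def strain_rate(self, points, tris, u, area=None, grads=None):
        """Strain-rate magnitude S = sqrt(2 S_ij S_ij) at nodes."""
        gx = _fem.node_gradient(points, tris, u[:, 0], area, grads)
        gy = _fem.node_gradient(points, tris, u[:, 1], area, grads)
        sxx = gx[:, 0]
        syy = gy[:, 1]
        sxy = 0.5 * (gx[:, 1] + gy[:, 0])
        return np.sqrt(2.0 * (sxx**2 + syy**2 + 2.0 * sxy**2)), (gx, gy)

    def blending(self, k, om, d_wall, grad_k=None, grad_w=None):
        """F1 and F2 blending functions (1 near walls, 0 in free shear)."""
        c = self.c
        nu = self.mu / self.rho
        if c.force_blend is not None:
            f1 = np.full_like(k, float(c.force_blend))
        else:
            d = np.maximum(d_wall, 1e-10)
            cd = np.full_like(k, 1e-10)
            if grad_k is not None and grad_w is not None:
                cd = np.maximum(2.0 * self.rho * c.sigma_w2 / np.maximum(
                    om, c.omega_min) * np.einsum("ij,ij->i", grad_k, grad_w),
                    1e-10)
            arg1 = np.minimum(
                np.maximum(np.sqrt(np.maximum(k, 0.0))
                           / (c.beta_star * np.maximum(om, c.omega_min) * d),
                           500.0 * nu / (d**2 * np.maximum(om, c.omega_min))),
                4.0 * self.rho * c.sigma_w2 * np.maximum(k, 0.0) / (cd * d**2))
            f1 = np.tanh(arg1**4)
        if c.force_blend is not None:
            f2 = np.full_like(k, float(c.force_blend))
        else:
            d = np.maximum(d_wall, 1e-10)
            arg2 = np.maximum(
                2.0 * np.sqrt(np.maximum(k, 0.0))
                / (c.beta_star * np.maximum(om, c.omega_min) * d),
                500.0 * nu / (d**2 * np.maximum(om, c.omega_min)))
            f2 = np.tanh(arg2**2)
        return f1, f2

    def eddy_viscosity(self, k, om, s_mag, f2):
        c = self.c
        denom = np.maximum(c.a1 * np.maximum(om, c.omega_min), s_mag * f2)
        return c.a1 * np.maximum(k, 0.0) / np.maximum(denom, 1e-30)

    # -- one transport step ------------------------------------------------

    def step(self, points, tris, a_rel_e, k, om, nut, u, dt, d_wall,
             dirichlet_k=(), dirichlet_w=(), k_bc=None, w_bc=None):
        """Advance (k, omega) by ``dt``; returns (k, omega, nu_t).

        ``a_rel_e`` is the element-mean ALE convective velocity.  Dirichlet
        node lists carry wall and inflow conditions; everything else is a
        natural (zero-flux) boundary.
        """
        c = self.c
        rho, mu = self.rho, self.mu
        area, grads = _fem.tri_geometry(points, tris)
        ml = _fem.lumped_mass(points, tris, area)

        s_mag, (gx, gy) = self.strain_rate(points, tris, u, area, grads)
        grad_k = _fem.node_gradient(points, tris, k, area, grads)
        grad_w = _fem.node_gradient(points, tris, om, area, grads)
        f1, f2 = self.blending(k, om, d_wall, grad_k, grad_w)
        mut = rho * self.eddy_viscosity(k, om, s_mag, f2)

        # production of k, limited
        p_k = mut * s_mag**2
        p_k = np.minimum(p_k, c.production_limit * c.beta_star * rho
                         * np.maximum(k, 0.0) * np.maximum(om, c.omega_min))
        gamma = c.blend(f1, c.gamma1, c.gamma2)
        beta = c.blend(f1, c.beta1, c.beta2)
        sig_k = c.blend(f1, c.sigma_k1, c.sigma_k2)
        sig_w = c.blend(f1, c.sigma_w1, c.sigma_w2)
        p_w = gamma * rho * s_mag**2
        cross = 2.0 * (1.0 - f1) * rho * c.sigma_w2 \
            / np.maximum(om, c.omega_min) \
            * np.einsum("ij,ij->i", grad_k, grad_w)

        conv = _fem.assemble_convection(points, tris, a_rel_e, area, grads) \
            + _fem.assemble_supg(points, tris, a_rel_e, area, grads)

        def transport(phi, diff_node, destr_coeff, src, dir_nodes, dir_vals):
            diff_e = _fem.element_mean(tris, diff_node)
            A = sp.diags(rho * ml / dt) + rho * conv \
                + _fem.assemble_stiffness(points, tris, diff_e, area, grads) \
                + sp.diags(ml * destr_coeff)
            rhs = rho * ml / dt * phi + ml * src
            if len(dir_nodes):
                A, rhs = _fem.apply_dirichlet(A, rhs, np.asarray(dir_nodes),
                                              dir_vals)
            return spla.spsolve(A.tocsc(), rhs)

        src_k = p_k + (self.c.s_k(points) if self.c.s_k else 0.0)
        src_w = p_w + cross + (self.c.s_w(points) if self.c.s_w else 0.0)

        k_new = transport(k, mu + sig_k * mut,
                          rho * c.beta_star * np.maximum(om, c.omega_min),
                          src_k, dirichlet_k,
                          k_bc if k_bc is not None else 0.0)
        om_new = transport(om, mu + sig_w * mut,
                           rho * beta * np.maximum(om, c.omega_min),
                           src_w, dirichlet_w,
                           w_bc if w_bc is not None else c.omega_min)

        k_new = np.maximum(k_new, 0.0)
        om_new = np.maximum(om_new, c.omega_min)
        if not (np.isfinite(k_new).all() and np.isfinite(om_new).all()):
            raise FloatingPointError("turbulence step produced NaN/Inf; "
                                     "reduce dt or check fields")
        s_mag2, _ = self.strain_rate(points, tris, u, area, grads)
        _, f2n = self.blending(k_new, om_new, d_wall)
        nut_new = self.eddy_viscosity(k_new, om_new, s_mag2, f2n)
        return k_new, om_new, nut_new
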