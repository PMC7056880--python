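import numpy as np
import pytest

from lvotflow import _fem
from lvotflow.meshing import structured_rect_mesh
from lvotflow.solver import (ALEFlowSolver, ConvergenceError, FluidProperties,
                             FlowState, SolverOptions)
from lvotflow.turbulence import TurbulenceClosure, SSTStepper

MU = 0.0035
RHO = 1050.0


def _wall_grading(n_core=12, n_bl=6, ratio=1.5, first=0.02):
    """Symmetric wall-refined grading for a channel: returns (grading, ny)."""
    h = [first * ratio ** k for k in range(n_bl)]
    total_bl = sum(h)
    core = np.full(n_core, (1.0 - 2 * total_bl) / n_core) \
        if 2 * total_bl < 1 else None
    steps = np.concatenate([h, core, h[::-1]])
    g = np.concatenate([[0.0], np.cumsum(steps)])
    return g / g[-1], len(steps)


class TestFreeStreamPreservation:
    def test_uniform_flow_on_translating_mesh(self):
        m = structured_rect_mesh(0.01, 0.01, 8, 8)
        u0 = np.array([0.3, 0.1])
        bc = {t: (lambda tt, xy: np.tile(u0, (len(xy), 1)))
              for t in ("left", "right", "top", "bottom")}
        bidx = m.boundary_nodes()
        base = m.points[bidx].copy()
        vel = np.array([2e-4, -1e-4])

        def motion(t):
            return bidx, base + vel * t

        s = ALEFlowSolver(m, FluidProperties(), SolverOptions(
            dt=1e-3, flux_ref=1e-3), bc, boundary_motion=motion)
        s.state.u[:] = u0
        for _ in range(100):
            s.step()
        assert np.abs(s.state.u - u0).max() < 1e-12


class TestPoiseuille:
    @pytest.fixture(scope="class")
    def channel(self, request):
        H, L, Um = 2e-3, 2e-2, 0.01
        grading, ny = _wall_grading(first=0.01)
        m = structured_rect_mesh(L, H, 30, ny, y_grading=grading)

        def inlet(t, xy):
            y = xy[:, 1]
            u = 1.5 * Um * (1 - ((y - H / 2) / (H / 2)) ** 2)
            return np.column_stack([u, np.zeros_like(u)])

        bc = {"left": inlet, "right": "neumann", "top": "wall",
              "bottom": "wall"}
        s = ALEFlowSolver(m, FluidProperties(), SolverOptions(
            dt=0.02, flux_ref=Um * H), bc)
        y = m.points[:, 1]
        s.state.u[:, 0] = 1.5 * Um * (1 - ((y - H / 2) / (H / 2)) ** 2)
        for _ in range(100):
            diag = s.step()
        return m, s, H, Um, diag

    def test_wall_shear_within_2pct(self, channel):
        m, s, H, Um, _ = channel
        tau_exact = 3 * MU * Um / (H / 2)
        area, grads = _fem.tri_geometry(m.points, m.tris)
        g1 = _fem.node_gradient(m.points, m.tris, s.state.u[:, 0], area,
                                grads)
        bot = m.nodes_with_tag("bottom")
        mid = bot[(m.points[bot, 0] > 0.008) & (m.points[bot, 0] < 0.012)]
        tau = MU * g1[mid, 1]
        assert abs(tau.mean() - tau_exact) / tau_exact < 0.02

    def test_centerline_velocity(self, channel):
        m, s, H, Um, _ = channel
        c = np.argmin(np.abs(m.points[:, 1] - H / 2)
                      + np.abs(m.points[:, 0] - 0.01))
        assert s.state.u[c, 0] == pytest.approx(1.5 * Um, rel=0.02)

    def test_continuity_criterion_met(self, channel):
        *_, diag = channel
        assert diag.residual < 1e-3

    def test_flow_reversal_flips_shear_sign(self, channel):
        """tau_12 is linear in the velocity: reversing U reverses the sign."""
        m, s, H, Um, _ = channel
        area, grads = _fem.tri_geometry(m.points, m.tris)
        g1 = _fem.node_gradient(m.points, m.tris, s.state.u[:, 0], area,
                                grads)
        g1r = _fem.node_gradient(m.points, m.tris, -s.state.u[:, 0], area,
                                 grads)
        np.testing.assert_allclose(g1r, -g1, atol=1e-12)


class TestCouette:
    def test_impulsive_start_profile(self):
        """Transient Couette against the image-series (erfc) solution."""
        from scipy.special import erfc
        H, U = 2e-3, 0.05
        nu = MU / RHO
        grading, ny = _wall_grading(n_core=10, n_bl=8, ratio=1.35,
                                    first=0.012)
        m = structured_rect_mesh(4e-3, H, 8, ny, y_grading=grading)
        t_final = 0.01
        nsteps = 100
        dt = t_final / nsteps

        def exact(y, t):
            s = np.zeros_like(y)
            rt = 2 * np.sqrt(nu * t)
            for n in range(6):
                s += erfc((2 * n * H + y) / rt) \
                    - erfc((2 * (n + 1) * H - y) / rt)
            return U * s

        def moving(t, xy):
            return np.tile([U, 0.0], (len(xy), 1))

        def side(t, xy):
            return np.column_stack([exact(xy[:, 1], max(t, 1e-9)),
                                    np.zeros(len(xy))])

        bc = {"bottom": moving, "top": "wall", "left": side, "right": side}
        s = ALEFlowSolver(m, FluidProperties(), SolverOptions(
            dt=dt, theta=0.5, flux_ref=U * H), bc)
        for _ in range(nsteps):
            s.step()
        mid = np.abs(m.points[:, 0] - 2e-3) < 1e-6
        y = m.points[mid, 1]
        u_num = s.state.u[mid, 0]
        u_ex = exact(y, t_final)
        err = np.abs(u_num - u_ex).max() / U
        assert err < 0.02


class TestSSTDecay:
    def test_decaying_turbulence_matches_ode(self):
        from scipy.integrate import solve_ivp
        m = structured_rect_mesh(0.01, 0.01, 4, 4)
        c = TurbulenceClosure(force_blend=0.0, omega_min=1e-8)
        st = SSTStepper(c, rho=RHO, mu=MU)
        k = np.full(m.n_points, 1.0)
        om = np.full(m.n_points, 100.0)
        nut = np.zeros(m.n_points)
        u = np.zeros((m.n_points, 2))
        a_e = np.zeros((m.n_cells, 2))
        d_wall = np.full(m.n_points, 1e3)
        T, nsteps = 0.05, 1500
        for _ in range(nsteps):
            k, om, nut = st.step(m.points, m.tris, a_e, k, om, nut, u,
                                 T / nsteps, d_wall)
        sol = solve_ivp(
            lambda t, y: [-c.beta_star * y[0] * y[1], -c.beta2 * y[1] ** 2],
            [0, T], [1.0, 100.0], rtol=1e-10, atol=1e-12)
        k_ex, om_ex = sol.y[0, -1], sol.y[1, -1]
        assert abs(k[0] - k_ex) / k_ex < 0.01
        assert abs(om[0] - om_ex) / om_ex < 0.01
        # closed-form check of the same reduced equations
        bw = c.beta2 * 100.0 * T
        k_cf = 1.0 * (1 + bw) ** (-c.beta_star / c.beta2)
        om_cf = 100.0 / (1 + bw)
        assert k_ex == pytest.approx(k_cf, rel=1e-6)
        assert om_ex == pytest.approx(om_cf, rel=1e-6)

    def test_zero_k_stays_laminar(self):
        m = structured_rect_mesh(0.01, 0.01, 4, 4)
        c = TurbulenceClosure()
        st = SSTStepper(c, rho=RHO, mu=MU)
        k = np.zeros(m.n_points)
        om = np.full(m.n_points, 10.0)
        u = np.zeros((m.n_points, 2))
        k2, om2, nut2 = st.step(m.points, m.tris,
                                np.zeros((m.n_cells, 2)), k, om,
                                np.zeros(m.n_points), u, 1e-3,
                                np.full(m.n_points, 1e3))
        assert np.all(k2 == 0.0)
        assert np.all(nut2 == 0.0)

    def test_solid_body_rotation_zero_production(self):
        # u = (-w x2, w x1): strain rate vanishes, so strain-based
        # production must vanish
        m = structured_rect_mesh(0.01, 0.01, 10, 10)
        c = TurbulenceClosure()
        st = SSTStepper(c, rho=RHO, mu=MU)
        w = 50.0
        x = m.points - m.points.mean(axis=0)
        u = np.column_stack([-w * x[:, 1], w * x[:, 0]])
        s_mag, _ = st.strain_rate(m.points, m.tris, u)
        interior = np.setdiff1d(np.arange(m.n_points), m.boundary_nodes())
        assert np.abs(s_mag[interior]).max() < 1e-8 * w


class TestEnergyAndErrors:
    def test_zero_everything_stays_zero(self):
        m = structured_rect_mesh(0.01, 0.01, 6, 6)
        bc = {t: "wall" for t in ("left", "right", "top", "bottom")}
        s = ALEFlowSolver(m, FluidProperties(), SolverOptions(
            dt=1e-3, flux_ref=1e-6), bc)
        for _ in range(5):
            s.step()
        assert np.all(s.state.u == 0.0)
        assert np.all(s.state.p == 0.0)

    def test_closed_box_kinetic_energy_decays(self):
        m = structured_rect_mesh(0.01, 0.01, 10, 10)
        bc = {t: "wall" for t in ("left", "right", "top", "bottom")}
        s = ALEFlowSolver(m, FluidProperties(), SolverOptions(
            dt=2e-3, flux_ref=1e-4), bc)
        x = m.points / 0.01
        free = np.setdiff1d(np.arange(m.n_points), m.boundary_nodes())
        s.state.u[free, 0] = 0.05 * np.sin(np.pi * x[free, 0]) \
            * np.cos(np.pi * x[free, 1])
        s.state.u[free, 1] = -0.05 * np.cos(np.pi * x[free, 0]) \
            * np.sin(np.pi * x[free, 1])
        ml = _fem.lumped_mass(m.points, m.tris)
        ke = [float((ml[:, None] * s.state.u ** 2).sum())]
        for _ in range(10):
            s.step()
            ke.append(float((ml[:, None] * s.state.u ** 2).sum()))
        assert all(b <= a * (1 + 1e-12) for a, b in zip(ke[:-1], ke[1:]))

    def test_bad_dt_rejected(self):
        m = structured_rect_mesh(0.01, 0.01, 4, 4)
        bc = {t: "wall" for t in ("left", "right", "top", "bottom")}
        s = ALEFlowSolver(m, FluidProperties(), SolverOptions(dt=1e-3), bc)
        with pytest.raises(ValueError):
            s.step(dt=-1.0)

    def test_bad_properties_rejected(self):
        with pytest.raises(ValueError):
            FluidProperties(rho=-1.0)

    def test_convergence_error_carries_history(self):
        err = ConvergenceError("x", [1.0, 0.5])
        assert err.history == [1.0, 0.5]
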