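"""Mixed-element solver: assembly, stepping, conservation, rejection."""

import numpy as np
import pytest
from scipy.sparse.linalg import splu

import microreactor as mr
from microreactor import fem
from microreactor import geometry as geo
from microreactor import scenarios as sc

from conftest import make_se_simulator


class LinearSink:
    """Single-species bulk sink -k y (exact backward-Euler solution known)."""

    n_species, n_params = 1, 0

    def __init__(self, k):
        self.k = k

    def bead_rates(self, y):
        return -self.k * np.asarray(y, dtype=float)

    def bead_jac_y(self, y):
        y = np.asarray(y)
        J = np.zeros((1, 1) + y.shape[1:])
        J[0, 0] = -self.k
        return J

    def bead_jac_lam(self, y):
        return np.zeros((1, 0) + np.asarray(y).shape[1:])

    def export_rates(self, y):
        return np.zeros(np.asarray(y).shape)

    def export_jac_y(self, y):
        return np.zeros((1, 1) + np.asarray(y).shape[1:])


@pytest.fixture(scope="module")
def small_mesh():
    return geo.structured_square_mesh(500e-6, 6)


def diffusion_sim(mesh, theta_e=0.0, y0=1.0, T=25.0, dt=0.25, **kw):
    tr = fem.TransportParameters(D=np.array([1e-9]), theta_e=theta_e,
                                 y0=np.array([y0]))
    return fem.ReactorSimulator(mesh, fem.NoReaction(1), tr,
                                fem.TimeSteppingConfig(T=T, dt=dt), **kw)


class TestAssembly:
    def test_uniform_steady_state_has_zero_residual(self, small_mesh):
        sim = diffusion_sim(small_mesh, y0=2.0)
        st = sim.initial_state()
        F = sim.residual(sim.pack(st), st.y, 0.25, 0.25)
        assert np.abs(F).max() < 1e-18

    def test_step_keeps_steady_state(self, small_mesh):
        sim = diffusion_sim(small_mesh, y0=2.0)
        new, iters = sim.implicit_euler_step(sim.initial_state(), 0.25)
        assert iters == 0
        np.testing.assert_array_equal(new.y, 2.0)

    def test_jacobian_matches_directional_finite_differences(self, hs_params):
        """Full step-system Jacobian vs FD on a coarse SE mesh."""
        mesh = geo.structured_square_mesh(500e-6, 3)
        lam = np.array([0.2, 0.5, 0.3])
        sim = make_se_simulator(mesh, hs_params.with_loading(1.94e-8), lam,
                                bulk_scale=np.pi * 1e-5 / (500e-6) ** 2)
        rng = np.random.default_rng(3)
        st = sim.initial_state()
        st.y[:] = rng.uniform(0.0, 2.0, st.y.shape)
        st.trace[:] = rng.uniform(0.0, 2.0, st.trace.shape)
        u = sim.pack(st)
        dt = 0.5
        Ldt = sim.L0 + sim.Mdiag / dt
        _, jvals = sim._reaction_terms(u, dt)
        J = sim._jacobian(Ldt, jvals)
        rng2 = np.random.default_rng(4)
        for _ in range(5):
            v = rng2.standard_normal(sim.n_dof)
            v /= np.linalg.norm(v)
            h = 1e-6
            Fp = sim.residual(u + h * v, st.y, dt, dt)
            Fm = sim.residual(u - h * v, st.y, dt, dt)
            fd = (Fp - Fm) / (2 * h)
            Jv = J @ v
            scale = np.abs(Jv).max()
            np.testing.assert_allclose(Jv, fd, atol=1e-6 * scale)

    def test_constant_bead_source_is_integrated_exactly(self, hs_params):
        """With y=0 everywhere only invertase fires: the first-step mass gain
        of G equals dt * |Gamma_b| * r_inv to solver tolerance (local
        conservation of the boundary source)."""
        fx = sc.make_fixtures("coarse-1-bead")
        scen = fx["scenario"]
        lam = np.array([1.0, 0.0, 0.0])  # invertase only: r_inv is constant
        sim = make_se_simulator(scen.mesh, scen.params, lam, dt=0.5, D=1e-7)
        st = sim.initial_state()
        new, _ = sim.implicit_euler_step(st, 0.5)
        Gb = geo.boundary_measures(scen.mesh)["Gamma_b"]
        r_inv = mr.rate_invertase(1.0, scen.params.S, scen.params)
        gained = sim.total_mass(new)[mr.Species.G]
        assert gained == pytest.approx(0.5 * Gb * r_inv, rel=1e-10)

    def test_bulk_on_bead_mesh_rejected(self, coarse_bead_mesh, hs_params):
        with pytest.raises(ValueError):
            make_se_simulator(coarse_bead_mesh, hs_params,
                              np.ones(3) / 3, bulk_scale=1.0)


class TestImplicitEuler:
    def test_linear_decay_closed_form(self, small_mesh):
        k, dt = 3.0, 0.25
        tr = fem.TransportParameters(D=np.array([1e-9]), theta_e=0.0,
                                     y0=np.array([2.0]))
        sim = fem.ReactorSimulator(small_mesh, LinearSink(k), tr,
                                   fem.TimeSteppingConfig(T=1.0, dt=dt),
                                   bulk_scale=1.0)
        new, _ = sim.implicit_euler_step(sim.initial_state(), dt)
        np.testing.assert_allclose(new.y, 2.0 / (1.0 + k * dt), rtol=1e-12)

    def test_vanishing_step_leaves_state_unchanged(self, small_mesh):
        sim = diffusion_sim(small_mesh, theta_e=0.0, y0=1.0)
        st = sim.initial_state()
        rng = np.random.default_rng(1)
        st.y[0] = rng.uniform(0.5, 2.0, sim.n_c)
        new, _ = sim.implicit_euler_step(st, 1e-9)
        np.testing.assert_allclose(new.y, st.y, rtol=1e-6)

    def test_stiff_sink_rejects_then_succeeds_at_halved_step(self):
        fx = sc.make_fixtures("stiff-sink")
        sim = fem.ReactorSimulator(fx["mesh"], fx["model"], fx["transport"],
                                   fx["tstep"], bulk_scale=1.0)
        with pytest.raises(fem.StepRejected):
            sim.implicit_euler_step(sim.initial_state(), fx["tstep"].dt)
        res = sim.run()
        assert res.rejections >= 1
        assert res.state.y.min() >= 0.0
        assert res.state.t == pytest.approx(fx["tstep"].T)

    def test_hard_failure_below_minimum_step(self):
        fx = sc.make_fixtures("stiff-sink")
        tstep = fem.TimeSteppingConfig(T=8.0, dt=2.0, dt_min=1.9)
        sim = fem.ReactorSimulator(fx["mesh"], fx["model"], fx["transport"],
                                   tstep, bulk_scale=1.0)
        with pytest.raises(fem.SolverError):
            sim.run()


class TestRunForward:
    def test_no_enzymes_all_observables_zero(self, coarse_bead_mesh, hs_params):
        """Zero loading x zero initial state: nothing happens."""
        p = hs_params.with_loading(0.0)
        sim = make_se_simulator(coarse_bead_mesh, p, np.ones(3) / 3,
                                T=5.0, dt=1.0)
        res = sim.run()
        assert np.allclose(res.production, 0.0, atol=1e-25)
        assert np.allclose(res.outflow, 0.0, atol=1e-25)

    def test_pure_diffusion_conserves_mass(self, small_mesh):
        sim = diffusion_sim(small_mesh, theta_e=0.0, T=25.0, dt=0.25)
        st = sim.initial_state()
        rng = np.random.default_rng(0)
        st.y[0] = rng.uniform(0.5, 2.0, sim.n_c)
        m0 = sim.total_mass(st)[0]
        res = sim.run(state0=st)
        assert len(res.step_dts) == 100
        assert abs(sim.total_mass(res.state)[0] - m0) <= 1e-12 * m0

    def test_deterministic_rerun(self, coarse_bead_mesh, hs_params):
        p = hs_params.with_loading(1.94e-8)
        runs = []
        for _ in range(2):
            sim = make_se_simulator(coarse_bead_mesh, p, np.ones(3) / 3,
                                    T=5.0, dt=1.0)
            runs.append(sim.run())
        np.testing.assert_array_equal(runs[0].outflow, runs[1].outflow)
        np.testing.assert_array_equal(runs[0].state.y, runs[1].state.y)

    def test_snapshots_recorded(self, small_mesh):
        sim = diffusion_sim(small_mesh, T=2.0, dt=0.5)
        res = sim.run(snapshot_times=[1.0, 2.0])
        assert set(res.snapshots) == {1.0, 2.0}
        assert res.snapshots[1.0].t == pytest.approx(1.0)


class TestNonHybridCrossCheck:
    def test_hybrid_equals_nonhybrid_on_linear_diffusion(self, small_mesh):
        sim = diffusion_sim(small_mesh, theta_e=0.0)
        st = sim.initial_state()
        rng = np.random.default_rng(5)
        st.y[0] = rng.uniform(0.5, 2.0, sim.n_c)
        new, _ = sim.implicit_euler_step(st, 0.25)
        y_nh = fem.solve_linear_mixed_nonhybrid(sim, st, 0.25)
        np.testing.assert_allclose(new.y, y_nh, rtol=1e-10)


class TestManufacturedSolution:
    def test_first_step_accuracy(self):
        """Single backward-Euler step against the exact manufactured field."""
        fx = sc.make_fixtures("manufactured")
        mesh = fx["mesh_factory"](16)
        tr = fem.TransportParameters(D=np.array([fx["D"]]), theta_e=0.0)
        sim = fem.ReactorSimulator(mesh, fem.NoReaction(1), tr,
                                   fem.TimeSteppingConfig(T=1.0, dt=0.05),
                                   source=fx["source"])
        st = sim.initial_state()
        st.y[:] = fx["exact"](0.0, mesh.cell_centroids)
        st.trace[:] = fx["exact"](0.0, mesh.facet_midpoints)
        new, _ = sim.implicit_euler_step(st, 0.05)
        ex = fx["exact"](0.05, mesh.cell_centroids)
        err = np.sqrt(np.sum(mesh.tri_area * (new.y - ex) ** 2))
        norm = np.sqrt(np.sum(mesh.tri_area * ex**2))
        assert err / norm < 5e-3
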