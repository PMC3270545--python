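"""First-order system residuals, the least-squares functional, Gauss-Newton."""

import numpy as np
import pytest

from wlsfem import (BoundarySpec, FlowProblem, FlowState, assemble_functional,
                    build_box_mesh, exact_interior_residuals, gauss_newton_step,
                    interior_residuals, recover_total_pressure, solve_timestep)
from wlsfem.fosls import assemble_normal_system, n_dof_per_node
from wlsfem.synthetic import analytic_flow


def state_from_flow(flow, mesh, t=0.0):
    return FlowState(flow.v(mesh.nodes, t), flow.omega(mesh.nodes, t),
                     flow.r(mesh.nodes, t), t=t)


def lid_specs(mesh, w=1.0):
    def lid(x, t):
        g = np.zeros_like(np.atleast_2d(x))
        g[:, 0] = np.where(np.abs(x[:, 1] - 1.0) < 1e-12, 1.0, 0.0)
        return g
    return [BoundarySpec(tag, "velocity", lid, w) for tag in mesh.boundary_tags]


class TestInteriorResiduals:
    def test_rigid_rotation_sign_convention(self):
        # v = (-y, x): the vorticity is omega = -curl v = -2, and the first
        # equation curl v + omega = 2 + (-2) must vanish
        flow = analytic_flow("rigid_rotation", Omega=1.0, Re=2.0)
        mesh = build_box_mesh([2.0, 2.0], [2, 2], origin=[-1, -1])
        st = state_from_flow(flow, mesh)
        assert st.omega[0, 0] == pytest.approx(-2.0)
        res = interior_residuals(st, 2.0, np.array([0.3, -0.2]), mesh)
        assert abs(res["vorticity_def"][0]) < 1e-12
        assert abs(res["continuity"][0]) < 1e-12

    def test_zero_state_gives_zero_residuals(self, unit_square_2x2):
        st = FlowState.zero(unit_square_2x2)
        res = interior_residuals(st, 10.0, np.array([0.4, 0.6]), unit_square_2x2)
        for v in res.values():
            np.testing.assert_allclose(v, 0.0, atol=1e-15)

    @pytest.mark.parametrize("name,kw", [
        ("poiseuille", dict(u_max=1.0, H=1.0, Re=50.0)),
        ("rigid_rotation", dict(Omega=1.3, Re=7.0)),
    ])
    def test_exact_flows_satisfy_all_equations(self, name, kw, rng):
        flow = analytic_flow(name, **kw)
        for _ in range(10):
            p = rng.uniform(0.1, 0.9, 2)
            res = exact_interior_residuals(flow, kw["Re"], p)
            for fam, v in res.items():
                assert np.abs(v).max() < 1e-10, fam

    def test_decaying_vortex_with_time_derivative(self, rng):
        flow = analytic_flow("decaying_vortex", Re=10.0, k=np.pi)
        for t in (0.0, 0.2):
            p = rng.uniform(0.1, 0.9, 2)
            res = exact_interior_residuals(flow, 10.0, p, t=t, transient=True)
            for fam, v in res.items():
                assert np.abs(v).max() < 1e-10, fam

    def test_verbatim_closure_differs_at_general_re(self, rng):
        # the commonly printed closure has Re where consistency requires Re^2;
        # it only vanishes for exact flows when v.r = 0 or Re = 1
        flow = analytic_flow("poiseuille", u_max=1.0, H=1.0, Re=50.0)
        p = np.array([0.5, 0.3])
        res = exact_interior_residuals(flow, 50.0, p, pressure_link="verbatim")
        assert abs(res["pressure_div"][0]) > 1.0

    def test_zero_dt_rejected(self, unit_square_2x2):
        st = FlowState.zero(unit_square_2x2)
        with pytest.raises(ValueError, match="dt"):
            interior_residuals(st, 1.0, np.array([0.5, 0.5]), unit_square_2x2,
                               dt=0.0, prev_state=st)

    def test_functional_matches_pointwise_residual_quadrature(self):
        # internal consistency: the assembled interior terms integrate exactly
        # the squared residuals the pointwise evaluator reports
        mesh = build_box_mesh([1.0, 1.0], [2, 2])
        rng = np.random.default_rng(3)
        st = FlowState(rng.normal(size=(mesh.n_nodes, 2)),
                       rng.normal(size=(mesh.n_nodes, 1)),
                       rng.normal(size=(mesh.n_nodes, 2)))
        prob = FlowProblem(mesh, Re=5.0)
        G, bd = assemble_functional(prob, st)
        xq, wdet, _, _ = mesh.element_quadrature()
        acc = 0.0
        for e in range(mesh.n_elements):
            for q in range(xq.shape[1]):
                res = interior_residuals(st, 5.0, xq[e, q], mesh)
                acc += wdet[e, q] * sum(float(v @ v) for v in res.values())
        assert G == pytest.approx(acc, rel=1e-9)


class TestFunctional:
    def test_nonnegative_and_zero_for_zero_data(self, unit_square_2x2):
        prob = FlowProblem(unit_square_2x2, Re=1.0,
                           boundary_specs=lid_specs(unit_square_2x2, 0.0))
        G, _ = assemble_functional(prob, FlowState.zero(unit_square_2x2))
        assert G == 0.0

    def test_boundary_term_zero_when_data_matched(self):
        mesh = build_box_mesh([2.0, 2.0], [2, 2], origin=[-1, -1])
        flow = analytic_flow("rigid_rotation", Omega=1.0, Re=2.0)
        st = state_from_flow(flow, mesh)
        specs = [BoundarySpec(t, "velocity", lambda x, tt: flow.v(x), 1.0)
                 for t in mesh.boundary_tags]
        prob = FlowProblem(mesh, Re=2.0, boundary_specs=specs)
        _, bd = assemble_functional(prob, st)
        assert bd["boundary_velocity"] < 1e-24

    def test_doubling_weight_doubles_only_the_boundary_term(self, unit_square_2x2):
        mesh = unit_square_2x2
        st = FlowState(np.ones((mesh.n_nodes, 2)), np.zeros((mesh.n_nodes, 1)),
                       np.zeros((mesh.n_nodes, 2)))
        bds = []
        for w in (1.0, 2.0):
            prob = FlowProblem(mesh, Re=1.0, boundary_specs=lid_specs(mesh, w))
            bds.append(assemble_functional(prob, st)[1])
        assert bds[1]["boundary_velocity"] == pytest.approx(
            2 * bds[0]["boundary_velocity"], rel=1e-13)
        for fam in ("vorticity_def", "continuity", "momentum"):
            assert bds[1][fam] == pytest.approx(bds[0][fam], rel=1e-13)

    def test_normal_vorticity_boundary_term(self, unit_cube_1):
        # on the top face (n = +z) the term penalizes omega_z - g2
        mesh = unit_cube_1
        st = FlowState.zero(mesh)
        st.omega[:, 2] = 0.7
        g2 = lambda x, t: np.full(np.atleast_2d(x).shape[0], 0.7)
        prob = FlowProblem(mesh, Re=1.0, boundary_specs=[
            BoundarySpec("top", "normal_vorticity", g2, 1.0)])
        _, bd = assemble_functional(prob, st)
        assert bd["boundary_vorticity"] < 1e-26
        st.omega[:, 2] = 0.0  # now the misfit is (0 - 0.7)^2 * area / h
        _, bd = assemble_functional(prob, st)
        assert bd["boundary_vorticity"] == pytest.approx(0.49, rel=1e-10)

    def test_normal_vorticity_term_is_3d_only(self, unit_square_2x2):
        g2 = lambda x, t: np.zeros(np.atleast_2d(x).shape[0])
        prob = FlowProblem(unit_square_2x2, Re=1.0, boundary_specs=[
            BoundarySpec("top", "normal_vorticity", g2, 1.0)])
        with pytest.raises(ValueError, match="3D"):
            assemble_functional(prob, FlowState.zero(unit_square_2x2))

    def test_missing_prev_state_rejected(self, unit_square_2x2):
        prob = FlowProblem(unit_square_2x2, Re=1.0, dt=0.1)
        with pytest.raises(ValueError, match="prev_state"):
            assemble_functional(prob, FlowState.zero(unit_square_2x2))

    def test_interpolated_solution_functional_decreases_under_refinement(self):
        flow = analytic_flow("decaying_vortex", Re=5.0, k=np.pi)
        Gs = []
        for n in (2, 4, 8):
            mesh = build_box_mesh([1.0, 1.0], [n, n])
            prob = FlowProblem(mesh, Re=5.0, stokes_limit=True)
            G, _ = assemble_functional(prob, state_from_flow(flow, mesh))
            Gs.append(G)
        assert Gs[0] > Gs[1] > Gs[2]


class TestGaussNewton:
    def test_linear_problem_minimized_in_one_step(self, unit_square_2x2):
        prob = FlowProblem(unit_square_2x2, Re=1.0,
                           boundary_specs=lid_specs(unit_square_2x2),
                           stokes_limit=True, solver_opts={"tol": 1e-13})
        s1, d1 = gauss_newton_step(prob, FlowState.zero(unit_square_2x2))
        assert d1["G_after"] < d1["G_before"]
        s2, d2 = gauss_newton_step(prob, s1)
        assert d2["rel_change"] < 1e-10

    def test_exact_minimizer_is_a_fixed_point(self, unit_square_2x2):
        prob = FlowProblem(unit_square_2x2, Re=1.0,
                           boundary_specs=lid_specs(unit_square_2x2),
                           stokes_limit=True, solver_opts={"tol": 1e-13})
        s1, _ = gauss_newton_step(prob, FlowState.zero(unit_square_2x2))
        _, d2 = gauss_newton_step(prob, s1)
        assert d2["step_norm"] < 1e-9 * (1 + np.linalg.norm(s1.pack()))

    def test_cavity_converges_within_iteration_envelope(self):
        # impulsively started lid-driven cavity at Re=100: each implicit step's
        # Gauss-Newton iteration reaches relative functional change < 1e-8
        # within the 15-iteration envelope
        mesh = build_box_mesh([1.0, 1.0], [3, 3])
        prev = FlowState.zero(mesh)
        for k in range(1, 4):
            prob = FlowProblem(mesh, Re=100.0, dt=0.05, time=0.05 * k,
                               boundary_specs=lid_specs(mesh), prev_state=prev)
            prev = solve_timestep(prob, initial_guess=prev, tol=1e-8, max_iter=15)
            assert prev.converged
            assert prev.iterations <= 15

    def test_negating_data_negates_stokes_solution(self, unit_square_2x2):
        mesh = unit_square_2x2
        sols = []
        for sign in (1.0, -1.0):
            def lid(x, t, s=sign):
                g = np.zeros_like(np.atleast_2d(x))
                g[:, 0] = s * np.where(np.abs(x[:, 1] - 1.0) < 1e-12, 1.0, 0.0)
                return g
            specs = [BoundarySpec(t, "velocity", lid, 1.0)
                     for t in mesh.boundary_tags]
            prob = FlowProblem(mesh, Re=1.0, boundary_specs=specs,
                               stokes_limit=True, solver_opts={"tol": 1e-13})
            sols.append(gauss_newton_step(prob, FlowState.zero(mesh))[0])
        np.testing.assert_allclose(sols[0].pack(), -sols[1].pack(), atol=1e-9)


class TestNormalSystemProperties:
    @pytest.mark.parametrize("re", [1.0, 100.0])
    def test_flow_normal_matrix_spd_by_dense_eigencheck(self, re):
        mesh = build_box_mesh([1.0, 1.0], [2, 2])  # 125 unknowns
        rng = np.random.default_rng(1)
        st = FlowState(0.1 * rng.normal(size=(mesh.n_nodes, 2)),
                       0.1 * rng.normal(size=(mesh.n_nodes, 1)),
                       0.1 * rng.normal(size=(mesh.n_nodes, 2)))
        prob = FlowProblem(mesh, Re=re, boundary_specs=lid_specs(mesh))
        sysm = assemble_normal_system(prob, st)
        assert sysm.matrix.shape[0] == mesh.n_nodes * n_dof_per_node(2) <= 500
        assert sysm.symmetry_error() < 1e-12
        ev = np.linalg.eigvalsh(sysm.matrix.toarray())
        assert ev.min() > 0

    def test_dof_map_layout(self, unit_square_2x2):
        prob = FlowProblem(unit_square_2x2, Re=1.0,
                           boundary_specs=lid_specs(unit_square_2x2))
        sysm = assemble_normal_system(prob, FlowState.zero(unit_square_2x2))
        assert sysm.dof_index(3, "v", 1) == 3 * 5 + 1
        assert sysm.dof_index(3, "omega") == 3 * 5 + 2
        assert sysm.dof_index(3, "r", 1) == 3 * 5 + 4
        with pytest.raises(IndexError):
            sysm.dof_index(0, "omega", 1)


class TestTimeStepping:
    def test_quiescent_problem_stays_at_rest(self, unit_square_2x2):
        mesh = unit_square_2x2
        zero = lambda x, t: np.zeros_like(np.atleast_2d(x))
        specs = [BoundarySpec(t, "velocity", zero, 1.0) for t in mesh.boundary_tags]
        prob = FlowProblem(mesh, Re=10.0, dt=0.1, boundary_specs=specs,
                           prev_state=FlowState.zero(mesh))
        sol = solve_timestep(prob)
        assert sol.functional_value < 1e-20
        np.testing.assert_allclose(sol.v, 0.0, atol=1e-10)

    def test_impulsive_channel_approaches_poiseuille(self):
        # impulsively started channel flow settles onto the analytic steady
        # profile; the remaining gap is discretization error and shrinks under
        # refinement (weak boundary enforcement, cubic total-pressure gradient)
        Re = 2.0
        flow = analytic_flow("poiseuille", u_max=1.0, H=1.0, Re=Re)
        errs = []
        for n in (4, 8):
            mesh = build_box_mesh([2.0, 1.0], [n, n])
            specs = [BoundarySpec(t, "velocity", lambda x, tt: flow.v(x), 1.0)
                     for t in ("left", "bottom", "top")]
            prev = FlowState.zero(mesh)
            for k in range(1, 16):
                prob = FlowProblem(mesh, Re=Re, dt=0.5, time=0.5 * k,
                                   boundary_specs=specs, prev_state=prev)
                prev = solve_timestep(prob, initial_guess=prev)
            xq, wdet, N, _ = mesh.element_quadrature()
            vh = np.einsum("qn,eni->eqi", N, prev.v[mesh.elements])
            vex = flow.v(xq.reshape(-1, 2)).reshape(vh.shape)
            errs.append(np.sqrt(np.sum(wdet[..., None] * (vh - vex) ** 2)))
        assert errs[1] < 0.08          # below the fine mesh's discretization level
        assert errs[0] / errs[1] > 3.0  # and clearly converging with h

    def test_backward_euler_first_order_in_time(self):
        # Richardson: error at dt vs dt/2 against a small-dt reference
        Re = 10.0
        flow = analytic_flow("decaying_vortex", Re=Re, k=np.pi)
        mesh = build_box_mesh([1.0, 1.0], [4, 4])
        specs = [BoundarySpec(t, "velocity", lambda x, tt: flow.v(x, tt), 1.0)
                 for t in mesh.boundary_tags]
        t_final = 0.2

        def advance(dt):
            prev = FlowState(flow.v(mesh.nodes, 0.0), flow.omega(mesh.nodes, 0.0),
                             flow.r(mesh.nodes, 0.0))
            n = int(round(t_final / dt))
            for k in range(1, n + 1):
                prob = FlowProblem(mesh, Re=Re, dt=dt, time=k * dt,
                                   boundary_specs=specs, prev_state=prev)
                prev = solve_timestep(prob, initial_guess=prev)
            return prev.v

        ref = advance(t_final / 16)
        e1 = np.linalg.norm(advance(t_final / 2) - ref)
        e2 = np.linalg.norm(advance(t_final / 4) - ref)
        assert 1.4 < e1 / e2 < 3.2  # ratio ~2 for first order


def test_pressure_recovery_reproduces_quadratic_pressure():
    # r = grad p with p = x^2 + y^2 (Stokes-limit field, v = 0)
    mesh = build_box_mesh([1.0, 1.0], [2, 2])
    st = FlowState.zero(mesh)
    st.r = 2.0 * mesh.nodes.copy()
    p, phi = recover_total_pressure(mesh, st, Re=1.0)
    exact = np.sum(mesh.nodes ** 2, axis=1)
    shift = p - exact
    np.testing.assert_allclose(shift - shift.mean(), 0.0, atol=1e-8)
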