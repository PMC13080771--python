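"""FE solver verification: assembly contracts, analytic benchmarks,
linear-regime behaviour and the viscoelastic time stepper."""

import numpy as np
import pytest

from cellindent.fixtures import flat_punch_fixture, randomized_property_cases
from cellindent.geometry import build_domain, build_gel_domain
from cellindent.loading import LoadCase, build_bcs, default_materials
from cellindent.materials import MaterialSpec
from cellindent.solver import (
    AxisymOperator,
    SolverSettings,
    assemble,
    materials_as_elastic,
    solve_quasistatic,
    solve_viscoelastic,
)


class TestAssembly:
    def test_zero_state_zero_residual(self, coarse_mesh, soft_materials):
        R, K = assemble(coarse_mesh, soft_materials, np.zeros(2 * coarse_mesh.n_nodes))
        assert np.allclose(R, 0.0, atol=1e-14)
        assert K.shape == (2 * coarse_mesh.n_nodes,) * 2

    def test_tangent_consistency_fd(self, coarse_mesh, soft_materials, rng):
        """K du matches the residual difference for random small states."""
        op = AxisymOperator(coarse_mesh, soft_materials)
        u = 1e-3 * rng.standard_normal(op.ndof)
        R0, K = assemble(op, soft_materials, u)
        du = 1e-6 * rng.standard_normal(op.ndof)
        R1, _ = assemble(op, soft_materials, u + du)
        lhs, rhs = K @ du, R1 - R0
        assert np.linalg.norm(lhs - rhs) / np.linalg.norm(rhs) < 1e-5

    def test_reactions_balance_applied_load(self):
        """Sum of reactions at constrained dofs equals minus the applied
        resultant (distributed surface load on a gel block)."""
        mesh = build_gel_domain(resolution=1, punch_radius=4.0)
        bcs = build_bcs(mesh)
        mats = {"gel": MaterialSpec(law="neo_hookean", E=2.4, nu=0.48)}
        top = mesh.surface_sets["punch"]
        F = 5.0
        fext = np.zeros(2 * mesh.n_nodes)
        fext[2 * top + 1] = -F / top.size
        st = solve_quasistatic(mesh, mats, fext, bcs, SolverSettings(n_load_steps=1))
        op = AxisymOperator(mesh, mats)
        f_int = op.internal_force(
            op.stress_and_tangent(op.deformation_gradients(st.u), need_tangent=False)[0]
        )
        # reactions = internal forces at constrained dofs; they balance the
        # net applied force of -F (downward)
        z_dofs = bcs.fixed_dofs[bcs.fixed_dofs % 2 == 1]
        assert f_int[z_dofs].sum() == pytest.approx(F, rel=1e-8)


class TestQuasistatic:
    def test_zero_load_zero_displacement(self, coarse_mesh, soft_materials, coarse_bcs):
        st = solve_quasistatic(
            coarse_mesh,
            soft_materials,
            None,
            coarse_bcs,
            SolverSettings(n_load_steps=1),
        )
        assert np.allclose(st.u, 0.0, atol=1e-12)
        assert st.converged

    def test_flat_punch_matches_boussinesq(self):
        """Rigid-punch depth within 5% of d = F (1-nu^2)/(2 a E)."""
        fx = flat_punch_fixture(a=3.0, E=2.4, nu=0.48, F=10.0, resolution=2)
        st = solve_quasistatic(
            fx.mesh, fx.materials, fx.loadcase, fx.bcs, SolverSettings(n_load_steps=1)
        )
        d = -st.u[fx.extra["punch_dof"][0]]
        expected, tol = fx.expected["depth"]
        assert d == pytest.approx(expected, rel=tol)

    def test_punch_error_decreases_under_refinement(self):
        errs = []
        for res in (1, 2):
            fx = flat_punch_fixture(resolution=res)
            st = solve_quasistatic(
                fx.mesh, fx.materials, fx.loadcase, fx.bcs, SolverSettings(n_load_steps=1)
            )
            d = -st.u[fx.extra["punch_dof"][0]]
            errs.append(abs(d - fx.expected["depth"][0]))
        assert errs[1] < errs[0]

    def test_small_load_linearity(self, coarse_mesh, soft_materials, coarse_bcs):
        """Doubling a sub-nN load doubles the displacement field within 1%."""
        s1 = solve_quasistatic(
            coarse_mesh,
            soft_materials,
            LoadCase(F_normal=0.5, config="top"),
            coarse_bcs,
            SolverSettings(n_load_steps=1),
        )
        s2 = solve_quasistatic(
            coarse_mesh,
            soft_materials,
            LoadCase(F_normal=1.0, config="top"),
            coarse_bcs,
            SolverSettings(n_load_steps=1),
        )
        scale = np.linalg.norm(s2.u) / np.linalg.norm(s1.u)
        assert scale == pytest.approx(2.0, rel=0.01)

    def test_deterministic_reruns_bit_identical(self, coarse_mesh, soft_materials, coarse_bcs):
        lc = LoadCase(F_normal=10.0, config="bottom")
        a = solve_quasistatic(coarse_mesh, soft_materials, lc, coarse_bcs)
        b = solve_quasistatic(coarse_mesh, soft_materials, lc, coarse_bcs)
        assert np.array_equal(a.u, b.u)

    def test_converged_state_contract(self, coarse_mesh, soft_materials, coarse_bcs):
        st = solve_quasistatic(
            coarse_mesh, soft_materials, LoadCase(F_normal=20.0), coarse_bcs
        )
        assert st.converged
        assert st.residual_norm <= SolverSettings().newton_tol
        assert np.all(np.linalg.det(st.F) > 0.0)

    def test_viscoelastic_material_rejected(self, coarse_mesh, coarse_bcs):
        mats = default_materials(cytoplasm_model="viscoelastic")
        with pytest.raises(ValueError):
            solve_quasistatic(coarse_mesh, mats, LoadCase(), coarse_bcs)


class TestEquilibriumProperty:
    def test_randomized_cases_reaction_balance(self):
        """Seeded random fixtures: reactions equal minus the applied load."""
        for fx in randomized_property_cases(seed=20240301, n=3):
            st = solve_quasistatic(
                fx.mesh, fx.materials, fx.loadcase, fx.bcs, SolverSettings(n_load_steps=2)
            )
            op = AxisymOperator(fx.mesh, fx.materials)
            f_int = op.internal_force(
                op.stress_and_tangent(op.deformation_gradients(st.u), need_tangent=False)[0]
            )
            z_dofs = fx.bcs.fixed_dofs[fx.bcs.fixed_dofs % 2 == 1]
            expected, tol = fx.expected["net_force"]
            assert f_int[z_dofs].sum() == pytest.approx(-expected, rel=1e-8)

    def test_randomized_cases_deterministic(self):
        a = randomized_property_cases(seed=7, n=2)
        b = randomized_property_cases(seed=7, n=2)
        for fa, fb in zip(a, b):
            assert np.array_equal(fa.loadcase, fb.loadcase)
            assert fa.materials["gel"].E == fb.materials["gel"].E


class TestViscoelasticSolve:
    @pytest.fixture(scope="class")
    def small_force_setup(self):
        mesh = build_domain(resolution=1)
        bcs = build_bcs(mesh)
        lc = LoadCase(F_normal=1.0, config="top")
        return mesh, bcs, lc

    def test_long_hold_matches_equilibrium_elastic(self, small_force_setup):
        """Equilibrium-anchored mode: after a hold of many relaxation times
        the state equals the elastic solve with the equilibrium modulus."""
        mesh, bcs, lc = small_force_setup
        mats = default_materials(
            E_cyto=0.8, cytoplasm_model="viscoelastic", prony_mode="equilibrium"
        )
        states = solve_viscoelastic(
            mesh,
            bcs=bcs,
            loadcase=lc,
            materials=mats,
            settings=SolverSettings(
                ramp_time=0.0, hold_time=400.0, dt=0.5, steady_state_tol=1e-7
            ),
        )
        st_el = solve_quasistatic(
            mesh, materials_as_elastic(mats, "equilibrium"), lc, bcs,
            SolverSettings(n_load_steps=1),
        )
        from cellindent.postprocess import indentation_depth

        d_v = indentation_depth(states[-1], mesh)
        d_e = indentation_depth(st_el, mesh)
        assert d_v == pytest.approx(d_e, rel=0.02)

    def test_time_step_halving_changes_little(self, small_force_setup):
        """Final indentation depth moves <=0.5% when dt is halved."""
        mesh, bcs, lc = small_force_setup
        mats = default_materials(
            E_cyto=0.8, cytoplasm_model="viscoelastic", prony_mode="equilibrium"
        )
        from cellindent.postprocess import indentation_depth

        depths = []
        for dt in (0.5, 0.25):
            states = solve_viscoelastic(
                mesh,
                bcs=bcs,
                loadcase=lc,
                materials=mats,
                settings=SolverSettings(
                    ramp_time=1.0,
                    ramp_steps=int(round(1.0 / dt)),
                    hold_time=20.0,
                    dt=dt,
                    dt_growth=1.0,
                    steady_state_tol=0.0,
                ),
            )
            depths.append(indentation_depth(states[-1], mesh))
        assert abs(depths[1] - depths[0]) / depths[1] < 0.005

    def test_zero_load_all_states_zero(self, small_force_setup):
        mesh, bcs, _ = small_force_setup
        mats = default_materials(cytoplasm_model="viscoelastic")
        states = solve_viscoelastic(
            mesh,
            bcs=bcs,
            loadcase=None,
            materials=mats,
            settings=SolverSettings(ramp_time=0.0, hold_time=2.0, dt=0.5),
        )
        for st in states:
            assert np.allclose(st.u, 0.0, atol=1e-12)

    def test_elastic_material_rejected(self, small_force_setup, soft_materials):
        mesh, bcs, lc = small_force_setup
        with pytest.raises(ValueError):
            solve_viscoelastic(mesh, soft_materials, lc, bcs)
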