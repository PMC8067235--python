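"""Solver verification: closed-form fixtures, contact law, stepping."""

import numpy as np
import pytest

from probemech import fe_solver as fes
from probemech import materials as mat
from probemech import synthetic_data as sd


class TestMicromotionWaveform:
    @pytest.mark.parametrize(
        "t, expected",
        [(0.0, 0.0),
         (0.25, 11.4),
         (0.125, 11.4 * np.sin(np.pi / 4.0) + 2.0 * np.sin(np.pi))],
    )
    def test_closed_form_values(self, t, expected):
        assert fes.micromotion_displacement(t) == pytest.approx(expected,
                                                               abs=1e-12)

    def test_vectorized_and_periodic(self):
        t = np.linspace(0, 1, 101)
        v = fes.micromotion_displacement(t)
        np.testing.assert_allclose(v, fes.micromotion_displacement(t + 1.0),
                                   atol=1e-9)
        assert v.shape == t.shape

    def test_boundary_load_matches_module_function(self):
        load = fes.BoundaryLoad()
        t = np.linspace(0, 1, 17)
        np.testing.assert_allclose(load.displacement_um(t),
                                   fes.micromotion_displacement(t))


@pytest.fixture(scope="module")
def uniaxial_fixture():
    return sd.solver_fixture("single_element_uniaxial")


class TestAssembly:
    def test_zero_state_zero_residual(self, uniaxial_fixture):
        model = fes.Model(uniaxial_fixture["mesh"],
                          uniaxial_fixture["tissue"], None, None, [])
        R, K, _ = model.assemble(np.zeros(model.ndof))
        assert np.linalg.norm(R) == pytest.approx(0.0, abs=1e-12)

    def test_tangent_symmetric_without_friction(self, uniaxial_fixture):
        model = fes.Model(uniaxial_fixture["mesh"],
                          uniaxial_fixture["tissue"], None, None, [])
        rng = np.random.default_rng(1)
        u = rng.uniform(-0.03, 0.03, model.ndof)
        _, K, _ = model.assemble(u)
        K = K.toarray()
        assert np.abs(K - K.T).max() <= 1e-9 * np.abs(K).max()

    def test_tangent_consistent_with_residual(self, uniaxial_fixture):
        model = fes.Model(uniaxial_fixture["mesh"],
                          uniaxial_fixture["tissue"], None, None, [])
        rng = np.random.default_rng(2)
        u = rng.uniform(-0.03, 0.03, model.ndof)
        R, K, _ = model.assemble(u)
        K = K.toarray()
        h = 1e-7
        for i in range(0, model.ndof, 5):
            up, um = u.copy(), u.copy()
            up[i] += h
            um[i] -= h
            Rp, _, _ = model.assemble(up, need_tangent=False)
            Rm, _, _ = model.assemble(um, need_tangent=False)
            np.testing.assert_allclose(K[:, i], (Rp - Rm) / (2 * h),
                                       rtol=5e-5, atol=1e-4)

    def test_single_element_residual_matches_nominal_stress(
        self, uniaxial_fixture
    ):
        # homogeneous incompressible uniaxial state: axial nodal forces sum
        # to P(lam) x area with the lateral faces traction-free
        mesh = uniaxial_fixture["mesh"]
        tissue = uniaxial_fixture["tissue"]
        nodes = mesh.nodes
        lam = 1.06
        top = np.where(nodes[:, 2] > 0.5)[0]
        bcs = [
            fes.DirichletBC(nodes=np.where(nodes[:, 2] < 0.5)[0], comp=2),
            fes.DirichletBC(nodes=top, comp=2, coef=lam - 1.0),
            fes.DirichletBC(nodes=np.array([0]), comp=0),
            fes.DirichletBC(nodes=np.array([0]), comp=1),
            # pin the rotation about z at the (1, 0, 0) corner node
            fes.DirichletBC(nodes=np.array([4]), comp=1),
        ]
        model = fes.Model(mesh, tissue, None, None, bcs)
        u = fes.solve_static(model, n_substeps=3)
        R, _, _ = model.assemble(u, need_tangent=False)
        P_fe = R.reshape(-1, 3)[top, 2].sum()  # reference area = 1 mm^2
        P_ref = uniaxial_fixture["reference"](lam)
        assert P_fe == pytest.approx(P_ref, rel=1e-6)


class TestStaticSolutions:
    def test_zero_load_zero_displacement(self, uniaxial_fixture):
        mesh = uniaxial_fixture["mesh"]
        bcs = [fes.DirichletBC(nodes=np.arange(4), comp=c) for c in range(3)]
        model = fes.Model(mesh, uniaxial_fixture["tissue"], None, None, bcs)
        u = fes.solve_static(model)
        assert np.abs(u).max() == pytest.approx(0.0, abs=1e-12)

    def test_linear_patch_test_reproduces_uniform_strain(self):
        fx = sd.solver_fixture("patch_test")
        mesh, grad = fx["mesh"], fx["displacement_gradient"]
        nodes = mesh.nodes
        onb = np.any((np.abs(nodes) < 1e-12) | (np.abs(nodes - 1.0) < 1e-12),
                     axis=1)
        ubc = nodes @ grad.T
        bcs = [
            fes.DirichletBC(nodes=np.array([n]), comp=c, coef=float(ubc[n, c]))
            for n in np.where(onb)[0] for c in range(3)
        ]
        model = fes.Model(mesh, fx["tissue"], None, None, bcs)
        u = fes.solve_static(model)
        np.testing.assert_allclose(u.reshape(-1, 3), ubc, atol=1e-10)

    def test_two_material_bar_series_compliance(self):
        fx = sd.solver_fixture("two_material_bar")
        mesh = fx["mesh"]
        nodes = mesh.nodes
        delta = 1e-4  # small strain so the series-spring formula applies
        right = np.where(np.abs(nodes[:, 0] - 2.0) < 1e-12)[0]
        left = np.where(np.abs(nodes[:, 0]) < 1e-12)[0]
        bcs = [
            fes.DirichletBC(nodes=left, comp=0),
            fes.DirichletBC(nodes=right, comp=0, coef=delta),
            fes.DirichletBC(nodes=left, comp=1),
            fes.DirichletBC(nodes=left, comp=2),
        ]
        model = fes.Model(mesh, fx["tissue"], fx["probe"], None, bcs)
        u = fes.solve_static(model)
        mid = np.where(np.abs(nodes[:, 0] - 1.0) < 1e-12)[0]
        frac = u.reshape(-1, 3)[mid, 0] / delta
        expected = fx["reference"]["interface_fraction"]
        np.testing.assert_allclose(frac, expected, rtol=1e-4)


def _friction_block_model(cof, **contact_kw):
    fx = sd.solver_fixture("friction_block")
    mesh = fx["mesh"]
    top = np.where(np.abs(mesh.nodes[:, 2] - 1.0) < 1e-12)[0]
    top = top[top < 8]
    slab = np.arange(8, 16)
    bcs = (
        [fes.DirichletBC(nodes=slab, comp=c) for c in range(3)]
        + [fes.DirichletBC(nodes=top, comp=2, coef=-1e-3),
           fes.DirichletBC(nodes=top, comp=0, coef=5e-3,
                           waveform=lambda t: t),
           fes.DirichletBC(nodes=top, comp=1)]
    )
    model = fes.Model(mesh, fx["tissue"], fx["probe"],
                      fes.ContactPair(cof=cof, **contact_kw), bcs)
    return model, top


class TestCoulombContact:
    def test_separated_surfaces_carry_no_traction(self):
        model, _ = _friction_block_model(0.4)
        cs = fes._ContactState(len(model.contact.ti))
        u = np.zeros(model.ndof)
        u.reshape(-1, 3)[:8, 2] = 0.1  # lift the block off the slab
        _, _, status = model.contact.evaluate(u, cs)
        assert not status["active"].any()
        assert np.abs(status["traction"]).max() < 1e-9
        # the smoothed unilateral law leaves only a vanishing far-field tail
        assert status["pressure_force"].max() < 1e-3

    @pytest.mark.parametrize("cof", [0.0, 0.2, 0.4])
    def test_slip_force_ratio_equals_cof(self, cof):
        model, top = _friction_block_model(cof)
        cfg = fes.SimulationConfig(total_time=1.0, dt_initial=0.05,
                                   dt_min=1e-3, dt_max=0.1)
        hist = fes.solve_transient(model, cfg)
        u = hist.displacements[-1].astype(float).ravel()
        R, _, _ = model.assemble(u, need_tangent=False)
        Rt = R.reshape(-1, 3)[top]
        fx, fn = Rt[:, 0].sum(), -Rt[:, 2].sum()
        assert fn > 0
        assert fx / fn == pytest.approx(cof, abs=2e-3)

    def test_transient_is_deterministic(self):
        cfg = fes.SimulationConfig(total_time=0.5, dt_initial=0.05,
                                   dt_min=1e-3, dt_max=0.1)
        runs = []
        for _ in range(2):
            model, _ = _friction_block_model(0.3)
            runs.append(fes.solve_transient(model, cfg))
        np.testing.assert_array_equal(runs[0].displacements,
                                      runs[1].displacements)
        assert runs[0].convergence == runs[1].convergence

    def test_periodic_drive_repeats_over_second_cycle(self):
        # scaled-down analogue of the scenario periodicity check: a block
        # sheared by one- plus four-cycle sinusoids repeats its reaction
        # trace in the second period
        fx = sd.solver_fixture("friction_block")
        mesh = fx["mesh"]
        top = np.where(np.abs(mesh.nodes[:, 2] - 1.0) < 1e-12)[0]
        top = top[top < 8]
        slab = np.arange(8, 16)

        def wave(t):
            return 2e-3 * np.sin(2 * np.pi * t) + 4e-4 * np.sin(8 * np.pi * t)

        bcs = (
            [fes.DirichletBC(nodes=slab, comp=c) for c in range(3)]
            + [fes.DirichletBC(nodes=top, comp=2, coef=-1e-3),
               fes.DirichletBC(nodes=top, comp=0, coef=1.0, waveform=wave),
               fes.DirichletBC(nodes=top, comp=1)]
        )
        model = fes.Model(mesh, fx["tissue"], fx["probe"],
                          fes.ContactPair(cof=0.3), bcs)
        cfg = fes.SimulationConfig(total_time=2.0, dt_initial=0.02,
                                   dt_min=1e-3, dt_max=0.02)
        hist = fes.solve_transient(model, cfg)
        t = hist.times
        ux = hist.displacements[:, 4, 0].astype(float)  # a bottom block node
        # skip the initial stick-slip transient; compare settled cycles
        grid = np.linspace(0.1, 1.0, 24)
        first = np.interp(grid, t, ux)
        second = np.interp(grid + 1.0, t, ux)
        np.testing.assert_allclose(second, first,
                                   atol=0.02 * np.abs(first).max())


class TestEnergyAndDynamics:
    def test_external_work_balances_strain_energy_frictionless(self):
        # quasi-static, contact-free shear of a tissue block: the work done
        # by the prescribed boundary equals the stored hyperelastic energy
        mesh = sd.box_mesh(2, 2, 2)
        tissue = mat.material_lookup("brain_tissue")
        nodes = mesh.nodes
        top = np.where(np.abs(nodes[:, 2] - 1.0) < 1e-12)[0]
        bot = np.where(np.abs(nodes[:, 2]) < 1e-12)[0]
        bcs = (
            [fes.DirichletBC(nodes=bot, comp=c) for c in range(3)]
            + [fes.DirichletBC(nodes=top, comp=0, coef=0.08,
                               waveform=lambda t: t),
               fes.DirichletBC(nodes=top, comp=1),
               fes.DirichletBC(nodes=top, comp=2)]
        )
        model = fes.Model(mesh, tissue, None, None, bcs)
        cfg = fes.SimulationConfig(total_time=1.0, dt_initial=0.05,
                                   dt_min=1e-3, dt_max=0.05)
        hist = fes.solve_transient(model, cfg)
        W_ext = hist.external_work[-1]
        W_int = hist.strain_energy[-1]
        assert W_ext == pytest.approx(W_int, rel=0.01)

    def test_zero_load_hht_trajectory_is_zero(self):
        mesh = sd.box_mesh(1, 1, 1)
        tissue = mat.material_lookup("brain_tissue")
        bcs = [fes.DirichletBC(nodes=np.arange(4), comp=c) for c in range(3)]
        model = fes.Model(mesh, tissue, None, None, bcs)
        cfg = fes.SimulationConfig(total_time=0.05, dt_initial=0.01,
                                   dt_min=1e-3, dt_max=0.01,
                                   quasi_static=False)
        hist = fes.solve_transient(model, cfg)
        assert np.abs(hist.displacements).max() == 0.0
        assert hist.times[-1] == pytest.approx(0.05)

    def test_adaptive_steps_respect_bounds_and_convergence_log(self):
        model, _ = _friction_block_model(0.3)
        cfg = fes.SimulationConfig(total_time=0.3, dt_initial=0.05,
                                   dt_min=1e-3, dt_max=0.1)
        hist = fes.solve_transient(model, cfg)
        assert np.all(np.diff(hist.times) > 0)
        assert hist.times[-1] == pytest.approx(0.3)
        for t, dt, iters in hist.convergence:
            assert 1e-3 - 1e-12 <= dt <= 0.1 + 1e-12
            assert iters >= 1


class TestBoundaryConditions:
    def test_micromotion_bcs_cover_faces_and_probe_top(self):
        from probemech import geometry as geo

        spec = geo.DomainSpec()
        sec = geo.build_cross_section("ellipse")
        mesh = geo.generate_domain_mesh(spec, sec, **geo.mesh_preset("tiny"))
        bcs = fes.build_micromotion_bcs(mesh, spec, fes.BoundaryLoad())
        # probe-top clamp (3 comps) + five loaded faces
        assert len(bcs) == 8
        t = 0.33
        val = 1e-3 * fes.micromotion_displacement(t)
        for bc in bcs[3:]:
            assert bc.value(t) == pytest.approx(val)
        for bc in bcs[:3]:
            assert bc.value(t) == 0.0

    def test_squeeze_mode_moves_opposite_faces_inward(self):
        from probemech import geometry as geo

        spec = geo.DomainSpec()
        sec = geo.build_cross_section("ellipse")
        mesh = geo.generate_domain_mesh(spec, sec, **geo.mesh_preset("tiny"))
        load = fes.BoundaryLoad(mode="squeeze", faces=("x-", "x+"))
        bcs = fes.build_micromotion_bcs(mesh, spec, load)
        coefs = {}
        for bc in bcs[3:]:
            side = np.sign(mesh.nodes[bc.nodes[0], 0])
            coefs[side] = bc.coef
        assert coefs[1.0] == -1.0 and coefs[-1.0] == 1.0


class TestFieldSymmetry:
    def test_squeeze_load_strain_field_has_quarter_symmetry(self):
        # circular probe + in-phase inward-normal (squeeze) load: the
        # problem is invariant under 90-degree rotation, so the nodal
        # equivalent-strain field must map onto itself
        from scipy.spatial import cKDTree

        from probemech import geometry as geo
        from probemech import postprocess as post

        spec = geo.DomainSpec()
        sec = geo.build_cross_section("ellipse")
        mesh = geo.generate_domain_mesh(spec, sec, **geo.mesh_preset("tiny"))
        tissue = mat.material_lookup("brain_tissue")
        probe = mat.material_lookup("hydrogel")
        load = fes.BoundaryLoad(mode="squeeze",
                                faces=("x-", "x+", "y-", "y+"))
        bcs = fes.build_micromotion_bcs(mesh, spec, load)
        # pin the tissue bottom axially (the squeeze load itself leaves the
        # z rigid mode held only by friction); preserves quarter symmetry
        bottom = np.unique(mesh.facet_sets["tissue_bottom"])
        bcs.append(fes.DirichletBC(nodes=bottom, comp=2))
        model = fes.Model(mesh, tissue, probe, fes.ContactPair(cof=0.3), bcs)
        cfg = fes.SimulationConfig(total_time=0.01, newton_rtol=1e-6)
        hist = fes.solve_transient(model, cfg)
        u = hist.displacements[-1].astype(float).ravel()
        eq = post.equivalent_strain(model.nodal_log_strain(u))
        rot = np.column_stack([-mesh.nodes[:, 1], mesh.nodes[:, 0],
                               mesh.nodes[:, 2]])
        # probe and tissue nodes coincide pairwise on the interface, so map
        # bodies separately
        for body in (0, 1):
            ids = np.unique(mesh.hexes[mesh.region == body])
            d, j = cKDTree(mesh.nodes[ids]).query(rot[ids])
            assert d.max() < 1e-9
            np.testing.assert_allclose(eq[ids], eq[ids][j], atol=2e-6)
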