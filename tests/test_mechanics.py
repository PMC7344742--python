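import numpy as np
import pytest

from osseoheal import (
    FeModel,
    LoadSpec,
    make_consolidation_column,
    make_patch_bar,
    octahedral_shear_strain,
    solve_elastic,
    solve_poroelastic_step,
)
from osseoheal.mechanics import SolverError, _Assembly, element_fluid_speed

from conftest import run_terzaghi


class TestOctahedralShearStrain:
    def test_hydrostatic_strain_has_no_shear(self):
        e = 1e-3
        assert octahedral_shear_strain(np.diag([e, e, e])) == pytest.approx(0.0, abs=1e-18)

    @pytest.mark.parametrize(
        "principal, expected_factor",
        [((1.0, 0.0, 0.0), 2 * np.sqrt(2) / 3), ((1.0, 0.0, -1.0), 2 / 3 * np.sqrt(6))],
    )
    def test_principal_strain_formulas(self, principal, expected_factor):
        e = 2.5e-3
        tensor = np.diag([p * e for p in principal])
        assert octahedral_shear_strain(tensor) == pytest.approx(expected_factor * e)

    def test_rotation_of_tensor_basis_is_irrelevant(self):
        rng = np.random.default_rng(7)
        t = rng.normal(size=(3, 3)) * 1e-3
        t = (t + t.T) / 2
        th = 0.7
        r = np.array([[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        assert octahedral_shear_strain(r @ t @ r.T) == pytest.approx(octahedral_shear_strain(t))

    def test_asymmetric_tensor_rejected(self):
        with pytest.raises(ValueError):
            octahedral_shear_strain(np.array([[0, 1e-3, 0], [0, 0, 0], [0, 0, 0]]))


class TestFluidSpeed:
    def test_zero_flux(self):
        assert element_fluid_speed([0.0, 0.0]) == 0.0

    def test_three_four_five(self):
        assert element_fluid_speed([3e-6, 4e-6]) == pytest.approx(5.0)

    def test_darcy_linearity_in_permeability(self):
        # halving permeability under an identical pressure gradient halves the flux
        bar = make_patch_bar(young_modulus=0.001, permeability=1e-14, as_callus=True)
        p = 1e4 * bar.nodes[:, 0] * 1e-3  # linear pressure field, Pa
        q1 = _Assembly(bar).darcy_flux(p)
        bar.permeability[:] = 0.5e-14
        q2 = _Assembly(bar).darcy_flux(p)
        assert np.allclose(q2, 0.5 * q1, rtol=1e-12)
        assert np.allclose(np.linalg.norm(q1, axis=1) * 1e6, 1e4 * 1e-14 * 1e6)


class TestElasticSolver:
    def test_patch_uniform_strain(self):
        length, delta_um = 10.0, 10.0
        bar = make_patch_bar(length=length, nx=10, ny=2)
        fld = solve_elastic(bar, LoadSpec(magnitude=delta_um, direction=(1, 0)))
        expected = delta_um * 1e-6 / (length * 1e-3)
        assert np.allclose(fld.strain[:, 0], expected, rtol=1e-12)
        assert np.allclose(fld.strain[:, 2], 0.0, atol=1e-15)

    def test_triangle_patch_uniform_strain(self):
        bar = make_patch_bar(length=4.0, nx=4, ny=1)
        # split each quad into two triangles, preserving region/state
        rows = []
        for e in range(bar.n_elements):
            a, b, c, d = bar.conn[e]
            rows += [[a, b, c, -1], [a, c, d, -1]]
        tri = FeModel(bar.nodes, np.array(rows), np.repeat(bar.region, 2), bar.node_sets)
        tri.young_modulus[:] = 1.0
        tri.poisson_ratio[:] = 0.3
        fld = solve_elastic(tri, LoadSpec(magnitude=4.0, direction=(1, 0)))
        assert np.allclose(fld.strain[:, 0], 1e-3, rtol=1e-12)

    def test_rigid_translation_stores_no_energy(self):
        bar = make_patch_bar()
        bar.node_sets = {"load": np.arange(bar.n_nodes), "fixed": np.zeros(0, int)}
        fld = solve_elastic(bar, LoadSpec(magnitude=5.0, direction=(1.0, 1.0)))
        assert np.allclose(fld.sed, 0.0, atol=1e-12)
        assert np.allclose(fld.gamma, 0.0, atol=1e-15)

    def test_single_element_constant_strain_from_linear_field(self):
        # impose a linear displacement field directly; the centroid strain
        # operator must return the exact constant strain tensor
        bar = make_patch_bar(length=1.0, height=1.0, nx=1, ny=1)
        asm = _Assembly(bar)
        exx, eyy, gxy = 2e-3, -1e-3, 5e-4
        xy = bar.nodes * 1e-3
        u = np.zeros((bar.n_nodes, 2))
        u[:, 0] = exx * xy[:, 0] + gxy * xy[:, 1]
        u[:, 1] = eyy * xy[:, 1]
        strain = asm.strains(u.ravel())
        assert strain[0] == pytest.approx([exx, eyy, gxy], rel=1e-12)

    def test_energy_identity_work_equals_stored_energy(self):
        bar = make_patch_bar(length=8.0, height=2.0, nx=8, ny=2)
        fld = solve_elastic(bar, LoadSpec(magnitude=20.0, direction=(1, 0)))
        stored = fld.total_strain_energy(bar.areas())
        loaded = bar.node_sets["load"]
        work = 0.5 * float(np.sum(fld.reactions[loaded] * fld.displacement[loaded]))
        assert stored == pytest.approx(work, rel=1e-8)

    def test_gamma_invariant_under_rigid_rotation(self):
        def solve_rotated(phi):
            bar = make_patch_bar(length=6.0, height=2.0, nx=6, ny=2)
            x = bar.nodes[:, 0]
            bar.node_sets = {
                "fixed": np.flatnonzero(np.abs(x) < 1e-12),
                "load": np.flatnonzero(np.abs(x - 6.0) < 1e-12),
            }
            c, s = np.cos(phi), np.sin(phi)
            rot = np.array([[c, -s], [s, c]])
            bar.nodes = bar.nodes @ rot.T
            fld = solve_elastic(
                bar,
                LoadSpec(mode="force", magnitude=5.0, direction=tuple(rot @ [1.0, 0.3])),
            )
            return fld.gamma

        g0 = solve_rotated(0.0)
        g30 = solve_rotated(np.deg2rad(30))
        assert np.allclose(g30, g0, rtol=1e-9, atol=1e-15)

    def test_unconstrained_system_names_rigid_mode(self):
        bar = make_patch_bar()
        bar.node_sets = {"load": bar.node_sets["load"], "fixed": np.zeros(0, int)}
        with pytest.raises(SolverError, match="rigid-body"):
            solve_elastic(bar, LoadSpec(mode="force", magnitude=1.0, direction=(1, 0)))


class TestPoroelasticSolver:
    def test_terzaghi_matches_series_solution(self):
        for num, ana in run_terzaghi(40, (0.1,)):
            assert num == pytest.approx(ana, rel=0.02)

    def test_terzaghi_error_decreases_under_refinement(self):
        (c_num, c_ana), = run_terzaghi(40, (0.5,))
        (f_num, f_ana), = run_terzaghi(80, (0.5,), n_steps=120)
        assert abs(f_num - f_ana) < abs(c_num - c_ana)

    def test_drained_limit_recovers_elastic_solution(self):
        bar = make_patch_bar(young_modulus=0.001, permeability=1.0, as_callus=True)
        bar.node_sets["drainage"] = np.arange(bar.n_nodes)
        load = LoadSpec(magnitude=5.0, direction=(1, 0), load_duration=1.0)
        poro = solve_poroelastic_step(bar, load)
        elastic = solve_elastic(bar, load)
        assert np.allclose(poro.gamma, elastic.gamma, rtol=1e-6)
        assert np.allclose(poro.pressure, 0.0, atol=1e-6 * abs(elastic.sed).max())

    def test_zero_load_gives_zero_fields(self):
        bar = make_patch_bar(young_modulus=0.001, permeability=1e-14, as_callus=True)
        fld = solve_poroelastic_step(bar, LoadSpec(magnitude=0.0, direction=(1, 0)))
        assert np.allclose(fld.gamma, 0.0, atol=1e-18)
        assert np.allclose(fld.fluid_speed, 0.0, atol=1e-18)
        assert np.allclose(fld.sed, 0.0, atol=1e-18)

    def test_nonpositive_time_step_rejected(self):
        bar = make_patch_bar(young_modulus=0.001, permeability=1e-14, as_callus=True)
        with pytest.raises(ValueError, match="time step"):
            solve_poroelastic_step(bar, LoadSpec(magnitude=1.0), dt=0.0)

    def test_uniform_undrained_state_has_no_flow(self):
        # uniform strain -> uniform pore pressure -> zero Darcy flux
        bar = make_patch_bar(young_modulus=0.001, permeability=1e-14, as_callus=True)
        fld = solve_poroelastic_step(bar, LoadSpec(magnitude=5.0, direction=(1, 0), load_duration=100.0))
        assert fld.fluid_speed.max() < 1e-9
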