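import numpy as np
import pytest

from osseoheal import (
    AttractorField,
    LoadSpec,
    RemodelingParams,
    attractor_from_reference,
    average_stimulus,
    density_to_modulus,
    handoff_from_short_term,
    make_patch_bar,
    modulus_to_density,
    remodeling_stimulus,
    run_remodeling,
    solve_elastic,
    summary_metrics,
    update_density,
)


class TestStimulus:
    def test_unit_conversion(self):
        # 1000 J/m^3 over 0.2 g/cm^3 (= 200 kg/m^3) -> 5 J/kg
        assert remodeling_stimulus(1000.0, 0.2) == pytest.approx(5.0)

    def test_zero_energy_gives_zero(self):
        assert remodeling_stimulus(0.0, 1.2) == 0.0

    def test_linearity_in_energy(self):
        assert remodeling_stimulus(2000.0, 0.7) == pytest.approx(2 * remodeling_stimulus(1000.0, 0.7))

    def test_density_below_floor_rejected(self):
        with pytest.raises(ValueError):
            remodeling_stimulus(100.0, 0.001, density_floor=0.01)


class TestCarterHayes:
    def test_unit_density(self):
        assert density_to_modulus(1.0) == pytest.approx(3.79)

    def test_zero_density(self):
        assert density_to_modulus(0.0) == 0.0

    @pytest.mark.parametrize("rho", [0.1, 0.8, 1.5])
    def test_inverse_round_trip(self, rho):
        assert modulus_to_density(density_to_modulus(rho)) == pytest.approx(rho, rel=1e-12)

    def test_cortical_density_is_physical(self):
        # cortical bone at 13.7 GPa maps to ~1.53 g/cm^3
        assert modulus_to_density(13.7) == pytest.approx(1.533, abs=2e-3)


class TestDensityUpdate:
    p = RemodelingParams()

    def test_lazy_zone_is_neutral(self):
        for s in (1.3, 3.0, 5.0, 8.74):  # inside ((1-s)K, (1+s)K] = (1.25, 8.75] for K=5
            assert update_density(1.0, s, 5.0, self.p) == 1.0

    def test_zero_increment_at_zone_boundaries(self):
        assert update_density(1.0, 8.75, 5.0, self.p) == pytest.approx(1.0)  # (1+s)K
        assert update_density(1.0, 1.25, 5.0, self.p) == pytest.approx(1.0)  # (1-s)K

    def test_formation_increment_quadratic(self):
        # S = (1+s)K + 10 -> drho = Af_dt * 10^2 = 1e-9
        rho1 = update_density(1.0, 18.75, 5.0, self.p)
        assert rho1 - 1.0 == pytest.approx(1e-9, rel=1e-9)

    def test_resorption_increment_cubic_and_negative(self):
        # S - (1-s)K = -10 -> drho = Ar_dt * (-10)^3 = -1e-8
        k, s_val = 5.0, 1.25 - 10.0
        rho1 = update_density(1.0, max(s_val, 0) if s_val > 0 else 0.0, k, self.p)
        # stimulus cannot be negative physically; construct via larger K instead
        k2 = (10.0 + 0.0) / (1 - self.p.lazy_zone_halfwidth)  # (1-s)K2 = 10, S=0
        rho2 = update_density(1.0, 0.0, k2, self.p)
        assert rho2 - 1.0 == pytest.approx(-1e-8, rel=1e-9)

    def test_continuity_across_branches(self):
        eps = 1e-9
        for bound in (1.25, 8.75):
            lo = update_density(1.0, bound - eps, 5.0, self.p)
            hi = update_density(1.0, bound + eps, 5.0, self.p)
            assert lo == pytest.approx(hi, abs=1e-15)

    def test_sign_correctness(self):
        rng = np.random.default_rng(3)
        s = rng.uniform(0, 20, 500)
        rho = update_density(np.full(500, 1.0), s, np.full(500, 5.0), self.p)
        assert np.all(rho[s >= 8.75] >= 1.0)
        assert np.all(rho[s <= 1.25] <= 1.0)
        inside = (s > 1.25) & (s <= 8.75)
        assert np.all(rho[inside] == 1.0)

    @pytest.mark.parametrize("d", [1.0, 10.0])
    def test_resorption_faster_than_formation_ratio(self, d):
        p = self.p
        form = update_density(1.0, 8.75 + d, 5.0, p) - 1.0
        k2 = d / (1 - p.lazy_zone_halfwidth)  # put S=0 a distance d below the zone
        res = 1.0 - update_density(1.0, 0.0, k2, p)
        assert res / form == pytest.approx(d * p.ar_dt / p.af_dt, rel=1e-6)

    def test_clamping_to_floor_and_ceiling(self):
        p = RemodelingParams(ar_dt=1.0, af_dt=1.0)
        assert update_density(0.02, 0.0, 40.0, p) == p.density_floor
        assert update_density(1.7, 100.0, 5.0, p) == p.density_ceiling

    def test_nan_attractor_leaves_density_unchanged(self):
        assert update_density(0.9, 50.0, np.nan, self.p) == 0.9


class TestAverageStimulus:
    def test_mean(self):
        assert average_stimulus([4.0, 6.0]) == 5.0
        assert average_stimulus([5.0]) == 5.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            average_stimulus([])


class TestHandoff:
    def test_mature_bone_modulus_maps_to_density(self):
        bar = make_patch_bar(young_modulus=6.0, as_callus=True)
        seeded = handoff_from_short_term(bar)
        expected = (6.0 / 3.79) ** (1 / 3)
        assert np.allclose(seeded.apparent_density, expected)
        assert expected == pytest.approx(1.165, abs=1e-3)

    def test_soft_tissue_density_from_inverse_law(self):
        bar = make_patch_bar(young_modulus=0.001, as_callus=True)
        seeded = handoff_from_short_term(bar)
        assert np.allclose(seeded.apparent_density, (0.001 / 3.79) ** (1 / 3))

    def test_density_clamped_at_floor(self):
        bar = make_patch_bar(young_modulus=0.001, as_callus=True)
        params = RemodelingParams(density_floor=0.1)
        seeded = handoff_from_short_term(bar, params)
        assert np.allclose(seeded.apparent_density, 0.1)

    def test_conventional_uniform_callus(self):
        bar = make_patch_bar(young_modulus=2.0, as_callus=True)
        seeded = handoff_from_short_term(bar)
        assert np.allclose(seeded.apparent_density, (2.0 / 3.79) ** (1 / 3))

    def test_phenotype_labels_retained(self):
        bar = make_patch_bar(young_modulus=6.0, as_callus=True)
        bar.phenotype[:] = "mature_bone"
        assert set(handoff_from_short_term(bar).phenotype) == {"mature_bone"}


class TestAttractor:
    def test_all_socket_toy_gets_constant_callus_attractor(self):
        target = make_patch_bar(young_modulus=2.0, as_callus=True)
        reference = make_patch_bar(young_modulus=2.0, as_callus=False)
        fld = solve_elastic(reference, LoadSpec(magnitude=1.0, direction=(1, 0)))
        k = attractor_from_reference(reference, fld, target)
        assert np.allclose(k.values[target.region == "callus"], 5.0)

    def test_uniform_reference_gives_uniform_bone_attractor(self):
        target = make_patch_bar(young_modulus=2.0)  # cancellous everywhere
        reference = make_patch_bar(young_modulus=2.0)
        fld = solve_elastic(reference, LoadSpec(magnitude=1.0, direction=(1, 0)))
        k = attractor_from_reference(reference, fld, target)
        vals = k.values[np.isfinite(k.values)]
        assert len(vals) == target.n_elements
        assert np.allclose(vals, vals[0], rtol=1e-9)

    def test_elementwise_two_value_pattern(self):
        u = np.array([1000.0, 4000.0, 1000.0, 4000.0])
        rho = np.array([0.5, 0.5, 1.0, 1.0])
        s = remodeling_stimulus(u, rho)
        assert s == pytest.approx([2.0, 8.0, 1.0, 4.0])

    def test_mesh_mismatch_rejected(self):
        target = make_patch_bar(nx=10)
        reference = make_patch_bar(nx=9)
        fld = solve_elastic(reference, LoadSpec(magnitude=1.0, direction=(1, 0)))
        with pytest.raises(ValueError):
            attractor_from_reference(reference, fld, target)


def _loaded_bar(e_gpa=2.0):
    bar = make_patch_bar(length=4.0, height=2.0, nx=4, ny=2, young_modulus=e_gpa, as_callus=True)
    load = LoadSpec(magnitude=2.0, direction=(1, 0))
    return bar, load


class TestRemodelingLoop:
    def test_fixed_point_when_attractor_equals_own_stimulus(self):
        bar, load = _loaded_bar()
        seeded = handoff_from_short_term(bar)
        fld = solve_elastic(seeded, load)
        k = AttractorField(remodeling_stimulus(fld.sed, seeded.apparent_density))
        rho0 = seeded.apparent_density.copy()
        params = RemodelingParams(max_iterations=20, save_tolerance=0.0)
        hist = run_remodeling(seeded, k, params, load)
        assert hist.iterations == 20
        assert np.array_equal(seeded.apparent_density, rho0)
        assert np.allclose(hist.save_series, hist.save_series[0])

    def test_stimulus_below_zone_resorbs_to_floor(self):
        bar, load = _loaded_bar()
        seeded = handoff_from_short_term(bar)
        fld = solve_elastic(seeded, load)
        s0 = remodeling_stimulus(fld.sed, seeded.apparent_density)
        k = AttractorField(np.full(bar.n_elements, s0.max() * 100.0))  # far above -> resorb
        params = RemodelingParams(ar_dt=1e-4, max_iterations=60, save_tolerance=0.0)
        rho_series = [seeded.apparent_density.copy()]
        hist = run_remodeling(seeded, k, params, load)
        assert np.allclose(seeded.apparent_density, params.density_floor)
        assert seeded.resorbed_flag.all()
        metrics = summary_metrics(seeded, params)
        assert metrics["resorption_volume_fraction"] == pytest.approx(100.0)

    def test_single_element_recurrence_matches_hand_iteration(self):
        # uniform bar in uniform strain == single-element recurrence
        bar, load = _loaded_bar()
        seeded = handoff_from_short_term(bar)
        k_val, ar = 50.0, 1e-5
        params = RemodelingParams(ar_dt=ar, max_iterations=5, save_tolerance=0.0)
        k = AttractorField(np.full(bar.n_elements, k_val))
        # hand-iterate one element: strain is load-controlled and uniform
        fld = solve_elastic(seeded, load)
        u_per_e = fld.sed[0] / seeded.young_modulus[0]  # SED scales linearly with E
        rho = seeded.apparent_density[0]
        for _ in range(5):
            e_gpa = 3.79 * rho**3
            s = (u_per_e * e_gpa) / (1000.0 * rho)
            rho = max(rho + ar * (s - (1 - 0.75) * k_val) ** 3, params.density_floor) if s <= (1 - 0.75) * k_val else rho
        run_remodeling(seeded, k, params, load)
        assert seeded.apparent_density[0] == pytest.approx(rho, rel=1e-9)

    def test_modulus_density_consistency_after_every_iteration(self):
        bar, load = _loaded_bar()
        seeded = handoff_from_short_term(bar)
        fld = solve_elastic(seeded, load)
        k = AttractorField(remodeling_stimulus(fld.sed, seeded.apparent_density) * 0.3)
        params = RemodelingParams(af_dt=1e-4, max_iterations=10, save_tolerance=0.0)
        run_remodeling(seeded, k, params, load)
        assert np.allclose(
            seeded.young_modulus, 3.79 * seeded.apparent_density**3, rtol=1e-12
        )


class TestSummaryMetrics:
    def test_no_flagged_elements(self):
        bar, _ = _loaded_bar()
        m = summary_metrics(handoff_from_short_term(bar))
        assert m["resorption_volume_fraction"] == 0.0

    def test_one_percent_flagged(self):
        bar = make_patch_bar(length=10.0, height=1.0, nx=100, ny=1, young_modulus=2.0, as_callus=True)
        seeded = handoff_from_short_term(bar)
        seeded.resorbed_flag[0] = True
        m = summary_metrics(seeded)
        assert m["resorption_volume_fraction"] == pytest.approx(1.0)

    def test_full_contact_when_interface_is_stiff(self, toy_implant_model):
        m = toy_implant_model
        m.young_modulus[m.region == "callus"] = 6.0
        metrics = summary_metrics(m)
        assert metrics["contact_fraction"] == pytest.approx(100.0)

    def test_area_weighted_average_modulus(self):
        bar, _ = _loaded_bar(e_gpa=4.0)
        assert summary_metrics(bar)["average_modulus"] == pytest.approx(4.0)
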