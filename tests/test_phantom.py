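"""Phantom simulator: voxelized truth, growth kinetics, cohort generation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ssngrowth import (GrowthKinetics, PhantomSpec, generate_cohort, mass_mg,
                       render_phantom, simulate_trajectory)


def lattice_sphere_volume(radius, spacing):
    """Independent oracle: count lattice cell centres inside the sphere."""
    n = int(np.ceil(radius / spacing)) + 2
    ax = np.arange(-n, n + 1) * spacing
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    return np.sum(zz**2 + yy**2 + xx**2 <= radius**2) * spacing**3


class TestRenderPhantom:
    def test_sphere_volume_close_to_analytic(self, sphere_spec, sphere_phantom):
        _, _, truth = sphere_phantom
        analytic = 4.0 / 3.0 * np.pi * 5.0**3
        assert truth.volume == pytest.approx(analytic, rel=0.05)
        # voxelized truth equals the lattice-counting oracle exactly
        assert truth.volume == pytest.approx(
            lattice_sphere_volume(5.0, 1.0), abs=1e-9)

    def test_air_density_nodule_has_zero_mass(self):
        spec = PhantomSpec(nodule_mean_hu=-1000.0, background_hu=-1000.0,
                           background_noise_sd=0.0, edge_softness=0.0,
                           nodule_radii=(5.0, 5.0, 5.0))
        _, _, truth = render_phantom(spec)
        assert truth.mass == 0.0

    def test_same_seed_is_deterministic(self, sphere_spec):
        noisy = sphere_spec.with_(background_noise_sd=25.0)
        g1, m1, _ = render_phantom(noisy)
        g2, m2, _ = render_phantom(noisy)
        np.testing.assert_array_equal(g1.values, g2.values)
        np.testing.assert_array_equal(m1.values, m2.values)

    def test_out_of_bounds_error_names_axis(self):
        spec = PhantomSpec(voi_shape=(20, 48, 48),
                           nodule_center=(2.0, 24.0, 24.0),
                           nodule_radii=(8.0, 8.0, 8.0))
        with pytest.raises(ValueError, match="axis 'z'"):
            render_phantom(spec)

    def test_diameter_window_enforced(self):
        with pytest.raises(ValueError, match="5-30 mm"):
            PhantomSpec(nodule_radii=(2.0, 2.0, 2.0))
        with pytest.raises(ValueError, match="5-30 mm"):
            PhantomSpec(nodule_radii=(16.0, 16.0, 16.0),
                        voi_shape=(64, 64, 64),
                        nodule_center=(32.0, 32.0, 32.0))

    @settings(max_examples=25, deadline=None)
    @given(hu=st.floats(-840, -400), r=st.floats(2.5, 8.0),
           soft=st.floats(0.0, 0.8))
    def test_mass_identity_machine_precision(self, hu, r, soft):
        spec = PhantomSpec(nodule_mean_hu=hu, nodule_radii=(r, r, r),
                           edge_softness=soft, background_noise_sd=0.0,
                           seed=1)
        _, _, truth = render_phantom(spec)
        assert truth.mass == truth.volume * (truth.mean_hu + 1000.0) / 1000.0


class TestSimulateTrajectory:
    def test_no_growth_keeps_truth_constant(self, sphere_spec):
        kin = GrowthKinetics(1.0, 0.0, (365.0, 365.0))
        exams = simulate_trajectory(sphere_spec, kin)
        t0 = exams[0][2]
        for _, _, t in exams[1:]:
            assert t.volume == t0.volume
            assert t.mass == pytest.approx(t0.mass)
            assert t.annualized_mass_rate == pytest.approx(0.0, abs=1e-12)
            assert t.growth_label is False

    def test_cube_root_scale_doubles_volume_and_mass(self, sphere_spec):
        kin = GrowthKinetics(2.0 ** (1.0 / 3.0), 0.0, (365.0,))
        exams = simulate_trajectory(sphere_spec, kin)
        a, b = exams[0][2], exams[1][2]
        assert b.analytic_volume == pytest.approx(2 * a.analytic_volume)
        assert b.analytic_mass == pytest.approx(2 * a.analytic_mass)
        # voxelized volume follows within discretization error
        assert b.volume == pytest.approx(2 * a.volume, rel=0.05)

    def test_closed_form_mass_ratio(self):
        # 5%/yr radius growth plus +40 HU/yr from -650 HU
        spec = PhantomSpec(nodule_radii=(6.0, 6.0, 6.0),
                           nodule_mean_hu=-650.0, background_noise_sd=0.0,
                           edge_softness=0.0, seed=3)
        kin = GrowthKinetics(1.05, 40.0, (365.0,))
        exams = simulate_trajectory(spec, kin)
        expected = 1.05**3 * (-650.0 + 40.0 + 1000.0) / (-650.0 + 1000.0)
        a, b = exams[0][2], exams[1][2]
        assert b.analytic_mass / a.analytic_mass == pytest.approx(expected)
        assert b.mass / a.mass == pytest.approx(expected, rel=0.05)

    def test_offset_is_recorded_in_truth_center(self, sphere_spec):
        kin = GrowthKinetics(1.0, 0.0, (365.0,), offset_sd_mm=2.0)
        exams = simulate_trajectory(sphere_spec, kin)
        c0 = np.asarray(exams[0][2].center)
        c1 = np.asarray(exams[1][2].center)
        assert not np.allclose(c0, c1)


class TestGenerateCohort:
    def test_stratified_counts_exact(self):
        samples, manifest = generate_cohort(40, growth_fraction=0.5, seed=5,
                                            noise_sd=0.0)
        assert manifest["growth_label"].sum() == 20

    def test_labels_consistent_with_rule(self):
        samples, manifest = generate_cohort(30, growth_fraction=0.5, seed=2)
        for _, row in manifest.iterrows():
            assert row["growth_label"] == (row["y_true"] >= 0.25)

    def test_same_seed_identical_manifest(self):
        _, m1 = generate_cohort(15, 0.4, seed=9)
        _, m2 = generate_cohort(15, 0.4, seed=9)
        assert m1.equals(m2)

    def test_manifest_roundtrip_via_files(self, tmp_path):
        _, m = generate_cohort(3, 0.34, seed=1, out_dir=tmp_path)
        assert (tmp_path / "manifest.csv").exists()
        from ssngrowth import load_nifti
        first = m.iloc[0]["files"].split(";")[0].split("|")[0]
        g = load_nifti(tmp_path / first)
        assert g.shape == (48, 48, 48)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            generate_cohort(0)
        with pytest.raises(ValueError):
            generate_cohort(10, growth_fraction=1.5)


def test_mass_formula_helper():
    assert mass_mg(240.0, -600.0) == pytest.approx(96.0)
    assert mass_mg(100.0, -1000.0) == 0.0
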