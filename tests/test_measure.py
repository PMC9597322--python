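"""Measurement: diameter/volume/mass, rates, doubling times, summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial import ConvexHull

from ssngrowth import (GrowthRecord, NoduleMask, NoduleMeasurement, VoxelGrid,
                       doubling_time, increase_rate, measure, render_phantom,
                       summarize_cohort)
from conftest import make_box_mask


def min_rect_longest_side(points):
    """Rotating-calipers oracle: brute force over hull-edge-aligned boxes."""
    pts = np.asarray(points, float)
    hull = ConvexHull(pts)
    hp = pts[hull.vertices]
    best_area, best_side = np.inf, None
    for i in range(len(hp)):
        e = hp[(i + 1) % len(hp)] - hp[i]
        e = e / np.linalg.norm(e)
        n = np.array([-e[1], e[0]])
        u = pts @ e
        v = pts @ n
        w, h = u.max() - u.min(), v.max() - v.min()
        if w * h < best_area - 1e-12:
            best_area = w * h
            best_side = max(w, h)
    return best_side


def voxel_corner_points(slice_mask, sy, sx):
    ys, xs = np.nonzero(slice_mask)
    pts = []
    for dy in (0, 1):
        for dx in (0, 1):
            pts.append(np.stack([(xs + dx) * sx, (ys + dy) * sy], axis=1))
    return np.unique(np.concatenate(pts), axis=0)


class TestMeasure:
    def test_solid_cuboid_exact(self):
        # 10 x 6 voxels in-plane (x by y), 4 slices, 1 mm spacing, -600 HU
        grid, mask = make_box_mask((12, 12, 16), (4, 6, 10))
        m = measure(grid, mask)
        assert m.volume == pytest.approx(240.0)
        assert m.mean_hu == pytest.approx(-600.0)
        assert m.mass == pytest.approx(96.0)
        assert m.diameter == pytest.approx(10.0)

    def test_single_voxel_convention(self):
        grid, mask = make_box_mask((6, 6, 6), (1, 1, 1), hu=-500.0)
        m = measure(grid, mask)
        assert m.volume == pytest.approx(1.0)
        assert m.diameter == pytest.approx(1.0)
        assert m.mass == pytest.approx(0.5)

    @pytest.mark.parametrize("angle_deg", [15, 30, 45, 60])
    def test_rotated_slab_matches_calipers_oracle(self, angle_deg):
        # rasterize a rotated rectangle into a single-slice mask
        t = np.deg2rad(angle_deg)
        R = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
        yy, xx = np.meshgrid(np.arange(40), np.arange(40), indexing="ij")
        pts = np.stack([xx.ravel() - 20, yy.ravel() - 20], 1) @ R.T
        inside = (np.abs(pts[:, 0]) <= 12) & (np.abs(pts[:, 1]) <= 4)
        sl = inside.reshape(40, 40)
        mask3 = np.zeros((3, 40, 40), bool)
        mask3[1] = sl
        grid = VoxelGrid(np.full((3, 40, 40), -600.0), (1, 1, 1))
        m = measure(grid, NoduleMask(mask3, (1, 1, 1)))
        oracle = min_rect_longest_side(voxel_corner_points(sl, 1.0, 1.0))
        assert m.diameter == pytest.approx(oracle, abs=1e-6)

    def test_anisotropic_inplane_spacing_maps_to_mm(self):
        grid, mask = make_box_mask((4, 8, 8), (2, 4, 4), spacing=(5.0, 1.0, 2.0))
        m = measure(grid, mask)
        # 4 voxels x 2 mm = 8 mm beats 4 voxels x 1 mm
        assert m.diameter == pytest.approx(8.0)
        assert m.volume == pytest.approx(2 * 4 * 4 * 10.0)

    def test_volume_invariant_under_axis_permutations(self, sphere_phantom):
        grid, mask, _ = sphere_phantom
        base = measure(grid, mask)
        for axes in [(0, 2, 1), (1, 0, 2), (2, 1, 0)]:
            g2 = VoxelGrid(grid.values.transpose(axes), (1, 1, 1))
            m2 = NoduleMask(mask.values.transpose(axes), (1, 1, 1))
            assert measure(g2, m2).volume == base.volume

    def test_diameter_invariant_under_inplane_rotation(self, sphere_phantom):
        grid, mask, _ = sphere_phantom
        base = measure(grid, mask)
        g2 = VoxelGrid(np.rot90(grid.values, axes=(1, 2)).copy(), (1, 1, 1))
        m2 = NoduleMask(np.rot90(mask.values, axes=(1, 2)).copy(), (1, 1, 1))
        assert measure(g2, m2).diameter == pytest.approx(base.diameter)

    def test_phantom_truth_reproduced_exactly(self, sphere_phantom):
        grid, mask, truth = sphere_phantom
        m = measure(grid, mask)
        assert m.volume == truth.volume
        assert m.mass == pytest.approx(truth.mass, abs=1e-12)

    def test_mask_growth_increases_mass(self, sphere_phantom):
        grid, mask, _ = sphere_phantom
        base = measure(grid, mask).mass
        bigger = mask.values.copy()
        # add a neighbouring background voxel (-850 HU > -1000)
        edge = np.argwhere(mask.values)[0]
        bigger[edge[0] - 1, edge[1], edge[2]] = True
        m2 = measure(grid, NoduleMask(bigger, (1, 1, 1)))
        assert m2.mass > base

    def test_errors(self, sphere_phantom):
        grid, mask, _ = sphere_phantom
        with pytest.raises(ValueError, match="empty"):
            measure(grid, NoduleMask(np.zeros(grid.shape, bool), grid.spacing))
        with pytest.raises(ValueError, match="shape"):
            measure(grid, NoduleMask(np.ones((4, 4, 4), bool), grid.spacing))


def meas(**kw):
    base = dict(diameter=10.0, volume=500.0, mean_hu=-600.0, mass=200.0)
    base.update(kw)
    return NoduleMeasurement(**base)


class TestRatesAndDoubling:
    @pytest.mark.parametrize("m0,m1,expected", [
        (100.0, 174.0, 0.74),
        (100.0, 100.0, 0.0),
        (200.0, 150.0, -0.25),
    ])
    def test_increase_rate(self, m0, m1, expected):
        assert increase_rate(meas(mass=m0), meas(mass=m1), "mass") == \
            pytest.approx(expected)

    def test_increase_rate_requires_positive_baseline(self):
        with pytest.raises(ValueError):
            increase_rate(meas(mass=0.0), meas(mass=1.0), "mass")

    def test_doubling_exact_on_doubling(self):
        assert doubling_time(meas(mass=100.0), meas(mass=200.0), 365.0,
                             "mass") == pytest.approx(365.0)

    def test_doubling_formula_value(self):
        dt = doubling_time(meas(mass=100.0), meas(mass=130.0), 300.0, "mass")
        assert dt == pytest.approx(300.0 * np.log(2) / np.log(1.3))
        assert dt == pytest.approx(792.57, abs=0.01)

    def test_shrinkage_is_undefined(self):
        assert doubling_time(meas(mass=100.0), meas(mass=90.0), 365.0,
                             "mass") is None

    @settings(max_examples=50, deadline=None)
    @given(x1=st.floats(1.0, 1e4), ratio=st.floats(1.01, 5.0),
           k=st.floats(0.01, 100.0), dt=st.floats(10.0, 2000.0))
    def test_doubling_time_scale_invariant(self, x1, ratio, k, dt):
        a = doubling_time(meas(mass=x1), meas(mass=x1 * ratio), dt, "mass")
        b = doubling_time(meas(mass=k * x1), meas(mass=k * x1 * ratio), dt,
                          "mass")
        assert a == pytest.approx(b, rel=1e-9)

    def test_random_triples_match_closed_form(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            x1 = rng.uniform(1, 1000)
            x2 = x1 * rng.uniform(1.001, 4.0)
            dt = rng.uniform(30, 1500)
            got = doubling_time(meas(mass=x1), meas(mass=x2), dt, "mass")
            assert got == pytest.approx(dt * np.log(2) / np.log(x2 / x1))


def record(rate=0.1, dts=None, dt_days=365.0):
    dts = dts or {}
    return GrowthRecord(
        rate_diameter=rate, rate_volume=rate, rate_mass=rate,
        dt_days=dt_days,
        doubling_time_diameter=dts.get("diameter"),
        doubling_time_volume=dts.get("volume"),
        doubling_time_mass=dts.get("mass"),
        annualized_mass_rate=rate, growth_label=rate >= 0.25)


class TestSummarizeCohort:
    def test_identical_groups_pvalue_one(self):
        recs = [record(0.1), record(0.2), record(0.1), record(0.2)]
        table = summarize_cohort(recs, ["a", "a", "b", "b"])
        rates = table[table.statistic == "rate"]
        assert np.allclose(rates.p_value.to_numpy(float), 1.0)

    def test_out_of_window_doubling_time_excluded(self):
        recs = [record(0.5, {"mass": 400.0}), record(0.5, {"mass": 600.0}),
                record(0.5, {"mass": 1500.0}), record(0.5, {"mass": 500.0})]
        table = summarize_cohort(recs, ["g"] * 4)
        dt_row = table[(table.statistic == "doubling_time") &
                       (table.metric == "mass")].iloc[0]
        assert dt_row["g_n"] == 3  # the 1500 d record is clipped out
        assert dt_row["g_median"] == pytest.approx(500.0)
        rate_row = table[(table.statistic == "rate") &
                         (table.metric == "mass")].iloc[0]
        assert rate_row["g_mean"] == pytest.approx(0.5)  # still counted

    def test_separated_groups_recover_generating_medians(self):
        rng = np.random.default_rng(4)
        recs, groups = [], []
        for mu, g, n in [(490.0, "cancer", 120), (620.0, "benign", 120)]:
            for _ in range(n):
                recs.append(record(0.3, {"mass": rng.normal(mu, 60)}))
                groups.append(g)
        table = summarize_cohort(recs, groups)
        dt = table[(table.statistic == "doubling_time") &
                   (table.metric == "mass")].iloc[0]
        assert dt["cancer_median"] == pytest.approx(490.0, abs=25.0)
        assert dt["benign_median"] == pytest.approx(620.0, abs=25.0)
        assert dt["p_value"] < 1e-6

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            summarize_cohort([record(), record()], ["a", "b"])
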