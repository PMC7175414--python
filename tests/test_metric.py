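"""Slope-pair metric: normalization, reference line, cluster statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oximetric as ox
from oximetric.errors import (
    DegenerateClusterError,
    DegenerateSpectrumError,
    ValidationError,
)
from oximetric.metric import (
    DEFAULT_LEFT_SET,
    DEFAULT_RIGHT_SET,
    SlopePair,
    cluster_stats,
    metric_plot_data,
    normalize_spectrum,
    reference_point_at,
    slope_pair,
)


class TestNormalize:
    def test_constant_becomes_ones(self, grid):
        out = normalize_spectrum(ox.Spectrum(grid, np.full(7, 3.2)))
        np.testing.assert_allclose(out.values, 1.0)

    def test_idempotent_and_scale_invariant(self, table):
        s = ox.blood_absorption(table, 37)
        once = normalize_spectrum(s)
        np.testing.assert_allclose(normalize_spectrum(once).values, once.values)
        np.testing.assert_allclose(
            normalize_spectrum(s.scaled(17.0)).values, once.values, rtol=1e-12
        )
        assert np.mean(once.values) == pytest.approx(1.0, abs=1e-14)

    def test_zero_mean_rejected(self, grid):
        vals = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 0.0])
        with pytest.raises(DegenerateSpectrumError):
            normalize_spectrum(ox.Spectrum(grid, vals))


class TestSlopePair:
    def test_constant_spectrum_zero_slopes(self, grid):
        p = slope_pair(ox.Spectrum(grid, np.full(7, 2.0)))
        assert p.m1 == pytest.approx(0.0, abs=1e-15)
        assert p.m2 == pytest.approx(0.0, abs=1e-15)

    def test_deoxygenated_blood_falls_on_both_sides(self, table):
        p = slope_pair(ox.blood_absorption(table, 0))
        assert p.m1 < 0 and p.m2 < 0

    def test_exact_line_matches_closed_form_ols(self, grid):
        # left subset values on an exact line of slope 0.004 per nm; oracle is
        # the hand-evaluated closed form sum((x-xb)(y-yb))/sum((x-xb)^2)
        lam = grid
        vals = 1.0 + 0.004 * (lam - 800.0)
        p = slope_pair(ox.Spectrum(lam, vals), normalize=False)
        x = np.asarray(DEFAULT_LEFT_SET)
        y = 1.0 + 0.004 * (x - 800.0)
        oracle = ((x - x.mean()) @ (y - y.mean())) / ((x - x.mean()) @ (x - x.mean()))
        assert p.m1 == pytest.approx(oracle, abs=1e-12)
        assert p.m1 == pytest.approx(0.004, abs=1e-12)

    def test_740nm_not_in_default_subsets(self):
        assert 740.0 not in DEFAULT_LEFT_SET
        assert 740.0 not in DEFAULT_RIGHT_SET

    def test_subset_not_in_grid_rejected(self, table):
        s = ox.blood_absorption(table, 50)
        with pytest.raises(ValidationError):
            slope_pair(s, left_set_nm=(755.0, 780.0))

    @settings(max_examples=25, deadline=None)
    @given(k=st.floats(1e-3, 1e3), seed=st.integers(0, 2**16))
    def test_full_scale_invariance_with_normalization(self, k, seed):
        s = ox.gen_noise_spectra(1, noise=ox.NoiseSpec(0.1, seed))[0]
        p1 = slope_pair(s)
        p2 = slope_pair(s.scaled(k))
        assert p2.m1 == pytest.approx(p1.m1, rel=1e-9, abs=1e-12)
        assert p2.m2 == pytest.approx(p1.m2, rel=1e-9, abs=1e-12)


class TestReferenceLine:
    def test_pure_blood_lies_on_the_line(self, table, grid, reference_line):
        # exactness: every stored entry reproduces the freshly computed pair
        for s, pair in zip(reference_line.so2_grid_percent, reference_line.pairs):
            fresh = slope_pair(ox.blood_absorption(table, s, grid))
            assert fresh.distance_to(pair) < 1e-10

    def test_injective_on_one_percent_grid(self, reference_line):
        pts = reference_line.as_array()
        diff = pts[:, None, :] - pts[None, :, :]
        dist = np.hypot(diff[..., 0], diff[..., 1])
        np.fill_diagonal(dist, np.inf)
        assert dist.min() > 0

    def test_oxygenation_orders_right_slope(self, reference_line):
        assert reference_line.pairs[-1].m2 > reference_line.pairs[0].m2

    def test_reference_point_exact_not_interpolated(self, table, grid, reference_line):
        at98 = reference_point_at(reference_line, table, grid, 98.0)
        assert at98.distance_to(reference_line.pairs[98]) < 1e-12
        at50 = reference_point_at(reference_line, table, grid, 50.0)
        fresh = slope_pair(ox.blood_absorption(table, 50.0, grid))
        assert at50.distance_to(fresh) == 0.0

    def test_off_grid_point_within_neighbor_bounding_box(self, table, grid, reference_line):
        p = reference_point_at(reference_line, table, grid, 35.5)
        lo, hi = reference_line.pairs[35], reference_line.pairs[36]
        assert min(lo.m1, hi.m1) <= p.m1 <= max(lo.m1, hi.m1)
        assert min(lo.m2, hi.m2) <= p.m2 <= max(lo.m2, hi.m2)


class TestClusterStats:
    def test_symmetric_pair_gives_ratio_one(self, table, grid, reference_line):
        ref = reference_point_at(reference_line, table, grid, 98.0)
        d = 2.5e-4
        members = [
            SlopePair(ref.m1 - d, ref.m2),
            SlopePair(ref.m1 + d, ref.m2),
        ]
        cs = cluster_stats(members, [98.0, 98.0], reference_line, table, grid)
        assert cs.centroid.distance_to(ref) < 1e-15
        assert cs.spread == pytest.approx(d)
        assert cs.distance == pytest.approx(d)
        assert cs.ratio == pytest.approx(1.0)

    def test_three_hand_placed_members(self, table, grid, reference_line):
        # oracle: all statistics recomputed by hand for three explicit points
        ref = reference_point_at(reference_line, table, grid, 50.0)
        pts = np.array([[0.001, 0.002], [0.003, 0.002], [0.002, 0.005]])
        members = [SlopePair(*p) for p in pts]
        cs = cluster_stats(members, [50.0, 50.0, 50.0], reference_line, table, grid)
        centroid = np.array([0.002, 0.003])  # componentwise means by hand
        np.testing.assert_allclose(cs.centroid.as_array(), centroid, rtol=1e-12)
        spread = np.mean(np.sqrt(((pts - centroid) ** 2).sum(axis=1)))
        assert cs.spread == pytest.approx(spread, rel=1e-12)
        dist = np.mean(np.sqrt(((pts - ref.as_array()) ** 2).sum(axis=1)))
        assert cs.distance == pytest.approx(dist, rel=1e-12)
        assert cs.ratio == pytest.approx(dist / spread, rel=1e-12)

    def test_isotropic_scatter_ratio_near_one(self, table, grid, reference_line):
        rng = np.random.default_rng(3)
        ref = reference_point_at(reference_line, table, grid, 98.0)
        pts = ref.as_array() + rng.normal(0, 4e-4, size=(1000, 2))
        members = [SlopePair(*p) for p in pts]
        cs = cluster_stats(members, [98.0] * 1000, reference_line, table, grid)
        assert 0.9 <= cs.ratio <= 1.15

    def test_degenerate_cluster_raises(self, table, grid, reference_line):
        p = SlopePair(0.001, 0.002)
        with pytest.raises(DegenerateClusterError):
            cluster_stats([p, p], [50.0, 50.0], reference_line, table, grid)

    def test_fewer_than_two_members_rejected(self, table, grid, reference_line):
        with pytest.raises(ValidationError):
            cluster_stats([SlopePair(0.0, 0.0)], [50.0], reference_line, table, grid)

    def test_json_export_field_names(self, table, grid, reference_line):
        specs = ox.gen_blood_spectra(20, 98.0, noise=ox.NoiseSpec(0.1, 5))
        pairs = [slope_pair(s) for s in specs]
        so2 = [ox.fit_so2(s, table).so2_percent for s in specs]
        cs = cluster_stats(pairs, so2, reference_line, table, grid)
        d = cs.to_dict()
        assert set(d) == {
            "centroid_m1", "centroid_m2", "spread",
            "mean_so2_percent", "distance", "ratio",
        }


class TestMetricPlot:
    def test_empty_member_list_reference_only(self, table, grid, reference_line):
        data = metric_plot_data([], [], reference_line, table, grid)
        assert data.member_xy.shape == (0, 2)
        assert data.reference_xy.shape[0] == 101
        assert data.stats is None

    def test_members_on_the_line_coincide(self, table, grid, reference_line):
        members = list(reference_line.pairs[:5])
        so2 = reference_line.so2_grid_percent[:5]
        data = metric_plot_data(members, so2, reference_line, table, grid)
        np.testing.assert_allclose(data.member_xy, data.reference_xy[:5])

    def test_reduced_mode_has_no_reference_or_stats(self, table, grid):
        members = [SlopePair(0.001, 0.002), SlopePair(0.002, 0.001)]
        data = metric_plot_data(members, [40.0, 60.0], None, table, grid)
        assert data.reference_xy is None and data.stats is None

    def test_color_values_are_clamped_so2(self, table, grid, reference_line):
        members = [SlopePair(0.001, 0.002), SlopePair(0.002, 0.001)]
        data = metric_plot_data(members, [-20.0, 140.0], reference_line, table, grid)
        np.testing.assert_allclose(data.member_so2, [0.0, 100.0])

    def test_rendering_smoke(self, table, grid, reference_line, tmp_path):
        import matplotlib

        matplotlib.use("Agg")
        from oximetric.metric import plot_metric

        members = list(reference_line.pairs[40:60])
        data = metric_plot_data(
            members, reference_line.so2_grid_percent[40:60], reference_line, table, grid
        )
        ax = plot_metric(data)
        out = tmp_path / "metric.svg"
        ax.figure.savefig(out)
        assert out.stat().st_size > 0
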