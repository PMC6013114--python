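"""Spatial hotspot machinery: aggregation, Moran's I, ISA, Gi*, IDW."""

import numpy as np
import pytest
from scipy import stats

from strandeffort.hotspots import (
    EventField,
    WeightKind,
    WeightScheme,
    clip_to_buffer,
    default_isa_bands,
    gi_star,
    idw_surface,
    integrate_collect,
    isa_profile,
    morans_i,
    significant_area,
)


def brute_force_gi_star(points, weights, scheme):
    """Independent double-loop evaluation of the Gi* formula."""
    pts = np.asarray(points, float)
    x = np.asarray(weights, float)
    n = len(x)
    x_bar = x.mean()
    S = np.sqrt((x**2).sum() / n - x_bar**2)
    out = []
    for i in range(n):
        wsum = w2sum = wx = 0.0
        for j in range(n):
            d = float(np.hypot(*(pts[i] - pts[j])))
            if i == j:
                w = 1.0
            elif scheme.kind is WeightKind.ZONE_OF_INDIFFERENCE:
                w = 1.0 if d <= scheme.threshold_d0 else scheme.threshold_d0 / d
            elif scheme.kind is WeightKind.FIXED_BAND:
                w = 1.0 if d <= scheme.threshold_d0 else 0.0
            else:
                raise NotImplementedError
            wsum += w
            w2sum += w * w
            wx += w * x[j]
        denom = S * np.sqrt((n * w2sum - wsum**2) / (n - 1))
        out.append((wx - x_bar * wsum) / denom)
    return np.array(out)


class TestIntegrateCollect:
    def test_identical_points_collapse(self):
        pts = np.zeros((5, 2))
        field = integrate_collect(pts, tolerance=25000)
        assert field.n == 1
        assert field.weights[0] == 5.0

    def test_separated_points_stay_apart(self):
        pts = np.array([[0.0, 0.0], [30000.0, 0.0]])
        field = integrate_collect(pts, tolerance=25000)
        assert field.n == 2
        assert list(field.weights) == [1.0, 1.0]

    def test_three_blobs_fixture(self):
        rng = np.random.default_rng(4)
        centers = np.array([[0.0, 0.0], [150000.0, 0.0], [0.0, 150000.0]])
        sizes = (40, 35, 25)
        pts = np.vstack(
            [c + rng.normal(0, 2000.0, size=(m, 2)) for c, m in zip(centers, sizes)]
        )
        field = integrate_collect(pts, tolerance=25000)
        assert field.n == 3
        assert field.weights.sum() == 100.0
        assert sorted(field.weights) == [25.0, 35.0, 40.0]

    def test_conserves_total_count_and_is_idempotent(self):
        rng = np.random.default_rng(6)
        centers = rng.uniform(0, 1e6, size=(8, 2))
        pts = np.vstack([c + rng.normal(0, 1500.0, size=(12, 2)) for c in centers])
        field = integrate_collect(pts, tolerance=10000)
        assert field.weights.sum() == pytest.approx(len(pts))
        again = integrate_collect(field.points, tolerance=10000, weights=field.weights)
        assert again.n == field.n
        np.testing.assert_allclose(np.sort(again.weights), np.sort(field.weights))

    def test_bad_tolerance(self):
        with pytest.raises(ValueError):
            integrate_collect(np.zeros((2, 2)), tolerance=0.0)


class TestMoransI:
    def line_field(self, values, spacing=1000.0):
        xs = np.arange(len(values)) * spacing
        return EventField(np.column_stack([xs, np.zeros_like(xs)]), np.asarray(values, float))

    def test_checkerboard_is_dispersed(self):
        field = self.line_field([1, 9] * 10)
        res = morans_i(field, band=1000.0)
        assert res.usable and res.I < 0

    def test_blocks_are_clustered(self):
        field = self.line_field([9] * 10 + [1] * 10)
        res = morans_i(field, band=1000.0)
        assert res.usable and res.I > 0

    def test_constant_weights_flagged(self):
        res = morans_i(self.line_field([3] * 10), band=1000.0)
        assert not res.usable

    def test_isolated_event_flags_band(self):
        pts = np.array([[0, 0], [500, 0], [1000, 0], [99999, 0]], float)
        res = morans_i(EventField(pts, [1, 2, 3, 4]), band=600.0)
        assert not res.usable

    def test_permutation_null_mean_and_variance(self):
        """Permuting values reproduces E[I] = -1/(n-1) and the analytic
        randomization variance within Monte-Carlo error."""
        rng = np.random.default_rng(12)
        field = self.line_field(np.concatenate([np.ones(25), np.full(5, 8.0)]))
        res = morans_i(field, band=4000.0)
        n = field.n
        D = field.pairwise_distances()
        W = ((D <= 4000.0) & (D > 0)).astype(float)
        z = field.weights - field.x_bar
        scale = (n / W.sum()) / (z**2).sum()
        sims = np.empty(2000)
        for k in range(sims.size):
            zp = rng.permutation(z)
            sims[k] = scale * (zp @ W @ zp)
        se_mean = sims.std() / np.sqrt(sims.size)
        assert sims.mean() == pytest.approx(-1.0 / (n - 1), abs=4 * se_mean)
        assert sims.var() == pytest.approx(res.variance_i, rel=0.15)


class TestISA:
    def test_cluster_scale_recovered(self):
        xs = np.arange(0, 200000.0, 2000.0)
        pts = np.column_stack([xs, np.zeros_like(xs)])
        w = np.ones(len(xs))
        w[np.abs(xs - 100000.0) <= 5000.0] = 10.0  # 10 km wide high block
        profile = isa_profile(EventField(pts, w), start=5000.0, step=5000.0, n_bands=10)
        assert abs(profile.peak_distance - 10000.0) <= 5000.0

    def test_monotone_profile_flags_no_local_peak(self):
        xs = np.arange(0, 200000.0, 2000.0)
        pts = np.column_stack([xs, np.zeros_like(xs)])
        w = 1.0 + xs / 200000.0 * 5.0  # smooth gradient: clustering grows with scale
        profile = isa_profile(EventField(pts, w), start=5000.0, step=5000.0, n_bands=10)
        assert profile.no_local_peak
        assert profile.peak_distance == profile.distances[-1]

    def test_default_bands_leave_no_isolated_event(self):
        rng = np.random.default_rng(13)
        field = EventField(rng.uniform(0, 1e5, size=(30, 2)), rng.integers(1, 9, 30))
        start, step = default_isa_bands(field)
        assert morans_i(field, start).usable
        assert step == pytest.approx(start / 2)


class TestGiStar:
    def test_collinear_fixture_matches_brute_force(self):
        pts = np.array([[0, 0], [1000, 0], [2000, 0], [3000, 0], [4000, 0]], float)
        x = np.array([1, 1, 9, 1, 1], float)
        scheme = WeightScheme(threshold_d0=1500.0)
        field = EventField(pts, x)
        got = np.array([s.gi_star for s in gi_star(field, scheme)])
        want = brute_force_gi_star(pts, x, scheme)
        np.testing.assert_allclose(got, want, atol=1e-12)
        assert np.argmax(got) == 2  # the high middle point is the hotspot

    def test_random_fields_match_brute_force(self):
        rng = np.random.default_rng(14)
        for kind in (WeightKind.ZONE_OF_INDIFFERENCE, WeightKind.FIXED_BAND):
            for _ in range(5):
                n = int(rng.integers(5, 60))
                pts = rng.uniform(0, 50000.0, size=(n, 2))
                x = rng.integers(1, 20, size=n).astype(float)
                scheme = WeightScheme(kind=kind, threshold_d0=float(rng.uniform(3000, 20000)))
                got = np.array([s.gi_star for s in gi_star(EventField(pts, x), scheme)])
                want = brute_force_gi_star(pts, x, scheme)
                np.testing.assert_allclose(got, want, atol=1e-12)

    def test_saturated_neighbourhood_is_zero_and_flagged(self):
        rng = np.random.default_rng(15)
        pts = rng.uniform(0, 1000.0, size=(8, 2))
        field = EventField(pts, rng.integers(1, 10, 8))
        scores = gi_star(field, WeightScheme(threshold_d0=1e7))  # every weight = 1
        assert all(s.gi_star == 0.0 and s.flagged for s in scores)

    def test_constant_field_is_zero_and_flagged(self):
        field = EventField(np.array([[0, 0], [5000, 0], [9000, 0]], float), [2, 2, 2])
        scores = gi_star(field, WeightScheme(threshold_d0=1500.0))
        assert all(s.gi_star == 0.0 and "S = 0" in s.flagged for s in scores)

    def test_event_order_invariance(self):
        rng = np.random.default_rng(16)
        pts = rng.uniform(0, 30000.0, size=(20, 2))
        x = rng.integers(1, 15, 20).astype(float)
        scheme = WeightScheme(threshold_d0=8000.0)
        base = np.array([s.gi_star for s in gi_star(EventField(pts, x), scheme)])
        perm = rng.permutation(20)
        shuffled = np.array([s.gi_star for s in gi_star(EventField(pts[perm], x[perm]), scheme)])
        np.testing.assert_allclose(shuffled, base[perm], atol=1e-12)

    def test_numerators_sum_to_zero_for_uniform_column_sums(self):
        """The Gi* numerators total sum_j c_j (x_j - xbar), c_j the weight
        column sums: it vanishes exactly when the c_j are all equal, as on
        a regular ring, regardless of the weight values."""
        rng = np.random.default_rng(17)
        n = 24
        theta = 2 * np.pi * np.arange(n) / n
        pts = 20000.0 * np.column_stack([np.cos(theta), np.sin(theta)])
        for _ in range(5):
            x = rng.integers(1, 12, n).astype(float)
            field = EventField(pts, x)
            W = WeightScheme(threshold_d0=9000.0).matrix(field.pairwise_distances())
            numerators = W @ x - x.mean() * W.sum(axis=1)
            assert numerators.sum() == pytest.approx(0.0, abs=1e-7)
            # and the general identity: the total equals sum_j c_j (x_j - xbar)
            c = W.sum(axis=0)
            assert numerators.sum() == pytest.approx(float(c @ (x - x.mean())), abs=1e-7)

    def test_hot_and_cold_classification_thresholds(self):
        assert stats.norm.sf(1.96) * 2 == pytest.approx(0.05, abs=1e-3)
        pts = np.array([[0, 0], [1000, 0], [2000, 0], [3000, 0], [4000, 0]], float)
        scores = gi_star(EventField(pts, [1, 1, 9, 1, 1]), WeightScheme(threshold_d0=1500.0))
        for s in scores:
            hot = s.hotspot_class.value
            if s.gi_star > 1.96:
                assert hot in ("P05", "P01")


class TestSurfaces:
    def test_event_cell_takes_exact_score(self):
        pts = np.array([[500.0, 500.0], [5500.0, 500.0]])
        z = [2.0, -1.0]
        surf = idw_surface(pts, z, cell_size=1000.0, bounds=(0, 0, 6000, 1000))
        assert surf.values[0, 0] == pytest.approx(2.0)
        assert surf.values[0, 5] == pytest.approx(-1.0)

    def test_midpoint_symmetry_and_bounds(self):
        pts = np.array([[0.0, 500.0], [10000.0, 500.0]])
        surf = idw_surface(pts, [3.0, 3.0], cell_size=1000.0, bounds=(0, 0, 10000, 1000))
        assert surf.values[0, 4] == pytest.approx(3.0)
        rng = np.random.default_rng(18)
        zr = rng.normal(size=2)
        surf2 = idw_surface(pts, zr, cell_size=1000.0, bounds=(0, 0, 10000, 1000))
        assert surf2.values.min() >= zr.min() - 1e-9
        assert surf2.values.max() <= zr.max() + 1e-9

    def test_bad_cell_size(self):
        with pytest.raises(ValueError):
            idw_surface(np.zeros((1, 2)), [1.0], cell_size=0.0)

    def test_clip_disc_area(self):
        pts = np.array([[0.0, 0.0]])
        r = 10000.0
        surf = idw_surface(pts, [3.0], cell_size=1000.0, bounds=(-15000, -15000, 15000, 15000))
        clipped = clip_to_buffer(surf, pts, radius=r)
        unmasked_km2 = (~clipped.mask).sum() * 1.0
        ring_km2 = 2 * np.pi * r / 1000.0  # one cell-ring tolerance
        assert abs(unmasked_km2 - np.pi * (r / 1000.0) ** 2) <= ring_km2

    def test_clip_monotone_in_radius(self):
        pts = np.array([[0.0, 0.0], [8000.0, 0.0]])
        surf = idw_surface(pts, [1.0, 2.0], cell_size=500.0, bounds=(-10000, -10000, 18000, 10000))
        masked_counts = [
            clip_to_buffer(surf, pts, radius=r).mask.sum() for r in (1000.0, 5000.0, 9000.0)
        ]
        assert masked_counts[0] >= masked_counts[1] >= masked_counts[2]

    def test_tiny_radius_keeps_only_event_cells(self):
        pts = np.array([[500.0, 500.0]])
        surf = idw_surface(pts, [1.0], cell_size=1000.0, bounds=(0, 0, 5000, 5000))
        clipped = clip_to_buffer(surf, pts, radius=1.0)
        assert (~clipped.mask).sum() == 1

    def test_significant_area(self):
        flat = idw_surface(np.array([[0.0, 0.0]]), [0.0], cell_size=1000.0, bounds=(0, 0, 10000, 10000))
        assert significant_area(flat) == 0.0
        hot = idw_surface(np.array([[5000.0, 5000.0]]), [3.0], cell_size=1000.0, bounds=(0, 0, 10000, 10000))
        assert significant_area(hot) == pytest.approx(100.0)

    def test_ascii_export_round_trip(self, tmp_path):
        surf = idw_surface(np.array([[500.0, 500.0]]), [2.5], cell_size=1000.0, bounds=(0, 0, 3000, 2000))
        path = tmp_path / "surf.asc"
        surf.write_ascii(path)
        lines = path.read_text().splitlines()
        assert lines[0].split() == ["ncols", "3"]
        assert lines[1].split() == ["nrows", "2"]
        grid = np.array([[float(v) for v in row.split()] for row in lines[6:]])
        np.testing.assert_allclose(grid, surf.values, rtol=1e-5)
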