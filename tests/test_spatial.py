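import numpy as np
import pytest
from scipy.stats import spearmanr

from bioregions.data import SiteRegistry
from bioregions.grids import GridGeometry, GridSurface
from bioregions.spatial import (SpatialWeights, correlogram, haversine_km,
                                idw_interpolate, mem_basis, mem_from_weights,
                                morans_i, rgb_compose)


def _ring_weights(n):
    w = np.zeros((n, n))
    for i in range(n):
        w[i, (i + 1) % n] = w[(i + 1) % n, i] = 1.0
    return SpatialWeights(w)


class TestHaversine:
    def test_one_degree_at_equator(self):
        d = haversine_km(np.array([0.0]), np.array([0.0]),
                         np.array([1.0]), np.array([0.0]))[0, 0]
        assert d == pytest.approx(111.19, abs=0.2)

    def test_symmetry_zero_diagonal(self, scattered_registry):
        r = scattered_registry
        d = haversine_km(r.lon, r.lat, r.lon, r.lat)
        np.testing.assert_allclose(d, d.T, atol=1e-9)
        assert np.all(np.diag(d) < 1e-9)


class TestIdw:
    def test_exact_hit_returns_site_value(self):
        reg = SiteRegistry(["a", "b"], np.array([-40.0, -41.0]),
                           np.array([-9.0, -9.5]))
        geom = GridGeometry(-40.0, -9.0, 30.0, 2, 2)
        out = idw_interpolate(reg, [3.0, 7.0], geom)
        assert out.values[0, 0] == 3.0

    def test_equidistant_cell_averages_for_any_power(self):
        reg = SiteRegistry(["a", "b"], np.array([-40.0, -40.0]),
                           np.array([-10.0, -12.0]))
        geom = GridGeometry(-40.0, -10.0, 60.0, 3, 1)
        for power in (1.0, 2.0, 3.5):
            out = idw_interpolate(reg, [0.0, 1.0], geom, power=power)
            assert out.values[1, 0] == pytest.approx(0.5, abs=1e-9)

    def test_matches_hand_formula(self):
        r = np.random.default_rng(3)
        reg = SiteRegistry([f"s{i}" for i in range(5)],
                           r.uniform(-41, -40, 5), r.uniform(-9, -8, 5))
        vals = r.random(5)
        geom = GridGeometry(-40.5, -8.5, 2.5, 1, 1)
        out = idw_interpolate(reg, vals, geom, power=2.0)
        lon, lat = geom.cell_centers()
        d = haversine_km(lon.ravel(), lat.ravel(), reg.lon, reg.lat)[0]
        w = d**-2.0
        assert out.values[0, 0] == pytest.approx(np.sum(w * vals) / w.sum(),
                                                 rel=1e-12)

    def test_convex_combination_bounds(self, scattered_registry):
        r = np.random.default_rng(4)
        vals = r.normal(size=len(scattered_registry))
        geom = GridGeometry(-43.0, -7.0, 10.0, 12, 12)
        out = idw_interpolate(scattered_registry, vals, geom)
        assert out.values.min() >= vals.min() - 1e-12
        assert out.values.max() <= vals.max() + 1e-12

    def test_nearest_neighbor_subset(self, scattered_registry):
        vals = np.arange(len(scattered_registry), dtype=float)
        geom = GridGeometry(-43.0, -7.0, 30.0, 4, 4)
        out = idw_interpolate(scattered_registry, vals, geom, n_neighbors=3)
        assert np.all(np.isfinite(out.values))


class TestMoransI:
    def test_alternating_ring_is_minus_one(self):
        vals = np.array([1.0, -1.0] * 4)
        i, e, _ = morans_i(vals, _ring_weights(8), n_perm=49, seed=0)
        assert i == pytest.approx(-1.0, abs=1e-12)
        assert e == pytest.approx(-1 / 7)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            morans_i(np.ones(8), _ring_weights(8))

    def test_smooth_ring_gradient_positive(self):
        vals = np.cos(2 * np.pi * np.arange(16) / 16)
        i, _, p = morans_i(vals, _ring_weights(16), n_perm=199, seed=1)
        assert i > 0.5 and p < 0.05

    def test_permutation_null_centers_on_expectation(self):
        r = np.random.default_rng(5)
        vals = r.normal(size=16)
        w = _ring_weights(16)
        sims = []
        for s in range(500):
            perm = r.permutation(vals)
            i, _, _ = morans_i(perm, w, n_perm=0)
            sims.append(i)
        e = -1 / 15
        se = np.std(sims) / np.sqrt(len(sims))
        assert abs(np.mean(sims) - e) < 3 * se


class TestCorrelogram:
    def test_gradient_short_distances_positive(self, scattered_registry):
        r = np.random.default_rng(6)
        vals = scattered_registry.lon * 10 + r.normal(0, 0.5, 40)
        cg = correlogram(vals, scattered_registry, n_classes=8, n_perm=199,
                         seed=0)
        assert cg.morans_i[0] > 0
        assert cg.p_values[0] < 0.05

    def test_shuffled_values_mostly_null(self, scattered_registry):
        r = np.random.default_rng(7)
        vals = r.permutation(scattered_registry.lon * 10)
        cg = correlogram(vals, scattered_registry, n_classes=8, n_perm=199,
                         seed=1)
        assert cg.significant().sum() <= 1

    def test_single_class_reduces_to_global(self, scattered_registry):
        r = np.random.default_rng(8)
        vals = r.normal(size=40)
        cg = correlogram(vals, scattered_registry, n_classes=1, n_perm=0)
        w = (haversine_km(scattered_registry.lon, scattered_registry.lat,
                          scattered_registry.lon, scattered_registry.lat)
             > 0).astype(float)
        i, _, _ = morans_i(vals, SpatialWeights(w), n_perm=0)
        assert cg.morans_i[0] == pytest.approx(i, abs=1e-12)


class TestMem:
    def test_orthonormal_eigenvectors(self, scattered_registry):
        b = mem_basis(scattered_registry, n_perm=49, seed=0)
        gram = b.vectors.T @ b.vectors
        np.testing.assert_allclose(gram, np.eye(gram.shape[0]), atol=1e-10)

    def test_morans_i_tracks_eigenvalues(self, scattered_registry):
        b = mem_basis(scattered_registry, n_perm=49, seed=0)
        rho = spearmanr(b.morans_i, b.eigenvalues).statistic
        assert rho > 0.999

    def test_ring_lattice_mems_are_sinusoids(self):
        n = 24
        b = mem_from_weights(SpatialWeights(_ring_weights(n).w), n_perm=0)
        t = 2 * np.pi * np.arange(n) / n
        basis = np.column_stack([np.cos(t), np.sin(t)])
        # leading eigenvector pair spans the first Fourier harmonics
        v = b.vectors[:, :2]
        proj = basis @ np.linalg.lstsq(basis, v, rcond=None)[0]
        for j in range(2):
            cos_sim = (proj[:, j] @ v[:, j]) / (
                np.linalg.norm(proj[:, j]) * np.linalg.norm(v[:, j]))
            assert cos_sim > 0.99

    def test_selected_are_positive_broad_patterns(self, scattered_registry):
        b = mem_basis(scattered_registry, n_perm=99, seed=0)
        assert np.all(b.eigenvalues[b.selected] > 0)
        assert np.all(b.morans_i[b.selected] > 0)

    def test_too_few_sites_rejected(self):
        reg = SiteRegistry(["a", "b", "c"], np.array([-40.0, -40.5, -41.0]),
                           np.array([-9.0, -9.1, -9.2]))
        with pytest.raises(ValueError):
            mem_basis(reg)


class TestRgbCompose:
    def _surf(self, vals):
        vals = np.asarray(vals, dtype=float)
        geom = GridGeometry(-40.0, -9.0, 2.5, *vals.shape)
        return GridSurface(geom, vals)

    def test_minimum_cell_is_channel_zero(self):
        a = self._surf([[0.0, 1.0], [0.5, 0.25]])
        rgba = rgb_compose(a, a, a)
        assert rgba[0, 0, 0] == 0
        assert rgba[0, 1, 0] == 255

    def test_channel_span_proportional_to_axis_spread(self):
        a = self._surf([[0.0, 1.0]])
        half = self._surf([[0.0, 0.5]])
        rgba = rgb_compose(a, half, a)
        assert rgba[..., 1].max() == pytest.approx(128, abs=1)

    def test_constant_axis_mid_intensity(self):
        a = self._surf([[0.0, 1.0]])
        const = self._surf([[0.3, 0.3]])
        rgba = rgb_compose(a, a, const)
        assert np.all(rgba[..., 2] == 128)
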