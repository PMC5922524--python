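import numpy as np
import pandas as pd
import pytest

from bioregions.data import SiteRegistry
from bioregions.grids import GridGeometry, GridSurface
from bioregions.predictors import (aridity_index, buffer_aggregate,
                                   collinearity_screen, envelope_distance,
                                   historical_ai, vif)
from bioregions.spatial import haversine_km


def _surf(vals, geom=None):
    vals = np.asarray(vals, dtype=float)
    geom = geom or GridGeometry(-41.0, -8.0, 2.5, *vals.shape)
    return GridSurface(geom, vals)


class TestAridityIndex:
    def test_printed_formula(self):
        ai = aridity_index(_surf([[1000.0]]), _surf([[27.0]]))
        assert ai.values[0, 0] == pytest.approx(1000 / 60, abs=5e-5)
        assert ai.values[0, 0] == pytest.approx(16.6667, abs=1e-4)

    def test_zero_precipitation(self):
        ai = aridity_index(_surf([[0.0]]), _surf([[25.0]]))
        assert ai.values[0, 0] == 0.0

    def test_singular_temperature_rejected(self):
        with pytest.raises(ValueError):
            aridity_index(_surf([[100.0]]), _surf([[-33.0]]))


class TestHistoricalAi:
    def test_identical_climates_zero(self):
        cur = _surf([[3.0, 4.0]])
        out = historical_ai(cur, [cur, cur])
        np.testing.assert_allclose(out.values, 0.0)

    def test_consensus_mean_over_gcms(self):
        cur = _surf([[10.0]])
        lgm = [_surf([[11.0]]), _surf([[12.0]]), _surf([[13.0]])]
        out = historical_ai(cur, lgm)
        assert out.values[0, 0] == pytest.approx(-2.0)

    def test_single_gcm_plain_difference(self):
        out = historical_ai(_surf([[10.0]]), [_surf([[7.5]])])
        assert out.values[0, 0] == pytest.approx(2.5)


class TestEnvelopeDistance:
    def _stack(self, x):
        """x: cells x variables; lay out cells on one row."""
        return [_surf(x[:, j][None, :]) for j in range(x.shape[1])]

    def test_mean_cell_sits_at_origin(self):
        r = np.random.default_rng(0)
        x = r.normal(size=(9, 4))
        x = np.vstack([x, x.mean(axis=0)])  # last cell = centroid of all cells
        out = envelope_distance(self._stack(x))
        assert out.values[0, -1] == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("seed", range(3))
    def test_distance_is_standardized_row_norm(self, seed):
        r = np.random.default_rng(seed)
        x = r.normal(size=(20, 6))
        out = envelope_distance(self._stack(x))
        z = (x - x.mean(0)) / x.std(0, ddof=1)
        np.testing.assert_allclose(out.values[0], np.linalg.norm(z, axis=1),
                                   atol=1e-10)

    def test_rotation_invariance(self):
        r = np.random.default_rng(5)
        x = r.normal(size=(15, 4))
        z = (x - x.mean(0)) / x.std(0, ddof=1)
        q, _ = np.linalg.qr(r.normal(size=(4, 4)))
        d1 = envelope_distance(self._stack(x)).values[0]
        # rotating the standardized space leaves every distance unchanged
        zr = z @ q
        d2 = np.linalg.norm(zr, axis=1)
        np.testing.assert_allclose(d1, d2, atol=1e-10)

    def test_single_informative_variable_is_zscore(self):
        r = np.random.default_rng(6)
        a = r.normal(size=12)
        const = np.full(12, 3.0)  # zero-variance column gets dropped
        out = envelope_distance(self._stack(np.column_stack([a, const])))
        z = (a - a.mean()) / a.std(ddof=1)
        np.testing.assert_allclose(out.values[0], np.abs(z), atol=1e-10)


class TestBufferAggregate:
    def _uniform_grid(self, value=4.2):
        geom = GridGeometry(-41.0, -8.0, 2.5, 20, 20)
        return GridSurface(geom, np.full((20, 20), value))

    def test_uniform_surface(self):
        surf = self._uniform_grid()
        reg = SiteRegistry(["a"], np.array([-40.5]), np.array([-8.3]))
        assert buffer_aggregate(surf, reg, 10.0, "mean")[0] == 4.2
        assert buffer_aggregate(surf, reg, 10.0, "range")[0] == 0.0
        assert buffer_aggregate(surf, reg, 10.0, "cv")[0] == 0.0

    def test_membership_matches_haversine_oracle(self):
        r = np.random.default_rng(1)
        geom = GridGeometry(-41.0, -8.0, 2.5, 15, 15)
        surf = GridSurface(geom, r.random((15, 15)))
        reg = SiteRegistry(["a", "b"], np.array([-40.7, -40.9]),
                           np.array([-8.2, -8.4]))
        got = buffer_aggregate(surf, reg, 12.0, "mean")
        lon, lat = geom.cell_centers()
        for i in range(2):
            d = haversine_km(np.array([reg.lon[i]]), np.array([reg.lat[i]]),
                             lon.ravel(), lat.ravel())[0]
            sel = d <= 12.0
            assert got[i] == pytest.approx(surf.values.ravel()[sel].mean(),
                                           rel=1e-12)

    def test_empty_buffer_names_site(self):
        surf = self._uniform_grid()
        reg = SiteRegistry(["far_site"], np.array([10.0]), np.array([40.0]))
        with pytest.raises(ValueError, match="far_site"):
            buffer_aggregate(surf, reg, 10.0, "mean")


class TestCollinearityScreen:
    def test_duplicate_column_dropped(self):
        r = np.random.default_rng(2)
        a = r.normal(size=30)
        df = pd.DataFrame({"a": a, "dup": a, "b": r.normal(size=30)})
        kept, report = collinearity_screen(df, 0.75)
        assert list(kept.columns) == ["a", "b"]
        assert report[0]["dropped"] == "dup"

    def test_uncorrelated_identity(self):
        r = np.random.default_rng(3)
        df = pd.DataFrame(r.normal(size=(200, 4)), columns=list("abcd"))
        kept, report = collinearity_screen(df, 0.75)
        assert list(kept.columns) == list("abcd") and report == []

    def test_priority_kept_in_correlated_triple(self):
        r = np.random.default_rng(4)
        base = r.normal(size=100)
        df = pd.DataFrame({
            "x": base + r.normal(0, 0.1, 100),
            "y": base + r.normal(0, 0.1, 100),
            "z": base + r.normal(0, 0.1, 100),
        })
        kept, report = collinearity_screen(df, 0.75, priority=["y", "x", "z"])
        assert list(kept.columns) == ["y"]
        assert len(report) == 2

    def test_threshold_respected_after_screen(self):
        r = np.random.default_rng(5)
        base = r.normal(size=80)
        df = pd.DataFrame({f"v{i}": base * w + r.normal(0, 1, 80)
                           for i, w in enumerate([3, 2.5, 2, 0.5, 0.1])})
        kept, _ = collinearity_screen(df, 0.75)
        corr = kept.corr().to_numpy()
        np.fill_diagonal(corr, 0.0)
        assert np.abs(corr).max() <= 0.75


class TestVif:
    def test_orthogonal_predictors_unity(self):
        n = 64
        t = np.arange(n)
        df = pd.DataFrame({"s": np.sin(2 * np.pi * t / n),
                           "c": np.cos(2 * np.pi * t / n)})
        v = vif(df)
        np.testing.assert_allclose(v.to_numpy(), 1.0, atol=1e-10)

    def test_duplicate_rejected(self):
        a = np.random.default_rng(6).normal(size=30)
        with pytest.raises(ValueError):
            vif(pd.DataFrame({"a": a, "b": a}))

    def test_matches_ols_oracle(self):
        r = np.random.default_rng(7)
        df = pd.DataFrame(r.normal(size=(50, 4)), columns=list("abcd"))
        df["a"] += 0.8 * df["b"]
        got = vif(df)
        import statsmodels.api as sm
        for col in df.columns:
            others = sm.add_constant(df.drop(columns=col))
            r2 = sm.OLS(df[col], others).fit().rsquared
            assert got[col] == pytest.approx(1 / (1 - r2), rel=1e-8)
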