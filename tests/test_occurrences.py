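import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import plateausdm as ps
from plateausdm.grids import pairwise_distance_km
from plateausdm.occurrences import OccurrenceSet


def occ_from(lons, lats, grid, label="presence"):
    return OccurrenceSet.from_points(lons, lats, grid, label)


class TestCleanRecords:
    def test_duplicates_within_cell_collapse_to_one(self, land):
        grid = land.env.grid
        r, c = np.nonzero(land.env.sea)
        lon, lat = grid.lons[c[5]], grid.lats[r[5]]
        occ = occ_from([lon, lon, lon], [lat, lat, lat], grid)
        out = ps.clean_records(occ, land.env)
        assert len(out) == 1
        assert out.meta["cleaning_log"]["removed_duplicate_cell"] == 2

    def test_land_records_dropped(self, land):
        grid = land.env.grid
        rl, cl = np.nonzero(~land.env.sea)
        rs, cs = np.nonzero(land.env.sea)
        occ = occ_from([grid.lons[cl[0]], grid.lons[cs[0]]],
                       [grid.lats[rl[0]], grid.lats[rs[0]]], grid)
        out = ps.clean_records(occ, land.env)
        assert len(out) == 1
        assert out.meta["cleaning_log"]["removed_land_or_offgrid"] == 1

    def test_clean_input_is_idempotent(self, land):
        once = ps.clean_records(land.occ, land.env)
        twice = ps.clean_records(once, land.env)
        pd.testing.assert_frame_equal(once.table, twice.table)

    def test_everything_removed_is_error(self, land):
        grid = land.env.grid
        rl, cl = np.nonzero(~land.env.sea)
        occ = occ_from([grid.lons[cl[0]]], [grid.lats[rl[0]]], grid)
        with pytest.raises(ValueError, match="removed"):
            ps.clean_records(occ, land.env)


class TestThinRecords:
    def test_close_pair_keeps_exactly_one(self, land):
        grid = land.env.grid
        occ = occ_from([125.0, 125.05], [35.0, 35.0], grid)  # ~4.6 km apart
        out = ps.thin_records(occ, 20.0, n_rep=3, seed=0)
        assert len(out) == 1

    def test_already_sparse_set_is_untouched(self, land):
        occ = occ_from([120.0, 122.0, 124.0], [35.0, 35.0, 35.0],
                       land.env.grid)
        out = ps.thin_records(occ, 20.0, n_rep=3, seed=0)
        assert len(out) == 3

    def test_single_record_passes(self, land):
        occ = occ_from([125.0], [35.0], land.env.grid)
        assert len(ps.thin_records(occ, 20.0, n_rep=2, seed=0)) == 1

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_min_pairwise_distance_contract(self, seed):
        """Any input, any seed: retained records are >= 20 km apart."""
        rng = np.random.default_rng(seed)
        n = 40
        lons = 120.0 + rng.uniform(0, 1.5, n)
        lats = 33.0 + rng.uniform(0, 1.5, n)
        grid = ps.RasterGrid.regular(10, 10, (32, 36), (119, 123))
        out = ps.thin_records(occ_from(lons, lats, grid), 20.0,
                              n_rep=3, seed=seed)
        t = out.table
        if len(t) > 1:
            D = pairwise_distance_km(t["lat"].to_numpy(), t["lon"].to_numpy())
            np.fill_diagonal(D, np.inf)
            assert D.min() >= 20.0

    def test_invalid_distance_is_error(self, land):
        occ = occ_from([125.0], [35.0], land.env.grid)
        with pytest.raises(ValueError, match="min_dist_km"):
            ps.thin_records(occ, 0.0)


class TestBufferArea:
    def test_presence_cells_inside_own_area(self, land, prepped):
        area = prepped.areas[1000.0]
        t = prepped.thinned.table
        assert area.mask[t["row"], t["col"]].all()

    def test_monotone_nesting(self, prepped):
        a, b, c = (prepped.areas[r].mask for r in (1000.0, 1500.0, 2000.0))
        assert not (a & ~b).any()
        assert not (b & ~c).any()

    def test_distance_membership_single_presence(self, land):
        grid = land.env.grid
        pres = occ_from([grid.lons[25]], [grid.lats[5]], grid)
        domain = np.ones(grid.shape, bool)
        lat2d, lon2d = grid.mesh()
        d = ps.haversine_km(lat2d, lon2d, grid.lats[5], grid.lons[25])
        far = (d > 1200) & (d < 1800)
        if far.any():
            r, c = np.argwhere(far)[0]
            small = ps.buffer_area(pres, 1000.0, domain, grid=grid)
            big = ps.buffer_area(pres, 2000.0, domain, grid=grid)
            assert not small.mask[r, c]
            assert big.mask[r, c]

    def test_area_within_domain(self, land, prepped):
        assert not (prepped.areas[2000.0].mask & ~prepped.domain).any()

    def test_bad_radius_is_error(self, land, prepped):
        with pytest.raises(ValueError, match="radius"):
            ps.buffer_area(prepped.thinned, 0.0, prepped.domain, env=land.env)


class TestPseudoAbsences:
    def test_count_and_exclusion(self, land, prepped):
        pa = prepped.pa
        assert len(pa) == len(prepped.thinned)  # same number as presences
        pres_cells = set(map(tuple, prepped.thinned.table[["row", "col"]]
                             .to_numpy()))
        pa_cells = set(map(tuple, pa.table[["row", "col"]].to_numpy()))
        assert not pres_cells & pa_cells
        assert (pa.table["label"] == "pseudo_absence").all()

    def test_inside_area_and_complete_data(self, land, prepped):
        pa = prepped.pa
        assert prepped.areas[1000.0].mask[pa.table["row"], pa.table["col"]].all()
        X = land.env.values_at(pa.table["row"].to_numpy(),
                               pa.table["col"].to_numpy())
        assert np.isfinite(X).all()

    def test_different_seeds_differ(self, land, prepped):
        a = ps.draw_pseudo_absences(prepped.areas[2000.0], 50, 1,
                                    prepped.thinned, env=land.env)
        b = ps.draw_pseudo_absences(prepped.areas[2000.0], 50, 2,
                                    prepped.thinned, env=land.env)
        assert not a.table.equals(b.table)

    def test_too_many_requested_is_error(self, land, prepped):
        n = prepped.areas[1000.0].n_cells + 1
        with pytest.raises(ValueError, match="eligible"):
            ps.draw_pseudo_absences(prepped.areas[1000.0], n,
                                    0, prepped.thinned, env=land.env)


class TestNormalization:
    def test_extremes_map_to_unit_interval(self, prepped):
        area = prepped.areas[2000.0]
        for name in prepped.env_norm.layer_names:
            vals = prepped.env_norm.layer(name)[area.mask]
            vals = vals[np.isfinite(vals)]
            assert vals.min() == pytest.approx(0.0, abs=1e-12)
            assert vals.max() == pytest.approx(1.0, abs=1e-12)

    def test_affine_transform_of_constants(self, prepped):
        tr = prepped.transform
        expected = (26.0 - tr.offsets["temp_mean"]) / tr.scales["temp_mean"]
        assert tr.normalize_value("temp_mean", 26.0) == pytest.approx(expected)
        assert tr.denormalize_value("temp_mean", expected) == pytest.approx(26.0)

    def test_future_values_not_clipped(self, land, prepped):
        fut = ps.make_future(land.env, 5.0, 0.0, seed=1, warming_sd=0.0)
        fut_norm = prepped.transform.apply(fut)
        assert np.nanmax(fut_norm.layer("temp_mean")) > 1.0

    def test_constant_layer_is_error(self, land, prepped):
        env = land.env.copy()
        env.layers["salinity"] = np.where(env.sea, 30.0, np.nan)
        with pytest.raises(ValueError, match="salinity"):
            ps.normalize_predictors(env, prepped.areas[2000.0])

    def test_roundtrip_json(self, prepped, tmp_path):
        prepped.transform.to_json(tmp_path / "t.json")
        back = ps.NormalizationTransform.from_json(tmp_path / "t.json")
        assert back.offsets == prepped.transform.offsets


class TestVIF:
    def _stack(self, X, names):
        n = X.shape[0]
        grid = ps.RasterGrid.regular(n, 2, (0, n), (0, 2))
        sea = np.ones((n, 2), bool)
        env = ps.EnvStack(grid, sea)
        for j, name in enumerate(names):
            arr = np.full((n, 2), np.nan)
            arr[:, 0] = X[:, j]
            arr[:, 1] = X[:, j]
            env.layers[name] = arr
        area = ps.CalibrationArea(np.pad(np.ones((n, 1), bool), ((0, 0), (0, 1))),
                                  1.0)
        return env, area

    def test_orthogonal_predictors_have_unit_vif(self, rng):
        n = 400
        X = rng.standard_normal((n, 3))
        X, _ = np.linalg.qr(X)  # exactly orthogonal columns
        env, area = self._stack(X, ["a", "b", "c"])
        report, ok = ps.vif_check(env, area)
        assert ok
        assert np.allclose(report["vif"], 1.0, atol=1e-6)

    def test_duplicate_layer_is_infinite_and_fails(self, rng):
        x = rng.standard_normal((300, 1))
        X = np.hstack([x, x, rng.standard_normal((300, 1))])
        env, area = self._stack(X, ["a", "a_copy", "b"])
        with pytest.warns(UserWarning, match="VIF"):
            report, ok = ps.vif_check(env, area)
        assert not ok
        assert np.isinf(report.loc["a", "vif"])

    def test_matches_analytic_covariance_oracle(self, rng):
        """Three jointly Gaussian layers with known correlation: VIF_j is
        the j-th diagonal of the inverse correlation matrix."""
        R = np.array([[1.0, 0.6, 0.3],
                      [0.6, 1.0, 0.5],
                      [0.3, 0.5, 1.0]])
        L = np.linalg.cholesky(R)
        X = rng.standard_normal((60_000, 3)) @ L.T
        env, area = self._stack(X, ["a", "b", "c"])
        report, _ = ps.vif_check(env, area)
        expected = np.diag(np.linalg.inv(R))
        assert np.allclose(report["vif"], expected, rtol=0.05)
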