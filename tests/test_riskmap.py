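"""Risk surfaces, Jenks classification, zonal means, plantation overlap."""

import itertools

import numpy as np
import pytest
from shapely.geometry import box

import riskpipe as rp
from riskpipe import synthetic as syn
from riskpipe.grids import GridSpec, Raster


def brute_force_jenks_ssd(values, k):
    v = np.sort(np.asarray(values, dtype=float))
    best = np.inf
    for cuts in itertools.combinations(range(1, len(v)), k - 1):
        ssd = sum(
            ((part - part.mean()) ** 2).sum() for part in np.split(v, cuts)
        )
        best = min(best, ssd)
    return best


def dp_jenks_ssd(values, k):
    v = np.sort(np.asarray(values, dtype=float))
    breaks = rp.jenks_breaks(v, k)
    cls = np.searchsorted(breaks, v, side="left")
    return sum(
        ((v[cls == c] - v[cls == c].mean()) ** 2).sum() for c in np.unique(cls)
    )


@pytest.fixture()
def small_grid():
    return GridSpec(0.0, 4.0, 1.0, 4, 4)


class TestNormalize:
    def test_three_values(self, small_grid):
        data = np.full(small_grid.shape, 4.0)
        data[0, :] = 2.0
        data[3, :] = 6.0
        out = rp.normalize_surface(Raster(data, small_grid))
        assert set(np.unique(out.data)) == {0.0, 0.5, 1.0}

    def test_already_unit_interval_unchanged(self, small_grid, rng):
        data = rng.random(small_grid.shape)
        data.flat[0], data.flat[-1] = 0.0, 1.0
        out = rp.normalize_surface(Raster(data, small_grid))
        np.testing.assert_allclose(out.data, data, atol=1e-15)

    def test_constant_raster_becomes_zero_with_warning(self, small_grid):
        with pytest.warns(UserWarning, match="constant"):
            out = rp.normalize_surface(Raster(np.full(small_grid.shape, 3.0),
                                              small_grid))
        assert np.all(out.data == 0.0)


class TestInvasionRisk:
    def test_cellwise_product(self, small_grid):
        suit = Raster(np.full(small_grid.shape, 0.8), small_grid)
        intro = Raster(np.full(small_grid.shape, 0.5), small_grid)
        out = rp.invasion_risk(suit, intro)
        np.testing.assert_allclose(out.data, 0.4, atol=1e-15)

    def test_zero_introduction_kills_risk(self, small_grid, rng):
        suit = Raster(rng.random(small_grid.shape), small_grid)
        intro = Raster(np.zeros(small_grid.shape), small_grid)
        assert np.all(rp.invasion_risk(suit, intro).data == 0.0)

    def test_product_bounded_by_operands_and_nodata_propagates(
        self, small_grid, rng
    ):
        s, i = rng.random(small_grid.shape), rng.random(small_grid.shape)
        s[0, 0] = np.nan
        out = rp.invasion_risk(Raster(s, small_grid), Raster(i, small_grid))
        assert np.isnan(out.data[0, 0])
        m = ~np.isnan(out.data)
        assert np.all(out.data[m] <= np.minimum(s, i)[m] + 1e-15)

    def test_misaligned_introduction_resampled(self, small_grid, rng):
        suit = Raster(rng.random(small_grid.shape), small_grid)
        fine = GridSpec(0.0, 4.0, 0.5, 8, 8)
        intro = Raster(np.full(fine.shape, 0.25), fine)
        with pytest.warns(UserWarning, match="resampling"):
            out = rp.invasion_risk(suit, intro)
        np.testing.assert_allclose(out.data, suit.data * 0.25, atol=1e-12)


class TestJenks:
    def test_obvious_gap(self):
        breaks = rp.jenks_breaks([1, 2, 10, 11], 2)
        assert breaks[0] == 2.0

    def test_outlier_isolated(self):
        breaks = rp.jenks_breaks([5.0, 5.1, 4.9, 5.0, 100.0], 2)
        assert 5.1 <= breaks[0] < 100.0

    def test_matches_exhaustive_partition_search(self, rng):
        for _ in range(300):
            n = int(rng.integers(4, 13))
            k = int(rng.integers(2, 5))
            v = np.round(rng.random(n) * 10, 2)
            if np.unique(v).size < k:
                continue
            assert dp_jenks_ssd(v, k) == pytest.approx(
                brute_force_jenks_ssd(v, k), abs=1e-10
            )

    def test_insufficient_distinct_values_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            rp.jenks_breaks([1.0, 1.0, 2.0], 3)
        with pytest.raises(ValueError, match=">= 2"):
            rp.jenks_breaks([1.0, 2.0], 1)


class TestClassify:
    @pytest.fixture()
    def classified(self, small_grid, rng):
        data = rng.random(small_grid.shape)
        return rp.classify(Raster(data, small_grid), k=4), data

    def test_four_class_labels(self, classified):
        cmap, _ = classified
        assert cmap.label_names == ("unsuitable", "marginal", "moderate", "high")
        assert cmap.breaks.size == 3 and np.all(np.diff(cmap.breaks) > 0)

    def test_counts_sum_to_valid_cells(self, classified):
        cmap, data = classified
        assert sum(cmap.class_counts().values()) == np.isfinite(data).sum()

    def test_value_on_break_falls_in_lower_class(self):
        grid = GridSpec(0.0, 2.0, 1.0, 2, 2)
        data = np.array([[1.0, 2.0], [10.0, 11.0]])
        cmap = rp.classify(Raster(data, grid), k=2, labels=("lo", "hi"))
        assert cmap.breaks[0] == 2.0
        assert cmap.labels[0, 1] == 0  # the break value itself stays low
        assert cmap.labels[1, 0] == 1

    def test_idempotent_on_break_midpoints(self, small_grid, rng):
        data = rng.random(small_grid.shape)
        cmap = rp.classify(Raster(data, small_grid), k=4)
        edges = np.concatenate([[data.min()], cmap.breaks, [data.max()]])
        mids = (edges[:-1] + edges[1:]) / 2
        assigned = np.searchsorted(cmap.breaks, mids, side="left")
        np.testing.assert_array_equal(assigned, np.arange(4))


class TestZonalMean:
    def test_two_cell_polygon_average(self, small_grid):
        data = np.zeros(small_grid.shape)
        data[0, 0], data[0, 1] = 0.2, 0.4
        poly = box(0.0, 3.0, 2.0, 4.0)  # covers cells (0,0) and (0,1)
        out = rp.zonal_mean(Raster(data, small_grid), [("A", poly)])
        assert out.loc[0, "mean_suitability"] == pytest.approx(0.3)
        assert out.loc[0, "n_cells"] == 2

    def test_uniform_raster_returns_constant(self, small_grid):
        out = rp.zonal_mean(
            Raster(np.full(small_grid.shape, 0.7), small_grid),
            [("A", box(0.5, 0.5, 3.5, 3.5))],
        )
        assert out.loc[0, "mean_suitability"] == pytest.approx(0.7)

    def test_tiling_matches_cell_membership_oracle(self, world_spec, surface):
        anc = syn.generate_ancillary_surfaces(world_spec, seed=8)
        out = rp.zonal_mean(surface, anc.municipalities).set_index("muni_id")
        for muni_id, (rows, cols) in anc.municipality_cells.items():
            expected = surface.data[rows, cols].mean()
            assert out.loc[muni_id, "mean_suitability"] == pytest.approx(expected)

    def test_empty_polygon_warns_and_yields_nan(self, small_grid):
        tiny = box(0.1, 3.6, 0.2, 3.9)  # contains no cell center
        with pytest.warns(UserWarning, match="no valid cell center"):
            out = rp.zonal_mean(Raster(np.ones(small_grid.shape), small_grid),
                                [("A", tiny)])
        assert np.isnan(out.loc[0, "mean_suitability"])


class TestPlantationOverlap:
    @pytest.fixture()
    def class_map(self):
        # 4x4 grid, one class per row: 0,1,2,3
        grid = GridSpec(0.0, 4.0, 1.0, 4, 4)
        labels = np.repeat(np.arange(4), 4).reshape(4, 4)
        return rp.ClassifiedMap(labels, np.array([0.25, 0.5, 0.75]),
                                rp.riskmap.SUITABILITY_LABELS, grid)

    def test_single_class_plantation(self, class_map):
        out = rp.plantation_overlap(class_map, [box(0, 3, 4, 4)])  # top row
        fr = dict(zip(out["class"], out["area_fraction"]))
        assert fr["unsuitable"] == 1.0 and fr["high"] == 0.0

    def test_two_equal_plantations_split_evenly(self, class_map):
        polys = [box(0, 3, 2, 4), box(0, 2, 2, 3)]  # 2 cells row0, 2 cells row1
        out = rp.plantation_overlap(class_map, polys)
        fr = dict(zip(out["class"], out["area_fraction"]))
        assert fr["unsuitable"] == 0.5 and fr["marginal"] == 0.5

    def test_fractions_sum_to_one(self, class_map):
        out = rp.plantation_overlap(class_map, [box(0.2, 0.2, 3.7, 3.7)],
                                    target_resolution=0.1)
        assert out["area_fraction"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_invariant_to_vertex_order_and_splitting(self, class_map):
        poly = box(0, 1, 3, 4)
        reversed_poly = poly.reverse()
        split = [box(0, 1, 3, 2.5), box(0, 2.5, 3, 4)]
        a = rp.plantation_overlap(class_map, [poly])["area_fraction"]
        b = rp.plantation_overlap(class_map, [reversed_poly])["area_fraction"]
        c = rp.plantation_overlap(class_map, split)["area_fraction"]
        np.testing.assert_allclose(a, b, atol=1e-15)
        np.testing.assert_allclose(a, c, atol=1e-15)
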