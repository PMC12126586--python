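import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wetlandscape.grids_io import GridSpec, SYNTHETIC_CRS
from wetlandscape.wfpi import (
    aggregate_population,
    fuzzy_and_overlay,
    fuzzy_linear_membership,
    fuzzy_or_overlay,
    threat_summary,
    wetland_area_per_cell,
)

from conftest import make_layer


def grid(nrows=2, ncols=2, cell=10_000.0):
    return GridSpec(cell, (0.0, nrows * cell), nrows, ncols, SYNTHETIC_CRS, fine_factor=10)


class TestAggregatePopulation:
    def test_sum_of_block(self):
        pop = make_layer(np.full((10, 10), 50.0), cell_size=1000.0)
        g = GridSpec(10_000.0, (0.0, 10_000.0), 1, 1, SYNTHETIC_CRS, fine_factor=10)
        assert aggregate_population(pop, g, "sum").values[0, 0] == pytest.approx(5000.0)

    def test_mean_of_block(self):
        pop = make_layer(np.full((10, 10), 50.0), cell_size=1000.0)
        g = GridSpec(10_000.0, (0.0, 10_000.0), 1, 1, SYNTHETIC_CRS, fine_factor=10)
        assert aggregate_population(pop, g, "mean").values[0, 0] == pytest.approx(50.0)

    def test_nodata_treated_as_zero_with_warning(self):
        pop = make_layer(np.full((10, 10), np.nan), cell_size=1000.0, nodata=np.nan)
        g = GridSpec(10_000.0, (0.0, 10_000.0), 1, 1, SYNTHETIC_CRS, fine_factor=10)
        with pytest.warns(UserWarning, match="nodata"):
            out = aggregate_population(pop, g, "sum")
        assert out.values[0, 0] == 0.0

    def test_negative_population_rejected(self):
        pop = make_layer(np.array([[-1.0]]), cell_size=1000.0)
        g = GridSpec(1000.0, (0.0, 1000.0), 1, 1, SYNTHETIC_CRS, fine_factor=1)
        with pytest.raises(ValueError, match="negative"):
            aggregate_population(pop, g)


class TestFuzzyMembership:
    def test_midpoint_and_endpoints(self):
        layer = make_layer(np.array([[0.0, 50.0, 100.0]]), cell_size=10_000.0)
        mu = fuzzy_linear_membership(layer, bounds="auto").layer.values
        np.testing.assert_allclose(mu, [[0.0, 0.5, 1.0]])

    def test_explicit_bounds_clamp(self):
        layer = make_layer(np.array([[5.0, 25.0]]), cell_size=10_000.0)
        mem = fuzzy_linear_membership(layer, bounds=(10.0, 20.0))
        np.testing.assert_allclose(mem.layer.values, [[0.0, 1.0]])
        assert mem.bounds == (10.0, 20.0)

    def test_constant_layer_rejected_by_name(self):
        layer = make_layer(np.full((2, 2), 7.0), cell_size=10_000.0)
        with pytest.raises(ValueError, match="population"):
            fuzzy_linear_membership(layer, source="population")

    @settings(max_examples=100, deadline=None)
    @given(scale=st.floats(1e-3, 1e3), offset=st.floats(0, 100))
    def test_auto_bounds_affine_invariance(self, scale, offset):
        """Membership under auto bounds is unchanged by any positive affine
        rescaling of the raw layer."""
        raw = np.array([[1.0, 4.0], [2.0, 9.0]])
        base = fuzzy_linear_membership(make_layer(raw, cell_size=10_000.0)).layer.values
        scaled = fuzzy_linear_membership(
            make_layer(scale * raw + offset, cell_size=10_000.0)
        ).layer.values
        np.testing.assert_allclose(base, scaled, atol=1e-9)


class TestFuzzyOverlay:
    def mem(self, vals):
        return fuzzy_linear_membership(
            make_layer(np.asarray(vals, dtype=float), cell_size=10_000.0), bounds=(0.0, 1.0)
        )

    def test_minimum_by_definition(self):
        out = fuzzy_and_overlay(self.mem([[1.0, 0.3]]), self.mem([[1.0, 0.8]]))
        np.testing.assert_allclose(out.values, [[1.0, 0.3]])

    def test_commutative(self):
        rng = np.random.default_rng(0)
        a, b = self.mem(rng.random((5, 5))), self.mem(rng.random((5, 5)))
        np.testing.assert_array_equal(
            fuzzy_and_overlay(a, b).values, fuzzy_and_overlay(b, a).values
        )

    def test_result_bounded_by_both_inputs(self):
        rng = np.random.default_rng(1)
        a, b = self.mem(rng.random((6, 6))), self.mem(rng.random((6, 6)))
        out = fuzzy_and_overlay(a, b).values
        assert (out <= a.layer.values + 1e-12).all()
        assert (out <= b.layer.values + 1e-12).all()
        assert np.array_equal(out == 1.0, (a.layer.values == 1.0) & (b.layer.values == 1.0))

    def test_or_is_maximum(self):
        out = fuzzy_or_overlay(self.mem([[0.3]]), self.mem([[0.8]]))
        assert out.values[0, 0] == pytest.approx(0.8)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="co-registered"):
            fuzzy_and_overlay(self.mem(np.zeros((2, 2))), self.mem(np.zeros((3, 3))))

    def test_nodata_propagates(self):
        a = self.mem([[0.5, np.nan]])
        a.layer.nodata = np.nan
        out = fuzzy_and_overlay(a, self.mem([[0.5, 0.5]]))
        assert np.isnan(out.values[0, 1])


class TestThreatSummary:
    def layers(self, wfpi_vals, area_vals):
        return (
            make_layer(np.asarray(wfpi_vals, dtype=float), cell_size=10_000.0),
            make_layer(np.asarray(area_vals, dtype=float), cell_size=10_000.0),
        )

    def test_all_zero_index(self):
        w, a = self.layers([[0.0, 0.0]], [[5.0, 7.0]])
        s = threat_summary(w, a)
        assert s.heavy_km2 == 0.0 and s.moderate_km2 == 0.0 and s.low_km2 == 12.0

    def test_heavy_cell_area(self):
        w, a = self.layers([[0.6]], [[12.0]])
        assert threat_summary(w, a).heavy_km2 == pytest.approx(12.0)

    def test_boundary_exactly_half_is_moderate(self):
        w, a = self.layers([[0.5]], [[3.0]])
        s = threat_summary(w, a)
        assert s.moderate_km2 == pytest.approx(3.0) and s.heavy_km2 == 0.0

    def test_boundary_exactly_lower_is_moderate(self):
        w, a = self.layers([[0.3]], [[2.0]])
        assert threat_summary(w, a).moderate_km2 == pytest.approx(2.0)

    def test_bad_thresholds_rejected(self):
        w, a = self.layers([[0.1]], [[1.0]])
        with pytest.raises(ValueError):
            threat_summary(w, a, thresholds=(0.5, 0.3))

    def test_top_cells_ranked_by_index(self):
        w, a = self.layers([[0.2, 0.9], [0.7, 0.1]], [[1.0, 1.0], [1.0, 1.0]])
        s = threat_summary(w, a, top_n=2)
        assert list(s.top_cells["wfpi"]) == [0.9, 0.7]


class TestMonotonicity:
    def test_more_fragments_never_lower_wfpi(self):
        """With fixed membership bounds and fixed population, increasing a
        cell's fragment count cannot decrease its WFPI."""
        frag = np.array([[10.0, 40.0], [5.0, 80.0]])
        pop = np.array([[100.0, 900.0], [50.0, 400.0]])
        bounds_f, bounds_p = (0.0, 100.0), (0.0, 1000.0)
        f_layer = make_layer(frag, cell_size=10_000.0)
        p_mem = fuzzy_linear_membership(make_layer(pop, cell_size=10_000.0), bounds=bounds_p)
        base = fuzzy_and_overlay(
            fuzzy_linear_membership(f_layer, bounds=bounds_f), p_mem
        ).values
        for bump in (1.0, 10.0, 50.0):
            bumped = frag.copy()
            bumped[0, 0] += bump
            out = fuzzy_and_overlay(
                fuzzy_linear_membership(make_layer(bumped, cell_size=10_000.0), bounds=bounds_f),
                p_mem,
            ).values
            assert out[0, 0] >= base[0, 0] - 1e-12
            np.testing.assert_allclose(out[0, 1:], base[0, 1:])


def test_wetland_area_per_cell():
    vals = np.zeros((20, 20), dtype=np.int16)
    vals[:2, :2] = 1  # 4 wetland cells of 100 m → 0.04 km²
    layer = make_layer(vals, cell_size=100.0)
    from wetlandscape.grids_io import make_grid

    out = wetland_area_per_cell(layer, make_grid(layer, 1000.0))
    assert out.values[0, 0] == pytest.approx(0.04)
    assert out.values.sum() == pytest.approx(0.04)
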