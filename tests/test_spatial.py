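"""Standardized-cell projection, heatmaps, demographs, stats, and LOESS."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from septrack.spatial import (
    LoessRegression,
    build_demograph,
    build_heatmap,
    compute_localization_stats,
    diff_heatmap,
    loess_trend,
    normalize_to_standard_cell,
)


def locs_df(xs, ys):
    return pd.DataFrame({"x_um": xs, "y_um": ys})


class TestNormalize:
    def test_cell_midpoint_maps_to_origin(self, one_cell):
        cx, cy = one_cell.center
        pts = normalize_to_standard_cell(locs_df([cx], [cy]), one_cell)
        assert pts["u"][0] == pytest.approx(0.0, abs=1e-9)
        assert pts["v"][0] == pytest.approx(0.0, abs=1e-9)
        assert pts["s_um"][0] == pytest.approx(0.0, abs=1e-9)

    def test_pole_maps_to_end(self, one_cell):
        pts = normalize_to_standard_cell(
            locs_df(one_cell.poles[:, 0], one_cell.poles[:, 1]), one_cell
        )
        assert sorted(np.abs(pts["u"])) == pytest.approx([1.5, 1.5])

    def test_membrane_maps_to_half_width(self, one_cell):
        cx, cy = one_cell.center
        pts = normalize_to_standard_cell(
            locs_df([cx, cx], [cy + 0.5, cy - 0.5]), one_cell
        )
        assert sorted(pts["v"]) == pytest.approx([-0.5, 0.5], abs=0.02)

    def test_uniform_axial_points_stay_uniform(self, one_cell, rng):
        cx, cy = one_cell.center
        xs = rng.uniform(-2.0, 2.0, size=5000) + cx
        pts = normalize_to_standard_cell(locs_df(xs, np.full(5000, cy)), one_cell)
        counts, _ = np.histogram(pts["u"], bins=10, range=(-1.5, 1.5))
        _, p = sps.chisquare(counts)
        assert p > 0.01

    def test_degenerate_poles_rejected(self, one_cell):
        bad = type(one_cell)(
            cell_id="bad", vertices=one_cell.vertices,
            poles=np.tile(one_cell.center, (2, 1)), length=one_cell.length,
        )
        with pytest.raises(ValueError, match="poles"):
            normalize_to_standard_cell(locs_df([0.0], [0.0]), bad)

    def test_orientation_convention(self, one_cell, rng):
        # plant 80/20 polar asymmetry: the sparse pole must end at negative u
        cx, cy = one_cell.center
        xs = np.concatenate([rng.normal(cx + 1.8, 0.1, 80), rng.normal(cx - 1.8, 0.1, 20)])
        pts = normalize_to_standard_cell(locs_df(xs, np.full(100, cy)), one_cell)
        assert np.sum(pts["u"] > 0) >= np.sum(pts["u"] < 0)


class TestHeatmap:
    def test_normalization(self, rng):
        pts = pd.DataFrame({"u": rng.uniform(-1.5, 1.5, 500),
                            "v": rng.uniform(-0.5, 0.5, 500)})
        grid = build_heatmap(pts)
        assert grid.shape == (30, 10)
        assert grid.sum() == pytest.approx(1.0, abs=1e-9)

    def test_single_pixel_degenerate(self):
        pts = pd.DataFrame({"u": [0.01] * 7, "v": [0.01] * 7})
        grid = build_heatmap(pts)
        assert grid.max() == pytest.approx(1.0)
        assert np.count_nonzero(grid) == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_heatmap(pd.DataFrame({"u": [], "v": []}))

    def test_self_difference_is_zero(self, rng):
        pts = pd.DataFrame({"u": rng.uniform(-1.5, 1.5, 200),
                            "v": rng.uniform(-0.5, 0.5, 200)})
        grid = build_heatmap(pts)
        assert np.all(diff_heatmap(grid, grid) == 0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            diff_heatmap(np.zeros((30, 10)), np.zeros((10, 30)))


class TestDemograph:
    def test_one_cell_one_row(self, rng):
        pts = pd.DataFrame({"cell_id": "c0", "s_um": rng.uniform(-1, 1, 50)})
        mat, order = build_demograph(pts, {"c0": 2.0})
        assert mat.shape[0] == 1
        assert order == ["c0"]
        assert mat.max() == pytest.approx(1.0)

    def test_rows_sorted_by_length(self, rng):
        lengths = {f"c{i}": L for i, L in enumerate([3.0, 1.5, 2.2, 2.9])}
        pts = pd.concat(
            [
                pd.DataFrame({"cell_id": cid, "s_um": rng.uniform(-L / 2, L / 2, 30)})
                for cid, L in lengths.items()
            ]
        )
        mat, order = build_demograph(pts, lengths)
        assert [lengths[c] for c in order] == sorted(lengths.values())

    def test_septal_cluster_peaks_at_midcell(self, rng):
        pts = pd.DataFrame({"cell_id": "c0", "s_um": rng.normal(0, 0.05, 200)})
        mat, _ = build_demograph(pts, {"c0": 3.0}, binwidth=0.1)
        assert abs(np.argmax(mat[0]) - mat.shape[1] / 2) <= 1


class TestLocalizationStats:
    def test_uniform_area_fractions(self, one_cell, rng):
        cx, cy = one_cell.center
        xs = rng.uniform(-2.0, 2.0, 20000) + cx
        pts = normalize_to_standard_cell(locs_df(xs, np.full(20000, cy)), one_cell)
        st = compute_localization_stats(pts, one_cell)
        assert st.midcell_prop == pytest.approx(0.2, abs=0.02)
        assert st.polar_prop == pytest.approx(0.4, abs=0.02)
        # region proportions partition the cell
        rest = 1.0 - st.midcell_prop - st.polar_prop
        assert 0 <= rest <= 1

    def test_all_points_at_one_pole(self, one_cell, rng):
        cx, cy = one_cell.center
        xs = rng.normal(cx + 1.9, 0.05, 300)
        pts = normalize_to_standard_cell(locs_df(xs, np.full(300, cy)), one_cell)
        st = compute_localization_stats(pts, one_cell)
        assert st.polar_ratio == 0.0
        assert st.polar_prop == pytest.approx(1.0, abs=0.02)

    def test_planted_polar_asymmetry(self, one_cell, rng):
        cx, cy = one_cell.center
        n = 10000
        side = rng.random(n) < 0.6
        xs = np.where(side, rng.normal(1.85, 0.05, n), rng.normal(-1.85, 0.05, n)) + cx
        pts = normalize_to_standard_cell(locs_df(xs, np.full(n, cy)), one_cell)
        st = compute_localization_stats(pts, one_cell)
        assert st.polar_ratio == pytest.approx(40 / 60, abs=0.05)

    def test_max_location_tie_broken_toward_midcell(self, one_cell):
        # two equally-populated bins, one nearer midcell
        pts = pd.DataFrame(
            {"u": [0.0] * 4, "v": [0.0] * 4, "s_um": [0.31, 0.31, 1.51, 1.51]}
        )
        st = compute_localization_stats(pts, one_cell)
        assert abs(st.max_location) < 1.0

    def test_empty_cell_rejected(self, one_cell):
        with pytest.raises(ValueError):
            compute_localization_stats(pd.DataFrame({"u": [], "v": [], "s_um": []}),
                                       one_cell)


class TestLoess:
    def test_constant_reproduced(self, rng):
        x = rng.uniform(0, 10, 50)
        grid, fitted, se = loess_trend(x, np.full(50, 3.7))
        assert fitted == pytest.approx(np.full(100, 3.7), abs=1e-9)
        assert np.all(se >= 0)

    def test_linear_exact(self, rng):
        x = np.sort(rng.uniform(0, 10, 60))
        grid, fitted, _ = loess_trend(x, 2.0 * x, span=0.75,
                                      grid=np.linspace(2, 8, 20))
        assert fitted == pytest.approx(2.0 * np.linspace(2, 8, 20), abs=1e-6)

    def test_span_one_is_global_weighted_fit(self, rng):
        x = np.concatenate([np.full(15, 1.0), np.full(15, 1.0 + 1e-9)])
        y = rng.normal(size=30)
        grid, fitted, _ = loess_trend(x, y, span=1.0, grid=np.array([1.0]))
        assert np.isfinite(fitted[0])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            LoessRegression().fit(np.arange(5), np.arange(5))

    def test_noisy_quadratic_trend_tracked(self, rng):
        x = np.sort(rng.uniform(-2, 2, 200))
        y = x**2 + rng.normal(0, 0.1, 200)
        est = LoessRegression(span=0.3).fit(x, y)
        pred = est.predict([0.0, 1.5])
        assert abs(pred[0] - 0.0) < 0.15
        assert abs(pred[1] - 2.25) < 0.25
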