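import numpy as np
import pandas as pd
import pytest

from tipc import (
    curve_auc, dichotomize, g_cross, l_cross, metric_table,
    morisita_horn, nnd_summary,
)
from tipc.comparators import RadialCurve, _ripley_weights

from conftest import make_cells


def cells_of(points):
    """Build a cell table from {compartment: [(x, y), ...]}."""
    rows = [
        {"sample_id": "s", "x": x, "y": y, "compartment": comp}
        for comp, pts in points.items() for x, y in pts
    ]
    return pd.DataFrame(rows)


class TestNnd:
    def test_three_four_five_triangle(self):
        cells = cells_of({
            "tumor": [(0.0, 0.0), (0.0, 4.0)],
            "immune": [(3.0, 0.0), (3.0, 4.0), (0.0, 9.0)],
        })
        # immune->nearest tumor distances: 3, 3, 5 -> median 3
        assert nnd_summary(cells) == 3.0

    def test_coincident_points(self):
        cells = cells_of({"tumor": [(1.0, 1.0)], "immune": [(1.0, 1.0), (1.0, 1.0)]})
        assert nnd_summary(cells) == 0.0

    def test_matches_quadratic_oracle(self):
        cells = make_cells(400, seed=21)
        imm = cells[cells.compartment == "immune"][["x", "y"]].to_numpy()
        tum = cells[cells.compartment == "tumor"][["x", "y"]].to_numpy()
        d = np.sqrt(((imm[:, None, :] - tum[None, :, :]) ** 2).sum(axis=2)).min(axis=1)
        assert nnd_summary(cells) == pytest.approx(np.median(d), abs=1e-12)

    def test_missing_compartment_raises(self):
        cells = cells_of({"tumor": [(0.0, 0.0)]})
        with pytest.raises(ValueError, match="immune"):
            nnd_summary(cells)


class TestMorisitaHorn:
    def test_identical_distributions_score_one(self):
        pts = [(0.2, 0.2), (7.3, 1.1), (12.0, 9.9), (3.3, 14.2)]
        cells = cells_of({"tumor": pts, "immune": pts})
        assert morisita_horn(cells) == pytest.approx(1.0)

    def test_disjoint_squares_score_zero(self):
        cells = cells_of({"tumor": [(0.0, 0.0), (1.0, 1.0)],
                          "immune": [(50.0, 50.0), (51.0, 51.0)]})
        assert morisita_horn(cells) == 0.0

    def test_hand_computed_toy_value(self):
        # 1-µm squares; immune counts (1, 2, 0), tumor counts (1, 1, 2)
        cells = cells_of({
            "immune": [(0.1, 0.1), (1.1, 0.1), (1.2, 0.1)],
            "tumor": [(0.1, 0.1), (1.1, 0.1), (2.1, 0.1), (2.2, 0.1)],
        })
        got = morisita_horn(cells, grid_size=1.0)
        # MH = 2*3 / ((5/9 + 6/16) * 3 * 4)
        assert got == pytest.approx(2 * 3 / ((5 / 9 + 6 / 16) * 12), abs=1e-12)
        assert got == pytest.approx(0.5373134328358209, abs=1e-12)

    def test_symmetric_in_the_two_types(self):
        cells = make_cells(300, seed=22)
        swapped = cells.replace({"compartment": {"immune": "tumor", "tumor": "immune"}})
        assert morisita_horn(cells) == pytest.approx(morisita_horn(swapped), abs=1e-12)

    def test_stroma_pair_and_errors(self):
        cells = make_cells(200, seed=23)
        v = morisita_horn(cells, pair="immune_vs_stroma")
        assert 0.0 <= v <= 1.0 + 1e-12
        with pytest.raises(ValueError, match="pair"):
            morisita_horn(cells, pair="tumor_vs_stroma")
        with pytest.raises(ValueError, match="positive"):
            morisita_horn(cells, grid_size=0.0)


class TestGCross:
    def test_step_function_on_known_distances(self):
        cells = cells_of({
            "tumor": [(0.0, 0.0), (0.0, 30.0), (30.0, 0.0), (30.0, 30.0)],
            "immune": [(2.0, 0.0), (0.0, 25.0), (30.0, 8.0), (24.0, 30.0)],
        })
        # tumor->nearest-immune distances: 2, 5, 6 (wait: hand-check below)
        tum = np.array([(0, 0), (0, 30), (30, 0), (30, 30)], float)
        imm = np.array([(2, 0), (0, 25), (30, 8), (24, 30)], float)
        nnd = np.sqrt(((tum[:, None] - imm[None]) ** 2).sum(-1)).min(1)
        curve = g_cross(cells, r_grid=np.arange(0, 21, 1.0))
        for r, v in zip(curve.r, curve.values):
            assert v == np.mean(nnd <= r)

    def test_matches_ecdf_oracle_random(self):
        cells = make_cells(500, seed=24)
        curve = g_cross(cells)
        tum = cells[cells.compartment == "tumor"][["x", "y"]].to_numpy()
        imm = cells[cells.compartment == "immune"][["x", "y"]].to_numpy()
        nnd = np.sqrt(((tum[:, None] - imm[None]) ** 2).sum(-1)).min(1)
        expected = np.array([(nnd <= r).mean() for r in curve.r])
        assert np.allclose(curve.values, expected)

    def test_border_correction_reduced_sample(self):
        cells = make_cells(500, seed=25, window=(200, 200))
        raw = g_cross(cells).values
        corr = g_cross(cells, correction="border")
        tum = cells[cells.compartment == "tumor"][["x", "y"]].to_numpy()
        imm = cells[cells.compartment == "immune"][["x", "y"]].to_numpy()
        nnd = np.sqrt(((tum[:, None] - imm[None]) ** 2).sum(-1)).min(1)
        xmin, ymin = cells.x.min(), cells.y.min()
        xmax, ymax = cells.x.max(), cells.y.max()
        border = np.minimum.reduce([tum[:, 0] - xmin, xmax - tum[:, 0],
                                    tum[:, 1] - ymin, ymax - tum[:, 1]])
        for r, v in zip(corr.r, corr.values):
            keep = border >= r
            assert v == pytest.approx(np.mean(nnd[keep] <= r))

    def test_rejects_bad_args(self):
        cells = make_cells(50, seed=26)
        with pytest.raises(ValueError, match="correction"):
            g_cross(cells, correction="torus")
        with pytest.raises(ValueError, match="empty"):
            g_cross(cells, r_grid=[])


class TestRipleyWeights:
    def test_interior_point_weight_one(self):
        pts = np.array([[50.0, 50.0]])
        w = _ripley_weights(pts, np.array([5.0]), (0.0, 0.0, 100.0, 100.0))
        assert w[0] == pytest.approx(1.0)

    def test_single_edge_crossing(self):
        # point 1 µm from the left edge, circle radius 2: the arc outside
        # subtends 2*arccos(1/2) = 2pi/3, so the weight is 1/(1 - 1/3) = 1.5
        pts = np.array([[1.0, 50.0]])
        w = _ripley_weights(pts, np.array([2.0]), (0.0, 0.0, 100.0, 100.0))
        assert w[0] == pytest.approx(1.5)

    def test_corner_point_weight_four(self):
        # circle centered exactly on a corner: quarter inside
        pts = np.array([[0.0, 0.0]])
        w = _ripley_weights(pts, np.array([3.0]), (0.0, 0.0, 100.0, 100.0))
        assert w[0] == pytest.approx(4.0)


class TestLCross:
    @staticmethod
    def split(cells):
        tum = cells[cells.compartment == "tumor"][["x", "y"]].to_numpy()
        imm = cells[cells.compartment == "immune"][["x", "y"]].to_numpy()
        return tum, imm

    def test_translation_matches_double_sum_oracle(self):
        cells = make_cells(60, seed=27, window=(120, 120))
        tum, imm = self.split(cells)
        xmin, xmax = cells.x.min(), cells.x.max()
        ymin, ymax = cells.y.min(), cells.y.max()
        W, H = xmax - xmin, ymax - ymin
        A = W * H
        curve = l_cross(cells, estimator="translation")
        for r in (5.0, 12.5, 20.0):
            k = 0.0
            for t in tum:
                for i in imm:
                    dx, dy = abs(t[0] - i[0]), abs(t[1] - i[1])
                    if np.hypot(dx, dy) <= r:
                        k += A / ((W - dx) * (H - dy))
            k *= A / (len(tum) * len(imm))
            expected = np.sqrt(k / np.pi)
            got = curve.values[np.flatnonzero(curve.r == r)[0]]
            assert got == pytest.approx(expected, rel=1e-10)

    def test_isotropic_matches_weighted_double_sum_oracle(self):
        cells = make_cells(60, seed=28, window=(120, 120))
        tum, imm = self.split(cells)
        xmin, xmax = cells.x.min(), cells.x.max()
        ymin, ymax = cells.y.min(), cells.y.max()
        A = (xmax - xmin) * (ymax - ymin)
        curve = l_cross(cells, estimator="isotropic")
        r = 15.0
        k = 0.0
        for t in tum:
            for i in imm:
                d = np.hypot(t[0] - i[0], t[1] - i[1])
                if 0 < d <= r or (d == 0 and True):
                    w = _ripley_weights(t[None, :], np.array([d]),
                                        (xmin, ymin, xmax, ymax))[0]
                    k += w
        k *= A / (len(tum) * len(imm))
        got = curve.values[np.flatnonzero(curve.r == r)[0]]
        assert got == pytest.approx(np.sqrt(k / np.pi), rel=1e-10)

    def test_border_matches_reduced_sample_oracle(self):
        cells = make_cells(80, seed=29, window=(150, 150))
        tum, imm = self.split(cells)
        xmin, xmax = cells.x.min(), cells.x.max()
        ymin, ymax = cells.y.min(), cells.y.max()
        A = (xmax - xmin) * (ymax - ymin)
        lam_i = len(imm) / A
        border = np.minimum.reduce([tum[:, 0] - xmin, xmax - tum[:, 0],
                                    tum[:, 1] - ymin, ymax - tum[:, 1]])
        curve = l_cross(cells, estimator="border")
        for r in (5.0, 10.0, 20.0):
            keep = border >= r
            cnt = sum(
                np.hypot(t[0] - i[0], t[1] - i[1]) <= r
                for t, k in zip(tum, keep) if k for i in imm
            )
            expected = np.sqrt(cnt / (lam_i * keep.sum()) / np.pi)
            got = curve.values[np.flatnonzero(curve.r == r)[0]]
            assert got == pytest.approx(expected, rel=1e-10)

    def test_csr_tracks_the_diagonal(self):
        from tipc.synthetic import simulate_csr_pair

        cells = simulate_csr_pair(0.004, 0.004, window=(400.0, 400.0), seed=30)
        for est in ("isotropic", "translation", "border"):
            curve = l_cross(cells, estimator=est)
            sel = curve.r >= 5
            rel = np.abs(curve.values[sel] - curve.r[sel]) / curve.r[sel]
            assert rel.max() < 0.15  # single realization, loose bound

    def test_rejects_bad_args(self):
        cells = make_cells(50, seed=31, window=(30, 30))
        with pytest.raises(ValueError, match="estimator"):
            l_cross(cells, estimator="torus")
        with pytest.raises(ValueError, match="half the shorter"):
            l_cross(cells, estimator="isotropic")  # default grid to 20 > 30/2 approx


class TestCurveAuc:
    def test_constant_curve(self):
        r = np.arange(0, 20.5, 0.5)
        c = RadialCurve(r=r, values=np.full_like(r, 0.4), estimator="x")
        assert curve_auc(c, 15.0) == pytest.approx(6.0)

    def test_linear_curve_quadrature_exact(self):
        r = np.arange(0, 20.5, 0.5)
        c = RadialCurve(r=r, values=2.0 * r, estimator="x")
        assert curve_auc(c, 20.0) == pytest.approx(400.0)

    def test_r_max_between_grid_points_interpolates(self):
        r = np.array([0.0, 10.0, 20.0])
        c = RadialCurve(r=r, values=np.array([0.0, 1.0, 1.0]), estimator="x")
        assert curve_auc(c, 15.0) == pytest.approx(5.0 + 5.0)

    def test_r_max_beyond_grid_rejected(self):
        c = RadialCurve(r=np.array([0.0, 5.0]), values=np.zeros(2), estimator="x")
        with pytest.raises(ValueError, match="beyond"):
            curve_auc(c, 20.0)


class TestDichotomize:
    def test_linear_quantile_cutoff(self):
        labels, cutoff = dichotomize(pd.Series([1.0, 2, 3, 4, 5]), 0.8)
        assert cutoff == pytest.approx(4.2)
        assert list(labels) == ["low", "low", "low", "low", "high"]

    def test_all_ties_all_low(self):
        labels, cutoff = dichotomize(pd.Series([3.0, 3.0, 3.0]), 0.8)
        assert (labels == "low").all()

    def test_errors(self):
        with pytest.raises(ValueError, match="two samples"):
            dichotomize(pd.Series([1.0]))
        with pytest.raises(ValueError, match="percentile"):
            dichotomize(pd.Series([1.0, 2.0]), 1.5)


class TestMetricTable:
    def test_columns_and_nan_policy(self):
        good = make_cells(300, seed=32, sample_id="good")
        cold = make_cells(300, seed=33, sample_id="cold", weights=(0.5, 0.5, 0.0))
        df = metric_table(pd.concat([good, cold], ignore_index=True))
        df = df.set_index("sample_id")
        expected_cols = {"nnd_median", "mh_tumor", "mh_stroma", "gcross_auc",
                         "lcross_auc_isotropic", "lcross_auc_translation",
                         "lcross_auc_border"}
        assert expected_cols <= set(df.columns)
        assert df.loc["good"].notna().all()
        assert df.loc["cold"].isna().all()

    def test_values_match_direct_calls(self):
        cells = make_cells(300, seed=34, sample_id="only")
        df = metric_table(cells).set_index("sample_id")
        assert df.loc["only", "nnd_median"] == pytest.approx(nnd_summary(cells))
        assert df.loc["only", "mh_tumor"] == pytest.approx(morisita_horn(cells))
        assert df.loc["only", "gcross_auc"] == pytest.approx(
            curve_auc(g_cross(cells), 20.0))
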