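"""Classical spatial metrics used as benchmarks.

These are the single-number summaries the six-parameter signature is
compared against: nearest-neighbor distance (NND), the Morisita-Horn
co-localization index on a square grid, and the cross-type G and L
functions of spatial point pattern analysis with an AUC summary at small
radii. All operate on one sample's cell coordinates; the observation
window for edge corrections is the bounding box of the sample's cells.

G-cross(r): the probability that a tumor cell has at least one immune
cell within distance r (the ECDF of tumor-to-nearest-immune distances).
K-cross(r): the expected number of immune cells within r of a tumor
cell, scaled by immune intensity; L(r) = sqrt(K(r) / pi) equals r under
complete spatial randomness. Three classical edge-corrected K estimators
are provided: Ripley's isotropic correction, the translation correction
and the border (reduced-sample) method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

DEFAULT_R_GRID = np.arange(0.0, 20.5, 0.5)

L_ESTIMATORS = ("isotropic", "translation", "border")
G_CORRECTIONS = ("raw", "border")


@dataclass
class RadialCurve:
    """A radial summary function sampled on an increasing r grid (µm)."""

    r: np.ndarray
    values: np.ndarray
    estimator: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"r": self.r, "value": self.values, "estimator": self.estimator})


def _split_types(cells: pd.DataFrame, type_a: str, type_b: str):
    pts = {}
    for t in (type_a, type_b):
        sub = cells[cells["compartment"] == t]
        if len(sub) == 0:
            raise ValueError(f"sample has no {t!r} cells")
        pts[t] = np.column_stack([sub["x"].to_numpy(float), sub["y"].to_numpy(float)])
    return pts[type_a], pts[type_b]


def _window(cells: pd.DataFrame):
    x, y = cells["x"].to_numpy(float), cells["y"].to_numpy(float)
    return float(x.min()), float(y.min()), float(x.max()), float(y.max())


def nnd_summary(cells: pd.DataFrame) -> float:
    """Median distance from each immune cell to its nearest tumor cell (µm)."""
    immune, tumor = _split_types(cells, "immune", "tumor")
    d, _ = cKDTree(tumor).query(immune, k=1)
    return float(np.median(d))


def morisita_horn(
    cells: pd.DataFrame, grid_size: float = 5.0, pair: str = "immune_vs_tumor"
) -> float:
    """Morisita-Horn co-localization index on a square grid.

    The window is tessellated into ``grid_size`` x ``grid_size`` µm
    squares anchored at the bounding-box minimum; with per-square counts
    ``x_i``/``y_i`` of the two cell types,

        MH = 2 sum(x_i y_i) / ((sum(x_i^2)/X^2 + sum(y_i^2)/Y^2) X Y)

    MH is 1 for identically distributed counts and 0 for types occupying
    disjoint squares; it is symmetric in the two types.
    """
    if grid_size <= 0:
        raise ValueError("grid_size must be positive")
    other = {"immune_vs_tumor": "tumor", "immune_vs_stroma": "stroma"}.get(pair)
    if other is None:
        raise ValueError(f"unknown pair {pair!r}")
    a, b = _split_types(cells, "immune", other)
    xmin, ymin, xmax, ymax = _window(cells)
    ncol = int(np.floor((xmax - xmin) / grid_size)) + 1
    nrow = int(np.floor((ymax - ymin) / grid_size)) + 1

    def counts(pts):
        ix = np.floor((pts[:, 0] - xmin) / grid_size).astype(np.int64)
        iy = np.floor((pts[:, 1] - ymin) / grid_size).astype(np.int64)
        ix = np.clip(ix, 0, ncol - 1)  # points exactly on the max edge
        iy = np.clip(iy, 0, nrow - 1)
        return np.bincount(iy * ncol + ix, minlength=ncol * nrow).astype(np.float64)

    xc, yc = counts(a), counts(b)
    X, Y = xc.sum(), yc.sum()
    denom = (np.sum(xc**2) / X**2 + np.sum(yc**2) / Y**2) * X * Y
    return float(2.0 * np.sum(xc * yc) / denom)


def g_cross(cells: pd.DataFrame, r_grid=None, correction: str = "raw") -> RadialCurve:
    """Cross-type nearest-neighbor distance distribution, tumor -> immune.

    ``raw`` is the plain ECDF of tumor-to-nearest-immune distances; with
    ``border`` correction, tumor cells closer than r to the window edge
    are excluded at that r (reduced-sample estimator; NaN where no tumor
    cell survives the exclusion).
    """
    if correction not in G_CORRECTIONS:
        raise ValueError(f"unknown correction {correction!r}; expected one of {G_CORRECTIONS}")
    r = DEFAULT_R_GRID if r_grid is None else np.asarray(r_grid, dtype=float)
    if len(r) == 0:
        raise ValueError("empty r grid")
    tumor, immune = _split_types(cells, "tumor", "immune")
    nnd, _ = cKDTree(immune).query(tumor, k=1)
    if correction == "raw":
        values = np.searchsorted(np.sort(nnd), r, side="right") / len(nnd)
    else:
        xmin, ymin, xmax, ymax = _window(cells)
        border = np.minimum.reduce(
            [tumor[:, 0] - xmin, xmax - tumor[:, 0], tumor[:, 1] - ymin, ymax - tumor[:, 1]]
        )
        values = np.empty(len(r))
        for i, ri in enumerate(r):
            keep = border >= ri
            values[i] = np.mean(nnd[keep] <= ri) if keep.any() else np.nan
    return RadialCurve(r=r, values=values, estimator=f"gcross_{correction}")


def _ripley_weights(pts: np.ndarray, d: np.ndarray, window) -> np.ndarray:
    """Isotropic edge-correction weights for circles of radius d at pts.

    Closed form for a rectangular window, valid while d is at most half
    the shorter window side (so a circle can cross at most two adjacent
    edges): the weight is the reciprocal of the fraction of the circle's
    circumference lying inside the window.
    """
    xmin, ymin, xmax, ymax = window
    d1 = np.minimum(pts[:, 0] - xmin, xmax - pts[:, 0])
    d2 = np.minimum(pts[:, 1] - ymin, ymax - pts[:, 1])
    with np.errstate(invalid="ignore", divide="ignore"):
        a1 = np.where(d1 < d, np.arccos(np.clip(d1 / d, -1.0, 1.0)), 0.0)
        a2 = np.where(d2 < d, np.arccos(np.clip(d2 / d, -1.0, 1.0)), 0.0)
    corner_inside = d1**2 + d2**2 < d**2
    alpha_out = np.where(corner_inside, 0.5 * np.pi + a1 + a2, 2.0 * a1 + 2.0 * a2)
    return 1.0 / (1.0 - alpha_out / (2.0 * np.pi))


def l_cross(cells: pd.DataFrame, r_grid=None, estimator: str = "isotropic") -> RadialCurve:
    """Cross-type Ripley L function, tumor -> immune, on a rectangular window."""
    if estimator not in L_ESTIMATORS:
        raise ValueError(f"unknown estimator {estimator!r}; expected one of {L_ESTIMATORS}")
    r = DEFAULT_R_GRID if r_grid is None else np.asarray(r_grid, dtype=float)
    if len(r) == 0:
        raise ValueError("empty r grid")
    tumor, immune = _split_types(cells, "tumor", "immune")
    window = _window(cells)
    xmin, ymin, xmax, ymax = window
    width, height = xmax - xmin, ymax - ymin
    area = width * height
    if area <= 0:
        raise ValueError("degenerate (zero-area) observation window")
    r_max = float(r.max())
    if estimator == "isotropic" and r_max > 0.5 * min(width, height):
        raise ValueError("isotropic correction requires max r <= half the shorter window side")
    n_t, n_i = len(tumor), len(immune)

    tree = cKDTree(immune)
    neighbor_lists = tree.query_ball_point(tumor, r_max)
    ti = np.concatenate(
        [np.full(len(nb), i, dtype=np.int64) for i, nb in enumerate(neighbor_lists)]
    ) if any(neighbor_lists) else np.empty(0, dtype=np.int64)
    ii = (
        np.concatenate([np.asarray(nb, dtype=np.int64) for nb in neighbor_lists])
        if any(neighbor_lists)
        else np.empty(0, dtype=np.int64)
    )
    if len(ti):
        diff = tumor[ti] - immune[ii]
        dist = np.hypot(diff[:, 0], diff[:, 1])
    else:
        diff = np.empty((0, 2))
        dist = np.empty(0)

    if estimator == "border":
        border = np.minimum.reduce(
            [tumor[:, 0] - xmin, xmax - tumor[:, 0], tumor[:, 1] - ymin, ymax - tumor[:, 1]]
        )
        lam_i = n_i / area
        order = np.argsort(dist)
        dist_s, ti_s = dist[order], ti[order]
        K = np.empty(len(r))
        for j, rj in enumerate(r):
            keep = border >= rj
            m = int(keep.sum())
            if m == 0:
                K[j] = np.nan
                continue
            within = dist_s <= rj
            K[j] = keep[ti_s[within]].sum() / (lam_i * m)
    else:
        if estimator == "isotropic":
            w = _ripley_weights(tumor[ti], dist, window) if len(ti) else np.empty(0)
        else:  # translation
            w = (
                area / ((width - np.abs(diff[:, 0])) * (height - np.abs(diff[:, 1])))
                if len(ti)
                else np.empty(0)
            )
        order = np.argsort(dist)
        dist_s, w_s = dist[order], w[order]
        cum = np.concatenate([[0.0], np.cumsum(w_s)])
        idx = np.searchsorted(dist_s, r, side="right")
        K = area / (n_t * n_i) * cum[idx]

    L = np.sqrt(np.maximum(K, 0.0) / np.pi)
    return RadialCurve(r=r, values=L, estimator=f"lcross_{estimator}")


def curve_auc(curve: RadialCurve, r_max: float = 20.0) -> float:
    """Trapezoidal area under a radial curve over [0, r_max]."""
    r, v = curve.r, curve.values
    if r_max > r.max() + 1e-9:
        raise ValueError(f"r_max={r_max} beyond the curve's grid (max {r.max()})")
    mask = r <= r_max
    rr, vv = r[mask], v[mask]
    if rr[-1] < r_max:  # close the interval exactly at r_max
        rr = np.append(rr, r_max)
        vv = np.append(vv, np.interp(r_max, r, v))
    return float(np.trapezoid(vv, rr))


def dichotomize(values: pd.Series, percentile: float = 0.8):
    """Split per-sample metric values into high/low at a cohort percentile.

    The cut-off is the linear-interpolation quantile; "high" means
    strictly greater than the cut-off (so an all-ties cohort is all low).

    Returns ``(labels, cutoff)`` where labels is a Series of "high"/"low".
    """
    values = pd.Series(values)
    if len(values) < 2:
        raise ValueError("dichotomize needs at least two samples")
    if not 0 < percentile < 1:
        raise ValueError("percentile must be in (0, 1)")
    cutoff = float(np.quantile(values.to_numpy(float), percentile))
    labels = pd.Series(np.where(values > cutoff, "high", "low"), index=values.index)
    return labels, cutoff


def metric_table(cohort: pd.DataFrame, mh_grid_size: float = 5.0, r_max: float = 20.0) -> pd.DataFrame:
    """All benchmark metrics per sample, as one tidy table.

    Columns: nnd_median, mh_tumor, mh_stroma, gcross_auc and the three
    lcross_auc_* columns. Samples missing a compartment get NaN for the
    affected metrics.
    """
    r_grid = DEFAULT_R_GRID if r_max <= DEFAULT_R_GRID.max() else np.arange(0, r_max + 0.5, 0.5)
    rows = []
    for sample_id, cells in cohort.groupby("sample_id", sort=True):
        row = {"sample_id": str(sample_id)}
        for name, fn in [
            ("nnd_median", lambda c: nnd_summary(c)),
            ("mh_tumor", lambda c: morisita_horn(c, mh_grid_size, "immune_vs_tumor")),
            ("mh_stroma", lambda c: morisita_horn(c, mh_grid_size, "immune_vs_stroma")),
            ("gcross_auc", lambda c: curve_auc(g_cross(c, r_grid), r_max)),
        ]:
            try:
                row[name] = fn(cells)
            except ValueError:
                row[name] = np.nan
        for est in L_ESTIMATORS:
            try:
                row[f"lcross_auc_{est}"] = curve_auc(l_cross(cells, r_grid, est), r_max)
            except ValueError:
                row[f"lcross_auc_{est}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
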