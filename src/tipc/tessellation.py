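"""Hexagonal tessellation of a tissue region.

The spatial unit of the analysis is a flat-top regular hexagon of side
length ``side_len`` (µm). Hexagon centers form a lattice with horizontal
pitch ``1.5 * side_len`` and vertical pitch ``sqrt(3) * side_len``; odd
columns are offset vertically by half the vertical pitch. Subregions are
indexed by axial coordinates ``(q, r)``.

A point belongs to the hexagon whose center is nearest in Euclidean
distance (the Voronoi cell of the hexagonal lattice *is* the hexagon);
exact ties on edges or vertices are broken by the lexicographically
smallest ``(q, r)`` index, so the assignment is a deterministic partition.

Grids are anchored at the minimum corner of the cell bounding box.
Shifted variants displace the anchor by half a side length along one
axis; comparing the six spatial parameters across the five shift
directions probes sensitivity to partially filled border hexagons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

SQRT3 = math.sqrt(3.0)

#: canonical compartment order used throughout the package
COMPARTMENTS = ("tumor", "stroma", "immune")

SHIFTS = ("center", "left", "right", "up", "down")

# anchor displacement in units of side_len
_SHIFT_OFFSETS = {
    "center": (0.0, 0.0),
    "left": (-0.5, 0.0),
    "right": (0.5, 0.0),
    "up": (0.0, 0.5),
    "down": (0.0, -0.5),
}

# axial offsets of a hexagon and its six neighbours (flat-top lattice)
_NEIGHBOR_OFFSETS = np.array(
    [(0, 0), (1, 0), (1, -1), (0, -1), (-1, 0), (-1, 1), (0, 1)], dtype=np.int64
)


@dataclass(frozen=True)
class HexGrid:
    """A hexagonal grid specification for one sample/ROI.

    Attributes
    ----------
    side_len : float
        Hexagon side length in µm (the "subregion size").
    origin : tuple of float
        Center of the ``(0, 0)`` hexagon, in µm.
    shift : str
        One of :data:`SHIFTS`.
    bbox : tuple of float
        ``(xmin, ymin, xmax, ymax)`` of the cells the grid was built for.
    """

    side_len: float
    origin: tuple[float, float]
    shift: str
    bbox: tuple[float, float, float, float]

    def hex_center(self, q, r):
        """Cartesian center of hexagon ``(q, r)`` (vectorized)."""
        q = np.asarray(q, dtype=np.float64)
        r = np.asarray(r, dtype=np.float64)
        x = self.origin[0] + 1.5 * self.side_len * q
        y = self.origin[1] + SQRT3 * self.side_len * (r + 0.5 * q)
        return x, y

    def covering_indices(self, margin: int = 1) -> np.ndarray:
        """All ``(q, r)`` whose hexagon may intersect the bbox, plus a margin ring.

        Used for enumerating candidate centers (e.g. by brute-force
        oracles); the assignment itself works on the unbounded lattice.
        """
        xmin, ymin, xmax, ymax = self.bbox
        s = self.side_len
        q_lo = math.floor((xmin - self.origin[0]) / (1.5 * s)) - 1 - margin
        q_hi = math.ceil((xmax - self.origin[0]) / (1.5 * s)) + 1 + margin
        out = []
        for q in range(q_lo, q_hi + 1):
            yq = self.origin[1] + SQRT3 * s * 0.5 * q
            r_lo = math.floor((ymin - yq) / (SQRT3 * s)) - 1 - margin
            r_hi = math.ceil((ymax - yq) / (SQRT3 * s)) + 1 + margin
            out.extend((q, r) for r in range(r_lo, r_hi + 1))
        return np.array(out, dtype=np.int64)


def build_hex_grid(cells: pd.DataFrame, side_len: float, shift: str = "center") -> HexGrid:
    """Build the hexagonal grid for one sample's cells.

    Parameters
    ----------
    cells : pandas.DataFrame
        Per-cell table with at least ``x`` and ``y`` columns (µm).
    side_len : float
        Hexagon side length in µm; must be positive.
    shift : str
        Grid anchor shift, one of :data:`SHIFTS`.
    """
    if side_len <= 0:
        raise ValueError(f"side_len must be positive, got {side_len!r}")
    if shift not in _SHIFT_OFFSETS:
        raise ValueError(f"unknown shift {shift!r}; expected one of {SHIFTS}")
    if len(cells) == 0:
        raise ValueError("no cells in sample")
    x = np.asarray(cells["x"], dtype=np.float64)
    y = np.asarray(cells["y"], dtype=np.float64)
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("cell coordinates must be finite")
    bbox = (float(x.min()), float(y.min()), float(x.max()), float(y.max()))
    dx, dy = _SHIFT_OFFSETS[shift]
    origin = (bbox[0] + dx * side_len, bbox[1] + dy * side_len)
    return HexGrid(side_len=float(side_len), origin=origin, shift=shift, bbox=bbox)


def shift_variants(grid: HexGrid) -> dict[str, HexGrid]:
    """The five shift variants of a center-anchored grid, keyed by direction."""
    if grid.shift != "center":
        raise ValueError("shift_variants expects the center grid")
    out = {}
    for shift in SHIFTS:
        dx, dy = _SHIFT_OFFSETS[shift]
        origin = (grid.bbox[0] + dx * grid.side_len, grid.bbox[1] + dy * grid.side_len)
        out[shift] = replace(grid, origin=origin, shift=shift)
    return out


def assign_points(grid: HexGrid, x, y) -> np.ndarray:
    """Axial index ``(q, r)`` of the hexagon containing each point.

    Returns an ``(n, 2)`` int array. Implemented as cube rounding of the
    fractional axial coordinate followed by an exact nearest-center check
    over the candidate hexagon and its six neighbours, with ties broken
    by the smallest ``(q, r)``.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    s = grid.side_len
    px = (x - grid.origin[0]) / s
    py = (y - grid.origin[1]) / s
    qf = (2.0 / 3.0) * px
    rf = -px / 3.0 + py / SQRT3

    # cube rounding to the nearest hexagon in hex metric
    xf, zf = qf, rf
    yf = -xf - zf
    rx, ry, rz = np.round(xf), np.round(yf), np.round(zf)
    dx_, dy_, dz_ = np.abs(rx - xf), np.abs(ry - yf), np.abs(rz - zf)
    fix_x = (dx_ > dy_) & (dx_ > dz_)
    fix_z = ~fix_x & (dz_ > dy_)
    rx = np.where(fix_x, -ry - rz, rx)
    rz = np.where(fix_z, -rx - ry, rz)
    q0 = rx.astype(np.int64)
    r0 = rz.astype(np.int64)

    # exact nearest-center selection among candidate + 6 neighbours
    qc = q0[:, None] + _NEIGHBOR_OFFSETS[:, 0][None, :]
    rc = r0[:, None] + _NEIGHBOR_OFFSETS[:, 1][None, :]
    cx, cy = grid.hex_center(qc, rc)
    d2 = (x[:, None] - cx) ** 2 + (y[:, None] - cy) ** 2
    # pick min d2; ties -> lexicographically smallest (q, r)
    best = np.lexsort((rc.T, qc.T, d2.T), axis=0)[0]
    rows = np.arange(len(x))
    return np.stack([qc[rows, best], rc[rows, best]], axis=1)


def assign_cells(cells: pd.DataFrame, grid: HexGrid) -> pd.DataFrame:
    """Tally cells per hexagon subregion.

    Returns a DataFrame with columns ``q, r, n_tumor, n_stroma, n_immune``,
    one row per non-empty subregion, sorted by ``(q, r)``. Every cell is
    counted exactly once.
    """
    comp = cells["compartment"].to_numpy()
    codes = np.empty(len(cells), dtype=np.int64)
    known = np.zeros(len(cells), dtype=bool)
    for i, name in enumerate(COMPARTMENTS):
        m = comp == name
        codes[m] = i
        known |= m
    if not known.all():
        bad = sorted(set(comp[~known]))
        raise ValueError(f"unknown compartment labels: {bad}")
    qr = assign_points(grid, cells["x"].to_numpy(), cells["y"].to_numpy())
    nt, ns, ni, uq = _tally(qr, codes)
    return pd.DataFrame(
        {"q": uq[:, 0], "r": uq[:, 1], "n_tumor": nt, "n_stroma": ns, "n_immune": ni}
    )


def _tally(qr: np.ndarray, codes: np.ndarray):
    """Per-hexagon compartment counts from axial indices + compartment codes."""
    uq, inv = np.unique(qr, axis=0, return_inverse=True)
    k = len(uq)
    counts = [np.bincount(inv[codes == c], minlength=k).astype(np.int64) for c in range(3)]
    return counts[0], counts[1], counts[2], uq
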