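import numpy as np
import pandas as pd
import pytest

from tipc.synthetic import TissueSpec, simulate_tissue


def make_cells(n=300, seed=0, window=(500.0, 500.0), sample_id="s0",
               weights=(0.4, 0.4, 0.2)):
    """Uniform random cell table with the three compartments."""
    rng = np.random.default_rng(seed)
    comp = rng.choice(["tumor", "stroma", "immune"], size=n, p=weights)
    return pd.DataFrame({
        "sample_id": sample_id,
        "x": rng.uniform(0, window[0], n),
        "y": rng.uniform(0, window[1], n),
        "compartment": comp,
    })


@pytest.fixture
def random_cells():
    return make_cells(n=500, seed=11)


@pytest.fixture
def tissue():
    return simulate_tissue(TissueSpec.preset("stromal_predominant", "disperse",
                                             seed=5, sample_id="t0"))


def hex_polygon(grid, q, r):
    """Explicit flat-top hexagon polygon for a lattice index (test oracle)."""
    import math
    cx, cy = grid.hex_center(q, r)
    s = grid.side_len
    angles = [math.radians(60 * k) for k in range(6)]
    return [(float(cx) + s * math.cos(a), float(cy) + s * math.sin(a)) for a in angles]


def brute_force_nearest_center(grid, x, y, margin=2):
    """Assign each point to the nearest enumerated hexagon center.

    Independent of the lattice arithmetic in the implementation: computes
    squared distances to *all* candidate centers and picks the minimum,
    ties broken by smallest (q, r).
    """
    centers = grid.covering_indices(margin)
    cx, cy = grid.hex_center(centers[:, 0], centers[:, 1])
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    d2 = (x[:, None] - cx[None, :]) ** 2 + (y[:, None] - cy[None, :]) ** 2
    n = len(x)
    qs = np.broadcast_to(centers[:, 0], (n, len(centers)))
    rs = np.broadcast_to(centers[:, 1], (n, len(centers)))
    best = np.lexsort((rs.T, qs.T, d2.T), axis=0)[0]
    return centers[best]
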