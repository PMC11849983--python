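"""The six-parameter spatial signature.

For one sample, the null model of neutral tumor–immune mixing is the pair
of global ratios

    gIT = N_immune / N_tumor       gIS = N_immune / N_stroma

computed over all cells of the sample. Each non-empty hexagon subregion is
classified by comparing its *local* immune-to-tumor and immune-to-stroma
ratios to the global ones:

    tumor-only   tumor cells but no immune cells
    I:T low/high immune present; local I:T below / above gIT
    stroma-only  stroma cells but no immune cells
    I:S low/high immune present; local I:S below / above gIS

A hexagon holding both tumor and stroma cells receives one tumor-side and
one stroma-side category (dual assignment); an immune-only hexagon has
local ratios of +inf and is counted I:T high and I:S high. Both policies
are configurable (see :class:`ClassifyPolicy`). The six category counts
are normalized by the number of non-empty subregions, yielding the
six-element spatial parameter vector. Because the classification depends
only on *ratios* of counts, the signature is insensitive to overall
immune-cell density — uniformly thinning immune cells leaves the expected
classification of a proportionally composed subregion unchanged.

Ratio comparisons are carried out by integer cross-multiplication
(``n_imm * N_tumor`` vs ``N_immune * n_t``), so classification and its tie
rule are exact, with no floating-point division involved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tessellation import (
    SHIFTS,
    HexGrid,
    assign_points,
    build_hex_grid,
    _tally,
)

#: fixed order of the six spatial parameters
CATEGORIES = ("tumor_only", "it_low", "it_high", "stroma_only", "is_low", "is_high")

#: default subregion-size sweep, µm
DEFAULT_SIZES = (30.0, 35.0, 40.0, 45.0)


@dataclass(frozen=True)
class ClassifyPolicy:
    """Tunable conventions of the subregion classifier.

    tie : "low" | "high"
        Category when the local ratio exactly equals the global ratio.
    mixed : "dual" | "majority"
        Whether a hexagon with both tumor and stroma cells gets one
        category per side, or only the side of its majority compartment
        (majority ties go to the tumor side).
    immune_only : "both_high" | "denominator_only"
        Treatment of hexagons containing only immune cells: classify as
        {I:T high, I:S high} (local ratio +inf), or count them only in
        the normalization denominator.
    """

    tie: str = "low"
    mixed: str = "dual"
    immune_only: str = "both_high"

    def __post_init__(self):
        if self.tie not in ("low", "high"):
            raise ValueError(f"tie must be 'low' or 'high', got {self.tie!r}")
        if self.mixed not in ("dual", "majority"):
            raise ValueError(f"mixed must be 'dual' or 'majority', got {self.mixed!r}")
        if self.immune_only not in ("both_high", "denominator_only"):
            raise ValueError(f"bad immune_only policy {self.immune_only!r}")


@dataclass(frozen=True)
class GlobalRatios:
    """Whole-sample compartment totals; the null model of neutral mixing."""

    n_tumor: int
    n_stroma: int
    n_immune: int

    @property
    def git(self) -> float:
        return self.n_immune / self.n_tumor

    @property
    def gis(self) -> float:
        return self.n_immune / self.n_stroma


@dataclass(frozen=True)
class TipcVector:
    """The six normalized spatial parameters for one sample."""

    values: np.ndarray  # length 6, order CATEGORIES
    sample_id: str
    side_len: float
    shift: str
    n_subregions: int  # non-empty subregions (the normalization denominator)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(CATEGORIES, map(float, self.values)))


def global_ratios(cells: pd.DataFrame, *, allow_empty_compartment: bool = False) -> GlobalRatios:
    """Compartment totals for one sample.

    By default a sample with zero tumor or zero stroma cells is rejected
    (its global ratio is undefined); ``allow_empty_compartment=True``
    relaxes this for diagnostic runs. Zero immune cells is always valid
    (a fully "cold" sample has both global ratios equal to 0).
    """
    comp = cells["compartment"].to_numpy()
    n = {name: int((comp == name).sum()) for name in ("tumor", "stroma", "immune")}
    if not allow_empty_compartment:
        for name in ("tumor", "stroma"):
            if n[name] == 0:
                raise ValueError(
                    f"sample has no {name} cells; global immune-to-{name} ratio undefined"
                )
    return GlobalRatios(n_tumor=n["tumor"], n_stroma=n["stroma"], n_immune=n["immune"])


def classify_subregion(
    n_tumor: int, n_stroma: int, n_immune: int, g: GlobalRatios,
    policy: ClassifyPolicy = ClassifyPolicy(),
) -> set[str]:
    """Category set (subset of :data:`CATEGORIES`) for a single subregion tally."""
    if n_tumor + n_stroma + n_immune == 0:
        raise ValueError("empty subregion tally")
    counts = _category_counts(
        np.array([n_tumor]), np.array([n_stroma]), np.array([n_immune]), g, policy
    )
    return {cat for cat, c in zip(CATEGORIES, counts) if c}


def _category_counts(nt, ns, ni, g: GlobalRatios, policy: ClassifyPolicy) -> np.ndarray:
    """Vectorized six-category counts from per-hexagon tallies (exact integer math)."""
    nt = np.asarray(nt, dtype=np.int64)
    ns = np.asarray(ns, dtype=np.int64)
    ni = np.asarray(ni, dtype=np.int64)
    has_t, has_s, has_i = nt > 0, ns > 0, ni > 0
    immune_only = has_i & ~has_t & ~has_s

    if policy.mixed == "majority":
        both = has_t & has_s
        tumor_side = has_t & (~both | (nt >= ns))
        stroma_side = has_s & (~both | (ns > nt))
    else:
        tumor_side, stroma_side = has_t, has_s

    # local I:T vs global: ni/nt <> N_i/N_t  <=>  ni*N_t <> N_i*nt
    lhs_t, rhs_t = ni * g.n_tumor, g.n_immune * nt
    hi_t = lhs_t > rhs_t if policy.tie == "low" else lhs_t >= rhs_t
    lhs_s, rhs_s = ni * g.n_stroma, g.n_immune * ns
    hi_s = lhs_s > rhs_s if policy.tie == "low" else lhs_s >= rhs_s

    counts = np.zeros(6, dtype=np.int64)
    counts[0] = int((tumor_side & ~has_i).sum())
    counts[1] = int((tumor_side & has_i & ~hi_t).sum())
    counts[2] = int((tumor_side & has_i & hi_t).sum())
    counts[3] = int((stroma_side & ~has_i).sum())
    counts[4] = int((stroma_side & has_i & ~hi_s).sum())
    counts[5] = int((stroma_side & has_i & hi_s).sum())
    if policy.immune_only == "both_high":
        n_io = int(immune_only.sum())
        counts[2] += n_io
        counts[5] += n_io
    return counts


def _iter_rois(cells: pd.DataFrame):
    if "roi_id" in cells.columns and cells["roi_id"].notna().any():
        for _, roi in cells.groupby("roi_id", sort=True):
            yield roi
    else:
        yield cells


def tipc_vector(
    cells: pd.DataFrame,
    side_len: float,
    shift: str = "center",
    policy: ClassifyPolicy = ClassifyPolicy(),
    *,
    allow_empty_compartment: bool = False,
) -> TipcVector:
    """Compute the six-element spatial parameter vector for one sample.

    Multi-ROI samples (disjoint tissue cores) are tessellated per ROI;
    category counts and the non-empty-subregion denominator are summed
    across ROIs before normalization.
    """
    g = global_ratios(cells, allow_empty_compartment=allow_empty_compartment)
    counts = np.zeros(6, dtype=np.int64)
    denom = 0
    for roi in _iter_rois(cells):
        grid = build_hex_grid(roi, side_len, shift)
        codes = _compartment_codes(roi)
        qr = assign_points(grid, roi["x"].to_numpy(), roi["y"].to_numpy())
        nt, ns, ni, _ = _tally(qr, codes)
        counts += _category_counts(nt, ns, ni, g, policy)
        denom += len(nt)
    sample_id = str(cells["sample_id"].iloc[0]) if "sample_id" in cells.columns else ""
    return TipcVector(
        values=counts / denom,
        sample_id=sample_id,
        side_len=float(side_len),
        shift=shift,
        n_subregions=denom,
    )


def _compartment_codes(cells: pd.DataFrame) -> np.ndarray:
    comp = cells["compartment"].to_numpy()
    codes = np.full(len(cells), -1, dtype=np.int64)
    for i, name in enumerate(("tumor", "stroma", "immune")):
        codes[comp == name] = i
    if (codes < 0).any():
        bad = sorted(set(comp[codes < 0]))
        raise ValueError(f"unknown compartment labels: {bad}")
    return codes


def sweep(
    cohort: pd.DataFrame,
    sizes=DEFAULT_SIZES,
    shifts=SHIFTS,
    policy: ClassifyPolicy = ClassifyPolicy(),
) -> pd.DataFrame:
    """Six-parameter vectors across a (subregion size × grid shift) sweep.

    Parameters
    ----------
    cohort : pandas.DataFrame
        Per-cell table for many samples (``sample_id`` column required).
    sizes, shifts
        Subregion side lengths (µm) and shift directions to evaluate.

    Returns
    -------
    pandas.DataFrame
        One row per (sample, size, shift) with the six parameter columns.
        Samples failing preconditions (e.g. no stroma cells) are skipped
        and listed in the ``attrs["skipped"]`` dict of the result.
    """
    sizes = list(sizes)
    if not sizes:
        raise ValueError("empty size list")
    rows = []
    skipped: dict[str, str] = {}
    for sample_id, cells in cohort.groupby("sample_id", sort=True):
        try:
            global_ratios(cells)  # validate once per sample
        except ValueError as e:
            skipped[str(sample_id)] = str(e)
            continue
        for size in sizes:
            for shift in shifts:
                v = tipc_vector(cells, size, shift, policy)
                rows.append(
                    {"sample_id": str(sample_id), "side_len": float(size), "shift": shift,
                     **v.as_dict()}
                )
    out = pd.DataFrame(rows)
    out.attrs["skipped"] = skipped
    return out


def trend_table(sweep_df: pd.DataFrame) -> pd.DataFrame:
    """Cohort mean of each parameter per (size, shift) — trend-plot data."""
    return (
        sweep_df.groupby(["side_len", "shift"], sort=True)[list(CATEGORIES)]
        .mean()
        .reset_index()
    )


def optimal_hex_len(sweep_df: pd.DataFrame) -> float:
    """Pick the subregion size balancing informativeness and shift robustness.

    For each size ``s`` let ``m[shift]`` be the cohort-mean parameter
    vector. The balance score ``B(s)`` is the variance across the six
    center-shift means (small = no category dominates, informative
    partition); the robustness score ``R(s)`` is the mean over the six
    parameters of the variance of the cohort means across the five shift
    directions (small = insensitive to grid placement). The chosen size
    minimizes ``rank(B) + rank(R)``, ties resolved toward the smaller
    size.
    """
    sizes = sorted(sweep_df["side_len"].unique())
    if len(sizes) < 2:
        raise ValueError("optimal_hex_len needs a sweep over at least two sizes")
    means = trend_table(sweep_df)
    B, R = [], []
    for s in sizes:
        sub = means[means["side_len"] == s]
        missing = set(SHIFTS) - set(sub["shift"])
        if missing:
            raise ValueError(f"size {s}: missing shift variants {sorted(missing)}")
        center = sub[sub["shift"] == "center"][list(CATEGORIES)].to_numpy()[0]
        B.append(float(np.var(center)))
        across = sub.set_index("shift").loc[list(SHIFTS), list(CATEGORIES)].to_numpy()
        R.append(float(np.mean(np.var(across, axis=0))))
    from scipy.stats import rankdata

    score = rankdata(B) + rankdata(R)
    best = min(zip(score, sizes))  # ties -> smaller size
    return float(best[1])
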