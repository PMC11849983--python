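"""Consensus clustering of spatial-parameter vectors into cohort subtypes.

Samples are compared by Pearson correlation distance on their six-element
vectors and repeatedly clustered (complete-linkage hierarchical
agglomeration) on random subsamples of the cohort. The consensus matrix
entry ``M_k[i, j]`` is the fraction of co-sampled repetitions in which
samples *i* and *j* landed in the same of *k* clusters; final subtype
labels come from complete-linkage clustering of ``1 - M_k``.

Two diagnostics guide the choice of *k*: the relative change in the area
under the CDF of consensus values (the "delta-area" curve, whose shoulder
marks the smallest stable *k*), and the normalized mutual information
between partitions at consecutive *k* (the tracking series, which stays
high while finer splits merely subdivide stable clusters). Small clusters
are relabeled as outliers rather than silently dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import normalized_mutual_info_score


def pearson_distance(m) -> np.ndarray:
    """Pairwise Pearson correlation distance ``d = 1 - r`` between rows.

    Rows with zero variance have no defined correlation and are rejected
    with the offending sample names/indices listed.
    """
    X, ids = _as_matrix(m)
    sd = X.std(axis=1)
    if (sd == 0).any():
        bad = [ids[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant rows (zero variance) have no Pearson distance: {bad}")
    d = 1.0 - np.corrcoef(X)
    np.fill_diagonal(d, 0.0)
    # guard against tiny negative rounding noise
    return np.clip(d, 0.0, 2.0)


def _as_matrix(m):
    if isinstance(m, pd.DataFrame):
        return m.to_numpy(dtype=np.float64), list(m.index)
    X = np.asarray(m, dtype=np.float64)
    return X, list(range(X.shape[0]))


@dataclass
class ConsensusResult:
    """Per-k consensus matrices, final assignments and diagnostics inputs."""

    sample_ids: list
    k_range: list[int]
    matrices: dict[int, np.ndarray]       # k -> n x n consensus matrix
    labels: dict[int, np.ndarray]         # k -> final cluster labels (1..k)
    n_never_cosampled: int                # pairs imputed 0 in every matrix
    seed: int
    reps: int
    frac: float

    def tracking_table(self) -> pd.DataFrame:
        """Sample-by-k membership table (the tracking-plot data)."""
        data = {f"k={k}": self.labels[k] for k in self.k_range}
        return pd.DataFrame(data, index=self.sample_ids)


def consensus_cluster(
    m, k_range=range(2, 7), reps: int = 50, frac: float = 0.8, seed: int = 0,
    inner_linkage: str = "average",
) -> ConsensusResult:
    """Resampled consensus hierarchical clustering.

    Parameters
    ----------
    m : DataFrame or array, samples x six parameters
    k_range : iterable of int
        Cluster numbers to evaluate (each must satisfy ``2 <= k < n``).
    reps : int
        Number of subsampled clustering repetitions.
    frac : float
        Fraction of samples drawn (without replacement) per repetition.
    seed : int
        Seed for the subsampling stream; results are fully reproducible.
    inner_linkage : str
        Linkage used *within* each resampled clustering (default
        "average", the convention of the classical consensus-clustering
        implementation). The finalization step on the cumulative
        consensus matrix always uses complete linkage.
    """
    X, ids = _as_matrix(m)
    n = X.shape[0]
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("empty k_range")
    if ks[0] < 2 or ks[-1] >= n:
        raise ValueError(f"k_range must lie in [2, n-1]={[2, n - 1]}, got {ks}")
    if not 0 < frac <= 1:
        raise ValueError(f"frac must be in (0, 1], got {frac}")
    n_sub = int(math.floor(frac * n))
    if n_sub <= ks[-1]:
        raise ValueError(f"subsample size {n_sub} too small for k={ks[-1]}")

    D = pearson_distance(m)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    cosample = np.zeros((n, n))
    cocluster = {k: np.zeros((n, n)) for k in ks}
    for _ in range(reps):
        idx = np.sort(rng.choice(n, size=n_sub, replace=False))
        sub = D[np.ix_(idx, idx)]
        Z = linkage(squareform(sub, checks=False), method=inner_linkage)
        cosample[np.ix_(idx, idx)] += 1.0
        for k in ks:
            lab = fcluster(Z, t=k, criterion="maxclust")
            same = (lab[:, None] == lab[None, :]).astype(float)
            cocluster[k][np.ix_(idx, idx)] += same

    never = cosample == 0
    np.fill_diagonal(never, False)
    matrices, labels = {}, {}
    for k in ks:
        with np.errstate(invalid="ignore", divide="ignore"):
            M = np.where(cosample > 0, cocluster[k] / np.where(cosample > 0, cosample, 1), 0.0)
        np.fill_diagonal(M, 1.0)
        matrices[k] = M
        Z = linkage(squareform(1.0 - M, checks=False), method="complete")
        labels[k] = fcluster(Z, t=k, criterion="maxclust")
    return ConsensusResult(
        sample_ids=ids,
        k_range=ks,
        matrices=matrices,
        labels=labels,
        n_never_cosampled=int(never.sum() // 2),
        seed=seed,
        reps=reps,
        frac=frac,
    )


def _cdf_area(values: np.ndarray) -> float:
    """Exact area under the empirical CDF of ``values`` over [0, 1]."""
    x = np.sort(np.asarray(values, dtype=np.float64))
    m = len(x)
    widths = np.diff(np.concatenate([x, [1.0]]))
    F = np.arange(1, m + 1) / m
    return float(np.sum(widths * F))


def cdf_delta(result: ConsensusResult, tau: float = 0.025):
    """Area-under-CDF curve, delta-area curve, and the shoulder k.

    ``A(k)`` is the area under the empirical CDF of the upper-triangle
    consensus entries; ``delta(k_min) = A(k_min)`` and for larger k
    ``delta(k) = (A(k) - A(k-1)) / A(k-1)``. The shoulder is the smallest
    k whose successor gains less than ``tau`` relative area — beyond it
    there is no further significant gain in consensus.
    """
    ks = result.k_range
    if len(ks) < 3:
        raise ValueError("cdf_delta needs at least three k values")
    iu = np.triu_indices(len(result.sample_ids), k=1)
    A = {k: _cdf_area(result.matrices[k][iu]) for k in ks}
    delta = {ks[0]: A[ks[0]]}
    for prev, k in zip(ks, ks[1:]):
        delta[k] = (A[k] - A[prev]) / A[prev]
    shoulder = ks[-1]
    for prev, k in zip(ks, ks[1:]):
        if delta[k] < tau:
            shoulder = prev
            break
    return A, delta, shoulder


def nmi(p1, p2) -> float:
    """Normalized mutual information between two partitions of one sample set.

    Normalization is by the arithmetic mean of the two partition
    entropies; a comparison where one partition carries zero information
    (e.g. all samples in a single cluster vs all singletons) scores 0.
    """
    a, b = _align_partitions(p1, p2)
    return float(normalized_mutual_info_score(a, b, average_method="arithmetic"))


def _align_partitions(p1, p2):
    if isinstance(p1, pd.Series) and isinstance(p2, pd.Series):
        if set(p1.index) != set(p2.index):
            raise ValueError("partitions cover different sample sets")
        p2 = p2.reindex(p1.index)
        return p1.to_numpy(), p2.to_numpy()
    a, b = np.asarray(p1), np.asarray(p2)
    if a.shape != b.shape:
        raise ValueError("partitions cover different sample sets")
    return a, b


def nmi_series(result: ConsensusResult) -> dict[int, float]:
    """NMI between final partitions at consecutive k, keyed by the larger k."""
    ks = result.k_range
    return {k: nmi(result.labels[prev], result.labels[k]) for prev, k in zip(ks, ks[1:])}


def optimal_k(result: ConsensusResult, tau: float = 0.025, eta: float = 0.9) -> int:
    """Choose the cluster number: stability first, then granularity.

    The shoulder of the delta-area curve gives the smallest stable k;
    from there, k is increased for as long as consecutive partitions
    remain consistent (NMI >= ``eta``), and the largest such k is
    returned.
    """
    _, _, shoulder = cdf_delta(result, tau=tau)
    series = nmi_series(result)
    best = shoulder
    for k in result.k_range:
        if k <= shoulder:
            continue
        if series[k] >= eta:
            best = k
        else:
            break
    return best


@dataclass
class SubtypeLabels:
    """Final subtype assignment with small clusters marked as outliers."""

    labels: pd.Series            # sample_id -> "1".."m" or "outlier"
    sizes: dict[str, int]
    threshold: int
    k: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.labels.index, "subtype": self.labels.values,
             "is_outlier": self.labels.values == "outlier"}
        )


def finalize_subtypes(
    result: ConsensusResult, k: int, min_abs: int = 30, min_frac: float = 0.03
) -> SubtypeLabels:
    """Relabel clusters smaller than ``max(min_abs, ceil(min_frac * n))`` as outliers.

    Major clusters are renamed "1", "2", ... by descending size (ties by
    original cluster id). Raises if no cluster reaches the threshold.
    """
    if k not in result.labels:
        raise ValueError(f"k={k} not in result (have {result.k_range})")
    raw = result.labels[k]
    n = len(raw)
    threshold = max(int(min_abs), math.ceil(min_frac * n))
    counts = pd.Series(raw).value_counts()
    major = [c for c in counts.index if counts[c] >= threshold]
    if not major:
        raise ValueError("no major clusters: every cluster is below the outlier threshold")
    major.sort(key=lambda c: (-counts[c], c))
    rename = {c: str(i + 1) for i, c in enumerate(major)}
    labels = pd.Series(
        [rename.get(c, "outlier") for c in raw], index=pd.Index(result.sample_ids, name="sample_id")
    )
    sizes = {rename[c]: int(counts[c]) for c in major}
    sizes["outlier"] = int(n - sum(sizes.values()))
    return SubtypeLabels(labels=labels, sizes=sizes, threshold=threshold, k=k)


def heatmap_order(result: ConsensusResult, k: int) -> list:
    """Sample ids ordered by the final dendrogram at k (heatmap-ready)."""
    M = result.matrices[k]
    Z = linkage(squareform(1.0 - M, checks=False), method="complete")
    return [result.sample_ids[i] for i in leaves_list(Z)]
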