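"""Transfer of reference-cohort subtypes to new samples by kNN matching.

A fitted :class:`SubtypeModel` holds the reference cohort's six-element
vectors, their subtype labels (outliers excluded — an outlier is not a
subtype), and the subregion size those vectors were computed at. A query
sample, vectorized at the *same* subregion size, is assigned the majority
subtype among its 10 nearest reference vectors in Euclidean distance;
vote ties fall back to the label of the single nearest neighbor.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .core import CATEGORIES


@dataclass
class SubtypeModel:
    """Reference vectors + labels for subtype transfer."""

    vectors: pd.DataFrame          # samples x six parameters, sample_id index
    labels: pd.Series              # sample_id -> subtype label (no "outlier")
    side_len: float
    k_neighbors: int = 10

    def __post_init__(self):
        self.vectors = self.vectors[list(CATEGORIES)]
        self.labels = self.labels.reindex(self.vectors.index)
        keep = (self.labels != "outlier") & self.labels.notna()
        self.vectors = self.vectors[keep]
        self.labels = self.labels[keep].astype(str)
        if len(self.labels) < self.k_neighbors:
            raise ValueError(
                f"model has {len(self.labels)} labeled references, "
                f"fewer than k_neighbors={self.k_neighbors}"
            )

    def save(self, path):
        """Write the model as a single zip archive (two CSVs + metadata JSON)."""
        with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
            zf.writestr("vectors.csv", self.vectors.to_csv(float_format="%.10g"))
            zf.writestr("labels.csv", self.labels.rename("subtype").to_csv())
            meta = {"side_len": self.side_len, "k_neighbors": self.k_neighbors,
                    "n_references": int(len(self.labels))}
            zf.writestr("metadata.json", json.dumps(meta, indent=2, sort_keys=True))

    @classmethod
    def load(cls, path) -> "SubtypeModel":
        with zipfile.ZipFile(path) as zf:
            vectors = pd.read_csv(io.BytesIO(zf.read("vectors.csv")), index_col=0)
            labels = pd.read_csv(io.BytesIO(zf.read("labels.csv")), index_col=0)["subtype"]
            meta = json.loads(zf.read("metadata.json"))
        return cls(vectors=vectors, labels=labels,
                   side_len=float(meta["side_len"]), k_neighbors=int(meta["k_neighbors"]))


def knn_assign(query: pd.DataFrame, model: SubtypeModel, side_len: float | None = None) -> pd.Series:
    """Assign each query vector the majority subtype of its k nearest references.

    Parameters
    ----------
    query : DataFrame
        Samples x six parameters (same column order as the model).
    model : SubtypeModel
    side_len : float, optional
        Subregion size the query vectors were computed at; if given, it
        must match the model's (vectors at different granularities are
        not comparable).
    """
    if side_len is not None and side_len != model.side_len:
        raise ValueError(
            f"query computed at side_len={side_len} but model expects {model.side_len}"
        )
    Q = query[list(CATEGORIES)].to_numpy(float)
    R = model.vectors.to_numpy(float)
    ref_labels = model.labels.to_numpy()
    nn = NearestNeighbors(n_neighbors=model.k_neighbors, metric="euclidean").fit(R)
    _, idx = nn.kneighbors(Q)
    out = []
    for row in idx:  # row is ordered nearest-first
        votes = pd.Series(ref_labels[row]).value_counts()
        top = votes[votes == votes.iloc[0]]
        out.append(ref_labels[row[0]] if len(top) > 1 else top.index[0])
    return pd.Series(out, index=query.index, name="subtype")
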