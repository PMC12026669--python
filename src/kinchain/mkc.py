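"""Merging indistinguishable kinship chains (mKCs) and PCA summaries.

Many chains of the same degree produce nearly identical IBS-score
distributions and cannot be told apart.  Chains are merged by computing each
chain's centroid in z-standardized six-score space, normalizing pairwise
centroid Euclidean distances by the largest centroid distance (so the
threshold D lives in [0, 1]), and taking single-linkage connected components
of the graph with edges below D.  The mKC count is non-increasing in D;
D = 0 keeps all chains separate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA

from .ibs import SCORE_COLUMNS


@dataclass
class MergePartition:
    threshold: float
    mapping: dict[str, int]        # KC -> mKC id
    n_mkc: int
    centroids: pd.DataFrame        # KC x standardized scores

    def members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for kc_str, mid in self.mapping.items():
            out.setdefault(mid, []).append(kc_str)
        return {m: sorted(v) for m, v in out.items()}

    def labels_for(self, kcs: pd.Series | np.ndarray) -> np.ndarray:
        """Relabel a KC column by mKC id (as strings "mKC<i>")."""
        return np.asarray([f"mKC{self.mapping[k]:02d}" for k in kcs],
                          dtype=object)


def standardize_scores(table: pd.DataFrame) -> pd.DataFrame:
    """Z-standardize the six scores over all rows.

    Missing Y scores are imputed with the unrelated male–male mean before
    standardization so that every chain lives in one 6-dimensional space.
    """
    X = table[SCORE_COLUMNS].copy().astype(float)
    if X["y_ibs"].isna().any():
        un_mm = table.loc[(table.get("sexes") == "MM")
                          & (table.get("kc") == "MM"), "y_ibs"] \
            if "kc" in table.columns else pd.Series(dtype=float)
        fill = float(un_mm.mean()) if len(un_mm) else \
            float(X["y_ibs"].mean())
        X["y_ibs"] = X["y_ibs"].fillna(fill)
    mu = X.mean()
    sd = X.std(ddof=0).replace(0.0, 1.0)
    return (X - mu) / sd


def kc_centroids(table: pd.DataFrame) -> pd.DataFrame:
    """Per-chain mean vector in standardized score space."""
    if "kc" not in table.columns:
        raise ValueError("score table needs a 'kc' column")
    counts = table["kc"].value_counts()
    if (counts == 0).any() or len(counts) == 0:
        raise ValueError("every KC needs at least one row")
    Z = standardize_scores(table)
    Z["kc"] = table["kc"].to_numpy()
    return Z.groupby("kc").mean().sort_index()


def merge_kcs(centroids: pd.DataFrame, d: float) -> MergePartition:
    """Single-linkage merge of chains at normalized centroid distance < d.

    Distances are Euclidean in standardized score space, divided by the
    maximum centroid-pair distance; component ids are assigned in order of
    each component's lexicographically smallest member.
    """
    if not 0.0 <= d <= 1.0:
        raise ValueError("threshold D must lie in [0, 1]")
    kcs = list(centroids.index)
    dist = squareform(pdist(centroids.to_numpy(float)))
    dmax = dist.max()
    if dmax > 0:
        dist = dist / dmax

    # union-find over edges with normalized distance < d
    parent = list(range(len(kcs)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(kcs)):
        for j in range(i + 1, len(kcs)):
            if dist[i, j] < d:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    comps: dict[int, list[int]] = {}
    for i in range(len(kcs)):
        comps.setdefault(find(i), []).append(i)
    ordered = sorted(comps.values(), key=lambda m: min(kcs[i] for i in m))
    mapping = {}
    for mid, members in enumerate(ordered, start=1):
        for i in members:
            mapping[kcs[i]] = mid
    return MergePartition(d, mapping, len(ordered), centroids)


def mkc_sweep(centroids: pd.DataFrame, thresholds) -> pd.DataFrame:
    """mKC count for a sweep of distance thresholds."""
    rows = [{"D": float(d), "n_mkc": merge_kcs(centroids, float(d)).n_mkc}
            for d in thresholds]
    return pd.DataFrame(rows)


def pca_summary(table: pd.DataFrame
                ) -> tuple[np.ndarray, pd.DataFrame]:
    """PCA of the standardized six-score matrix.

    Returns the explained-variance fractions of all six components and the
    per-pair projections (with the kc column carried through when present).
    """
    Z = standardize_scores(table)
    if len(Z) < Z.shape[1]:
        raise ValueError("need at least as many rows as score dimensions")
    pca = PCA(n_components=Z.shape[1], svd_solver="full")
    proj = pca.fit_transform(Z.to_numpy(float))
    cols = [f"PC{i + 1}" for i in range(Z.shape[1])]
    out = pd.DataFrame(proj, columns=cols, index=table.index)
    if "kc" in table.columns:
        out.insert(0, "kc", table["kc"].to_numpy())
    return pca.explained_variance_ratio_, out
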