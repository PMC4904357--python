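"""Ward hierarchical clustering with silhouette-selected cluster number.

Gene profiles (expression over groups, or per-model loadings) are clustered
with Ward linkage on Euclidean distances (Ward.D2 convention). The number of
clusters is the k in the candidate range maximizing the mean silhouette width;
ties go to the smallest k. Cluster summaries are mean profiles normalized to
each cluster's maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import silhouette_score


class DegenerateInputError(ValueError):
    """All profiles identical: distances are zero and silhouettes undefined."""


@dataclass
class ClusterResult:
    linkage: np.ndarray
    k: int
    assignment: pd.Series              # gene -> cluster id (1..k)
    silhouette: pd.Series              # candidate k -> mean silhouette width
    profiles: pd.DataFrame | None = None


def ward_cluster(profiles: pd.DataFrame, k_range=range(2, 11),
                 standardize_rows: bool = True) -> ClusterResult:
    """Cluster gene rows of ``profiles`` (gene x feature)."""
    ks = sorted(set(int(k) for k in k_range))
    if not ks or ks[0] < 2:
        raise ValueError("k_range lower bound must be >= 2")
    if profiles.shape[0] <= max(ks):
        raise ValueError("need more genes than the largest candidate k")
    x = profiles.to_numpy(float)
    if not np.all(np.isfinite(x)):
        raise ValueError("profiles must be finite")
    if standardize_rows:
        sd = x.std(axis=1, ddof=0)
        if np.any(sd == 0):
            raise DegenerateInputError("constant rows cannot be z-scored")
        x = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    if np.allclose(x, x[0], atol=1e-12):
        raise DegenerateInputError("all profiles identical; clustering undefined")
    z = linkage(x, method="ward")
    sil = {}
    for k in ks:
        labels = fcluster(z, t=k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        sil[k] = float(silhouette_score(x, labels))
    if not sil:
        raise DegenerateInputError("no candidate k produced >=2 clusters")
    best_k = min(k for k, s in sil.items() if s == max(sil.values()))
    assignment = pd.Series(fcluster(z, t=best_k, criterion="maxclust"),
                           index=profiles.index, name="cluster")
    return ClusterResult(z, best_k, assignment,
                         pd.Series(sil, name="mean_silhouette").sort_index())


def cluster_profiles(em: pd.DataFrame, assignment: pd.Series, groups: pd.Series,
                     group_order: list[str] | None = None) -> pd.DataFrame:
    """Per-cluster mean expression per sample group, normalized to the
    cluster's maximum group mean.

    Intended for nonnegative expression (counts or CPM), mirroring
    "read counts normalized to the maximum value"; values land in (0, 1].
    """
    genes = [g for g in assignment.index if g in em.index]
    if not genes:
        raise ValueError("assignment does not cover any gene in the matrix")
    groups = pd.Series(groups, index=em.columns) if not isinstance(groups, pd.Series) else groups
    order = list(pd.unique(groups)) if group_order is None else list(group_order)
    rows = {}
    for cluster_id in sorted(assignment.unique()):
        members = assignment.index[assignment == cluster_id]
        members = [g for g in members if g in em.index]
        if not members:
            raise ValueError(f"cluster {cluster_id} has no genes in the matrix")
        sub = em.loc[members]
        means = np.array([sub.loc[:, groups == g].to_numpy().mean() for g in order])
        peak = means.max()
        if peak <= 0:
            raise ValueError(f"cluster {cluster_id} has non-positive peak mean; "
                             "profiles require nonnegative expression values")
        rows[cluster_id] = means / peak
    return pd.DataFrame.from_dict(rows, orient="index", columns=order).rename_axis("cluster")
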