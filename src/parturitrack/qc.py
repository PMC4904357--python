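"""Outlier-sample detection by distance from the centroid in PCA space.

Within each model's sample set, expression profiles are z-scored per gene,
embedded onto the top principal components, and each sample's Euclidean
distance to the centroid is studentized against the leave-one-out mean and
standard deviation of the remaining distances. The two-sided p-value uses a
t reference with n - 2 degrees of freedom (the standard Bonferroni outlier
test; a normal reference is anti-conservative at these sample sizes), and is
Bonferroni corrected across the samples tested.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist


def _pc_scores(x: np.ndarray, n_pcs: int) -> np.ndarray:
    """Top-``n_pcs`` PCA scores of a samples x genes matrix after per-gene
    z-scoring (zero-variance genes dropped)."""
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    z = (x[:, keep] - mu[keep]) / sd[keep]
    zc = z - z.mean(axis=0)
    u, s, _ = np.linalg.svd(zc, full_matrices=False)
    k = min(n_pcs, s.size)
    return u[:, :k] * s[:k]


def centroid_outliers(em: pd.DataFrame, groups: pd.Series, alpha: float = 0.01,
                      n_pcs: int = 2) -> pd.DataFrame:
    """Flag outlier samples per group of ``groups`` (typically the model label).

    Returns a frame indexed by sample id with columns
    ``group, distance, pvalue, p_adj, flagged`` where
    ``p_adj = min(1, p * n_samples_in_group)`` and ``flagged = p_adj < alpha``.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    groups = pd.Series(groups, index=em.columns) if not isinstance(groups, pd.Series) else groups
    rows = []
    for label in pd.unique(groups):
        ids = list(groups.index[groups == label])
        if len(ids) < 3:
            warnings.warn(f"group {label!r} has <3 samples; skipped", stacklevel=2)
            continue
        x = em[ids].to_numpy(float).T  # samples x genes
        scores = _pc_scores(x, n_pcs)
        centroid = scores.mean(axis=0)
        d = np.linalg.norm(scores - centroid, axis=1)
        n = len(ids)
        for i, sid in enumerate(ids):
            rest = np.delete(d, i)
            mu, sd = rest.mean(), rest.std(ddof=1)
            if sd == 0:
                p = 1.0 if d[i] == mu else 0.0
            else:
                p = 2.0 * t_dist.sf(abs(d[i] - mu) / sd, df=n - 2)
            p_adj = min(1.0, p * n)
            rows.append((sid, label, d[i], p, p_adj, p_adj < alpha))
    report = pd.DataFrame(rows, columns=["sample_id", "group", "distance",
                                         "pvalue", "p_adj", "flagged"])
    return report.set_index("sample_id")
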