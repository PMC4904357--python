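"""Mouse-human ortholog intersection, gestational-time harmonization, and
human transfer analysis.

Human in-labor (IL) vs not-in-labor (NIL) DEGs are mapped through a 1:1
ortholog table and intersected with genes changing in at least one mouse
pairwise contrast. The mouse trajectory models are refit on this shared gene
set and used to score the human samples; the human matrix is z-scored per
gene within the human cohort before projection to remove species-level
baseline offsets. NIL samples are anchored at the mouse E18 equivalent
(gestational day 263 vs 270 at term labor) and IL samples at labor onset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import clusterprof, mva

# (mouse E-day, human gestational day) anchors; strictly increasing in E-day
TIME_ANCHORS = ((16.0, 234.0), (18.0, 263.0), (18.5, 270.0))

# on the linear E14-E18.5 pseudotime scale used for the term model
HUMAN_GROUP_PSEUDOTIME = {"NIL": 0.889, "IL": 1.0}


@dataclass
class OrthologMap:
    pairs: pd.DataFrame  # columns mouse_id, human_id

    def __post_init__(self) -> None:
        if self.pairs.empty:
            raise ValueError("empty ortholog map")
        for col in ("mouse_id", "human_id"):
            if col not in self.pairs.columns:
                raise ValueError(f"ortholog map missing column {col!r}")
            if self.pairs[col].duplicated().any():
                raise ValueError(f"ortholog map is not 1:1 in {col}")

    @property
    def mouse_to_human(self) -> pd.Series:
        return self.pairs.set_index("mouse_id")["human_id"]

    @property
    def human_to_mouse(self) -> pd.Series:
        return self.pairs.set_index("human_id")["mouse_id"]


def read_ortholog_map(path) -> OrthologMap:
    return OrthologMap(pd.read_csv(path, sep="\t"))


def mouse_day_to_human_day(e_day: float) -> float:
    """Piecewise-linear interpolation between the anchor gestational days."""
    xs = [a for a, _ in TIME_ANCHORS]
    ys = [b for _, b in TIME_ANCHORS]
    return float(np.interp(e_day, xs, ys))


def harmonize_pseudotime(human_groups) -> pd.Series:
    """Pseudotime for NIL/IL human samples on the mouse term scale.

    NIL = 0.889 (E18 equivalent, term not in labor), IL = 1.0 (labor onset).
    Any affine recoding leaves downstream Pearson transfer r unchanged.
    """
    groups = pd.Series(human_groups)
    unknown = sorted(set(groups.unique()) - set(HUMAN_GROUP_PSEUDOTIME))
    if unknown:
        raise ValueError(f"unknown human group labels: {unknown}")
    return groups.map(HUMAN_GROUP_PSEUDOTIME).astype(float)


def shared_degs(mouse_union_genes, human_deg_genes, omap: OrthologMap) -> pd.DataFrame:
    """Orthologs of human DEGs that are mouse DEGs in >=1 pairwise contrast.

    Returns a two-column frame (mouse_id, human_id); empty when either side
    contributes nothing.
    """
    h2m = omap.human_to_mouse
    mouse_union = set(mouse_union_genes)
    rows = [(h2m[h], h) for h in human_deg_genes if h in h2m.index and h2m[h] in mouse_union]
    return pd.DataFrame(rows, columns=["mouse_id", "human_id"])


def human_transfer(mouse_data: dict[str, tuple[pd.DataFrame, np.ndarray]],
                   human_em: pd.DataFrame, human_y, shared: pd.DataFrame,
                   n_osc: int = 1):
    """Refit each mouse model on the shared gene set and score the human cohort.

    ``mouse_data`` maps model label -> (log-CPM matrix over mouse gene ids,
    pseudotime). ``human_em`` is indexed by human gene ids. Returns
    (list of TransferResult, gene x model loading matrix on mouse ids).
    """
    if shared.empty:
        raise ValueError("shared gene set is empty")
    mouse_genes = list(shared["mouse_id"])
    human_genes = list(shared["human_id"])
    missing = [g for g in human_genes if g not in human_em.index]
    if missing:
        raise KeyError(f"human matrix lacks shared genes: {missing[:10]}")
    # z-score human expression per gene within the cohort, relabel to mouse ids
    hx = human_em.loc[human_genes].to_numpy(float)
    sd = hx.std(axis=1, ddof=1)
    if np.any(sd == 0):
        keep = sd > 0
        hx, sd = hx[keep], sd[keep]
        mouse_genes = [g for g, k in zip(mouse_genes, keep) if k]
    hz = pd.DataFrame((hx - hx.mean(axis=1, keepdims=True)) / sd[:, None],
                      index=mouse_genes, columns=human_em.columns)
    y = np.asarray(human_y, float)
    results, loadings = [], {}
    for label, (em, mouse_y) in mouse_data.items():
        model = mva.fit_oscpls(em, mouse_y, genes=[g for g in mouse_genes if g in em.index],
                               n_osc=n_osc, label=label)
        res = mva.transfer_correlation(model, hz, y, test_label="human",
                                       pre_standardized=True)
        results.append(res)
        loadings[label] = model.loadings
    loading_matrix = pd.DataFrame(loadings).dropna()
    return results, loading_matrix


def loading_clusters(loading_matrix: pd.DataFrame,
                     k_range=range(2, 13)) -> clusterprof.ClusterResult:
    """Ward/silhouette clustering of per-model loading profiles.

    Loadings are already on a comparable scale, so rows are not re-standardized.
    """
    return clusterprof.ward_cluster(loading_matrix, k_range=k_range,
                                    standardize_rows=False)
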