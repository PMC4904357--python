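"""PCA and orthogonal-signal-correction PLS (OSC-PLS) trajectory modeling.

The supervised model regresses standardized expression of a feature gene set
on gestational pseudotime y. One OSC component — the dominant direction of
X-variance orthogonal to the response — is estimated by a fixed-point
iteration and removed from X; a single-component PLS1 model is then fit on the
deflated matrix. Per-gene PLS weights serve as loadings (relative importance
of each gene to the trajectory). A model trained on one parturition model can
score samples of another; the Pearson correlation between predicted scores and
the test set's pseudotime ("transfer correlation") quantifies how far the two
models share a temporal expression program.

After the OSC iteration converges, the OSC weight vector is orthogonalized
against the PLS direction X'y and renormalized, so the OSC training score
t_osc = X @ w_osc is orthogonal to y to machine precision while training
deflation and prediction remain exactly self-consistent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class PcaResult:
    scores: pd.DataFrame          # samples x components
    percent_variance: np.ndarray  # per component


@dataclass
class OscPlsModel:
    genes: list
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float
    w_osc: np.ndarray | None   # unit norm, None when n_osc = 0
    p_osc: np.ndarray | None
    t_osc: np.ndarray | None   # training OSC scores
    w: np.ndarray              # unit-norm PLS1 weights = exported loadings
    p: np.ndarray
    q: float
    t: np.ndarray              # training latent scores
    label: str = ""

    @property
    def loadings(self) -> pd.Series:
        return pd.Series(self.w, index=self.genes, name=self.label or "loading")

    def to_dict(self) -> dict:
        return {
            "label": self.label, "genes": list(self.genes),
            "x_mean": self.x_mean.tolist(), "x_sd": self.x_sd.tolist(),
            "y_mean": self.y_mean, "y_sd": self.y_sd,
            "w_osc": None if self.w_osc is None else self.w_osc.tolist(),
            "p_osc": None if self.p_osc is None else self.p_osc.tolist(),
            "t_osc": None if self.t_osc is None else self.t_osc.tolist(),
            "w": self.w.tolist(), "p": self.p.tolist(), "q": self.q,
            "t": self.t.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OscPlsModel":
        arr = lambda v: None if v is None else np.asarray(v, float)
        return cls(genes=list(d["genes"]), x_mean=np.asarray(d["x_mean"], float),
                   x_sd=np.asarray(d["x_sd"], float), y_mean=float(d["y_mean"]),
                   y_sd=float(d["y_sd"]), w_osc=arr(d["w_osc"]), p_osc=arr(d["p_osc"]),
                   t_osc=arr(d["t_osc"]), w=np.asarray(d["w"], float),
                   p=np.asarray(d["p"], float), q=float(d["q"]),
                   t=np.asarray(d["t"], float), label=d.get("label", ""))


@dataclass
class TransferResult:
    train_label: str
    test_label: str
    scores: pd.Series
    r: float
    pvalue: float
    n: int


def pca(em: pd.DataFrame, n_components: int | None = None) -> PcaResult:
    """SVD-based PCA of samples over mean-centered, unit-variance-scaled genes.

    ``em`` is genes x samples; genes constant across samples are excluded from
    scaling. Percent variance is relative to the total over all components.
    """
    if em.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples")
    x = em.to_numpy(float).T  # samples x genes
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("no variable genes for PCA")
    z = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    var = s ** 2
    pct = 100.0 * var / var.sum()
    k = s.size if n_components is None else min(n_components, s.size)
    scores = pd.DataFrame(u[:, :k] * s[:k], index=em.columns,
                          columns=[f"PC{i + 1}" for i in range(k)])
    return PcaResult(scores, pct[:k])


def _standardize_training(x: np.ndarray):
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    return mu, sd


def fit_oscpls(em: pd.DataFrame, y, genes=None, n_osc: int = 1, n_pls: int = 1,
               label: str = "", tol: float = 1e-10, max_iter: int = 500) -> OscPlsModel:
    """Fit the OSC-PLS trajectory model on a gene x sample expression matrix.

    ``y`` is the per-sample pseudotime; ``genes`` restricts the features
    (default: all rows). Only a single OSC and a single PLS component are
    supported (``n_osc`` in {0, 1}, ``n_pls`` = 1).
    """
    if n_pls != 1 or n_osc not in (0, 1):
        raise NotImplementedError("supported: n_osc in {0, 1}, n_pls = 1")
    genes = list(em.index) if genes is None else list(genes)
    missing = [g for g in genes if g not in em.index]
    if missing:
        raise KeyError(f"genes absent from expression matrix: {missing[:10]}")
    y = np.asarray(y, dtype=float)
    if y.size != em.shape[1]:
        raise ValueError("y length must match number of samples")
    if y.size < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(y) == 0:
        raise ValueError("constant response: no pseudotime variance")

    x = em.loc[genes].to_numpy(float).T  # samples x genes
    mu, sd = _standardize_training(x)
    variable = sd > 0
    if not variable.all():
        warnings.warn(f"{int((~variable).sum())} zero-variance genes excluded from fit",
                      stacklevel=2)
        genes = [g for g, v in zip(genes, variable) if v]
        x, mu, sd = x[:, variable], mu[variable], sd[variable]
    xs = (x - mu) / sd
    y_mean, y_sd = float(y.mean()), float(y.std(ddof=1))
    ys = (y - y_mean) / y_sd

    w_osc = p_osc = t_osc = None
    xd = xs
    if n_osc == 1:
        # initialize the OSC score with the first principal component of X
        u, s, _ = np.linalg.svd(xs, full_matrices=False)
        t = u[:, 0] * s[0]
        yy = float(ys @ ys)
        for _ in range(max_iter):
            t_orth = t - ys * (ys @ t) / yy
            w_osc = xs.T @ t_orth / float(t_orth @ t_orth)
            w_osc /= np.linalg.norm(w_osc)
            t_new = xs @ w_osc
            if np.linalg.norm(t_new - t) < tol * max(1.0, np.linalg.norm(t_new)):
                t = t_new
                break
            t = t_new
        # remove the PLS direction from the OSC weights so X @ w_osc is
        # exactly orthogonal to y (see module docstring)
        v = xs.T @ ys
        v /= np.linalg.norm(v)
        w_osc = w_osc - v * float(v @ w_osc)
        nrm = np.linalg.norm(w_osc)
        if nrm < 1e-8:
            # no X-variance orthogonal to the response: OSC has nothing to
            # remove, reduce to plain PLS1
            warnings.warn("degenerate OSC component (no orthogonal variance); "
                          "fitting without signal correction", stacklevel=2)
            w_osc = p_osc = t_osc = None
        else:
            w_osc /= nrm
            t_osc = xs @ w_osc
            p_osc = xs.T @ t_osc / float(t_osc @ t_osc)
            xd = xs - np.outer(t_osc, p_osc)

    # single-component PLS1 on the (possibly deflated) matrix
    w = xd.T @ ys
    nw = np.linalg.norm(w)
    if nw == 0:
        raise ValueError("X'y is zero: no covariance between expression and response")
    w /= nw
    t_pls = xd @ w
    p_pls = xd.T @ t_pls / float(t_pls @ t_pls)
    q = float(ys @ t_pls / (t_pls @ t_pls))
    if np.corrcoef(t_pls, y)[0, 1] < 0:  # sign convention: score increases with y
        w, p_pls, t_pls, q = -w, -p_pls, -t_pls, -q
    return OscPlsModel(genes=genes, x_mean=mu, x_sd=sd, y_mean=y_mean, y_sd=y_sd,
                       w_osc=w_osc, p_osc=p_osc, t_osc=t_osc,
                       w=w, p=p_pls, q=q, t=t_pls, label=label)


def predict_scores(model: OscPlsModel, em: pd.DataFrame,
                   pre_standardized: bool = False) -> pd.Series:
    """Latent scores for new samples.

    Samples are standardized with the *training* means/SDs (skipped when
    ``pre_standardized``, e.g. for cross-species matrices z-scored within
    their own cohort), the OSC component is removed with the training
    w_osc/p_osc, and the score is the projection on the PLS weights.
    """
    if em.shape[1] == 0:
        raise ValueError("empty test set")
    missing = [g for g in model.genes if g not in em.index]
    if missing:
        raise KeyError(f"genes absent from test matrix: {missing[:10]}")
    x = em.loc[model.genes].to_numpy(float).T
    xs = x if pre_standardized else (x - model.x_mean) / model.x_sd
    if model.w_osc is not None:
        t_osc = xs @ model.w_osc
        xs = xs - np.outer(t_osc, model.p_osc)
    return pd.Series(xs @ model.w, index=em.columns, name="score")


def transfer_correlation(model: OscPlsModel, test_em: pd.DataFrame, test_y,
                         test_label: str = "", pre_standardized: bool = False) -> TransferResult:
    """Pearson correlation between predicted scores and the test pseudotime.

    The p-value is the two-sided t-test with n - 2 degrees of freedom.
    """
    y = np.asarray(test_y, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 test samples")
    if np.ptp(y) == 0:
        raise ValueError("constant test pseudotime")
    scores = predict_scores(model, test_em, pre_standardized=pre_standardized)
    if np.ptp(scores.to_numpy()) == 0:
        raise ValueError("constant predicted scores: transfer correlation undefined")
    r, p = stats.pearsonr(scores.to_numpy(), y)
    return TransferResult(model.label, test_label, scores, float(r), float(p), int(y.size))


def zscore_within(em: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-score across the samples of one cohort.

    Genes with zero variance carry no information and are set to 0.
    """
    x = em.to_numpy(float)
    sd = x.std(axis=1, ddof=1)
    mu = x.mean(axis=1)
    z = np.zeros_like(x)
    ok = sd > 0
    z[ok] = (x[ok] - mu[ok, None]) / sd[ok, None]
    return pd.DataFrame(z, index=em.index, columns=em.columns)


def pairwise_transfer_matrix(models: dict[str, OscPlsModel],
                             data: dict[str, tuple[pd.DataFrame, np.ndarray]],
                             within_test_standardize: bool = True) -> pd.DataFrame:
    """Transfer correlations for every (training model, other test model) pair.

    ``models`` maps model label -> fitted OscPlsModel; ``data`` maps label ->
    (expression matrix, pseudotime). Each model is a separate experiment on
    its own time scale, so by default test matrices are z-scored per gene
    within the test cohort before projection (as in the cross-species
    comparison), rather than reusing the training means/SDs. Returns a tidy
    frame with one row per train/test pair.
    """
    rows = []
    for train_label, model in models.items():
        for test_label, (em, y) in data.items():
            if test_label == train_label:
                continue
            test_em = zscore_within(em) if within_test_standardize else em
            res = transfer_correlation(model, test_em, y, test_label=test_label,
                                       pre_standardized=within_test_standardize)
            rows.append((train_label, test_label, res.r, res.pvalue, res.n))
    return pd.DataFrame(rows, columns=["train", "test", "r", "pvalue", "n"])
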