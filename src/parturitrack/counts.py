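"""Count-matrix containers, I/O, TMM normalization and log2-CPM transformation.

The count matrix is genes x samples with nonnegative integer entries; per-sample
metadata (species, model, group, treatment, pseudotime) travels with it in a
sample sheet. Between-sample normalization follows the trimmed mean of M-values
(TMM) scheme: each sample is compared to a reference sample, log-ratios (M) and
average log-abundances (A) are double-trimmed, and the scaling factor is the
precision-weighted mean of the surviving M-values. Factors are rescaled so that
their geometric mean is one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

SHEET_COLUMNS = ["model", "group", "treatment", "pseudotime"]


class CountMatrixError(ValueError):
    """Raised for structurally invalid count data."""


@dataclass
class CountMatrix:
    """Gene x sample integer counts plus a per-sample metadata sheet.

    ``counts`` is indexed by gene id with one column per sample id;
    ``samples`` is indexed by sample id, in the same order as the columns.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise CountMatrixError("duplicate gene ids in count matrix")
        if self.counts.columns.has_duplicates:
            raise CountMatrixError("duplicate sample ids in count matrix")
        if list(self.counts.columns) != list(self.samples.index):
            missing = set(self.samples.index) ^ set(self.counts.columns)
            raise CountMatrixError(
                "sample sheet does not match count columns; offending ids: "
                f"{sorted(missing) if missing else 'ordering mismatch'}"
            )
        vals = self.counts.to_numpy()
        if np.issubdtype(vals.dtype, np.floating):
            if not np.all(np.isfinite(vals)) or np.any(vals != np.round(vals)):
                raise CountMatrixError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
            vals = self.counts.to_numpy()
        if np.any(vals < 0):
            raise CountMatrixError("counts must be nonnegative")
        if "pseudotime" in self.samples.columns:
            pt = pd.to_numeric(self.samples["pseudotime"], errors="coerce")
            ok = pt.isna() | ((pt >= 0.0) & (pt <= 1.0))
            if not ok.all():
                bad = list(self.samples.index[~ok])
                raise CountMatrixError(f"pseudotime outside [0, 1] for samples {bad}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def lib_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_samples(self, sample_ids) -> "CountMatrix":
        ids = list(sample_ids)
        return CountMatrix(self.counts[ids].copy(), self.samples.loc[ids].copy())

    def subset_genes(self, gene_ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(gene_ids)].copy(), self.samples.copy())


@dataclass
class NormFactors:
    """Per-sample TMM scaling factors and raw library sizes."""

    factors: pd.Series
    lib_sizes: pd.Series

    def __post_init__(self) -> None:
        if np.any(self.factors.to_numpy() <= 0):
            raise CountMatrixError("TMM factors must be positive")
        logmean = float(np.mean(np.log(self.factors.to_numpy(float))))
        if abs(logmean) > 1e-8:
            raise CountMatrixError("TMM factors must have geometric mean 1")

    @property
    def effective_lib_sizes(self) -> pd.Series:
        return self.lib_sizes * self.factors


def read_counts(counts_path, sample_sheet_path) -> CountMatrix:
    """Read a TSV count matrix (first column = gene id) and a sample sheet.

    The sheet must have a ``sample_id`` column (or index) covering exactly the
    count columns; samples are reordered to follow the sheet.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    sheet = pd.read_csv(sample_sheet_path, sep="\t")
    if "sample_id" in sheet.columns:
        sheet = sheet.set_index("sample_id")
    sheet.index = sheet.index.astype(str)
    counts.columns = counts.columns.astype(str)
    only_counts = sorted(set(counts.columns) - set(sheet.index))
    only_sheet = sorted(set(sheet.index) - set(counts.columns))
    if only_counts or only_sheet:
        raise CountMatrixError(
            f"sample id mismatch; in counts only: {only_counts}; in sheet only: {only_sheet}"
        )
    return CountMatrix(counts[list(sheet.index)], sheet)


def write_counts(cm: CountMatrix, counts_path, sample_sheet_path) -> None:
    cm.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
    cm.samples.to_csv(sample_sheet_path, sep="\t", index_label="sample_id")


def read_counts_mtx(mtx_path, genes_path, samples_path, sample_sheet_path) -> CountMatrix:
    """Read MatrixMarket counts with row (gene) and column (sample) id files."""
    from scipy.io import mmread
    from scipy.sparse import issparse

    mat = mmread(str(mtx_path))
    mat = np.asarray(mat.todense()) if issparse(mat) else np.asarray(mat)
    genes = [line.strip() for line in Path(genes_path).read_text().splitlines() if line.strip()]
    samples = [line.strip() for line in Path(samples_path).read_text().splitlines() if line.strip()]
    counts = pd.DataFrame(mat, index=genes, columns=samples)
    sheet = pd.read_csv(sample_sheet_path, sep="\t")
    if "sample_id" in sheet.columns:
        sheet = sheet.set_index("sample_id")
    return CountMatrix(counts[list(sheet.index)], sheet)


def _tmm_pair_factor(obs: np.ndarray, lib_obs: float, ref: np.ndarray,
                     lib_ref: float, trim_m: float, trim_a: float) -> float:
    """TMM factor of one sample against the reference (doubly trimmed,
    precision-weighted mean of M-values)."""
    pos = (obs > 0) & (ref > 0)
    if not pos.any():
        return 1.0
    o = obs[pos] / lib_obs
    r = ref[pos] / lib_ref
    m = np.log2(o / r)
    a = 0.5 * np.log2(o * r)
    # inverse of the delta-method variance of M
    w = (lib_obs - obs[pos]) / (lib_obs * obs[pos]) + (lib_ref - ref[pos]) / (lib_ref * ref[pos])
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = rankdata(m)
    rank_a = rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    f = 2.0 ** (np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))
    return float(f) if np.isfinite(f) and f > 0 else 1.0


def tmm_factors(cm: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05,
                ref_sample: str | None = None) -> NormFactors:
    """Trimmed-mean-of-M-values scaling factors, geometric mean rescaled to 1.

    The reference is the sample whose 75th-percentile count fraction is closest
    to the across-sample mean, unless ``ref_sample`` is given.
    """
    if cm.counts.shape[1] < 2:
        raise CountMatrixError("TMM requires at least 2 samples")
    y = cm.counts.to_numpy(float)
    lib = y.sum(axis=0)
    if np.any(lib <= 0):
        bad = list(cm.sample_ids[lib <= 0])
        raise CountMatrixError(f"samples with zero library size: {bad}")
    f75 = np.quantile(y / lib, 0.75, axis=0)
    if ref_sample is None:
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref_idx = list(cm.sample_ids).index(ref_sample)
    factors = np.array([
        _tmm_pair_factor(y[:, j], lib[j], y[:, ref_idx], lib[ref_idx], trim_m, trim_a)
        for j in range(y.shape[1])
    ])
    factors /= np.exp(np.mean(np.log(factors)))
    return NormFactors(pd.Series(factors, index=cm.sample_ids),
                       pd.Series(lib.astype(np.int64), index=cm.sample_ids))


def log_cpm(cm: CountMatrix, nf: NormFactors, prior_count: float = 0.5) -> pd.DataFrame:
    """log2 counts per million on TMM-effective library sizes.

    value = log2((count + prior) / (libsize * factor + 2 * prior) * 1e6)
    """
    if list(nf.factors.index) != list(cm.sample_ids):
        raise CountMatrixError("normalization factors not aligned with samples")
    eff = nf.effective_lib_sizes.to_numpy(float)
    if np.any(eff <= 0):
        raise CountMatrixError("non-positive effective library size")
    y = cm.counts.to_numpy(float)
    vals = np.log2((y + prior_count) / (eff + 2.0 * prior_count) * 1e6)
    return pd.DataFrame(vals, index=cm.gene_ids, columns=cm.sample_ids)


def drop_zero_genes(x):
    """Remove genes with zero counts in every sample (order preserved).

    Accepts a CountMatrix or a genes x samples DataFrame; returns the same type.
    """
    if isinstance(x, CountMatrix):
        keep = x.counts.sum(axis=1) > 0
        if not keep.any():
            warnings.warn("all genes are zero in every sample", stacklevel=2)
        return CountMatrix(x.counts.loc[keep].copy(), x.samples.copy())
    keep = (x != 0).any(axis=1)
    if not keep.any():
        warnings.warn("all genes are zero in every sample", stacklevel=2)
    return x.loc[keep]
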