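"""Negative-binomial exact-test differential expression.

Counts are modeled per gene as NB with variance mu + phi * mu^2. A common
dispersion is estimated by maximizing the conditional log-likelihood on counts
scaled to a common (geometric-mean) effective library size; per-gene (tagwise)
dispersions shrink the per-gene conditional MLE toward the common value. For a
two-group contrast the group sums of library-equalized counts are compared with
a two-sided exact test: conditional on the observed total, the p-value is the
summed probability of all splits as or less likely than the observed one.
P-values are Benjamini-Hochberg adjusted and DEG sets taken at an FDR cutoff
(0.001 by default; 0.01 for the early/late-wave comparison).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp
from scipy.stats import nbinom, poisson
from statsmodels.stats.multitest import multipletests

from .counts import CountMatrix, NormFactors

_PHI_GRID = np.concatenate([[1e-6], np.geomspace(1e-4, 10.0, 120)])
_POISSON_PHI = 1e-8


@dataclass
class DispersionEstimate:
    common: float
    tagwise: pd.Series
    shrinkage_weight: float = 0.7

    def __post_init__(self) -> None:
        if self.common < 0 or np.any(self.tagwise.to_numpy() < 0):
            raise ValueError("dispersions must be nonnegative")


@dataclass
class ContrastResult:
    """One group-pair contrast: per-gene log2 FC (B relative to A), exact-test
    p-value and BH-FDR."""

    group_a: str
    group_b: str
    table: pd.DataFrame  # columns: logFC, pvalue, fdr

    @property
    def label(self) -> str:
        return f"{self.group_a}_vs_{self.group_b}"

    def deg_set(self, fdr_cutoff: float = 0.001) -> "DEGSet":
        sig = self.table[self.table["fdr"] < fdr_cutoff]
        return DEGSet(self.label,
                      up=set(sig.index[sig["logFC"] > 0]),
                      down=set(sig.index[sig["logFC"] < 0]),
                      threshold=fdr_cutoff)


@dataclass
class DEGSet:
    label: str
    up: set = field(default_factory=set)
    down: set = field(default_factory=set)
    threshold: float = 0.001

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("a gene cannot be both up and down in one set")

    @property
    def genes(self) -> set:
        return self.up | self.down


def _equalized_counts(cm: CountMatrix, nf: NormFactors | None):
    """Counts scaled to the geometric-mean effective library size."""
    y = cm.counts.to_numpy(float)
    lib = y.sum(axis=0)
    eff = lib * nf.factors.to_numpy(float) if nf is not None else lib
    common_lib = float(np.exp(np.mean(np.log(eff))))
    return y * (common_lib / eff), common_lib


def _cond_loglik(pseudo: np.ndarray, group_sizes: list[int], group_slices: list,
                 phi: float) -> np.ndarray:
    """Conditional NB log-likelihood per gene at a single dispersion value
    (terms free of phi dropped); returns one value per gene."""
    r = 1.0 / max(phi, 1e-10)
    ll = np.zeros(pseudo.shape[0])
    for n_g, sl in zip(group_sizes, group_slices):
        yg = pseudo[:, sl]
        t = yg.sum(axis=1)
        ll += (gammaln(yg + r).sum(axis=1)
               - n_g * gammaln(r)
               + gammaln(n_g * r)
               - gammaln(t + n_g * r))
    return ll


def estimate_dispersion(cm: CountMatrix, groups, nf: NormFactors | None = None,
                        shrinkage_weight: float = 0.7) -> DispersionEstimate:
    """Common + tagwise NB dispersion via conditional maximum likelihood.

    Groups with a single sample carry no within-group information and are
    excluded with a warning. The tagwise value is a linear blend
    ``w * common + (1 - w) * per-gene CML``.
    """
    groups = pd.Series(groups, index=cm.sample_ids) if not isinstance(groups, pd.Series) else groups
    keep_ids, sizes = [], []
    for label in pd.unique(groups):
        ids = list(groups.index[groups == label])
        if len(ids) < 2:
            warnings.warn(f"group {label!r} has 1 sample; excluded from dispersion estimation",
                          stacklevel=2)
            continue
        keep_ids.append(ids)
        sizes.append(len(ids))
    if len(sizes) < 1:
        raise ValueError("need at least one group with >=2 samples")
    sub = cm.subset_samples([i for ids in keep_ids for i in ids])
    sub_nf = None
    if nf is not None:
        f = nf.factors.loc[sub.sample_ids]
        sub_nf = NormFactors(f / np.exp(np.mean(np.log(f))), sub.lib_sizes)
    pseudo, _ = _equalized_counts(sub, sub_nf)
    slices, start = [], 0
    for n_g in sizes:
        slices.append(slice(start, start + n_g))
        start += n_g

    # per-gene conditional likelihood profile on a fixed dispersion grid;
    # the common value maximizes the summed profile, refined off-grid
    per_gene_ll = np.stack([_cond_loglik(pseudo, sizes, slices, float(phi))
                            for phi in _PHI_GRID])
    total_ll = per_gene_ll.sum(axis=1)
    i = int(np.argmax(total_ll))
    if i == 0:
        common = 0.0
    else:
        lo = _PHI_GRID[max(i - 1, 0)]
        hi = _PHI_GRID[min(i + 1, _PHI_GRID.size - 1)]
        opt = minimize_scalar(
            lambda lp: -_cond_loglik(pseudo, sizes, slices, float(np.exp(lp))).sum(),
            bounds=(np.log(lo), np.log(hi)), method="bounded",
            options={"xatol": 1e-4})
        common = float(np.exp(opt.x))
    gene_idx = per_gene_ll.argmax(axis=0)
    genewise = np.where(gene_idx == 0, 0.0, _PHI_GRID[gene_idx])
    tagwise = shrinkage_weight * common + (1.0 - shrinkage_weight) * genewise
    return DispersionEstimate(common, pd.Series(tagwise, index=cm.gene_ids),
                              shrinkage_weight)


def _split_logpmf(t: int, n_a: int, n_b: int, phi: float) -> np.ndarray:
    """Log-probability of every split (a, t-a) of the total under equal group
    means; group sums of n iid NB(mu, phi) are NB(n*mu, phi/n)."""
    a = np.arange(t + 1)
    mu = t / (n_a + n_b)
    if phi < _POISSON_PHI:
        lp_a = poisson.logpmf(a, n_a * mu)
        lp_b = poisson.logpmf(t - a, n_b * mu)
    else:
        r_a, r_b = n_a / phi, n_b / phi
        m_a, m_b = n_a * mu, n_b * mu
        lp_a = nbinom.logpmf(a, r_a, r_a / (r_a + m_a))
        lp_b = nbinom.logpmf(t - a, r_b, r_b / (r_b + m_b))
    return lp_a + lp_b


def exact_test_pvalue(s_a: int, s_b: int, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided conditional exact p for group sums ``s_a`` vs ``s_b``."""
    t = int(s_a + s_b)
    if t == 0:
        return 1.0
    joint = _split_logpmf(t, n_a, n_b, phi)
    obs = joint[int(s_a)]
    total = logsumexp(joint)
    mass = logsumexp(joint[joint <= obs + 1e-10])
    return float(min(1.0, np.exp(mass - total)))


def _nb_logpmf(k: np.ndarray, r: np.ndarray, m: np.ndarray) -> np.ndarray:
    """NB log-pmf with mean m and size r (variance m + m^2/r)."""
    return (gammaln(k + r) - gammaln(r) - gammaln(k + 1)
            + r * np.log(r / (r + m)) + k * np.log(m / (r + m)))


def _exact_pvalues_batch(s_a: np.ndarray, s_b: np.ndarray, n_a: int, n_b: int,
                         phi: np.ndarray, block_elems: int = 5_000_000) -> np.ndarray:
    """Vectorized two-sided exact p for many genes at once.

    All splits (a, t-a) of each gene's total are laid out in one flat array
    (chunked by gene blocks to bound memory) and per-gene reductions are done
    with ``reduceat``.
    """
    s_a = np.asarray(s_a, np.int64)
    s_b = np.asarray(s_b, np.int64)
    phi = np.asarray(phi, float)
    t = s_a + s_b
    pvals = np.ones(t.size)
    order = np.arange(t.size)
    nonzero = order[t > 0]
    pos = 0
    while pos < nonzero.size:
        take = [nonzero[pos]]
        elems = t[nonzero[pos]] + 1
        pos += 1
        while pos < nonzero.size and elems + t[nonzero[pos]] + 1 <= block_elems:
            elems += t[nonzero[pos]] + 1
            take.append(nonzero[pos])
            pos += 1
        idx = np.asarray(take)
        tt = t[idx]
        lens = tt + 1
        offsets = np.concatenate([[0], np.cumsum(lens)[:-1]])
        flat_a = np.concatenate([np.arange(L) for L in lens])
        gene = np.repeat(np.arange(idx.size), lens)
        mu = tt / (n_a + n_b)
        m_a = np.repeat(n_a * mu, lens)
        m_b = np.repeat(n_b * mu, lens)
        ph = phi[idx]
        flat_b = np.repeat(tt, lens) - flat_a
        poislike = np.repeat(ph < _POISSON_PHI, lens)
        joint = np.empty(flat_a.size)
        if poislike.any():
            ka, kb = flat_a[poislike], flat_b[poislike]
            ma, mb = m_a[poislike], m_b[poislike]
            joint[poislike] = (-ma + ka * np.log(ma) - gammaln(ka + 1)
                               - mb + kb * np.log(mb) - gammaln(kb + 1))
        nb = ~poislike
        if nb.any():
            r_a = np.repeat(n_a / np.maximum(ph, 1e-12), lens)[nb]
            r_b = np.repeat(n_b / np.maximum(ph, 1e-12), lens)[nb]
            joint[nb] = (_nb_logpmf(flat_a[nb], r_a, m_a[nb])
                         + _nb_logpmf(flat_b[nb], r_b, m_b[nb]))
        obs = joint[offsets + s_a[idx]]
        obs_flat = np.repeat(obs, lens)
        peak = np.maximum.reduceat(joint, offsets)
        shifted = np.exp(joint - np.repeat(peak, lens))
        total = np.add.reduceat(shifted, offsets)
        mass = np.add.reduceat(np.where(joint <= obs_flat + 1e-10, shifted, 0.0),
                               offsets)
        pvals[idx] = np.minimum(1.0, mass / total)
    return pvals


def exact_test(cm: CountMatrix, nf: NormFactors, disp: DispersionEstimate,
               group_a, group_b, groups=None, prior_count: float = 0.5) -> ContrastResult:
    """Exact NB test for every gene between two sample groups.

    ``groups`` defaults to ``cm.samples['group']``. logFC is log2 of the
    normalized mean of B relative to A, with ``prior_count`` added to both.
    """
    groups = cm.samples["group"] if groups is None else pd.Series(groups, index=cm.sample_ids)
    ids_a = list(groups.index[groups == group_a])
    ids_b = list(groups.index[groups == group_b])
    if not ids_a or not ids_b:
        raise ValueError(f"empty group in contrast {group_a} vs {group_b}")
    sub = cm.subset_samples(ids_a + ids_b)
    f = nf.factors.loc[sub.sample_ids]
    f = f / np.exp(np.mean(np.log(f)))
    pseudo, _ = _equalized_counts(sub, NormFactors(f, sub.lib_sizes))
    n_a, n_b = len(ids_a), len(ids_b)
    s_a = np.rint(pseudo[:, :n_a].sum(axis=1)).astype(np.int64)
    s_b = np.rint(pseudo[:, n_a:].sum(axis=1)).astype(np.int64)
    phi = disp.tagwise.loc[sub.gene_ids].to_numpy(float)
    pvals = _exact_pvalues_batch(s_a, s_b, n_a, n_b, phi)
    logfc = np.log2((s_b / n_b + prior_count) / (s_a / n_a + prior_count))
    fdr = bh_adjust(pvals)
    table = pd.DataFrame({"logFC": logfc, "pvalue": pvals, "fdr": fdr},
                         index=sub.gene_ids)
    return ContrastResult(str(group_a), str(group_b), table)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p))):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def deg_sets(results: list[ContrastResult], fdr_cutoff: float = 0.001) -> list[DEGSet]:
    return [r.deg_set(fdr_cutoff) for r in results]


def model_deg_union(results: list[ContrastResult], model_label: str,
                    fdr_cutoff: float = 0.001) -> DEGSet:
    """Genes changing in at least one pairwise comparison within a model.

    Direction is by consistency: genes up in some contrast and down in another
    are kept in the union but in neither directional set.
    """
    up, down = set(), set()
    for r in results:
        s = r.deg_set(fdr_cutoff)
        up |= s.up
        down |= s.down
    ambiguous = up & down
    return DEGSet(model_label, up=up - ambiguous, down=down - ambiguous,
                  threshold=fdr_cutoff)


def overlap_partition(sets: list[DEGSet]) -> dict:
    """Venn partition counts over 2-3 DEG sets, plus the all-model core set
    split into consistently up / consistently down genes."""
    if not 2 <= len(sets) <= 3:
        raise ValueError("overlap_partition expects 2 or 3 sets")
    labels = [s.label for s in sets]
    members = {s.label: s.genes for s in sets}
    universe = set().union(*members.values())
    cells: dict[str, int] = {}
    cell_genes: dict[str, set] = {}
    n = len(sets)
    for mask in range(1, 2 ** n):
        inside = [labels[i] for i in range(n) if mask >> i & 1]
        outside = [labels[i] for i in range(n) if not mask >> i & 1]
        genes = set(universe)
        for lab in inside:
            genes &= members[lab]
        for lab in outside:
            genes -= members[lab]
        key = "&".join(inside)
        cells[key] = len(genes)
        cell_genes[key] = genes
    core = set(universe)
    for lab in labels:
        core &= members[lab]
    core_up = set.intersection(*[s.up for s in sets]) if sets else set()
    core_down = set.intersection(*[s.down for s in sets]) if sets else set()
    return {"labels": labels, "cells": cells, "cell_genes": cell_genes,
            "union_size": len(universe), "core": core,
            "core_up": core_up, "core_down": core_down}
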