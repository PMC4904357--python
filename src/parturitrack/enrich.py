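"""Gene-set over-representation and signed activation Z-scores.

Generic stand-ins for commercial pathway/causal-network statistics: the
over-representation p is the hypergeometric upper tail of the query/set
overlap within a stated gene universe (one-sided Fisher), flagged when
-log10 p exceeds 1.3 (p < 0.05); the activation Z compares observed DEG signs
with the expected regulator-target signs, z = (consistent - inconsistent) /
sqrt(overlap), called activated/inhibited at |z| >= 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

SIGNIFICANCE_NEGLOG10_P = 1.3
ACTIVATION_Z_CUTOFF = 2.0


@dataclass
class GeneSetCollection:
    sets: dict[str, set]
    universe: set

    def __post_init__(self) -> None:
        filtered = {}
        for name, genes in self.sets.items():
            inside = set(genes) & self.universe
            if not inside:
                warnings.warn(f"gene set {name!r} empty after universe filtering; dropped",
                              stacklevel=2)
                continue
            filtered[name] = inside
        self.sets = filtered


def read_gmt(path, universe=None) -> GeneSetCollection:
    """Read GMT (name <tab> description <tab> genes...)."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    if universe is None:
        universe = set().union(*sets.values()) if sets else set()
    return GeneSetCollection(sets, set(universe))


def ora_test(query, collection: GeneSetCollection) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    Returns a frame with overlap, pvalue, neg_log10_p and a significance flag
    at -log10 p > 1.3.
    """
    query = set(query)
    stray = query - collection.universe
    if stray:
        raise ValueError(f"query genes outside the universe: {sorted(stray)[:10]}")
    m = len(collection.universe)
    n_query = len(query)
    if n_query == 0:
        warnings.warn("empty query: all p-values are 1", stacklevel=2)
    rows = []
    for name, genes in collection.sets.items():
        k = len(query & genes)
        p = 1.0 if n_query == 0 else float(hypergeom.sf(k - 1, m, len(genes), n_query))
        p = min(1.0, p)
        rows.append((name, len(genes), k, p, -np.log10(max(p, 1e-300))))
    out = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "pvalue",
                                      "neg_log10_p"]).set_index("set")
    out["significant"] = out["neg_log10_p"] > SIGNIFICANCE_NEGLOG10_P
    return out.sort_values("pvalue")


def activation_z(deg_signs: dict, expected_signs: dict) -> float:
    """Signed activation Z over the genes shared by DEGs and the edge list.

    z = (n_consistent - n_inconsistent) / sqrt(n_overlap); signs are +/-1.
    """
    overlap = set(deg_signs) & set(expected_signs)
    if not overlap:
        raise ValueError("no overlap between DEG signs and regulator targets")
    for g in overlap:
        if deg_signs[g] not in (-1, 1) or expected_signs[g] not in (-1, 1):
            raise ValueError("signs must be +1 or -1")
    consistent = sum(1 for g in overlap if deg_signs[g] == expected_signs[g])
    inconsistent = len(overlap) - consistent
    return float((consistent - inconsistent) / np.sqrt(len(overlap)))


def read_edges(path) -> pd.DataFrame:
    """Signed regulator-target edge TSV: regulator, target, sign (+1/-1)."""
    edges = pd.read_csv(path, sep="\t")
    need = {"regulator", "target", "sign"}
    if not need <= set(edges.columns):
        raise ValueError(f"edge table needs columns {sorted(need)}")
    return edges
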