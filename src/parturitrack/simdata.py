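"""Synthetic three-model parturition time courses and a matched human cohort.

Counts are negative-binomial over gestational pseudotime. Three mouse models
share a monotone "core" program (up and down arms); a further program is
shared by term gestation and progesterone-withdrawal (RU486) preterm labor; a
remodeling program responds only to RU486; an inflammatory program only to
LPS; surgery-transient genes rise after laparotomy in the LPS arm (both LPS
and PBS) and return to baseline by labor. A two-group human cohort (in labor
vs not in labor) copies the core program plus configurable fractions of the
LPS- and RU486-specific programs, so that by construction the human labor
signature most resembles the inflammatory model.

Pseudotime encodings: term gestation {E14: 0, E16: 0.444, E18: 0.889,
LAB: 1.0} (linear in days, E14 to E18.5); treated preterm arms {0.3, 0.9,
1.0}, i.e. 30/90/100 % of the injection-to-labor interval. Vehicle controls
carry the collection pseudotime but zero treatment effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .counts import CountMatrix

PROGRAMS = ("core_up", "core_down", "term_ru486_shared", "ru486_specific",
            "lps_specific", "surgery_transient", "null")

# program proportions mirror the reported DEG composition: the inflammatory
# model's changes are mostly private to it (~80 % of its DEGs), the core set
# shared by all three models is comparatively small, and term gestation and
# progesterone withdrawal share the largest block of regulated genes
DEFAULT_PROGRAM_SIZES = {
    "core_up": 40, "core_down": 60, "term_ru486_shared": 250,
    "ru486_specific": 250, "lps_specific": 500, "surgery_transient": 60,
    "null": 840,
}

TERM_PSEUDOTIME = {"E14": 0.0, "E16": 0.444, "E18": 0.889, "LAB": 1.0}

# (model, group, treatment, pseudotime, treated)
MOUSE_DESIGN = [
    ("term", "E14", "none", 0.0, True),
    ("term", "E16", "none", 0.444, True),
    ("term", "E18", "none", 0.889, True),
    ("term", "LAB", "none", 1.0, True),
    ("ru486", "6h_DMSO", "DMSO", 0.3, False),
    ("ru486", "6h_RU486", "RU486", 0.3, True),
    ("ru486", "18h_RU486", "RU486", 0.9, True),
    ("ru486", "LAB_RU486", "RU486", 1.0, True),
    ("lps", "2h_PBS", "PBS", 0.3, False),
    ("lps", "2h_LPS", "LPS", 0.3, True),
    ("lps", "6h_LPS", "LPS", 0.9, True),
    ("lps", "LAB_LPS", "LPS", 1.0, True),
]


@dataclass
class SimConfig:
    n_genes: int = 2000
    n_per_group: int = 4
    program_sizes: dict = field(default_factory=lambda: dict(DEFAULT_PROGRAM_SIZES))
    lfc_range: tuple = (1.0, 3.0)
    dispersion_shape: float = 2.0
    dispersion_rate: float = 20.0
    libsize_meanlog: float = float(np.log(3e5))
    libsize_sdlog: float = 0.15
    abundance_sdlog: float = 1.2
    # biological stage scatter of individual animals around the nominal
    # collection time (the sample sheet records the nominal pseudotime)
    pseudotime_jitter_sd: float = 0.05
    # low-rank correlated sample-level variation (animal/batch latent
    # factors); this is the structured orthogonal variance OSC removes
    n_noise_factors: int = 3
    noise_factor_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_per_group <= 0:
            raise ValueError("n_genes and n_per_group must be positive")
        unknown = set(self.program_sizes) - set(PROGRAMS)
        if unknown:
            raise ValueError(f"unknown programs: {sorted(unknown)}")
        if any(v < 0 for v in self.program_sizes.values()):
            raise ValueError("program sizes must be nonnegative")
        if sum(self.program_sizes.values()) != self.n_genes:
            raise ValueError("program sizes must sum to n_genes")
        lo, hi = self.lfc_range
        if lo < 0 or hi < lo:
            raise ValueError("lfc_range must satisfy 0 <= lo <= hi")
        if self.dispersion_shape <= 0 or self.dispersion_rate <= 0:
            raise ValueError("dispersion gamma parameters must be positive")
        if self.libsize_sdlog < 0:
            raise ValueError("libsize_sdlog must be nonnegative")
        if self.pseudotime_jitter_sd < 0:
            raise ValueError("pseudotime_jitter_sd must be nonnegative")
        if self.n_noise_factors < 0 or self.noise_factor_sd < 0:
            raise ValueError("noise factor parameters must be nonnegative")


def _transient_shape(pt: float) -> float:
    """Surgery transient: peaks soon after laparotomy, gone by labor onset."""
    return float(np.interp(pt, [0.0, 0.3, 0.9, 1.0], [0.0, 1.0, 0.6, 0.0]))


def _draw_truth(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    width = len(str(config.n_genes))
    genes = [f"g{i:0{width}d}" for i in range(1, config.n_genes + 1)]
    labels = []
    for name in PROGRAMS:
        labels += [name] * config.program_sizes.get(name, 0)
    lo, hi = config.lfc_range
    mag = rng.uniform(lo, hi, size=config.n_genes)
    sign = np.ones(config.n_genes)
    truth = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    truth["program"] = labels
    prog = truth["program"].to_numpy()
    sign[prog == "core_down"] = -1.0
    for name in ("term_ru486_shared", "ru486_specific", "lps_specific"):
        mask = prog == name
        sign[mask] = rng.choice([-1.0, 1.0], size=mask.sum())
    effect = mag * sign
    active_term = np.isin(prog, ["core_up", "core_down", "term_ru486_shared"])
    active_ru = np.isin(prog, ["core_up", "core_down", "term_ru486_shared", "ru486_specific"])
    active_lps = np.isin(prog, ["core_up", "core_down", "lps_specific"])
    truth["effect_term"] = np.where(active_term, effect, 0.0)
    truth["effect_ru486"] = np.where(active_ru, effect, 0.0)
    truth["effect_lps"] = np.where(active_lps, effect, 0.0)
    truth["transient_amp"] = np.where(prog == "surgery_transient", mag, 0.0)
    return truth


def _nb_counts(mu: np.ndarray, phi: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Gamma-Poisson draw with variance mu + phi * mu^2."""
    lam = rng.gamma(shape=1.0 / phi, scale=phi * mu)
    return rng.poisson(lam)


def simulate_mouse_models(config: SimConfig):
    """Generate the three-model mouse count matrix and its truth table.

    Returns (CountMatrix, truth DataFrame). The truth table records each
    gene's program and signed per-unit-pseudotime log2 effect in every model.
    """
    rng = np.random.default_rng(config.seed)
    truth = _draw_truth(config, rng)
    base = rng.lognormal(mean=0.0, sigma=config.abundance_sdlog, size=config.n_genes)
    phi = rng.gamma(shape=config.dispersion_shape,
                    scale=1.0 / config.dispersion_rate, size=config.n_genes)
    phi = np.maximum(phi, 1e-6)
    effect_by_model = {m: truth[f"effect_{m}"].to_numpy() for m in ("term", "ru486", "lps")}
    transient = truth["transient_amp"].to_numpy()
    factor_loadings = rng.normal(0.0, 1.0, size=(config.n_genes, config.n_noise_factors))

    cols, meta = {}, []
    for model, group, treatment, pt, treated in MOUSE_DESIGN:
        for rep in range(1, config.n_per_group + 1):
            pt_real = float(np.clip(pt + rng.normal(0.0, config.pseudotime_jitter_sd), 0.0, 1.0))
            log2mult = np.zeros(config.n_genes)
            if treated:
                log2mult += effect_by_model[model] * pt_real
            if model == "lps":  # laparotomy affects both LPS and PBS arms
                log2mult += transient * _transient_shape(pt_real)
            if config.n_noise_factors:
                f = rng.normal(0.0, config.noise_factor_sd, size=config.n_noise_factors)
                log2mult += factor_loadings @ f
            weights = base * 2.0 ** log2mult
            rel = weights / weights.sum()
            lib = rng.lognormal(config.libsize_meanlog, config.libsize_sdlog)
            sid = f"{model}_{group}_r{rep}"
            cols[sid] = _nb_counts(lib * rel, phi, rng)
            meta.append((sid, "mouse", model, group, treatment, pt))
    counts = pd.DataFrame(cols, index=truth.index)
    sheet = pd.DataFrame(meta, columns=["sample_id", "species", "model", "group",
                                        "treatment", "pseudotime"]).set_index("sample_id")
    return CountMatrix(counts, sheet), truth


def simulate_human_labor(config: SimConfig, truth: pd.DataFrame,
                         frac_core: float = 1.0, frac_lps: float = 0.7,
                         frac_ru486: float = 0.2, ortholog_fraction: float = 0.8,
                         n_il: int = 5, n_nil: int = 5):
    """Generate the matched human in-labor / not-in-labor cohort.

    Returns (CountMatrix, ortholog map DataFrame, human truth DataFrame).
    The in-labor effect copies the core program for a ``frac_core`` subset
    plus ``frac_lps`` of the LPS-specific and ``frac_ru486`` of the
    RU486-specific programs of the mouse truth.
    """
    for name, frac in (("frac_core", frac_core), ("frac_lps", frac_lps),
                       ("frac_ru486", frac_ru486), ("ortholog_fraction", ortholog_fraction)):
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    rng = np.random.default_rng([config.seed, 104729])
    mouse_genes = np.asarray(truth.index)
    n_mapped = int(round(ortholog_fraction * len(mouse_genes)))
    mapped = np.sort(rng.choice(len(mouse_genes), size=n_mapped, replace=False))
    mouse_ids = mouse_genes[mapped]
    human_ids = np.array([g.upper().replace("G", "H", 1) for g in mouse_ids])
    ortho = pd.DataFrame({"mouse_id": mouse_ids, "human_id": human_ids})

    sub = truth.loc[mouse_ids]
    prog = sub["program"].to_numpy()
    effect_h = np.zeros(len(sub))

    def _pick(mask: np.ndarray, frac: float) -> np.ndarray:
        idx = np.flatnonzero(mask)
        take = rng.choice(idx, size=int(round(frac * idx.size)), replace=False)
        sel = np.zeros(len(sub), dtype=bool)
        sel[take] = True
        return sel

    core_mask = _pick(np.isin(prog, ["core_up", "core_down"]), frac_core)
    lps_mask = _pick(prog == "lps_specific", frac_lps)
    ru_mask = _pick(prog == "ru486_specific", frac_ru486)
    effect_h[core_mask] = sub["effect_term"].to_numpy()[core_mask]
    effect_h[lps_mask] = sub["effect_lps"].to_numpy()[lps_mask]
    effect_h[ru_mask] = sub["effect_ru486"].to_numpy()[ru_mask]

    base = rng.lognormal(mean=0.0, sigma=config.abundance_sdlog, size=len(sub))
    phi = np.maximum(rng.gamma(config.dispersion_shape, 1.0 / config.dispersion_rate,
                               size=len(sub)), 1e-6)
    factor_loadings = rng.normal(0.0, 1.0, size=(len(sub), config.n_noise_factors))
    cols, meta = {}, []
    for group, n, labor in (("NIL", n_nil, False), ("IL", n_il, True)):
        pt = 1.0 if labor else 0.889  # E18-equivalent for term-not-in-labor
        for rep in range(1, n + 1):
            log2mult = effect_h.copy() if labor else np.zeros(len(sub))
            if config.n_noise_factors:
                f = rng.normal(0.0, config.noise_factor_sd, size=config.n_noise_factors)
                log2mult = log2mult + factor_loadings @ f
            weights = base * 2.0 ** log2mult
            rel = weights / weights.sum()
            lib = rng.lognormal(config.libsize_meanlog, config.libsize_sdlog)
            sid = f"human_{group}_r{rep}"
            cols[sid] = _nb_counts(lib * rel, phi, rng)
            meta.append((sid, "human", "human", group, "none", pt))
    counts = pd.DataFrame(cols, index=pd.Index(human_ids, name="gene_id"))
    sheet = pd.DataFrame(meta, columns=["sample_id", "species", "model", "group",
                                        "treatment", "pseudotime"]).set_index("sample_id")
    human_truth = pd.DataFrame({"mouse_id": mouse_ids, "program": prog,
                                "effect_human": effect_h},
                               index=pd.Index(human_ids, name="gene_id"))
    return CountMatrix(counts, sheet), ortho, human_truth


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index_label=truth.index.name or "gene_id")


def read_truth(path) -> pd.DataFrame:
    # keep_default_na so the program label "null" survives as a string
    return pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False,
                       na_values=[])
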