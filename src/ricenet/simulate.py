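"""Synthetic expression compendia with planted co-expression structure.

The generator emulates the shape of a spatiotemporal bulk-microarray
compendium: ~176 arrays spread over ~24 tissue/stage categories with at
least three biological replicates each, and planted gene modules whose
members share a latent per-sample factor.

Module genes follow a single-factor Gaussian model

    x_g = mu_g + sigma * ( sqrt(rho) * f  +  sqrt(1 - rho) * eps_g )

so any two members have population correlation exactly ``rho`` — a closed
form the recovery tests lean on.  Each module's factor carries an additive
mean shift in that module's preferred category (standardized back to unit
variance), making module genes both co-expressed and tissue-preferential.
Non-module genes are iid given their baseline.

Raw intensities for normalization tests come from an intensity model with
per-array gain and background plus multiplicative and additive noise:

    y = b_s * ( k_s + exp(x + eps_mult) ) + eps_add
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression_io import ExpressionCompendium, GeneSetCatalog, GOCategory, GuideSet

logger = logging.getLogger("ricenet")

NAMESPACE_CYCLE = ("BP", "MF", "CC")


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Study-shape defaults: 176 arrays, 24 categories, >=3 replicates each.

    ``n_samples`` is the total array count; every category receives at least
    ``replicates_per_category`` arrays and the remainder is distributed
    round-robin, mirroring an unevenly sampled real compendium.
    Intensity-model units: ``baseline_mean``/``baseline_sd`` and
    ``sample_sd`` are on the natural-log intensity scale; ``noise_sd_add``
    is in raw intensity units.
    """

    n_genes: int = 2000
    n_samples: int = 176
    n_categories: int = 24
    replicates_per_category: int = 3
    n_modules: int = 10
    module_size: int = 20
    within_module_rho: float = 0.8
    tissue_effect_sd: float = 3.0
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    sample_sd: float = 0.4
    noise_sd_mult: float = 0.25
    noise_sd_add: float = 30.0
    intensity_scale_sd: float = 0.25   # sd of log per-array gain b_s
    background_lo: float = 80.0        # per-array background k_s ~ U(lo, hi)
    background_hi: float = 120.0
    background_go_terms: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_modules * self.module_size > self.n_genes:
            raise SimulationError("n_modules * module_size exceeds n_genes")
        if not 0.0 <= self.within_module_rho < 1.0:
            raise SimulationError("within_module_rho must be in [0, 1)")
        for name in ("tissue_effect_sd", "sample_sd", "noise_sd_mult",
                     "noise_sd_add", "baseline_sd", "intensity_scale_sd"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")
        if self.n_samples < self.n_categories * self.replicates_per_category:
            raise SimulationError(
                "n_samples too small for the category/replicate minimum"
            )


@dataclass
class SimulationTruth:
    """Planted structure returned alongside the generated compendium."""

    module_members: dict[int, list[str]]
    gene_module: dict[str, int]                  # module genes only
    module_category: dict[int, str]
    gene_preferred_category: dict[str, str]      # module genes only
    array_gain: pd.Series | None = None          # b_s, set by raw generator
    array_background: pd.Series | None = None    # k_s

    def within_module_pairs(self) -> list[tuple[str, str]]:
        pairs = []
        for members in self.module_members.values():
            ms = sorted(members)
            pairs.extend(
                (ms[i], ms[j]) for i in range(len(ms)) for j in range(i + 1, len(ms))
            )
        return pairs

    def guides(self, module_id: int = 0, n_guides: int = 3,
               label: str = "planted-module") -> GuideSet:
        members = self.module_members[module_id]
        return GuideSet(tuple(members[:n_guides]), label=label)


def _sample_layout(cfg: SimulationConfig) -> pd.DataFrame:
    """Assign arrays to categories: replicate minimum, extras round-robin."""
    cats = [f"T{c + 1:02d}" for c in range(cfg.n_categories)]
    counts = {c: cfg.replicates_per_category for c in cats}
    extra = cfg.n_samples - cfg.n_categories * cfg.replicates_per_category
    for i in range(extra):
        counts[cats[i % cfg.n_categories]] += 1
    rows = []
    for c in cats:
        for r in range(1, counts[c] + 1):
            rows.append((f"S{len(rows) + 1:03d}", c, r))
    return pd.DataFrame(rows, columns=["sample_id", "category", "replicate"]
                        ).set_index("sample_id")


def _gene_ids(n: int) -> list[str]:
    # synthetic but RAP-DB-shaped locus identifiers
    return [f"Os{(i % 12) + 1:02d}g{7000000 + i:07d}" for i in range(n)]


def generate_compendium(
    cfg: SimulationConfig,
) -> tuple[ExpressionCompendium, SimulationTruth]:
    """Generate a log-scale compendium plus the planted truth tables."""
    rng = np.random.default_rng(cfg.seed)
    meta = _sample_layout(cfg)
    m = cfg.n_samples
    genes = _gene_ids(cfg.n_genes)
    cats = meta["category"].to_numpy()

    mu = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)
    eps = rng.normal(size=(cfg.n_genes, m))
    x = np.empty((cfg.n_genes, m))

    rho = cfg.within_module_rho
    module_members: dict[int, list[str]] = {}
    gene_module: dict[str, int] = {}
    module_category: dict[int, str] = {}
    preferred: dict[str, str] = {}
    cat_labels = list(dict.fromkeys(cats))

    for mod in range(cfg.n_modules):
        lo = mod * cfg.module_size
        idx = np.arange(lo, lo + cfg.module_size)
        members = [genes[i] for i in idx]
        module_members[mod] = members
        cat = cat_labels[mod % len(cat_labels)]
        module_category[mod] = cat
        for g in members:
            gene_module[g] = mod
            preferred[g] = cat
        # factor: unit-variance noise plus a standardized category shift
        in_cat = (cats == cat).astype(float)
        p = in_cat.mean()
        delta = cfg.tissue_effect_sd
        f_raw = rng.normal(size=m) + delta * in_cat
        f = (f_raw - delta * p) / np.sqrt(1.0 + delta * delta * p * (1.0 - p))
        x[idx] = (
            mu[idx, None]
            + cfg.sample_sd * (np.sqrt(rho) * f[None, :]
                               + np.sqrt(1.0 - rho) * eps[idx])
        )

    bg = np.arange(cfg.n_modules * cfg.module_size, cfg.n_genes)
    x[bg] = mu[bg, None] + cfg.sample_sd * eps[bg]

    values = pd.DataFrame(x, index=genes, columns=meta.index)
    comp = ExpressionCompendium(values, meta)
    truth = SimulationTruth(module_members, gene_module, module_category, preferred)
    logger.info("simulated %d genes x %d samples (%d modules of %d, rho=%.2f)",
                cfg.n_genes, m, cfg.n_modules, cfg.module_size, rho)
    return comp, truth


def generate_raw_intensities(
    comp: ExpressionCompendium,
    cfg: SimulationConfig,
    truth: SimulationTruth | None = None,
    seed_offset: int = 1,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Raw positive intensities y = b_s(k_s + exp(x + e_mult)) + e_add.

    Returns ``(raw, gain, background)`` with the true per-array gain b_s and
    background k_s (also stored on ``truth`` when given).  Intensities are
    floored at a small positive value so the matrix is strictly positive
    even in the far additive-noise tail.
    """
    rng = np.random.default_rng(cfg.seed + seed_offset)
    x = comp.values.to_numpy(float)
    n, m = x.shape
    b = np.exp(rng.normal(0.0, cfg.intensity_scale_sd, size=m))
    k = rng.uniform(cfg.background_lo, cfg.background_hi, size=m)
    e_mult = rng.normal(0.0, cfg.noise_sd_mult, size=(n, m))
    e_add = rng.normal(0.0, cfg.noise_sd_add, size=(n, m))
    y = b[None, :] * (k[None, :] + np.exp(x + e_mult)) + e_add
    n_floored = int((y <= 0).sum())
    if n_floored:
        logger.debug("floored %d non-positive intensities", n_floored)
    y = np.maximum(y, 0.5)
    raw = pd.DataFrame(y, index=comp.values.index, columns=comp.values.columns)
    gain = pd.Series(b, index=comp.values.columns, name="gain")
    background = pd.Series(k, index=comp.values.columns, name="background")
    if truth is not None:
        truth.array_gain = gain
        truth.array_background = background
    return raw, gain, background


def generate_go_catalog(
    truth: SimulationTruth,
    cfg: SimulationConfig,
    gene_ids: list[str] | None = None,
) -> dict[str, GeneSetCatalog]:
    """One exact GO term per planted module plus random background terms.

    Background terms draw 10-50 genes uniformly from the whole platform, so
    every term is EC-eligible.  Namespaces are assigned round-robin over
    BP/MF/CC in term order.  Returns one catalog per namespace.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    genes = gene_ids or sorted(truth.gene_module) + []
    if gene_ids is None:
        raise SimulationError("gene_ids (the platform gene list) is required")
    terms: list[tuple[str, str, tuple[str, ...]]] = []
    for mod, members in truth.module_members.items():
        terms.append((
            f"GO:9{mod:06d}", f"planted module {mod} co-regulated set",
            tuple(sorted(members)),
        ))
    for t in range(cfg.background_go_terms):
        size = int(rng.integers(10, 51))
        members = rng.choice(len(genes), size=size, replace=False)
        terms.append((
            f"GO:8{t:06d}", f"random background set {t}",
            tuple(sorted(genes[i] for i in members)),
        ))
    catalogs = {ns: {} for ns in NAMESPACE_CYCLE}
    for i, (tid, name, members) in enumerate(terms):
        ns = NAMESPACE_CYCLE[i % 3]
        catalogs[ns][tid] = GOCategory(tid, name, members)
    return {ns: GeneSetCatalog(ns, cats) for ns, cats in catalogs.items()}


def module_term_id(module_id: int) -> str:
    """Term identifier the catalog generator assigns to a planted module."""
    return f"GO:9{module_id:06d}"


def module_term_namespace(module_id: int) -> str:
    return NAMESPACE_CYCLE[module_id % 3]
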