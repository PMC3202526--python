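"""Expression coherence, GO over-representation, and tissue preference.

Expression coherence (EC) of a gene set is the fraction of its unordered
gene pairs whose PCC exceeds a fixed similarity threshold (the calibrated
network cutoff).  Significance is judged against size-matched random gene
sets.  Over-representation of GO terms in a gene list uses the one-sided
hypergeometric tail against a configurable background — by default the
genes with at least one network connection — with no multiple-testing
correction (a Benjamini-Hochberg option exists but is off by default).
Tissue preference assigns each gene to the spatiotemporal category of the
single array where its signal is maximal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .coexpression import CorrelationMatrix
from .expression_io import ExpressionCompendium, GeneSetCatalog

logger = logging.getLogger("ricenet")


class FunctionalAnalysisError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Expression coherence
# ---------------------------------------------------------------------------

@dataclass
class ECResult:
    term_id: str
    namespace: str
    set_size: int
    ec: float
    null_ecs: np.ndarray
    empirical_p: float


def _set_indices(corr: CorrelationMatrix, gene_set) -> np.ndarray:
    present = [g for g in dict.fromkeys(gene_set) if g in set(corr.gene_ids)]
    return corr.index_of(present)


def ec_score(corr: CorrelationMatrix, gene_set, pcc_threshold: float) -> float:
    """Fraction of within-set unordered pairs with PCC > threshold.

    Counted over set members present in the correlation matrix, after
    duplicate removal; at least two resolvable members are required.
    """
    idx = _set_indices(corr, gene_set)
    if idx.size < 2:
        raise FunctionalAnalysisError(
            f"gene set has {idx.size} member(s) in the matrix; need >= 2"
        )
    sub = corr.pcc[np.ix_(idx, idx)]
    iu = np.triu_indices(idx.size, k=1)
    return float(np.mean(sub[iu] > pcc_threshold))


def ec_null(
    corr: CorrelationMatrix,
    set_size: int,
    n_draws: int,
    pcc_threshold: float,
    seed: int,
) -> np.ndarray:
    """EC values of ``n_draws`` uniformly sampled gene sets of ``set_size``.

    Genes are sampled without replacement within each draw; seeded.
    """
    if set_size > corr.n_genes:
        raise FunctionalAnalysisError("set_size exceeds gene count")
    if n_draws < 1:
        raise FunctionalAnalysisError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(set_size, k=1)
    out = np.empty(n_draws)
    for d in range(n_draws):
        idx = rng.choice(corr.n_genes, size=set_size, replace=False)
        sub = corr.pcc[np.ix_(idx, idx)]
        out[d] = np.mean(sub[iu] > pcc_threshold)
    return out


def ec_analysis(
    corr: CorrelationMatrix,
    catalog: GeneSetCatalog,
    pcc_threshold: float,
    n_draws: int = 1000,
    seed: int = 0,
) -> list[ECResult]:
    """EC with size-matched random nulls for every EC-eligible category.

    ``empirical_p`` is the fraction of null draws with EC >= the observed EC.
    Null draws are shared between categories of identical size (one seeded
    null per size) to keep the analysis affordable at catalog scale.
    """
    null_cache: dict[int, np.ndarray] = {}
    results = []
    for term_id in catalog.ec_eligible_terms():
        cat = catalog.categories[term_id]
        idx = _set_indices(corr, cat.genes)
        if idx.size < 2:
            continue
        ec = ec_score(corr, cat.genes, pcc_threshold)
        size = int(idx.size)
        if size not in null_cache:
            null_cache[size] = ec_null(
                corr, size, n_draws, pcc_threshold, seed=seed + size
            )
        null = null_cache[size]
        results.append(ECResult(
            term_id=term_id,
            namespace=catalog.namespace,
            set_size=size,
            ec=ec,
            null_ecs=null,
            empirical_p=float(np.mean(null >= ec)),
        ))
    return results


def ec_category_curve(
    results: list[ECResult],
    thresholds: np.ndarray | None = None,
) -> pd.DataFrame:
    """Fraction of GO categories with EC above each threshold, with the
    paired random-null curve (mean over draws).

    One row per (namespace, threshold): ``fraction`` counts observed
    categories with EC > t; ``null_fraction`` is the mean over null draws of
    the same count.
    """
    if not results:
        raise FunctionalAnalysisError("no EC results supplied")
    if thresholds is None:
        thresholds = np.round(np.arange(0.0, 1.0001, 0.05), 10)
    rows = []
    for ns in sorted({r.namespace for r in results}):
        rs = [r for r in results if r.namespace == ns]
        ecs = np.array([r.ec for r in rs])
        nulls = np.stack([r.null_ecs for r in rs])  # categories x draws
        for t in thresholds:
            rows.append((
                ns, float(t),
                float(np.mean(ecs > t)),
                float(np.mean(nulls > t)),
            ))
    return pd.DataFrame(
        rows, columns=["namespace", "threshold", "fraction", "null_fraction"]
    )


def write_ec_results(results: list[ECResult], path) -> None:
    pd.DataFrame(
        [(r.term_id, r.namespace, r.set_size, r.ec, r.empirical_p)
         for r in results],
        columns=["term_id", "namespace", "set_size", "ec", "empirical_p"],
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# Hypergeometric over-representation
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    term_id: str
    namespace: str
    k: int  # overlap with the query list
    n: int  # query size (after background restriction)
    K: int  # term size in the background
    N: int  # background size
    p_value: float
    enriched: bool


def hypergeom_pvalue(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts annotated genes in a size-``n`` draw from a background of ``N``
    genes of which ``K`` carry the annotation.
    """
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def hypergeom_enrichment(
    query_genes,
    background_genes,
    catalog: GeneSetCatalog,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> list[EnrichmentResult]:
    """One-sided hypergeometric over-representation, P(X >= k), per term.

    Query genes outside the background are reported and dropped.  No
    multiple-testing correction by default; ``bh_correct`` applies
    Benjamini-Hochberg to the p-values before flagging (off by default to
    mirror the classical protocol).  Results are sorted by p-value.
    """
    background = set(background_genes)
    query = list(dict.fromkeys(query_genes))
    outside = [g for g in query if g not in background]
    if outside:
        logger.warning("%d query gene(s) outside the background dropped: %s",
                       len(outside), outside[:5])
    query_set = {g for g in query if g in background}
    if not query_set:
        raise FunctionalAnalysisError("query list empty after background restriction")
    N, n = len(background), len(query_set)
    results = []
    for term_id, cat in catalog.categories.items():
        members = set(cat.genes) & background
        K = len(members)
        if K < 1:
            continue
        k = len(members & query_set)
        p = hypergeom_pvalue(k, N, K, n)
        p = min(max(p, np.nextafter(0, 1)), 1.0)
        results.append(EnrichmentResult(
            term_id, catalog.namespace, k, n, K, N, p, False
        ))
    results.sort(key=lambda r: (r.p_value, r.term_id))
    if bh_correct:
        m = len(results)
        q = 1.0
        for rank in range(m, 0, -1):
            r = results[rank - 1]
            q = min(q, r.p_value * m / rank)
            r.enriched = q < alpha
    else:
        for r in results:
            r.enriched = r.p_value < alpha
    return results


def write_enrichment_results(results: list[EnrichmentResult], path) -> None:
    pd.DataFrame(
        [(r.term_id, r.namespace, r.k, r.n, r.K, r.N, r.p_value, r.enriched)
         for r in results],
        columns=["term_id", "namespace", "k", "n", "K", "N", "p_value",
                 "enriched"],
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# Tissue preference
# ---------------------------------------------------------------------------

@dataclass
class TissuePreferenceTable:
    """Per-gene spatiotemporal category of maximal expression."""

    table: pd.DataFrame  # index: gene; columns: category, sample, value

    def category_counts(self) -> pd.Series:
        return self.table["category"].value_counts().sort_index()


def classify_tissue_preference(
    comp: ExpressionCompendium,
    mode: str = "max_sample",
) -> TissuePreferenceTable:
    """Assign each gene to the category of its maximal signal.

    ``max_sample`` (default) uses the single array with the highest value;
    ``category_mean`` uses replicate means per category first.  Exact ties
    resolve deterministically to the lexicographically first category (then
    first sample in compendium order) and are logged.
    """
    if comp.samples_meta is None:
        raise FunctionalAnalysisError("tissue preference needs sample metadata")
    x = comp.values.to_numpy(float)
    cats = comp.categories().to_numpy()
    if mode == "max_sample":
        # order columns by (category, original position) so np.argmax's
        # first-hit rule realizes the documented tie resolution
        order = np.lexsort((np.arange(len(cats)), cats))
        xo = x[:, order]
        j = np.argmax(xo, axis=1)
        maxv = xo[np.arange(len(j)), j]
        n_ties = int(np.sum(np.sum(xo == maxv[:, None], axis=1) > 1))
        if n_ties:
            logger.info("%d gene(s) with tied maxima resolved by category order",
                        n_ties)
        samples = np.array(comp.sample_ids)[order][j]
        categories = cats[order][j]
        df = pd.DataFrame(
            {"category": categories, "sample": samples, "value": maxv},
            index=pd.Index(comp.gene_ids, name="gene_id"),
        )
    elif mode == "category_mean":
        means = comp.values.T.groupby(cats).mean().T  # genes x categories
        cat = means.idxmax(axis=1)
        df = pd.DataFrame(
            {"category": cat, "sample": "", "value": means.max(axis=1)},
            index=pd.Index(comp.gene_ids, name="gene_id"),
        )
    else:
        raise FunctionalAnalysisError(f"unknown mode {mode!r}")
    return TissuePreferenceTable(df)


def write_tissue_preference(tp: TissuePreferenceTable, path) -> None:
    tp.table.to_csv(path, sep="\t", index_label="gene_id",
                    float_format="%.6g")
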