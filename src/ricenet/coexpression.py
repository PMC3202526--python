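"""All-pairs Pearson correlation, threshold calibration, mutual rank, and
co-expression network assembly.

The network keeps a gene pair as an edge when its Pearson correlation
coefficient (PCC) exceeds an empirically calibrated cutoff *and* its mutual
rank (MR) — the geometric mean of the two reciprocal neighbour ranks in each
other's PCC-sorted partner lists — falls below a cutoff.  The study-design
defaults are PCC > 0.64 and MR < 10; the PCC cutoff corresponds to the 99th
percentile of the PCC distribution among 1,000 randomly sampled genes.

The PCC matrix is computed in row blocks so the N x N matrix never has to be
formed at once for calibration-sized problems, and results are guaranteed
independent of the block size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .expression_io import ExpressionCompendium

logger = logging.getLogger("ricenet")

DEFAULT_PCC_MIN = 0.64
DEFAULT_MR_MAX = 10.0


class CoexpressionError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Pearson correlation
# ---------------------------------------------------------------------------

@dataclass
class CorrelationMatrix:
    """Symmetric PCC matrix with unit diagonal over an ordered gene list."""

    gene_ids: list[str]
    pcc: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        if self.pcc.shape != (n, n):
            raise CoexpressionError("PCC matrix shape does not match gene list")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def index_of(self, gene_ids) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lookup[g] for g in gene_ids], dtype=int)
        except KeyError as e:
            raise CoexpressionError(f"gene not in correlation matrix: {e}") from e


def _standardized_rows(x: np.ndarray) -> np.ndarray:
    """Rows centered and scaled so that Z @ Z.T gives the PCC exactly."""
    mu = x.mean(axis=1, keepdims=True)
    xc = x - mu
    norm = np.sqrt((xc * xc).sum(axis=1, keepdims=True))
    if (norm == 0).any():
        bad = np.flatnonzero(norm.ravel() == 0)
        raise CoexpressionError(
            f"constant gene rows reached correlation (indices {bad[:5].tolist()}); "
            "filter them at load"
        )
    return xc / norm


def pearson_matrix(
    comp: ExpressionCompendium, block_size: int | None = None
) -> CorrelationMatrix:
    """Product-moment correlation for all gene pairs across all samples.

    ``block_size`` bounds the number of rows multiplied at a time; the result
    is identical for every block size.
    """
    if comp.n_samples < 3:
        raise CoexpressionError("need >=3 samples for correlation")
    z = _standardized_rows(comp.values.to_numpy(float))
    n = z.shape[0]
    if block_size is None or block_size >= n:
        pcc = z @ z.T
    else:
        pcc = np.empty((n, n))
        for start in range(0, n, block_size):
            stop = min(start + block_size, n)
            pcc[start:stop] = z[start:stop] @ z.T
    np.clip(pcc, -1.0, 1.0, out=pcc)
    pcc = (pcc + pcc.T) / 2.0  # enforce exact symmetry against fp noise
    np.fill_diagonal(pcc, 1.0)
    return CorrelationMatrix(comp.gene_ids, pcc)


# ---------------------------------------------------------------------------
# Threshold calibration
# ---------------------------------------------------------------------------

@dataclass
class ThresholdCalibration:
    """An empirical PCC cutoff with its sampling provenance."""

    n_random_genes: int
    percentile: float
    n_pairs: int
    threshold: float
    seed: int

    def __post_init__(self) -> None:
        expected = self.n_random_genes * (self.n_random_genes - 1) // 2
        if self.n_pairs != expected:
            raise CoexpressionError(
                f"n_pairs {self.n_pairs} != C({self.n_random_genes},2)"
            )
        if not -1.0 <= self.threshold <= 1.0:
            raise CoexpressionError("threshold outside [-1, 1]")


def calibrate_pcc_threshold(
    comp: ExpressionCompendium,
    n_random: int = 1000,
    percentile: float = 99.0,
    seed: int = 0,
) -> ThresholdCalibration:
    """Empirical PCC percentile among randomly sampled genes.

    Samples ``n_random`` genes uniformly without replacement (seeded),
    computes their ~n(n-1)/2 pairwise PCCs, and returns the requested
    percentile with linear interpolation.
    """
    if n_random < 2:
        raise CoexpressionError("n_random must be >= 2")
    if n_random > comp.n_genes:
        raise CoexpressionError(
            f"n_random {n_random} exceeds gene count {comp.n_genes}"
        )
    if not 0.0 < percentile <= 100.0:
        raise CoexpressionError("percentile must be in (0, 100]")
    rng = np.random.default_rng(seed)
    idx = rng.choice(comp.n_genes, size=n_random, replace=False)
    sub = comp.values.iloc[np.sort(idx)]
    corr = pearson_matrix(ExpressionCompendium(sub, comp.samples_meta))
    iu = np.triu_indices(n_random, k=1)
    pairs = corr.pcc[iu]
    thr = float(np.percentile(pairs, percentile, method="linear"))
    logger.info("PCC threshold: %.4f (%gth percentile of %d random pairs)",
                thr, percentile, pairs.size)
    return ThresholdCalibration(n_random, percentile, pairs.size, thr, seed)


def analytic_null_pcc_quantile(n_samples: int, percentile: float = 99.0) -> float:
    """Closed-form null quantile of the sample PCC for iid normal profiles.

    Uses the exact monotone map between the sample correlation r and the
    t statistic with m-2 degrees of freedom: r = t / sqrt(m - 2 + t^2).
    """
    from scipy import stats

    df = n_samples - 2
    t = stats.t.ppf(percentile / 100.0, df)
    return float(t / np.sqrt(df + t * t))


# ---------------------------------------------------------------------------
# Mutual rank
# ---------------------------------------------------------------------------

def _rank_rows(pcc: np.ndarray, tie_method: str, block_size: int | None) -> np.ndarray:
    """R[i, j] = rank of j in gene i's partner list (1 = most correlated).

    Ranks are computed against ALL genes on the platform (the full row),
    excluding the self pair.  Ties are broken by stable gene order by default
    (``tie_method='stable'``); ``'average'`` yields fractional ranks.
    """
    n = pcc.shape[0]
    ranks = np.empty((n, n))
    step = block_size or n
    for start in range(0, n, step):
        stop = min(start + step, n)
        block = pcc[start:stop].copy()
        for local, i in enumerate(range(start, stop)):
            block[local, i] = np.inf  # self sorts first, removed below
        if tie_method == "stable":
            order = np.argsort(-block, axis=1, kind="stable")
            r = np.empty_like(order)
            cols = np.arange(n)
            for local in range(stop - start):
                r[local, order[local]] = cols
            ranks[start:stop] = r  # self has rank 0; others 1..n-1
        elif tie_method == "average":
            from scipy.stats import rankdata

            for local in range(stop - start):
                rr = rankdata(-block[local], method="average")
                ranks[start:stop][local] = rr - 1.0
        else:
            raise CoexpressionError(f"unknown tie method {tie_method!r}")
    return ranks


def mutual_rank(
    corr: CorrelationMatrix,
    tie_method: str = "stable",
    block_size: int | None = None,
) -> np.ndarray:
    """MR(i, j) = sqrt(rank_i(j) * rank_j(i)); symmetric, >= 1 off-diagonal.

    The diagonal is set to 0 (a gene has no rank against itself).
    """
    ranks = _rank_rows(corr.pcc, tie_method, block_size)
    mr = np.sqrt(ranks * ranks.T)
    np.fill_diagonal(mr, 0.0)
    return mr


# ---------------------------------------------------------------------------
# Network assembly
# ---------------------------------------------------------------------------

@dataclass
class CoexpressionNetwork:
    """Thresholded co-expression graph; edges carry pcc and mr attributes."""

    graph: nx.Graph
    pcc_min: float
    mr_max: float
    calibration: ThresholdCalibration | None = field(default=None, repr=False)

    @property
    def node_count(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def edge_count(self) -> int:
        return self.graph.number_of_edges()

    def connected_gene_ids(self) -> list[str]:
        """Genes with at least one retained connection (enrichment background)."""
        return sorted(self.graph.nodes)

    def edge_table(self):
        import pandas as pd

        rows = [
            (min(u, v), max(u, v), d["pcc"], d["mr"])
            for u, v, d in self.graph.edges(data=True)
        ]
        rows.sort()
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "pcc", "mr"])

    def write_edges_tsv(self, path: str | Path) -> None:
        self.edge_table().to_csv(path, sep="\t", index=False,
                                 float_format="%.6g")

    def write_sif(self, path: str | Path) -> None:
        """Cytoscape SIF, interaction type 'co': gene_a co gene_b."""
        with open(path, "w") as fh:
            for _, row in self.edge_table().iterrows():
                fh.write(f"{row.gene_a}\tco\t{row.gene_b}\n")

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.graph, path)


def build_network(
    corr: CorrelationMatrix,
    mr: np.ndarray,
    pcc_min: float = DEFAULT_PCC_MIN,
    mr_max: float = DEFAULT_MR_MAX,
    calibration: ThresholdCalibration | None = None,
) -> CoexpressionNetwork:
    """Retain edge (i, j) iff PCC > pcc_min and MR < mr_max (both strict).

    Nodes are the genes incident to at least one retained edge.
    """
    n = corr.n_genes
    iu = np.triu_indices(n, k=1)
    keep = (corr.pcc[iu] > pcc_min) & (mr[iu] < mr_max)
    g = nx.Graph()
    ii, jj = iu[0][keep], iu[1][keep]
    genes = corr.gene_ids
    g.add_edges_from(
        (genes[i], genes[j], {"pcc": float(corr.pcc[i, j]), "mr": float(mr[i, j])})
        for i, j in zip(ii, jj)
    )
    net = CoexpressionNetwork(g, pcc_min, mr_max, calibration)
    logger.info("network: %d nodes, %d edges (PCC > %.3g, MR < %.3g)",
                net.node_count, net.edge_count, pcc_min, mr_max)
    return net


def network_from_compendium(
    comp: ExpressionCompendium,
    pcc_min: float | None = None,
    mr_max: float = DEFAULT_MR_MAX,
    calibrate: bool = False,
    n_random: int = 1000,
    percentile: float = 99.0,
    seed: int = 0,
    block_size: int | None = None,
    tie_method: str = "stable",
) -> CoexpressionNetwork:
    """Compendium -> thresholded network in one call.

    When ``calibrate`` is set (or ``pcc_min`` is None), the PCC cutoff is the
    empirical ``percentile`` among ``n_random`` randomly sampled genes;
    otherwise the supplied/default cutoff is used as-is.
    """
    comp = comp.drop_constant_genes()
    calibration = None
    if calibrate or pcc_min is None:
        calibration = calibrate_pcc_threshold(
            comp, n_random=min(n_random, comp.n_genes),
            percentile=percentile, seed=seed,
        )
        pcc_min = calibration.threshold
    corr = pearson_matrix(comp, block_size=block_size)
    mr = mutual_rank(corr, tie_method=tie_method, block_size=block_size)
    return build_network(corr, mr, pcc_min, mr_max, calibration)
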