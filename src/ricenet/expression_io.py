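"""Reading and writing of expression compendia, GO annotations and guide lists.

The central container is :class:`ExpressionCompendium`: a gene x sample matrix
of normalized, log-scale intensities plus per-sample metadata mapping each
array to a spatiotemporal category and a replicate index.  Probe-level
matrices are collapsed to one row per gene before any correlation analysis.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("ricenet")

NAMESPACES = ("BP", "MF", "CC")

#: RAP-DB locus identifier pattern, e.g. Os09g0517700.
RAPDB_ID_RE = re.compile(r"^Os\d{2}g\d{7}$")

#: GAF namespace column codes -> short namespace labels.
_GAF_ASPECT = {"P": "BP", "F": "MF", "C": "CC"}


class ExpressionIOError(ValueError):
    """Raised on malformed expression, annotation or metadata input."""


# ---------------------------------------------------------------------------
# ExpressionCompendium
# ---------------------------------------------------------------------------

@dataclass
class ExpressionCompendium:
    """Gene x sample expression matrix with sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene identifier with one column per sample,
        on a normalized log scale.
    samples_meta
        DataFrame indexed by sample identifier with columns ``category``
        and ``replicate``.  May be ``None`` for matrices used only for
        correlation (tissue-preference classification then refuses to run).
    """

    values: pd.DataFrame
    samples_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dups = sorted(idx[idx.duplicated()].unique())
            raise ExpressionIOError(f"duplicate gene identifiers: {dups}")
        if cols.has_duplicates:
            dups = sorted(cols[cols.duplicated()].unique())
            raise ExpressionIOError(f"duplicate sample identifiers: {dups}")
        if self.samples_meta is not None:
            missing = [s for s in cols if s not in self.samples_meta.index]
            if missing:
                raise ExpressionIOError(
                    f"samples without metadata: {missing[:10]}"
                )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def categories(self) -> pd.Series:
        if self.samples_meta is None:
            raise ExpressionIOError("compendium has no sample metadata")
        return self.samples_meta.loc[self.sample_ids, "category"]

    def constant_gene_mask(self) -> np.ndarray:
        """Boolean mask of rows with zero variance across samples."""
        x = self.values.to_numpy(float)
        return np.nanstd(x, axis=1) == 0.0

    def drop_constant_genes(self) -> "ExpressionCompendium":
        """Return a compendium without zero-variance rows (flagged in the log)."""
        mask = self.constant_gene_mask()
        if mask.any():
            flagged = list(self.values.index[mask])
            logger.warning(
                "excluding %d constant gene row(s) from correlation: %s%s",
                len(flagged), flagged[:5], "..." if len(flagged) > 5 else "",
            )
            return replace(self, values=self.values.loc[~mask])
        return self

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionCompendium":
        return replace(self, values=self.values.loc[list(gene_ids)])


def _clean_missing(values: pd.DataFrame, max_missing_frac: float = 0.2) -> pd.DataFrame:
    """Drop rows with too many missing values; impute the rest by row median.

    Downstream mutual-rank computation needs a complete ranking per gene, so
    the correlation stage must see a dense matrix: rows missing more than
    ``max_missing_frac`` of their samples are dropped at load, remaining gaps
    are filled with the row median.
    """
    x = values.to_numpy(float)
    frac_missing = np.mean(~np.isfinite(x), axis=1)
    keep = frac_missing <= max_missing_frac
    if not keep.all():
        logger.warning(
            "dropping %d gene row(s) with >%d%% missing values",
            int((~keep).sum()), int(100 * max_missing_frac),
        )
    values = values.loc[keep]
    x = values.to_numpy(float)
    bad = ~np.isfinite(x)
    if bad.any():
        med = np.nanmedian(np.where(np.isfinite(x), x, np.nan), axis=1)
        x = np.where(bad, med[:, None], x)
        values = pd.DataFrame(x, index=values.index, columns=values.columns)
        logger.info("imputed %d missing cells with row medians", int(bad.sum()))
    return values


def _normalize_ids(ids: Iterable) -> list[str]:
    """Trim whitespace, preserve case; warn (not fail) on non-RAP-DB patterns."""
    out = [str(i).strip() for i in ids]
    n_bad = sum(1 for i in out if not RAPDB_ID_RE.match(i))
    if 0 < n_bad < len(out):
        logger.debug("%d identifier(s) do not match the Os##g####### pattern", n_bad)
    elif n_bad == len(out) and out:
        logger.warning(
            "no identifier matches the RAP-DB Os##g####### pattern "
            "(synthetic or foreign IDs?)"
        )
    return out


def read_expression_table(
    path: str | Path,
    dialect: str = "tsv",
    samples_meta: pd.DataFrame | None = None,
    max_missing_frac: float = 0.2,
) -> ExpressionCompendium:
    """Read an expression matrix from a TSV or GEO series-matrix file.

    For ``dialect='tsv'`` the first column holds gene identifiers and the
    header row holds sample identifiers.  For ``dialect='geo_series_matrix'``
    the table between ``!series_matrix_table_begin`` / ``_end`` is read and
    sample columns are named by GEO accession.
    """
    path = Path(path)
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
    elif dialect == "geo_series_matrix":
        df = _read_series_matrix(path)
    else:
        raise ExpressionIOError(f"unknown dialect: {dialect!r}")

    df.index = _normalize_ids(df.index)
    df.columns = [str(c).strip() for c in df.columns]
    if df.index.has_duplicates:
        dups = sorted(pd.Index(df.index)[pd.Index(df.index).duplicated()].unique())
        raise ExpressionIOError(f"duplicate gene identifiers in {path}: {dups}")

    try:
        numeric = df.apply(pd.to_numeric, errors="raise")
    except (ValueError, TypeError):
        for j, col in enumerate(df.columns):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = df.index[np.flatnonzero(bad)[0]]
                raise ExpressionIOError(
                    f"non-numeric cell at gene {row!r}, sample {col!r} in {path}"
                ) from None
        raise  # pragma: no cover - unreachable
    numeric = _clean_missing(numeric, max_missing_frac)
    logger.info("read %d genes x %d samples from %s", *numeric.shape, path)
    return ExpressionCompendium(values=numeric, samples_meta=samples_meta)


def _read_series_matrix(path: Path) -> pd.DataFrame:
    """Minimal GEO series-matrix reader: the expression block only."""
    lines = path.read_text().splitlines()
    try:
        start = next(i for i, l in enumerate(lines)
                     if l.startswith("!series_matrix_table_begin"))
        end = next(i for i, l in enumerate(lines)
                   if l.startswith("!series_matrix_table_end"))
    except StopIteration:
        raise ExpressionIOError(
            f"{path} has no series_matrix_table_begin/end block"
        ) from None
    block = "\n".join(lines[start + 1:end])
    from io import StringIO

    df = pd.read_csv(StringIO(block), sep="\t", index_col=0)
    df.columns = [str(c).strip().strip('"') for c in df.columns]
    df.index = [str(i).strip().strip('"') for i in df.index]
    return df


def write_expression_table(comp: ExpressionCompendium, path: str | Path,
                           float_format: str = "%.6g") -> None:
    comp.values.to_csv(path, sep="\t", float_format=float_format,
                       index_label="gene_id")


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read ``sample_id<TAB>category<TAB>replicate`` metadata."""
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    df.columns = ["sample_id", "category", "replicate"][: len(df.columns)]
    if df["sample_id"].duplicated().any():
        dups = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"])
        raise ExpressionIOError(f"duplicate sample identifiers in metadata: {dups}")
    return df.set_index("sample_id")


def write_sample_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# Probe collapsing
# ---------------------------------------------------------------------------

def collapse_probes(
    probe_matrix: pd.DataFrame,
    probe_map: Mapping[str, str],
    agg: str = "median",
    unmapped: str = "error",
    samples_meta: pd.DataFrame | None = None,
) -> ExpressionCompendium:
    """Collapse a probe x sample matrix to one row per gene.

    Multi-probe genes are aggregated per sample; the default aggregate is the
    median, robust to a single aberrant probe.  ``unmapped`` controls probes
    absent from ``probe_map``: ``'error'`` raises, ``'drop'`` discards with a
    warning.
    """
    if agg not in ("median", "mean", "max"):
        raise ExpressionIOError(f"unknown aggregation rule: {agg!r}")
    probes = list(probe_matrix.index)
    missing = [p for p in probes if p not in probe_map]
    if missing:
        if unmapped == "error":
            raise ExpressionIOError(
                f"{len(missing)} probe(s) without gene mapping, e.g. {missing[:5]}"
            )
        logger.warning("dropping %d unmapped probe(s)", len(missing))
        probe_matrix = probe_matrix.drop(index=missing)
    genes = pd.Series({p: probe_map[p] for p in probe_matrix.index})
    collapsed = probe_matrix.groupby(genes, sort=True).agg(agg)
    logger.info("collapsed %d probes to %d genes (%s)",
                len(probe_matrix), len(collapsed), agg)
    return ExpressionCompendium(values=collapsed, samples_meta=samples_meta)


# ---------------------------------------------------------------------------
# GO catalogs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GOCategory:
    term_id: str
    term_name: str
    genes: tuple[str, ...]

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetCatalog:
    """GO gene sets for one namespace, restricted to platform genes.

    Categories below ``min_ec_size`` members stay in the catalog (usable for
    enrichment) but are flagged ineligible for expression-coherence analysis.
    """

    namespace: str
    categories: dict[str, GOCategory] = field(default_factory=dict)
    min_ec_size: int = 10

    def __post_init__(self) -> None:
        if self.namespace not in NAMESPACES:
            raise ExpressionIOError(
                f"unknown namespace {self.namespace!r}; expected one of {NAMESPACES}"
            )

    def ec_eligible(self, term_id: str) -> bool:
        return self.categories[term_id].size >= self.min_ec_size

    def ec_eligible_terms(self) -> list[str]:
        return [t for t in self.categories if self.ec_eligible(t)]

    def restrict(self, gene_ids: Iterable[str]) -> "GeneSetCatalog":
        """Intersect every category with ``gene_ids``; idempotent."""
        universe = set(gene_ids)
        cats = {}
        for t, cat in self.categories.items():
            kept = tuple(g for g in cat.genes if g in universe)
            if kept:
                cats[t] = GOCategory(t, cat.term_name, kept)
        return GeneSetCatalog(self.namespace, cats, self.min_ec_size)


def read_gene_sets(
    path: str | Path,
    format: str = "two_column_tsv",
    namespace: str = "BP",
    compendium: ExpressionCompendium | None = None,
    term_names: Mapping[str, str] | None = None,
    min_ec_size: int = 10,
) -> GeneSetCatalog:
    """Read gene -> GO-term annotations into a namespace catalog.

    ``two_column_tsv``: ``gene_id<TAB>term_id`` rows (term names supplied
    separately via ``term_names``).  ``gaf``: GAF 2.x, using the DB object ID
    (col 2), GO ID (col 5) and aspect (col 9) columns; only rows whose aspect
    matches ``namespace`` are kept.
    """
    if namespace not in NAMESPACES:
        raise ExpressionIOError(
            f"unknown namespace {namespace!r}; expected one of {NAMESPACES}"
        )
    pairs: list[tuple[str, str]] = []
    path = Path(path)
    if format == "two_column_tsv":
        df = pd.read_csv(path, sep="\t", comment="#", header=None,
                         usecols=[0, 1], names=["gene_id", "term_id"], dtype=str)
        pairs = list(df.itertuples(index=False, name=None))
    elif format == "gaf":
        for line in path.read_text().splitlines():
            if not line or line.startswith("!"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                continue
            gene, term, aspect = cols[1].strip(), cols[4].strip(), cols[8].strip()
            if _GAF_ASPECT.get(aspect) == namespace:
                pairs.append((gene, term))
    else:
        raise ExpressionIOError(f"unknown annotation format: {format!r}")

    by_term: dict[str, set[str]] = {}
    for gene, term in pairs:
        by_term.setdefault(term, set()).add(gene)
    names = dict(term_names or {})
    cats = {
        t: GOCategory(t, names.get(t, t), tuple(sorted(gs)))
        for t, gs in sorted(by_term.items())
    }
    catalog = GeneSetCatalog(namespace, cats, min_ec_size)
    if compendium is not None:
        catalog = catalog.restrict(compendium.gene_ids)
    logger.info("read %d %s categories from %s", len(catalog.categories),
                namespace, path)
    return catalog


def write_gene_sets(catalog: GeneSetCatalog, path: str | Path) -> None:
    with open(path, "w") as fh:
        for t, cat in catalog.categories.items():
            for g in cat.genes:
                fh.write(f"{g}\t{t}\n")


# ---------------------------------------------------------------------------
# Guide sets
# ---------------------------------------------------------------------------

@dataclass
class GuideSet:
    """A nonempty list of guide-gene identifiers with a free-text label."""

    guide_ids: tuple[str, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.guide_ids:
            raise ExpressionIOError("guide set is empty")
        self.guide_ids = tuple(_normalize_ids(self.guide_ids))

    def resolve(self, gene_ids: Iterable[str]) -> tuple[list[str], list[str]]:
        """Split guides into (present, missing) against a gene universe.

        Unresolvable identifiers are reported, never silently dropped.
        """
        universe = set(gene_ids)
        present = [g for g in self.guide_ids if g in universe]
        missing = [g for g in self.guide_ids if g not in universe]
        if missing:
            logger.warning("guide set %r: %d unresolved id(s): %s",
                           self.label, len(missing), missing)
        return present, missing


def read_guide_list(path: str | Path, label: str = "") -> GuideSet:
    ids = [l.strip() for l in Path(path).read_text().splitlines()
           if l.strip() and not l.startswith("#")]
    return GuideSet(tuple(ids), label=label or Path(path).stem)
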