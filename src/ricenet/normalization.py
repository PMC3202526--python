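"""Variance-stabilizing normalization of raw microarray intensities.

Arrays are calibrated against a median pseudo-array and transformed with a
generalized log (arsinh) on the log2 scale:

    h_s(y) = glog((y - a_s) / b_s),    glog(z) = ln(z + sqrt(z^2 + 1)) / ln 2

The per-array affine parameters (a_s, b_s) are estimated by trimmed least
squares: the glog-transformed array is matched to the glog-transformed
median pseudo-array, with the largest residuals ignored.  This is the same
model family as full VSN but a deliberately simpler estimator; a
``passthrough`` mode accepts externally normalized matrices, and ``log2``
offers a plain shifted-log alternative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .expression_io import ExpressionCompendium

logger = logging.getLogger("ricenet")

_LN2 = np.log(2.0)


class NormalizationError(ValueError):
    pass


def glog(z: np.ndarray | float) -> np.ndarray | float:
    """Generalized log on the log2 scale: arsinh(z)/ln 2.

    Strictly increasing, defined for all reals, and asymptotically equal to
    log2(2z) for large positive z (within 0.01 beyond z ~ 2^10 / 2).
    """
    return np.arcsinh(z) / _LN2


@dataclass
class NormalizationModel:
    """Per-array affine calibration plus the transform applied after it."""

    params: pd.DataFrame  # index: sample_id; columns: a, b
    transform: str = "glog_vsn"  # glog_vsn | log2 | passthrough

    def __post_init__(self) -> None:
        if self.transform not in ("glog_vsn", "log2", "passthrough"):
            raise NormalizationError(f"unknown transform {self.transform!r}")
        if self.transform != "passthrough" and (self.params["b"] <= 0).any():
            bad = list(self.params.index[self.params["b"] <= 0])
            raise NormalizationError(f"non-positive scale b for arrays: {bad}")

    def to_tsv(self, path) -> None:
        self.params.to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path, transform: str = "glog_vsn") -> "NormalizationModel":
        return cls(pd.read_csv(path, sep="\t", index_col="sample_id"), transform)

    @classmethod
    def identity(cls, sample_ids, transform: str = "passthrough"):
        params = pd.DataFrame(
            {"a": 0.0, "b": 1.0}, index=pd.Index(sample_ids, name="sample_id")
        )
        return cls(params, transform)


def _fit_one_array(y: np.ndarray, target: np.ndarray, trim_fraction: float,
                   n_refits: int = 3) -> tuple[float, float]:
    """Trimmed least-squares fit of glog((y-a)/b) to ``target``.

    Optimizes over (a, log b) so b stays positive.  The trim set is
    re-selected after each fit (classic alternating trimmed LS).
    """
    # moment-based start: match location/scale of the raw intensities
    b0 = max(np.median(np.abs(y - np.median(y))) /
             max(np.median(np.abs(np.sinh(target * _LN2) -
                                  np.median(np.sinh(target * _LN2)))), 1e-12),
             1e-6)
    x = np.array([0.0, np.log(b0)])
    keep = np.ones(len(y), bool)
    n_keep = max(int(round((1.0 - trim_fraction) * len(y))), 2)
    for _ in range(n_refits):
        res = least_squares(
            lambda p: glog((y[keep] - p[0]) / np.exp(p[1])) - target[keep],
            x, method="lm", max_nfev=200,
        )
        x = res.x
        r = np.abs(glog((y - x[0]) / np.exp(x[1])) - target)
        keep = np.zeros(len(y), bool)
        keep[np.argsort(r, kind="stable")[:n_keep]] = True
    return float(x[0]), float(np.exp(x[1]))


def _variance_gauge(z: np.ndarray, n_bins: int = 20) -> tuple[float, float]:
    """Estimate the glog offset/scale that stabilizes variance.

    After relative calibration all arrays live on a common intensity scale
    ``z``.  The per-gene SD across arrays is modelled as
    ``sd(m)^2 = (M * (m - alpha))^2 + A^2`` — a multiplicative component
    proportional to the background-corrected level plus an additive floor.
    The glog argument ``(z - alpha) / lambda`` with ``lambda = A / M`` then
    has asymptotically constant variance at every intensity.

    Returns ``(alpha, lambda)``; falls back to ``(0, 1)`` when the data show
    no intensity-dependent variance (e.g. identical or noiseless arrays).
    """
    m = np.mean(z, axis=1)
    s = np.std(z, axis=1, ddof=1)
    order = np.argsort(m, kind="stable")
    edges = np.linspace(0, len(m), n_bins + 1).astype(int)
    mb = np.array([np.median(m[order[edges[i]:edges[i + 1]]])
                   for i in range(n_bins)])
    sb = np.array([np.median(s[order[edges[i]:edges[i + 1]]])
                   for i in range(n_bins)])
    if not np.all(np.isfinite(sb)) or sb.max() <= 0:
        return 0.0, 1.0
    # slope of the multiplicative regime from the upper half of the bins;
    # the background offset is the line's intensity intercept, clipped so it
    # never exceeds the dimmest bin
    top = slice(n_bins // 2, n_bins)
    slope, intercept = np.polyfit(mb[top], sb[top], 1)
    if slope <= 0 or not np.isfinite(slope):
        return 0.0, 1.0
    alpha = float(np.clip(-intercept / slope, 0.0, 0.75 * mb[0]))
    # additive floor: bottom-bin SD after removing the multiplicative part
    floor2 = float(np.median(sb[:2]) ** 2
                   - (slope * (np.median(mb[:2]) - alpha)) ** 2)
    lam = float(np.sqrt(max(floor2, 0.0)) / slope)
    # keep the dimmest data out of the glog's steep near-linear region even
    # when the additive floor is hard to separate from the trend
    lam = max(lam, 0.25 * (mb[0] - alpha))
    if not np.isfinite(lam) or lam <= 0:
        return 0.0, 1.0
    return alpha, lam


def fit_vsn(raw: pd.DataFrame, trim_fraction: float = 0.1) -> NormalizationModel:
    """Fit per-array (a_s, b_s) for the glog transform.

    Two stages:

    1. *Relative calibration*: per array, trimmed least squares matches the
       glog-transformed array to the glog-transformed median pseudo-array,
       guarding against differentially expressed genes (``trim_fraction``
       of the largest residuals ignored).
    2. *Gauge fixing*: a single global offset/scale for the glog argument is
       estimated from the variance-vs-intensity relationship of the
       calibrated data and folded into every array's (a_s, b_s), so the
       transform actually stabilizes variance rather than inheriting the
       raw reference's arbitrary offset.

    Parameters
    ----------
    raw
        Gene x sample matrix of nonnegative raw intensities.
    trim_fraction
        Fraction of largest residuals ignored in each array's fit
        (default 0.1).
    """
    if raw.shape[1] < 2:
        raise NormalizationError("need at least 2 arrays to fit a reference")
    y = raw.to_numpy(float)
    if (y < 0).any():
        raise NormalizationError("raw intensities must be nonnegative")
    zero = np.flatnonzero((y == 0).all(axis=0))
    if zero.size:
        raise NormalizationError(
            f"array(s) with all-zero intensities: {list(raw.columns[zero])}"
        )
    reference = np.median(y, axis=1)
    target = glog(reference)
    a1 = np.empty(y.shape[1])
    b1 = np.empty(y.shape[1])
    for j in range(y.shape[1]):
        a1[j], b1[j] = _fit_one_array(y[:, j], target, trim_fraction)
    z = (y - a1[None, :]) / b1[None, :]
    alpha, lam = _variance_gauge(z)
    params = pd.DataFrame(
        {"a": a1 + b1 * alpha, "b": b1 * lam},
        index=pd.Index(raw.columns, name="sample_id"),
    )
    logger.info(
        "fit VSN calibration for %d arrays (trim=%.2f, gauge alpha=%.3g "
        "lambda=%.3g)", len(params), trim_fraction, alpha, lam,
    )
    return NormalizationModel(params, "glog_vsn")


def apply_normalization(
    raw: pd.DataFrame,
    model: NormalizationModel,
    samples_meta: pd.DataFrame | None = None,
) -> ExpressionCompendium:
    """Apply a fitted model; output values are on a log2-like scale."""
    if model.transform == "passthrough":
        return ExpressionCompendium(raw.copy(), samples_meta)
    missing = [s for s in raw.columns if s not in model.params.index]
    if missing:
        raise NormalizationError(f"model lacks parameters for arrays: {missing}")
    a = model.params.loc[raw.columns, "a"].to_numpy()
    b = model.params.loc[raw.columns, "b"].to_numpy()
    z = (raw.to_numpy(float) - a) / b
    if model.transform == "glog_vsn":
        out = glog(z)
    else:  # log2; undefined below the offset, masked to NaN then row-imputed
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(z > 0, np.log2(np.maximum(z, 1e-300)), np.nan)
    values = pd.DataFrame(out, index=raw.index, columns=raw.columns)
    if values.isna().any().any():
        med = values.median(axis=1)
        values = values.apply(lambda col: col.fillna(med))
    return ExpressionCompendium(values, samples_meta)


def normalize(
    raw: pd.DataFrame,
    method: str = "vsn",
    trim_fraction: float = 0.1,
    samples_meta: pd.DataFrame | None = None,
) -> tuple[ExpressionCompendium, NormalizationModel]:
    """One-call normalization: fit (if needed) and apply."""
    if method == "vsn":
        model = fit_vsn(raw, trim_fraction)
    elif method == "log2":
        model = NormalizationModel.identity(raw.columns, "log2")
    elif method == "passthrough":
        model = NormalizationModel.identity(raw.columns, "passthrough")
    else:
        raise NormalizationError(f"unknown normalization method {method!r}")
    return apply_normalization(raw, model, samples_meta), model


def replicate_sd_profile(
    values: pd.DataFrame,
    samples_meta: pd.DataFrame,
    n_bins: int = 10,
) -> pd.DataFrame:
    """SD of replicate differences in equal-count mean-intensity bins.

    For every category with >=2 replicates, differences between consecutive
    replicate measurements of each gene are pooled, binned by the gene's mean
    level in that category, and the within-bin SD computed.  A flat profile
    (max/min ratio near 1) indicates intensity-independent noise.
    """
    cats = samples_meta.loc[values.columns, "category"]
    diffs, means = [], []
    for cat in cats.unique():
        cols = values.columns[(cats == cat).to_numpy()]
        if len(cols) < 2:
            continue
        block = values[cols].to_numpy(float)
        diffs.append((block[:, 1:] - block[:, :-1]).ravel())
        m = block.mean(axis=1)
        means.append(np.repeat(m, block.shape[1] - 1))
    d = np.concatenate(diffs)
    m = np.concatenate(means)
    order = np.argsort(m, kind="stable")
    d, m = d[order], m[order]
    edges = np.linspace(0, len(d), n_bins + 1).astype(int)
    rows = []
    for i in range(n_bins):
        sl = slice(edges[i], edges[i + 1])
        rows.append((float(np.mean(m[sl])), float(np.std(d[sl]))))
    return pd.DataFrame(rows, columns=["mean_intensity", "replicate_sd"])
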