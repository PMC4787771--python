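"""Replicate pooling and between-sample normalization.

Two distinct data paths feed the downstream analyses and are never
mixed:

* differential expression uses replicate-collapsed matrices — counts are
  *summed* and array log-ratios *averaged* across the preparation and
  chip/lane replicates within each biological replicate, leaving two
  true replicates per condition (anything else would be pseudoreplication
  that understates the within-group variance);
* the variance decomposition uses the full unpooled 16-sample matrices,
  since the replicate structure is exactly what it quantifies.

Counts are placed on the log2 scale as log-counts-per-million with a
mean-variance precision-weight trend in the style of voom; TMM, RLE and
quantile normalization are offered for scaling between samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io_design import ExpressionMatrix, NestedDesign

__all__ = [
    "WeightedLogMatrix",
    "pool_counts",
    "average_array",
    "log_cpm",
    "voom_weights",
    "tmm_factors",
    "rle_factors",
    "quantile_normalize",
    "normalized_log_matrix",
]

WEIGHT_FLOOR = 1e-6


@dataclass
class WeightedLogMatrix:
    """log2 expression values with per-observation precision weights."""

    values: pd.DataFrame  # genes x samples, log2 scale
    weights: pd.DataFrame  # same shape, strictly positive
    norm_factors: pd.Series  # one per sample, geometric mean 1
    lib_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.shape != self.weights.shape:
            raise ValueError("values and weights must have the same shape")
        if (self.weights.to_numpy() <= 0).any():
            raise ValueError("weights must be strictly positive")

    @property
    def genes(self):
        return self.values.index

    @property
    def samples(self):
        return self.values.columns


def _collapse_design(design: NestedDesign) -> pd.DataFrame:
    t = design.table.drop_duplicates("biological")
    return pd.DataFrame(
        {"sample": t["biological"].values, "condition": t["condition"].values}
    )


def pool_counts(counts: ExpressionMatrix, design: NestedDesign):
    """Sum counts over preparation and chip/lane replicates per biological replicate.

    Returns the pooled :class:`ExpressionMatrix` (one column per
    biological replicate; four for the canonical design) and the
    collapsed design table (columns ``sample, condition``).
    """
    if counts.platform != "counts":
        raise ValueError("pool_counts requires platform='counts'")
    t = design.table
    if list(counts.samples) != list(t["sample"]):
        raise ValueError("matrix samples do not match design samples")
    grouped = counts.values.T.groupby(t.set_index("sample")["biological"]).sum().T
    bios = t.drop_duplicates("biological")["biological"].tolist()
    grouped = grouped[bios]
    grouped.columns.name = None
    pooled = ExpressionMatrix(grouped, "counts", counts.intensity)
    return pooled, _collapse_design(design)


def average_array(ratios: ExpressionMatrix, design: NestedDesign):
    """Average log-ratios over preparation and chip replicates per biological replicate."""
    if ratios.platform != "logratio":
        raise ValueError("average_array requires platform='logratio'")
    t = design.table
    if list(ratios.samples) != list(t["sample"]):
        raise ValueError("matrix samples do not match design samples")
    grouped = ratios.values.T.groupby(t.set_index("sample")["biological"]).mean().T
    bios = t.drop_duplicates("biological")["biological"].tolist()
    grouped = grouped[bios]
    grouped.columns.name = None
    averaged = ExpressionMatrix(grouped, "logratio", ratios.intensity)
    return averaged, _collapse_design(design)


def log_cpm(counts, lib_sizes=None, prior: float = 0.5):
    """log2 counts-per-million: log2((y + prior) / (L + 2 prior) * 1e6)."""
    y = np.asarray(counts, dtype=float)
    if lib_sizes is None:
        lib_sizes = y.sum(axis=0)
    lib = np.asarray(lib_sizes, dtype=float)
    if (lib <= 0).any():
        raise ValueError("library sizes must be positive")
    out = np.log2((y + prior) / (lib + 2.0 * prior) * 1e6)
    if isinstance(counts, pd.DataFrame):
        return pd.DataFrame(out, index=counts.index, columns=counts.columns)
    return out


def _condition_design_matrix(condition_labels) -> np.ndarray:
    labels = pd.Series(list(condition_labels))
    levels = sorted(labels.unique())
    if len(levels) != 2:
        raise ValueError(f"expected 2 condition levels, found {levels}")
    ind = (labels == levels[1]).to_numpy(float)
    return np.column_stack([np.ones(len(labels)), ind])


def voom_weights(
    counts: ExpressionMatrix | pd.DataFrame,
    condition_labels,
    norm_factors=None,
    span: float = 0.5,
    prior: float = 0.5,
) -> WeightedLogMatrix:
    """log2-CPM with precision weights from the fitted mean-variance trend.

    Gene-wise linear models (condition means) are fit to log2-CPM; a
    locally weighted regression of sqrt(residual sd) on mean log2 count
    gives the technical variance trend, and each observation's weight is
    the predicted fourth inverse power at its fitted log-count.  Weights
    are floored at a small positive constant.
    """
    values = counts.values if isinstance(counts, ExpressionMatrix) else counts
    y = values.to_numpy(float)
    n_genes, n_samples = y.shape
    lib = y.sum(axis=0)
    if norm_factors is not None:
        lib = lib * np.asarray(norm_factors, dtype=float)
    X = _condition_design_matrix(condition_labels)
    p = np.linalg.matrix_rank(X)
    df_resid = n_samples - p
    if df_resid < 1:
        raise ValueError("model leaves no residual degrees of freedom")
    if df_resid < 2:
        raise ValueError(
            "voom_weights needs >= 2 residual degrees of freedom to "
            "estimate the mean-variance trend"
        )
    logc = log_cpm(y, lib, prior=prior)
    # common hat matrix: one design for all genes, unit weights at this stage
    pinv = np.linalg.pinv(X)
    coef = logc @ pinv.T  # genes x p
    fitted = coef @ X.T
    resid = logc - fitted
    s = np.sqrt((resid**2).sum(axis=1) / df_resid)  # residual sd per gene
    mean_logcount = logc.mean(axis=1) + np.log2(np.exp(np.mean(np.log(lib + 1)))) - np.log2(1e6)
    sqrt_s = np.sqrt(s)
    trend = lowess(sqrt_s, mean_logcount, frac=span, return_sorted=True)
    tx, ty = trend[:, 0], trend[:, 1]
    # fitted log2 count of every observation, on the same scale as the trend
    fitted_logcount = fitted + (np.log2(lib + 1) - np.log2(1e6))[None, :]
    pred = np.interp(fitted_logcount, tx, ty)  # flat extrapolation at the ends
    pred = np.maximum(pred, np.sqrt(np.sqrt(WEIGHT_FLOOR)))
    w = pred**-4.0
    w = np.maximum(w, WEIGHT_FLOOR)
    idx, cols = values.index, values.columns
    factors = (
        pd.Series(np.asarray(norm_factors, float), index=cols)
        if norm_factors is not None
        else pd.Series(np.ones(n_samples), index=cols)
    )
    return WeightedLogMatrix(
        pd.DataFrame(logc, index=idx, columns=cols),
        pd.DataFrame(w, index=idx, columns=cols),
        factors,
        lib_sizes=pd.Series(lib, index=cols),
    )


def _rescale_geomean(f: np.ndarray) -> np.ndarray:
    return f / np.exp(np.mean(np.log(f)))


def tmm_factors(
    counts,
    ref_column: int | str = "auto",
    logratio_trim: float = 0.30,
    sum_trim: float = 0.05,
    weighted: bool = True,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors.

    For each sample versus the reference, M (log-ratio) and A (mean
    log-abundance) values are computed over genes positive in both
    libraries after library-size adjustment, doubly trimmed (30% on M,
    5% on A by default), and combined as a precision-weighted mean; the
    factor is 2 to that mean.  Factors are rescaled to geometric mean 1.
    """
    values = counts.values if isinstance(counts, ExpressionMatrix) else counts
    y = np.asarray(values, dtype=float)
    cols = values.columns if isinstance(values, pd.DataFrame) else range(y.shape[1])
    lib = y.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("every column must have a positive total")
    if ref_column == "auto":
        # column whose upper quartile of scaled counts is closest to the mean
        uq = np.array([np.quantile(y[:, j] / lib[j], 0.75) for j in range(y.shape[1])])
        ref = int(np.argmin(np.abs(uq - uq.mean())))
    elif isinstance(ref_column, str):
        ref = list(cols).index(ref_column)
    else:
        ref = int(ref_column)

    factors = np.ones(y.shape[1])
    for j in range(y.shape[1]):
        if j == ref:
            factors[j] = 1.0
            continue
        obs, refc = y[:, j], y[:, ref]
        keep = (obs > 0) & (refc > 0)
        po, pr = obs[keep] / lib[j], refc[keep] / lib[ref]
        m = np.log2(po / pr)
        a = 0.5 * np.log2(po * pr)
        # asymptotic binomial variance of M, used as precision weight
        v = (lib[j] - obs[keep]) / (lib[j] * obs[keep]) + (lib[ref] - refc[keep]) / (
            lib[ref] * refc[keep]
        )
        n = len(m)
        lo_m = np.floor(n * logratio_trim) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * sum_trim) + 1
        hi_a = n + 1 - lo_a
        rm = rankdata(m)
        ra = rankdata(a)
        kept = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if not kept.any():
            factors[j] = 1.0
            continue
        if weighted:
            factors[j] = 2.0 ** (np.sum(m[kept] / v[kept]) / np.sum(1.0 / v[kept]))
        else:
            factors[j] = 2.0 ** np.mean(m[kept])
    return pd.Series(_rescale_geomean(factors), index=cols, name="tmm_factor")


def rle_factors(counts) -> pd.Series:
    """Relative-log-expression (median-of-ratios) scaling factors."""
    values = counts.values if isinstance(counts, ExpressionMatrix) else counts
    y = np.asarray(values, dtype=float)
    cols = values.columns if isinstance(values, pd.DataFrame) else range(y.shape[1])
    allpos = (y > 0).all(axis=1)
    if not allpos.any():
        raise ValueError("RLE needs at least one gene positive in all samples")
    ref = np.exp(np.mean(np.log(y[allpos]), axis=1))  # per-gene geometric mean
    ratios = y[allpos] / ref[:, None]
    factors = np.median(ratios, axis=0)
    # express as scaling of library size: divide out the library-size part
    factors = _rescale_geomean(factors)
    return pd.Series(factors, index=cols, name="rle_factor")


def quantile_normalize(matrix):
    """Force every column onto the mean order-statistic distribution.

    Ties within a column receive the mean of the reference values they
    would jointly occupy (linear interpolation at fractional ranks).
    """
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    y = np.asarray(values, dtype=float)
    n = y.shape[0]
    ref = np.sort(y, axis=0).mean(axis=1)
    out = np.empty_like(y)
    grid = np.arange(1, n + 1, dtype=float)
    for j in range(y.shape[1]):
        r = rankdata(y[:, j], method="average")
        out[:, j] = np.interp(r, grid, ref)
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    return out


def normalized_log_matrix(
    matrix: ExpressionMatrix, method: str = "none", prior: float = 0.5
) -> pd.DataFrame:
    """Place a platform matrix on a normalized log2 scale for decomposition.

    Counts become log2-CPM with the chosen between-sample scaling (TMM
    or RLE factors fold into the effective library sizes; quantile acts
    on the log2-CPM matrix).  Array log-ratios pass through unchanged
    except under quantile normalization.
    """
    if matrix.platform == "counts":
        lib = matrix.values.sum(axis=0).to_numpy(float)
        if method == "tmm":
            lib = lib * tmm_factors(matrix).to_numpy()
        elif method == "rle":
            # RLE factors already carry sequencing depth: use them as the
            # effective library sizes, anchored at the mean depth
            lib = np.exp(np.mean(np.log(lib))) * rle_factors(matrix).to_numpy()
        logc = log_cpm(matrix.values, lib, prior=prior)
        if method == "quantile":
            logc = quantile_normalize(logc)
        elif method not in ("none", "tmm", "rle"):
            raise ValueError(f"unknown normalization method {method!r}")
        return logc
    if matrix.platform == "logratio":
        if method == "quantile":
            return quantile_normalize(matrix.values)
        if method in ("none", "tmm", "rle"):
            return matrix.values.astype(float)
        raise ValueError(f"unknown normalization method {method!r}")
    raise ValueError(f"unsupported platform {matrix.platform!r}")
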