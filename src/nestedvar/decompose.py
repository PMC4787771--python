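"""Per-gene nested-ANOVA variance decomposition and intensity smoothing.

For each gene's 16-sample profile three nested fixed-effects models are
fit — condition means (2 groups), biological-replicate means (4), and
preparation means (8) — and each experimental stage's share of variance
is read off the *adjusted* R-squared increments:

    condition    = adjR2(M1)
    biological   = adjR2(M2) - adjR2(M1)
    preparation  = adjR2(M3) - adjR2(M2)
    chip/lane    = 1 - adjR2(M3)        (the residual stratum)

with adjR2 = 1 - (1 - R2)(n - 1)/(n - p).  The chip/lane stage is left
as residual because parameterizing it would leave zero residual df.
Negative increments (a small-sample artifact of the adjustment) are
clipped at zero and the four components renormalized to sum to one.

A count-data variant replaces sums of squares with Poisson deviances
(log-linear group-mean models with library-size offsets, deviance
R-squared) and applies the same df adjustment, so discreteness of the
read counts can be ruled out as the source of any platform contrast.

Per-gene fractions are smoothed over intensity quantiles with a locally
weighted quadratic regression (LOESS) carrying a 95% confidence band,
and platform differences are tested within equal-size intensity bins by
a paired Wilcoxon signed-rank test on the per-gene residual fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_design import ExpressionMatrix, NestedDesign

__all__ = [
    "COMPONENTS",
    "SmoothedTrack",
    "nested_r2",
    "count_nested_r2",
    "decompose_matrix",
    "smooth_over_intensity",
    "bin_platform_test",
    "intensity_quantiles",
]

COMPONENTS = ["condition", "biological", "preparation", "residual"]

_LEVELS = ["condition", "biological", "preparation"]


def adjusted_r2(r2: np.ndarray, n: int, p: int) -> np.ndarray:
    """Standard small-sample adjustment: 1 - (1 - R2)(n - 1)/(n - p)."""
    return 1.0 - (1.0 - r2) * (n - 1.0) / (n - p)


def _clip_renormalize(raw: np.ndarray) -> np.ndarray:
    comp = np.clip(raw, 0.0, None)
    total = comp.sum(axis=-1, keepdims=True)
    total[total == 0] = 1.0
    return comp / total


def _group_codes(design: NestedDesign) -> dict[str, np.ndarray]:
    return {level: design.codes(level) for level in _LEVELS}


def _group_mean_matrix(codes: np.ndarray) -> np.ndarray:
    """n x n matrix mapping a sample vector to its group means."""
    n = len(codes)
    m = np.zeros((n, n))
    for g in np.unique(codes):
        mask = codes == g
        m[np.ix_(mask, mask)] = 1.0 / mask.sum()
    return m


def _gaussian_fractions(y: np.ndarray, design: NestedDesign):
    """Vectorized adjusted-R2 decomposition; y is genes x samples."""
    n = y.shape[1]
    codes = _group_codes(design)
    center = y - y.mean(axis=1, keepdims=True)
    tss = (center**2).sum(axis=1)
    degenerate = tss <= 1e-12 * np.maximum(1.0, (y**2).sum(axis=1))
    adj = {}
    raw_r2 = {}
    for level in _LEVELS:
        m = _group_mean_matrix(codes[level])
        fitted = y @ m.T
        rss = ((y - fitted) ** 2).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = 1.0 - rss / tss
        p = len(np.unique(codes[level]))
        raw_r2[level] = r2
        adj[level] = adjusted_r2(r2, n, p)
    raw = np.column_stack(
        [
            adj["condition"],
            adj["biological"] - adj["condition"],
            adj["preparation"] - adj["biological"],
            1.0 - adj["preparation"],
        ]
    )
    frac = _clip_renormalize(raw)
    frac[degenerate] = np.nan
    return frac, degenerate, raw_r2


def _poisson_deviance(y: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """2 sum[y log(y/mu) - (y - mu)], with 0 log 0 = 0; summed over samples."""
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return 2.0 * (term - (y - mu)).sum(axis=-1)


def _count_fractions(y: np.ndarray, design: NestedDesign, lib_sizes: np.ndarray):
    """Deviance-R2 decomposition for counts; y is genes x samples (ints)."""
    n = y.shape[1]
    lib = np.asarray(lib_sizes, dtype=float)
    if lib.shape != (n,) or (lib <= 0).any():
        raise ValueError("lib_sizes must be positive, one per sample")
    codes = _group_codes(design)
    total = y.sum(axis=1)
    degenerate = total == 0
    # null model: one common rate; Poisson group-mean MLE has closed form
    rate0 = total / lib.sum()
    mu0 = rate0[:, None] * lib[None, :]
    d0 = _poisson_deviance(y, np.where(mu0 > 0, mu0, np.nan))
    adj = {}
    for level in _LEVELS:
        c = codes[level]
        mu = np.empty_like(y, dtype=float)
        for g in np.unique(c):
            mask = c == g
            rate = y[:, mask].sum(axis=1) / lib[mask].sum()
            mu[:, mask] = rate[:, None] * lib[None, mask]
        dm = _poisson_deviance(y, np.where(mu > 0, mu, np.nan))
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = 1.0 - dm / d0
        p = len(np.unique(c))
        adj[level] = adjusted_r2(r2, n, p)
    raw = np.column_stack(
        [
            adj["condition"],
            adj["biological"] - adj["condition"],
            adj["preparation"] - adj["biological"],
            1.0 - adj["preparation"],
        ]
    )
    # deviance exactly zero under the null happens for flat all-equal rows
    degenerate = degenerate | ~np.isfinite(raw).all(axis=1)
    frac = _clip_renormalize(np.where(np.isfinite(raw), raw, 0.0))
    frac[degenerate] = np.nan
    return frac, degenerate


def nested_r2(y, design: NestedDesign) -> pd.Series:
    """Adjusted-R2 decomposition of one gene's profile into stage fractions."""
    y = np.asarray(y, dtype=float)[None, :]
    if y.shape[1] != len(design.samples):
        raise ValueError("profile length does not match design")
    frac, degenerate, _ = _gaussian_fractions(y, design)
    if degenerate[0]:
        raise ValueError("zero total variance: degenerate gene")
    return pd.Series(frac[0], index=COMPONENTS)


def count_nested_r2(counts, design: NestedDesign, lib_sizes) -> pd.Series:
    """Poisson deviance-R2 decomposition of one gene's count profile."""
    y = np.asarray(counts, dtype=float)[None, :]
    if y.shape[1] != len(design.samples):
        raise ValueError("profile length does not match design")
    frac, degenerate = _count_fractions(y, design, lib_sizes)
    if degenerate[0]:
        raise ValueError("zero total count or null deviance: degenerate gene")
    return pd.Series(frac[0], index=COMPONENTS)


def intensity_quantiles(intensity: pd.Series) -> pd.Series:
    """Average-rank quantiles in (0, 1], ties shared."""
    r = stats.rankdata(intensity.to_numpy(), method="average")
    return pd.Series(r / len(r), index=intensity.index)


def decompose_matrix(
    matrix: ExpressionMatrix | pd.DataFrame,
    design: NestedDesign,
    variant: str = "gaussian",
    values: pd.DataFrame | None = None,
    intensity: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene variance decomposition of an unpooled 16-sample matrix.

    ``variant='gaussian'`` decomposes log-scale values (pass the
    normalized log matrix via ``values`` when ``matrix`` holds raw
    counts); ``variant='count'`` works on the raw counts with Poisson
    deviances and library-size offsets.  Degenerate genes (no variance
    or zero total count) are flagged, not dropped, and carry NaN
    fractions.
    """
    if isinstance(matrix, ExpressionMatrix):
        base = matrix.values
        intens = matrix.intensity if intensity is None else intensity
    else:
        base = matrix
        if intensity is None:
            raise ValueError("intensity required when passing a bare DataFrame")
        intens = intensity
    if list(base.columns) != design.samples:
        raise ValueError("matrix samples do not match design")
    if variant == "gaussian":
        y = (values if values is not None else base).to_numpy(float)
        frac, degenerate, _ = _gaussian_fractions(y, design)
    elif variant == "count":
        y = base.to_numpy(float)
        if (y < 0).any() or not np.allclose(y, np.round(y)):
            raise ValueError("count variant requires nonnegative integer values")
        lib = y.sum(axis=0)
        frac, degenerate = _count_fractions(y, design, lib)
    else:
        raise ValueError("variant must be 'gaussian' or 'count'")
    out = pd.DataFrame(frac, index=base.index, columns=COMPONENTS)
    out["degenerate"] = degenerate
    out["intensity"] = pd.Series(intens).reindex(base.index)
    out["quantile"] = intensity_quantiles(out["intensity"])
    return out


@dataclass
class SmoothedTrack:
    """A LOESS curve over intensity quantiles with a 95% band."""

    grid: np.ndarray
    value: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    component: str = ""
    platform: str = ""

    def __post_init__(self) -> None:
        if not (
            np.all(self.lower <= self.value + 1e-12)
            and np.all(self.value <= self.upper + 1e-12)
        ):
            raise ValueError("confidence band must contain the point estimate")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "quantile": self.grid,
                "value": self.value,
                "lower": self.lower,
                "upper": self.upper,
                "component": self.component,
                "platform": self.platform,
            }
        )


def _loess_fit(
    x: np.ndarray, y: np.ndarray, grid: np.ndarray, span: float, se: bool
):
    """Locally weighted quadratic regression with tricube weights.

    Returns fitted values on ``grid`` and, if ``se``, pointwise standard
    errors from the local weighted-least-squares linear functional.
    """
    n = len(x)
    k = max(4, int(np.ceil(span * n)))
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    fit = np.empty(len(grid))
    ses = np.empty(len(grid))
    for i, x0 in enumerate(grid):
        # k nearest neighbours of x0 along the sorted axis
        j = np.searchsorted(xs, x0)
        lo = max(0, j - k)
        hi = min(n, j + k)
        d = np.abs(xs[lo:hi] - x0)
        cut = np.partition(d, k - 1)[k - 1] if len(d) > k else d.max()
        keep = d <= cut
        xi, yi, di = xs[lo:hi][keep], ys[lo:hi][keep], d[keep]
        h = max(cut, 1e-12)
        w = (1.0 - np.minimum(di / h, 1.0) ** 3) ** 3
        w = np.maximum(w, 1e-9)
        b = np.column_stack([np.ones(len(xi)), xi - x0, (xi - x0) ** 2])
        bw = b * w[:, None]
        btb = b.T @ bw
        try:
            li = np.linalg.solve(btb, bw.T)[0]  # row of the smoother matrix
        except np.linalg.LinAlgError:
            li = w / w.sum()
        fit[i] = li @ yi
        if se:
            resid = yi - b @ np.linalg.lstsq(bw.T @ b, bw.T @ yi, rcond=None)[0]
            dfw = max(w.sum() ** 2 / (w**2).sum() - 3.0, 1.0)
            sigma2 = float((w * resid**2).sum() / w.sum()) * len(yi) / dfw
            ses[i] = np.sqrt(max(sigma2, 0.0) * (li**2).sum())
    return fit, (ses if se else None)


def smooth_over_intensity(
    values,
    quantiles,
    span: float = 0.75,
    ci: str = "analytic",
    grid: np.ndarray | None = None,
    n_grid: int = 100,
    n_boot: int = 200,
    seed: int = 0,
    component: str = "",
    platform: str = "",
) -> SmoothedTrack:
    """LOESS-smooth per-gene values across their intensity quantiles.

    ``ci='analytic'`` uses local standard errors; ``ci='bootstrap'``
    resamples genes (``n_boot`` replicates, seeded) and takes percentile
    bounds.  At least 50 genes are required.
    """
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    v = np.asarray(values, dtype=float)
    q = np.asarray(quantiles, dtype=float)
    keep = np.isfinite(v) & np.isfinite(q)
    v, q = v[keep], q[keep]
    if len(v) < 50:
        raise ValueError("need at least 50 genes to smooth")
    if grid is None:
        grid = np.linspace(q.min(), q.max(), n_grid)
    grid = np.asarray(grid, dtype=float)
    fit, ses = _loess_fit(q, v, grid, span, se=(ci == "analytic"))
    if ci == "analytic":
        lower, upper = fit - 1.96 * ses, fit + 1.96 * ses
    elif ci == "bootstrap":
        rng = np.random.default_rng(seed)
        boots = np.empty((n_boot, len(grid)))
        n = len(v)
        for b in range(n_boot):
            idx = rng.integers(0, n, n)
            boots[b], _ = _loess_fit(q[idx], v[idx], grid, span, se=False)
        lower = np.minimum(np.quantile(boots, 0.025, axis=0), fit)
        upper = np.maximum(np.quantile(boots, 0.975, axis=0), fit)
    else:
        raise ValueError("ci must be 'analytic' or 'bootstrap'")
    return SmoothedTrack(grid, fit, lower, upper, component, platform)


def bin_platform_test(
    decomp_a: pd.DataFrame,
    decomp_b: pd.DataFrame,
    shared_quantile: pd.Series | None = None,
    n_bins: int = 10,
    component: str = "residual",
    statistic: str = "signed_rank",
    min_bin_genes: int = 10,
) -> pd.DataFrame:
    """Binned paired test of a decomposition component between platforms.

    Genes are placed in ``n_bins`` equal-size bins by the shared
    min-quantile intensity rank (or by the first table's quantile when
    none is given); within each bin the per-gene component fractions of
    the two platforms are compared with a paired two-sided Wilcoxon
    signed-rank test (``statistic='rank_sum'`` switches to an unpaired
    Mann-Whitney test).  P-values are BH-adjusted across bins; bins with
    fewer than ``min_bin_genes`` usable genes are flagged untested.
    """
    genes = decomp_a.index.intersection(decomp_b.index)
    if len(genes) == 0:
        raise ValueError("no shared genes between the two tables")
    a = decomp_a.loc[genes]
    b = decomp_b.loc[genes]
    ok = ~(a["degenerate"].astype(bool) | b["degenerate"].astype(bool))
    if shared_quantile is None:
        q = a["quantile"]
    else:
        q = pd.Series(shared_quantile).reindex(genes)
    a, b, q = a[ok], b[ok], q[ok]
    ranks = stats.rankdata(q.to_numpy(), method="ordinal")
    bins = np.ceil(ranks * n_bins / len(ranks)).astype(int)
    rows = []
    for bi in range(1, n_bins + 1):
        mask = bins == bi
        xa = a.loc[mask, component].to_numpy()
        xb = b.loc[mask, component].to_numpy()
        n = int(mask.sum())
        if n < min_bin_genes:
            rows.append((bi, n, np.nan, np.nan, True))
            continue
        diffs = xa - xb
        if statistic == "signed_rank":
            if np.allclose(diffs, 0.0):
                p = 1.0
            else:
                p = stats.wilcoxon(xa, xb, zero_method="wilcox").pvalue
        elif statistic == "rank_sum":
            if np.array_equal(np.sort(xa), np.sort(xb)):
                p = 1.0
            else:
                p = stats.mannwhitneyu(xa, xb, alternative="two-sided").pvalue
        else:
            raise ValueError("statistic must be 'signed_rank' or 'rank_sum'")
        rows.append((bi, n, float(np.median(diffs)), float(p), False))
    out = pd.DataFrame(
        rows, columns=["bin", "n_genes", "median_diff", "p", "flagged"]
    ).set_index("bin")
    tested = ~out["flagged"]
    padj = np.full(len(out), np.nan)
    if tested.any():
        from statsmodels.stats.multitest import multipletests

        padj[tested.to_numpy()] = multipletests(
            out.loc[tested, "p"].to_numpy(), method="fdr_bh"
        )[1]
    out["p_adj"] = padj
    return out
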