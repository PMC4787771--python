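"""Cross- and within-platform fold-change agreement versus intensity.

Agreement between the microarray and sequencing arms is analysed as a
function of per-gene abundance: genes are ordered by the *min quantile*
— the lower of a gene's array-intensity quantile and read-depth
quantile — and Pearson/Spearman correlations of log2(G/E) estimates are
computed in rolling fixed-size windows over that ordering.  The same
machinery serves within-platform comparisons, where fold changes
estimated separately on the two chips (or two lanes) of the same
preparations are compared by rolling correlation and by a LOESS-smoothed
|difference| track.  Low-intensity genes whose platform fold changes
disagree strongly can be selected for qPCR-style validation, and a small
helper turns replicate Ct tables into per-gene log2 fold changes using
per-replicate all-gene centering.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .decompose import SmoothedTrack, smooth_over_intensity
from .io_design import ExpressionMatrix, NestedDesign
from .normalize import log_cpm

__all__ = [
    "min_quantile",
    "rolling_correlation",
    "per_unit_logfc",
    "replicate_divergence",
    "select_discordant_low",
    "qpcr_logfc",
    "validation_report",
]


def min_quantile(intensity_a: pd.Series, intensity_b: pd.Series) -> pd.DataFrame:
    """Per-gene intensity quantiles on each platform and their minimum.

    Quantiles are average ranks scaled to (0, 1]; ties share the
    averaged rank.  The two series must cover the same genes and be
    strictly positive.
    """
    a = pd.Series(intensity_a, dtype=float)
    b = pd.Series(intensity_b, dtype=float)
    if set(a.index) != set(b.index):
        raise ValueError("the two intensity series must share one gene set")
    b = b.reindex(a.index)
    if (a <= 0).any() or (b <= 0).any():
        raise ValueError("intensities must be positive")
    n = len(a)
    qa = stats.rankdata(a.to_numpy(), method="average") / n
    qb = stats.rankdata(b.to_numpy(), method="average") / n
    return pd.DataFrame(
        {"quantile_a": qa, "quantile_b": qb, "min_quantile": np.minimum(qa, qb)},
        index=a.index,
    )


def _fisher_band(r: float, n: int) -> tuple[float, float]:
    if n <= 3 or abs(r) >= 1.0:
        return (min(r, -1.0 + 1e-12), max(r, 1.0 - 1e-12)) if abs(r) >= 1 else (-1.0, 1.0)
    z = np.arctanh(r)
    half = 1.96 / np.sqrt(n - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def rolling_correlation(
    x: pd.Series,
    y: pd.Series,
    order: pd.Series | pd.DataFrame,
    window: int = 500,
    step: int = 1,
    ci: bool = True,
    n_boot: int = 200,
    seed: int = 0,
    subset: str = "all",
) -> pd.DataFrame:
    """Pearson and Spearman correlation of two per-gene statistics in
    rolling windows over an intensity ordering.

    ``order`` is the per-gene min quantile (or the frame produced by
    :func:`min_quantile`).  Windows of ``window`` genes advance by
    ``step``; partial edge windows are dropped.  95% bands use the
    Fisher z transform for Pearson and a seeded gene-resampling
    bootstrap for Spearman.
    """
    if isinstance(order, pd.DataFrame):
        order = order["min_quantile"]
    genes = x.index
    if not (set(genes) == set(y.index) == set(order.index)):
        raise ValueError("x, y and order must share one gene set")
    if window < 10:
        raise ValueError("window must be at least 10 genes")
    n = len(genes)
    if n < window:
        raise ValueError(
            f"only {n} genes for a {window}-gene window; use a smaller window"
        )
    srt = order.reindex(genes).sort_values(kind="stable").index
    xv = x.reindex(srt).to_numpy(float)
    yv = y.reindex(srt).to_numpy(float)
    rng = np.random.default_rng(seed)
    rows = []
    for start in range(0, n - window + 1, step):
        xs = xv[start : start + window]
        ys = yv[start : start + window]
        r = float(stats.pearsonr(xs, ys).statistic)
        rho = float(stats.spearmanr(xs, ys).statistic)
        center = start + (window - 1) / 2.0
        if ci:
            plo, phi = _fisher_band(r, window)
            boots = np.empty(n_boot)
            for b in range(n_boot):
                idx = rng.integers(0, window, window)
                bs = stats.spearmanr(xs[idx], ys[idx]).statistic
                boots[b] = bs if np.isfinite(bs) else rho
            slo = min(float(np.quantile(boots, 0.025)), rho)
            shi = max(float(np.quantile(boots, 0.975)), rho)
        else:
            plo = phi = slo = shi = np.nan
        rows.append((center, window, r, plo, phi, rho, slo, shi))
    out = pd.DataFrame(
        rows,
        columns=[
            "center_rank",
            "n_genes",
            "pearson",
            "pearson_lower",
            "pearson_upper",
            "spearman",
            "spearman_lower",
            "spearman_upper",
        ],
    )
    out["subset"] = subset
    return out


def per_unit_logfc(
    matrix: ExpressionMatrix, design: NestedDesign, unit_index: int
) -> pd.Series:
    """log2(G/E) estimated from only the ``unit_index``-th chip/lane of
    each preparation (1-based), as a simple mean difference of log2
    values between conditions.

    Counts are first placed on the log2-CPM scale within the selected
    samples; log-ratios are used directly.  No variance moderation is
    applied: the point is to isolate the chip/lane contrast.
    """
    which = design.unit_index_within_preparation()
    keep = which[which == unit_index].index.tolist()
    if not keep:
        raise ValueError(f"no samples with unit index {unit_index}")
    t = design.table.set_index("sample").loc[keep]
    if matrix.platform == "counts":
        sub = matrix.values[keep]
        vals = log_cpm(sub, sub.sum(axis=0))
    else:
        vals = matrix.values[keep].astype(float)
    hi = design.conditions[-1]
    g_cols = t.index[t["condition"] == hi]
    e_cols = t.index[t["condition"] != hi]
    return vals[list(g_cols)].mean(axis=1) - vals[list(e_cols)].mean(axis=1)


def replicate_divergence(
    fc1: pd.Series,
    fc2: pd.Series,
    quantiles: pd.Series,
    span: float = 0.75,
    window: int = 500,
    platform: str = "",
    ci: str = "analytic",
    rolling_ci: bool = False,
    seed: int = 0,
) -> tuple[SmoothedTrack, pd.DataFrame]:
    """Within-platform divergence of per-unit fold-change estimates.

    Returns the LOESS-smoothed track of |fc1 - fc2| over intensity
    quantile plus the rolling correlation between the two per-unit
    estimates (both confirm or refute intensity dependence of chip/lane
    noise).
    """
    if not fc1.index.equals(fc2.index):
        raise ValueError("fc1 and fc2 must share an identical gene index")
    q = pd.Series(quantiles).reindex(fc1.index)
    if q.isna().any():
        raise ValueError("quantiles missing for some genes")
    absdiff = (fc1 - fc2).abs()
    track = smooth_over_intensity(
        absdiff.to_numpy(),
        q.to_numpy(),
        span=span,
        ci=ci,
        seed=seed,
        component="abs_logfc_diff",
        platform=platform,
    )
    corr = rolling_correlation(
        fc1, fc2, q, window=min(window, len(fc1)), step=max(1, len(fc1) // 200),
        ci=rolling_ci, seed=seed,
    )
    return track, corr


def select_discordant_low(
    de_a: pd.DataFrame,
    de_b: pd.DataFrame,
    ranks: pd.DataFrame,
    max_quantile: float = 0.2,
    min_gap: float = 1.0,
) -> pd.DataFrame:
    """Low-intensity genes whose platform fold changes disagree.

    Selects genes in the bottom ``max_quantile`` of intensity on *both*
    platforms whose log2 fold-change estimates differ by at least
    ``min_gap``, sorted by decreasing gap — the rule used to pick
    candidates for independent qPCR validation.
    """
    genes = de_a.index.intersection(de_b.index).intersection(ranks.index)
    fa = de_a.loc[genes, "logfc"]
    fb = de_b.loc[genes, "logfc"]
    r = ranks.loc[genes]
    gap = (fa - fb).abs()
    sel = (
        (r["quantile_a"] <= max_quantile)
        & (r["quantile_b"] <= max_quantile)
        & (gap >= min_gap)
    )
    out = pd.DataFrame(
        {
            "logfc_a": fa[sel],
            "logfc_b": fb[sel],
            "gap": gap[sel],
            "quantile_a": r.loc[sel, "quantile_a"],
            "quantile_b": r.loc[sel, "quantile_b"],
        }
    )
    return out.sort_values("gap", ascending=False)


def qpcr_logfc(ct: pd.DataFrame, numerator_condition: str | None = None) -> pd.Series:
    """Per-gene log2 fold change from a replicate Ct table.

    Every Ct value is centered by the all-gene mean Ct of its biological
    replicate (removing plate and loading offsets), then the per-gene
    fold change is mean centered Ct in the denominator condition minus
    mean centered Ct in the numerator condition — one PCR cycle is one
    log2 unit and lower Ct means higher abundance, so the sign matches
    log2(numerator/denominator).

    The table needs columns ``gene, biological, condition, ct``.  By
    default the numerator is the last condition label in sorted order
    (G for a G/E experiment).
    """
    required = {"gene", "biological", "condition", "ct"}
    if not required.issubset(ct.columns):
        raise ValueError(f"Ct table must have columns {sorted(required)}")
    conds = sorted(ct["condition"].unique())
    if len(conds) != 2:
        raise ValueError(f"expected 2 conditions in Ct table, found {conds}")
    num = conds[-1] if numerator_condition is None else numerator_condition
    den = [c for c in conds if c != num]
    if not den:
        raise ValueError(f"numerator condition {num!r} not found")
    den = den[0]
    per_cond = ct.groupby(["gene", "condition"]).size().unstack(fill_value=0)
    missing = per_cond[(per_cond == 0).any(axis=1)].index.tolist()
    if missing:
        raise ValueError(f"genes missing one condition: {missing}")
    centered = ct.copy()
    centered["ct_centered"] = centered["ct"] - centered.groupby("biological")[
        "ct"
    ].transform("mean")
    means = centered.groupby(["gene", "condition"])["ct_centered"].mean().unstack()
    return (means[den] - means[num]).rename("logfc")


def validation_report(
    fc_qpcr: pd.Series, fc_a: pd.Series, fc_b: pd.Series, labels=("array", "counts")
) -> dict:
    """Correlate each platform's fold changes with the qPCR estimates.

    Returns Pearson r and two-sided p for each platform against qPCR,
    plus the merged per-gene table for replicate-distribution plots.
    """
    genes = fc_qpcr.index.intersection(fc_a.index).intersection(fc_b.index)
    if len(genes) < 3:
        raise ValueError("need at least 3 shared genes")
    table = pd.DataFrame(
        {
            "qpcr": fc_qpcr.loc[genes],
            labels[0]: fc_a.loc[genes],
            labels[1]: fc_b.loc[genes],
        }
    )
    out = {"table": table, "n": int(len(genes))}
    for lab in labels:
        res = stats.pearsonr(table["qpcr"], table[lab])
        out[f"pearson_{lab}"] = float(res.statistic)
        out[f"p_{lab}"] = float(res.pvalue)
    return out
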