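"""End-to-end reproduction studies on the synthetic experiment.

Each function runs one of the package's headline analyses on a fresh
simulation and returns a small dict of summary metrics: the platform
intensity contrast of the variance decomposition (binned tests and
smoothed residual tracks), flat-fraction parameter recovery, per-unit
fold-change divergence, qPCR validation of biased low-intensity genes,
differential-expression calibration, and the intensity confounding of
gene-set enrichment rankings.  The acceptance script and the
acceptance-level tests both drive these functions, so the numbers they
report are always produced by the same code path as the library itself.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .concordance import (
    min_quantile,
    per_unit_logfc,
    qpcr_logfc,
    replicate_divergence,
    validation_report,
)
from .decompose import (
    COMPONENTS,
    bin_platform_test,
    decompose_matrix,
    smooth_over_intensity,
)
from .diffexpr import de_table
from .enrichment import binwise_pvalue_diagnostic, enrich_all
from .normalize import normalized_log_matrix, pool_counts, tmm_factors, voom_weights
from .simulate import (
    BiasSpec,
    SimulationParams,
    flat_fraction_params,
    intensity_dependent_array_sigma,
    simulate_experiment,
    simulate_gene_sets,
    simulate_qpcr,
)

__all__ = [
    "platform_contrast_study",
    "flat_recovery_study",
    "replicate_divergence_study",
    "qpcr_validation_study",
    "calibration_study",
    "enrichment_confounding_study",
]


def _decompositions(params, counts, arrays, norm="none", variant="gaussian"):
    if variant == "count":
        dec_c = decompose_matrix(counts, params.design, variant="count")
    else:
        logc = normalized_log_matrix(counts, norm)
        dec_c = decompose_matrix(counts, params.design, variant="gaussian", values=logc)
    arr_vals = normalized_log_matrix(arrays, norm)
    dec_a = decompose_matrix(
        arrays, params.design, variant="gaussian", values=arr_vals,
        intensity=arrays.intensity,
    )
    return dec_c, dec_a


def platform_contrast_study(
    seed: int, n_genes: int = 5000, norm: str = "none", variant: str = "gaussian"
) -> dict:
    """Intensity-dependence contrast of chip vs lane variance fractions.

    Runs the default paired simulation, decomposes both platforms, and
    summarizes: the binned paired Wilcoxon tests of the residual
    (chip/lane) fraction in 10 shared-intensity bins, and whether the
    LOESS-smoothed residual track of the count platform lies strictly
    above the array's over the bottom half of intensity quantiles.
    """
    params = SimulationParams(seed=seed, n_genes=n_genes)
    truth, counts, arrays = simulate_experiment(params)
    dec_c, dec_a = _decompositions(params, counts, arrays, norm=norm, variant=variant)
    mq = min_quantile(counts.intensity + 0.5, arrays.intensity)
    bins = bin_platform_test(dec_c, dec_a, mq["min_quantile"])
    ok_c, ok_a = ~dec_c["degenerate"], ~dec_a["degenerate"]
    tr_c = smooth_over_intensity(dec_c.loc[ok_c, "residual"], dec_c.loc[ok_c, "quantile"])
    tr_a = smooth_over_intensity(dec_a.loc[ok_a, "residual"], dec_a.loc[ok_a, "quantile"])
    half = tr_c.grid <= 0.5
    p = bins["p"].to_numpy()
    return {
        "bin_p": p,
        "bottom5_max_p": float(np.nanmax(p[:5])),
        "top_bin_p": float(p[-1]),
        "count_above_array_bottom_half": bool(
            (tr_c.value[half] > tr_a.value[half]).all()
        ),
        "mean_residual_counts": float(dec_c.loc[ok_c, "residual"].mean()),
        "mean_residual_array": float(dec_a.loc[ok_a, "residual"].mean()),
        "bins": bins,
    }


def flat_recovery_study(seed: int, n_genes: int = 5000) -> dict:
    """Recovery of intensity-flat true fractions (0.5, 0.1, 0.1, 0.3)."""
    params = flat_fraction_params(seed=seed, n_genes=n_genes)
    truth, counts, arrays = simulate_experiment(params)
    dec_c, dec_a = _decompositions(params, counts, arrays)
    target = np.array([0.5, 0.1, 0.1, 0.3])
    out = {"target": target}
    for label, dec in [("counts", dec_c), ("array", dec_a)]:
        got = dec.loc[~dec["degenerate"], COMPONENTS].mean().to_numpy()
        out[f"mean_fractions_{label}"] = got
        out[f"max_abs_error_{label}"] = float(np.abs(got - target).max())
    return out


def replicate_divergence_study(seed: int, n_genes: int = 5000) -> dict:
    """Within-platform chip-vs-chip / lane-vs-lane fold-change divergence.

    Uses the simulator's intensity-dependent chip-noise option (real
    chips are noisier at low fluorescence, though far less so than lanes
    at low depth) so both divergence tracks fall with intensity, with
    the lane track above the chip track at low depth.
    """
    params = SimulationParams(
        seed=seed, n_genes=n_genes,
        array_sigma_unit=intensity_dependent_array_sigma(),
    )
    truth, counts, arrays = simulate_experiment(params)
    mq = min_quantile(counts.intensity + 0.5, arrays.intensity)["min_quantile"]
    out = {}
    tracks = {}
    for label, matrix in [("counts", counts), ("array", arrays)]:
        fc1 = per_unit_logfc(matrix, params.design, 1)
        fc2 = per_unit_logfc(matrix, params.design, 2)
        track, _ = replicate_divergence(fc1, fc2, mq, platform=label,
                                        window=500, seed=seed)
        tracks[label] = track
        out[f"divergence_spearman_{label}"] = float(
            stats.spearmanr(track.grid, track.value).statistic
        )
        out[f"mean_divergence_{label}"] = float(track.value.mean())
    half = tracks["counts"].grid <= 0.5
    out["count_above_array_bottom_half"] = bool(
        (tracks["counts"].value[half] > tracks["array"].value[half]).all()
    )
    return out


def _standard_de_tables(params, truth, counts, arrays):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # 2v2 replication: moderation dominates
        pooled, collapsed = pool_counts(counts, params.design)
        wlm = voom_weights(pooled, collapsed["condition"],
                           norm_factors=tmm_factors(pooled))
        de_c = de_table(wlm, collapsed["condition"], intensity=counts.intensity)
        from .normalize import average_array

        avg, acollapsed = average_array(arrays, params.design)
        de_a = de_table(avg.values, acollapsed["condition"],
                        intensity=arrays.intensity)
    return de_c, de_a


def qpcr_validation_study(seed: int, n_genes: int = 5000) -> dict:
    """qPCR arbitration of low-intensity genes biased on the array.

    Injects array-only log-FC offsets into 13 low-intensity genes,
    estimates fold changes on both platforms through the standard DE
    path, simulates replicate qPCR on the offset panel, and compares
    platform-vs-qPCR Pearson correlations.
    """
    params = SimulationParams(seed=seed, n_genes=n_genes, bias_spec=BiasSpec())
    truth, counts, arrays = simulate_experiment(params)
    de_c, de_a = _standard_de_tables(params, truth, counts, arrays)
    panel = truth.bias_array[truth.bias_array != 0].index
    from .concordance import select_discordant_low

    mq = min_quantile(arrays.intensity, counts.intensity + 0.5)
    selected = select_discordant_low(de_a, de_c, mq)
    ct = simulate_qpcr(truth, panel, seed=seed)
    rep = validation_report(
        qpcr_logfc(ct), de_a.loc[panel, "logfc"], de_c.loc[panel, "logfc"],
        labels=("array", "counts"),
    )
    return {
        "n_panel": int(len(panel)),
        "n_panel_recovered_by_rule": int(len(set(panel) & set(selected.index))),
        "pearson_array": rep["pearson_array"],
        "p_array": rep["p_array"],
        "pearson_counts": rep["pearson_counts"],
        "p_counts": rep["p_counts"],
    }


def calibration_study(seed: int, n_genes: int = 5000) -> dict:
    """Null calibration of the moderated t and realized FDR control.

    Part 1: 5000 null genes of Gaussian 2-vs-2 data; the moderated-t
    p-values should be uniform.  Part 2: the default simulation (20% of
    genes DE); among q <= 0.05 calls the realized false discovery
    proportion should respect the nominal level.
    """
    rng = np.random.default_rng([seed % (2**31), 99])
    null = pd.DataFrame(rng.normal(0.0, 1.0, (n_genes, 4)),
                        index=[f"n{i}" for i in range(n_genes)])
    from .diffexpr import eb_moderate, fit_gene_models

    fits = fit_gene_models(null, ["E", "E", "G", "G"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mod = eb_moderate(fits["s2"], fits["df"], coef=fits["coef"],
                          stdev_unscaled=fits["stdev_unscaled"])
    ks = stats.kstest(mod["p"], "uniform")

    params = SimulationParams(seed=seed, n_genes=n_genes)
    truth, counts, arrays = simulate_experiment(params)
    de_c, _ = _standard_de_tables(params, truth, counts, arrays)
    calls = de_c[de_c["q"] <= 0.05]
    is_true = truth.beta.reindex(calls.index) != 0
    fdp = float(1.0 - is_true.mean()) if len(calls) else 0.0
    return {
        "null_ks_p": float(ks.pvalue),
        "n_calls_q05": int(len(calls)),
        "realized_fdp_q05": fdp,
        "power_true_de": float(
            (de_c.loc[truth.beta[truth.beta != 0].index, "q"] <= 0.05).mean()
        ),
    }


def enrichment_confounding_study(
    seed: int,
    n_genes: int = 5000,
    n_sets: int = 300,
    set_size: tuple[int, int] = (40, 100),
) -> dict:
    """Intensity confounding of enrichment rankings (p-value vs log-FC).

    Enrichment-null, intensity-coherent gene sets are tested against
    per-gene DE p-values (one-sided rank-sum for greater significance)
    and against signed log fold changes (two-sided).  Sets are binned by
    median intensity; the study reports the KS uniformity p-value of
    each ranking's enrichment p-values within the lowest-intensity bin,
    where the p-value ranking is expected to be conservative.
    """
    params = SimulationParams(seed=seed, n_genes=n_genes)
    truth, counts, arrays = simulate_experiment(params)
    de_c, _ = _standard_de_tables(params, truth, counts, arrays)
    mq = min_quantile(arrays.intensity, counts.intensity + 0.5)
    sets = simulate_gene_sets(mq["min_quantile"], n_sets=n_sets,
                              set_size=set_size, seed=seed)
    res_p = enrich_all(de_c["p"], sets, ranking="pvalue", ranks=mq)
    res_f = enrich_all(de_c["logfc"], sets, ranking="logfc", ranks=mq)
    diag = binwise_pvalue_diagnostic({"pvalue": res_p, "logfc": res_f})
    low = diag[diag["intensity_bin"] == 1].set_index("label")
    return {
        "ks_p_lowest_bin_pvalue_ranking": float(low.loc["pvalue", "ks_p"]),
        "ks_p_lowest_bin_logfc_ranking": float(low.loc["logfc", "ks_p"]),
        "median_enrichment_p_lowest_bin_pvalue_ranking": float(
            low.loc["pvalue", "median_p"]
        ),
        "diagnostic": diag,
    }
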