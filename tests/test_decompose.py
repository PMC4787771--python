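import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nestedvar import (
    COMPONENTS,
    ExpressionMatrix,
    SimulationParams,
    bin_platform_test,
    count_nested_r2,
    decompose_matrix,
    flat_fraction_params,
    nested_r2,
    normalized_log_matrix,
    simulate_counts,
    simulate_experiment,
    simulate_truth,
    smooth_over_intensity,
)


# -- independent oracles ------------------------------------------------------

def oracle_gaussian(y, design):
    """Brute-force adjusted-R2 decomposition via explicit group means."""
    y = np.asarray(y, dtype=float)
    t = design.table
    n = len(y)
    tss = np.sum((y - y.mean()) ** 2)
    adj = {}
    for level, in [("condition",), ("biological",), ("preparation",)]:
        fitted = np.empty(n)
        for label in t[level].unique():
            mask = (t[level] == label).to_numpy()
            fitted[mask] = y[mask].mean()
        rss = np.sum((y - fitted) ** 2)
        p = t[level].nunique()
        r2 = 1.0 - rss / tss
        adj[level] = 1.0 - (1.0 - r2) * (n - 1) / (n - p)
    raw = np.array(
        [
            adj["condition"],
            adj["biological"] - adj["condition"],
            adj["preparation"] - adj["biological"],
            1.0 - adj["preparation"],
        ]
    )
    clipped = np.clip(raw, 0.0, None)
    return clipped / clipped.sum()


def oracle_count(y, design, lib):
    """Brute-force deviance-R2 decomposition; group MLE rate = sum y / sum lib."""

    def deviance(y, mu):
        tot = 0.0
        for yi, mi in zip(y, mu):
            if yi > 0:
                tot += yi * np.log(yi / mi) - (yi - mi)
            else:
                tot += mi
        return 2.0 * tot

    y = np.asarray(y, dtype=float)
    lib = np.asarray(lib, dtype=float)
    t = design.table
    n = len(y)
    mu0 = y.sum() / lib.sum() * lib
    d0 = deviance(y, mu0)
    adj = {}
    for level in ["condition", "biological", "preparation"]:
        mu = np.empty(n)
        for label in t[level].unique():
            mask = (t[level] == label).to_numpy()
            mu[mask] = y[mask].sum() / lib[mask].sum() * lib[mask]
        r2 = 1.0 - deviance(y, mu) / d0
        p = t[level].nunique()
        adj[level] = 1.0 - (1.0 - r2) * (n - 1) / (n - p)
    raw = np.array(
        [
            adj["condition"],
            adj["biological"] - adj["condition"],
            adj["preparation"] - adj["biological"],
            1.0 - adj["preparation"],
        ]
    )
    clipped = np.clip(raw, 0.0, None)
    return clipped / clipped.sum()


class TestNestedR2:
    def test_pure_condition_indicator_gives_all_condition(self, design):
        cond = design.table["condition"].eq("G").to_numpy(float)
        frac = nested_r2(cond, design)
        np.testing.assert_allclose(frac.to_numpy(), [1.0, 0.0, 0.0, 0.0], atol=1e-12)

    def test_preparation_structured_profile_has_zero_residual(self, design):
        rng = np.random.default_rng(0)
        t = design.table
        prep_vals = {p: rng.normal() for p in t["preparation"].unique()}
        y = t["preparation"].map(prep_vals).to_numpy(float)
        frac = nested_r2(y, design)
        assert frac["residual"] == pytest.approx(0.0, abs=1e-12)
        assert frac["preparation"] > 0.3

    def test_matches_bruteforce_oracle_on_random_profiles(self, design):
        rng = np.random.default_rng(42)
        for _ in range(100):
            y = rng.normal(0, 1, 16)
            got = nested_r2(y, design).to_numpy()
            np.testing.assert_allclose(got, oracle_gaussian(y, design), atol=1e-10)

    def test_location_scale_invariance(self, design):
        rng = np.random.default_rng(8)
        y = rng.normal(0, 1, 16)
        base = nested_r2(y, design).to_numpy()
        for a, b in [(5.0, 2.0), (-3.0, -0.5), (0.0, 100.0)]:
            np.testing.assert_allclose(
                nested_r2(a + b * y, design).to_numpy(), base, atol=1e-10
            )

    def test_unadjusted_r2_monotone_under_nesting(self, design):
        from nestedvar.decompose import _gaussian_fractions

        rng = np.random.default_rng(3)
        y = rng.normal(0, 1, (200, 16))
        _, _, raw_r2 = _gaussian_fractions(y, design)
        assert (raw_r2["biological"] >= raw_r2["condition"] - 1e-12).all()
        assert (raw_r2["preparation"] >= raw_r2["biological"] - 1e-12).all()

    def test_zero_variance_profile_rejected(self, design):
        with pytest.raises(ValueError, match="degenerate"):
            nested_r2(np.ones(16), design)

    def test_components_sum_to_one(self, design):
        rng = np.random.default_rng(1)
        for _ in range(20):
            frac = nested_r2(rng.normal(0, 1, 16), design)
            assert frac.sum() == pytest.approx(1.0, abs=1e-9)
            assert ((frac >= 0) & (frac <= 1)).all()


class TestCountNestedR2:
    def test_matches_bruteforce_oracle_on_random_counts(self, design):
        rng = np.random.default_rng(10)
        lib = rng.integers(8_000, 12_000, 16).astype(float)
        for _ in range(100):
            y = rng.poisson(rng.uniform(5, 200), 16)
            if y.sum() == 0:
                continue
            got = count_nested_r2(y, design, lib).to_numpy()
            np.testing.assert_allclose(got, oracle_count(y, design, lib), atol=1e-8)

    def test_saturated_at_preparation_level_gives_zero_residual(self, design):
        t = design.table
        vals = {p: 10 * (i + 1) for i, p in enumerate(t["preparation"].unique())}
        y = t["preparation"].map(vals).to_numpy()
        lib = np.full(16, 1000.0)
        frac = count_nested_r2(y, design, lib)
        assert frac["residual"] == pytest.approx(0.0, abs=1e-9)

    def test_flat_counts_with_flat_libs_are_degenerate(self, design):
        with pytest.raises(ValueError, match="degenerate"):
            count_nested_r2(np.full(16, 7), design, np.full(16, 1000.0))

    def test_equal_group_rates_leave_condition_near_zero(self, design):
        # equal condition rates, noise only at sampling level: after the df
        # adjustment the condition component should be near zero on average
        rng = np.random.default_rng(2)
        lib = np.full(16, 1000.0)
        fracs = []
        for _ in range(200):
            y = rng.poisson(50, 16)
            fracs.append(count_nested_r2(y, design, lib)["condition"])
        assert np.mean(fracs) < 0.1


class TestDecomposeMatrix:
    def test_duplicated_gene_rows_get_identical_decompositions(self, design):
        rng = np.random.default_rng(0)
        row = rng.poisson(80, 16)
        values = pd.DataFrame([row, row, row], index=list("abc"),
                              columns=design.samples)
        m = ExpressionMatrix(values, "counts")
        out = decompose_matrix(m, design, variant="count")
        assert out[COMPONENTS].round(12).drop_duplicates().shape[0] == 1

    def test_degenerate_genes_flagged_not_fatal(self, design):
        rng = np.random.default_rng(1)
        values = pd.DataFrame(
            np.vstack(
                [np.zeros(16, int)]
                + [rng.poisson(mu, 16) for mu in (20, 80, 300)]
            ),
            index=["dead", "a1", "a2", "a3"], columns=design.samples,
        )
        m = ExpressionMatrix(values, "counts")
        out = decompose_matrix(m, design, variant="count")
        assert bool(out.loc["dead", "degenerate"])
        assert not out.loc[["a1", "a2", "a3"], "degenerate"].any()
        assert np.isnan(out.loc["dead", "condition"])

    def test_gaussian_and_count_variants_agree_at_high_depth(self):
        # high counts, modest log-scale dispersion: the two estimators target
        # the same decomposition
        params = flat_fraction_params(seed=3, n_genes=2000, total_var=0.1)
        truth = simulate_truth(params)
        counts = simulate_counts(truth)
        logc = normalized_log_matrix(counts, "none")
        dec_g = decompose_matrix(counts, params.design, variant="gaussian", values=logc)
        dec_p = decompose_matrix(counts, params.design, variant="count")
        diff = (dec_g[COMPONENTS] - dec_p[COMPONENTS]).abs().mean()
        assert (diff < 0.02).all()

    def test_mean_fractions_recover_simulated_truth(self):
        params = flat_fraction_params(seed=5)
        truth, counts, arrays = simulate_experiment(params)
        logc = normalized_log_matrix(counts, "none")
        dec_c = decompose_matrix(counts, params.design, variant="gaussian", values=logc)
        dec_a = decompose_matrix(arrays, params.design, variant="gaussian")
        target = np.array([0.5, 0.1, 0.1, 0.3])
        for dec in (dec_c, dec_a):
            got = dec[COMPONENTS].mean().to_numpy()
            np.testing.assert_allclose(got, target, atol=0.05)

    def test_intensity_flat_noise_gives_flat_tracks(self):
        params = flat_fraction_params(seed=7)
        truth, counts, arrays = simulate_experiment(params)
        dec_a = decompose_matrix(arrays, params.design, variant="gaussian")
        ok = ~dec_a["degenerate"]
        for comp in COMPONENTS:
            tr = smooth_over_intensity(dec_a.loc[ok, comp], dec_a.loc[ok, "quantile"])
            assert tr.value.max() - tr.value.min() < 0.1


class TestSmoothing:
    def test_constant_values_give_flat_track_with_covering_band(self):
        rng = np.random.default_rng(0)
        q = rng.uniform(0, 1, 300)
        tr = smooth_over_intensity(np.full(300, 0.4), q)
        np.testing.assert_allclose(tr.value, 0.4, atol=1e-9)
        assert (tr.lower <= 0.4 + 1e-9).all() and (tr.upper >= 0.4 - 1e-9).all()

    def test_local_quadratic_reproduces_linear_data_exactly(self):
        rng = np.random.default_rng(1)
        q = np.sort(rng.uniform(0, 1, 500))
        tr = smooth_over_intensity(q, q, span=0.3)
        inner = (tr.grid > 0.05) & (tr.grid < 0.95)
        np.testing.assert_allclose(tr.value[inner], tr.grid[inner], atol=1e-6)

    def test_invalid_span_rejected(self):
        with pytest.raises(ValueError, match="span"):
            smooth_over_intensity(np.ones(100), np.linspace(0, 1, 100), span=1.5)

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError, match="50"):
            smooth_over_intensity(np.ones(10), np.linspace(0, 1, 10))

    def test_bootstrap_band_covers_true_line(self):
        rng = np.random.default_rng(6)
        q = rng.uniform(0, 1, 800)
        y = 2.0 * q + rng.normal(0, 0.3, 800)
        tr = smooth_over_intensity(y, q, ci="bootstrap", n_boot=200, seed=3)
        covered = (tr.lower <= 2.0 * tr.grid) & (2.0 * tr.grid <= tr.upper)
        assert covered.mean() >= 0.90

    def test_band_always_contains_point_estimate(self):
        rng = np.random.default_rng(9)
        q = rng.uniform(0, 1, 400)
        y = np.sin(4 * q) + rng.normal(0, 0.2, 400)
        for ci in ("analytic", "bootstrap"):
            tr = smooth_over_intensity(y, q, ci=ci, n_boot=50, seed=1)
            assert (tr.lower <= tr.value + 1e-9).all()
            assert (tr.value <= tr.upper + 1e-9).all()


def _decomp_frame(res, quant, degenerate=None):
    n = len(res)
    df = pd.DataFrame(
        {
            "residual": res,
            "quantile": quant,
            "degenerate": np.zeros(n, bool) if degenerate is None else degenerate,
        },
        index=[f"g{i}" for i in range(n)],
    )
    return df


class TestBinPlatformTest:
    def test_identical_tables_give_p_one_and_zero_differences(self):
        rng = np.random.default_rng(0)
        a = _decomp_frame(rng.uniform(0, 1, 400), rng.uniform(0, 1, 400))
        out = bin_platform_test(a, a.copy(), n_bins=4)
        assert (out["p"] == 1.0).all()
        assert (out["median_diff"] == 0.0).all()

    def test_constant_shift_detected_in_every_bin(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(0.1, 0.6, 500)
        a = _decomp_frame(base + 0.2, rng.uniform(0, 1, 500))
        b = _decomp_frame(base, a["quantile"].to_numpy())
        out = bin_platform_test(a, b, n_bins=5)
        assert (out["p"] < 1e-6).all()
        np.testing.assert_allclose(out["median_diff"], 0.2, atol=1e-12)

    def test_small_bins_flagged_untested(self):
        rng = np.random.default_rng(2)
        a = _decomp_frame(rng.uniform(0, 1, 30), rng.uniform(0, 1, 30))
        out = bin_platform_test(a, a.copy(), n_bins=10, min_bin_genes=10)
        assert out["flagged"].all()

    def test_rank_sum_alternative_available(self):
        rng = np.random.default_rng(3)
        base = rng.uniform(0.1, 0.6, 300)
        a = _decomp_frame(base + 0.3, rng.uniform(0, 1, 300))
        b = _decomp_frame(base, a["quantile"].to_numpy())
        out = bin_platform_test(a, b, n_bins=3, statistic="rank_sum")
        assert (out["p"] < 0.01).all()
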