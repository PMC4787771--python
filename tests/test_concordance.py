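import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nestedvar import (
    SimulationParams,
    min_quantile,
    per_unit_logfc,
    qpcr_logfc,
    replicate_divergence,
    rolling_correlation,
    select_discordant_low,
    simulate_qpcr,
    simulate_truth,
    validation_report,
)


def _series(vals, prefix="g"):
    return pd.Series(vals, index=[f"{prefix}{i}" for i in range(len(vals))], dtype=float)


class TestMinQuantile:
    def test_hand_ranked_example(self):
        a = _series([1, 2, 3, 4])
        b = _series([4, 3, 2, 1])
        mq = min_quantile(a, b)
        np.testing.assert_allclose(mq["min_quantile"], [0.25, 0.5, 0.5, 0.25])

    def test_top_ranked_in_both_gets_quantile_one(self):
        a = _series([1, 2, 3, 10])
        b = _series([5, 6, 7, 30])
        assert min_quantile(a, b)["min_quantile"].iloc[-1] == 1.0

    def test_ties_share_averaged_ranks(self):
        a = _series([1, 1, 2])
        b = _series([3, 3, 4])
        mq = min_quantile(a, b)
        assert mq["quantile_a"].iloc[0] == mq["quantile_a"].iloc[1] == 0.5

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(0)
        a = _series(rng.uniform(1, 100, 50))
        b = _series(rng.uniform(1, 100, 50))
        np.testing.assert_allclose(
            min_quantile(a, b)["min_quantile"], min_quantile(b, a)["min_quantile"]
        )

    def test_nonpositive_intensity_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            min_quantile(_series([0, 1, 2]), _series([1, 2, 3]))


class TestRollingCorrelation:
    def test_perfectly_correlated_windows(self):
        rng = np.random.default_rng(1)
        x = _series(rng.normal(0, 1, 40))
        order = _series(rng.uniform(0, 1, 40))
        out = rolling_correlation(x, x, order, window=10, ci=False)
        np.testing.assert_allclose(out["pearson"], 1.0)
        np.testing.assert_allclose(out["spearman"], 1.0)

    def test_perfectly_anticorrelated_windows(self):
        rng = np.random.default_rng(2)
        x = _series(rng.normal(0, 1, 40))
        order = _series(rng.uniform(0, 1, 40))
        out = rolling_correlation(x, -x, order, window=10, ci=False)
        np.testing.assert_allclose(out["pearson"], -1.0)
        np.testing.assert_allclose(out["spearman"], -1.0)

    def test_matches_bruteforce_window_recomputation(self):
        rng = np.random.default_rng(3)
        x = _series(rng.normal(0, 1, 30))
        y = _series(x.to_numpy() + rng.normal(0, 0.7, 30))
        order = _series(rng.uniform(0, 1, 30))
        out = rolling_correlation(x, y, order, window=10, ci=False)
        srt = order.sort_values(kind="stable").index
        xs, ys = x.reindex(srt).to_numpy(), y.reindex(srt).to_numpy()
        for i, row in out.iterrows():
            s = int(row["center_rank"] - 4.5)
            assert row["pearson"] == pytest.approx(
                stats.pearsonr(xs[s : s + 10], ys[s : s + 10]).statistic
            )
            assert row["spearman"] == pytest.approx(
                stats.spearmanr(xs[s : s + 10], ys[s : s + 10]).statistic
            )

    def test_strided_results_are_subsequence_of_dense_results(self):
        rng = np.random.default_rng(4)
        x = _series(rng.normal(0, 1, 60))
        y = _series(rng.normal(0, 1, 60))
        order = _series(rng.uniform(0, 1, 60))
        dense = rolling_correlation(x, y, order, window=20, step=1, ci=False)
        strided = rolling_correlation(x, y, order, window=20, step=7, ci=False)
        merged = dense.merge(strided, on="center_rank", suffixes=("", "_s"))
        np.testing.assert_allclose(merged["pearson"], merged["pearson_s"])

    def test_confidence_bands_contain_estimates(self):
        rng = np.random.default_rng(5)
        x = _series(rng.normal(0, 1, 30))
        y = _series(x.to_numpy() + rng.normal(0, 1, 30))
        out = rolling_correlation(x, y, _series(rng.uniform(0, 1, 30)),
                                  window=15, step=5, seed=1)
        assert (out["pearson_lower"] <= out["pearson"]).all()
        assert (out["pearson"] <= out["pearson_upper"]).all()
        assert (out["spearman_lower"] <= out["spearman"]).all()
        assert (out["spearman"] <= out["spearman_upper"]).all()

    def test_window_larger_than_gene_set_rejected(self):
        x = _series(np.arange(20))
        with pytest.raises(ValueError, match="smaller window"):
            rolling_correlation(x, x, x + 1, window=50)


class TestReplicateDivergence:
    def test_identical_unit_estimates_give_zero_track(self):
        rng = np.random.default_rng(0)
        fc = _series(rng.normal(0, 1, 300))
        q = _series(rng.uniform(0, 1, 300))
        track, corr = replicate_divergence(fc, fc.copy(), q, window=100)
        np.testing.assert_allclose(track.value, 0.0, atol=1e-12)
        np.testing.assert_allclose(corr["pearson"], 1.0)

    def test_decreasing_noise_gives_decreasing_track(self):
        rng = np.random.default_rng(1)
        n = 2000
        q = _series(np.sort(rng.uniform(0, 1, n)))
        sigma = 1.0 - 0.9 * q.to_numpy()
        fc1 = _series(rng.normal(0, 1, n))
        fc2 = fc1 + rng.normal(0, sigma, n)
        track, _ = replicate_divergence(fc1, fc2, q, window=500)
        rho = stats.spearmanr(track.grid, track.value).statistic
        assert rho < -0.9

    def test_mismatched_gene_sets_rejected(self):
        fc1 = _series(np.arange(100))
        fc2 = _series(np.arange(100), prefix="x")
        with pytest.raises(ValueError, match="identical gene index"):
            replicate_divergence(fc1, fc2, fc1)

    def test_per_unit_logfc_uses_one_chip_per_preparation(self, design):
        # array values equal to +1 on G samples of unit 1, -1 on E of unit 1,
        # and 0 on all unit-2 samples: unit-1 FC is 2, unit-2 FC is 0
        from nestedvar import ExpressionMatrix

        t = design.table
        unit_idx = design.unit_index_within_preparation()
        vals = pd.DataFrame(0.0, index=["g0"], columns=design.samples)
        for s in design.samples:
            if unit_idx[s] == 1:
                cond = t.set_index("sample").loc[s, "condition"]
                vals.loc["g0", s] = 1.0 if cond == "G" else -1.0
        m = ExpressionMatrix(vals, "logratio", intensity=pd.Series([1.0], index=["g0"]))
        fc1 = per_unit_logfc(m, design, 1)
        fc2 = per_unit_logfc(m, design, 2)
        assert fc1["g0"] == pytest.approx(2.0)
        assert fc2["g0"] == pytest.approx(0.0)


class TestSelectDiscordant:
    def _tables(self, fc_a, fc_b, qa, qb):
        genes = [f"g{i}" for i in range(len(fc_a))]
        de_a = pd.DataFrame({"logfc": fc_a}, index=genes)
        de_b = pd.DataFrame({"logfc": fc_b}, index=genes)
        ranks = pd.DataFrame({"quantile_a": qa, "quantile_b": qb}, index=genes)
        return de_a, de_b, ranks

    def test_equal_fold_changes_select_nothing(self):
        rng = np.random.default_rng(0)
        fc = rng.normal(0, 2, 50)
        q = rng.uniform(0, 1, 50)
        de_a, de_b, ranks = self._tables(fc, fc, q, q)
        assert len(select_discordant_low(de_a, de_b, ranks)) == 0

    def test_single_qualifying_gene_found(self):
        de_a, de_b, ranks = self._tables(
            [2.0, 0.0, 0.0], [0.5, 0.0, 3.0], [0.1, 0.15, 0.9], [0.12, 0.1, 0.95]
        )
        out = select_discordant_low(de_a, de_b, ranks)
        assert out.index.tolist() == ["g0"]
        assert out["gap"].iloc[0] == pytest.approx(1.5)

    def test_default_thresholds_are_bottom_twenty_percent_and_unit_gap(self):
        de_a, de_b, ranks = self._tables(
            [1.0, 1.0], [0.0, 0.0], [0.2, 0.21], [0.2, 0.2]
        )
        out = select_discordant_low(de_a, de_b, ranks)
        assert out.index.tolist() == ["g0"]  # 0.21 > 0.2 excluded; gap 1.0 kept


class TestQpcr:
    def _toy_ct(self):
        rows = []
        # two genes, two conditions x two biological reps, one replicate
        # gene A: 2 cycles lower (4x more abundant) in G; gene B: flat
        for bio, cond, shift in [("G1", "G", 0.0), ("G2", "G", 1.0),
                                 ("E1", "E", 0.0), ("E2", "E", -1.0)]:
            a_ct = (20.0 if cond == "G" else 22.0) + shift
            b_ct = 25.0 + shift
            rows.append(("A", bio, cond, 1, a_ct))
            rows.append(("B", bio, cond, 1, b_ct))
        return pd.DataFrame(rows, columns=["gene", "biological", "condition",
                                           "replicate", "ct"])

    def test_two_gene_hand_computation(self):
        fc = qpcr_logfc(self._toy_ct())
        # centering removes the per-replicate shifts; A is 2 cycles lower in
        # G than E relative to the panel mean, B is the mirror image
        assert fc["A"] == pytest.approx(1.0)
        assert fc["B"] == pytest.approx(-1.0)

    def test_per_replicate_constant_offsets_cancel(self):
        ct = self._toy_ct()
        fc0 = qpcr_logfc(ct)
        shifted = ct.copy()
        shifted.loc[shifted["biological"] == "G1", "ct"] += 7.5
        pd.testing.assert_series_equal(qpcr_logfc(shifted), fc0)

    def test_gene_missing_one_condition_rejected(self):
        ct = self._toy_ct()
        ct = ct[~((ct["gene"] == "B") & (ct["condition"] == "E"))]
        with pytest.raises(ValueError, match="missing"):
            qpcr_logfc(ct)

    def test_round_trip_recovers_beta_for_balanced_panel(self):
        # sign-balanced panel: the all-gene centering subtracts the panel
        # mean effect, which is zero here, so recovery is exact
        params = SimulationParams(
            n_genes=10, prop_de=1.0, de_logfc=(1.2, 0.0), de_balanced_signs=True,
            sigma_bio=0.0, sigma_prep=0.0, seed=3,
        )
        truth = simulate_truth(params)
        assert truth.beta.sum() == pytest.approx(0.0)
        ct = simulate_qpcr(truth, truth.genes, sigma_ct=0.0)
        fc = qpcr_logfc(ct)
        np.testing.assert_allclose(
            fc.loc[truth.genes], truth.beta.to_numpy(), atol=1e-10
        )


class TestValidationReport:
    def test_perfect_agreement_gives_unit_correlation(self):
        rng = np.random.default_rng(0)
        fc = _series(rng.normal(0, 1, 10))
        rep = validation_report(fc, fc.copy(), _series(rng.normal(0, 1, 10)))
        assert rep["pearson_array"] == pytest.approx(1.0)

    def test_anticorrelated_platform_gives_minus_one(self):
        rng = np.random.default_rng(1)
        fc = _series(rng.normal(0, 1, 8))
        rep = validation_report(fc, -fc, fc.copy())
        assert rep["pearson_array"] == pytest.approx(-1.0)
        assert rep["pearson_counts"] == pytest.approx(1.0)

    def test_fewer_than_three_genes_rejected(self):
        fc = _series([1.0, 2.0])
        with pytest.raises(ValueError, match="3"):
            validation_report(fc, fc, fc)
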