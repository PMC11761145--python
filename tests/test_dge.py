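"""Differential expression: filtering, TMM, log-CPM, contrasts, eFDR, calls."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from hierflux.dge import (
    DifferentialExpressionModel,
    call_degs,
    contrast_fit,
    deg_asymmetry_ratio,
    empirical_fdr,
    filter_low_counts,
    log_cpm,
    permutation_null_pvalues,
    tmm_normalize,
)


def tiny_meta(conditions):
    return pd.DataFrame({
        "sample_id": [f"s{k}" for k in range(len(conditions))],
        "condition": conditions,
        "group_id": [f"g{k}" for k in range(len(conditions))],
    })


class TestFilter:
    def test_boundary_total_ten(self):
        counts = pd.DataFrame(
            {"s0": [9, 10, 0], "s1": [0, 0, 0]},
            index=["below", "at", "zero"])
        kept = filter_low_counts(counts)
        assert list(kept.index) == ["at"]

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.poisson(2, size=(300, 8)),
                              index=[f"g{k}" for k in range(300)],
                              columns=[f"s{k}" for k in range(8)])
        kept = filter_low_counts(counts, min_total=10)
        expected = [g for g in counts.index if counts.loc[g].sum() >= 10]
        assert list(kept.index) == expected

    def test_empty_result_rejected(self):
        counts = pd.DataFrame({"s0": [1, 2]}, index=["a", "b"])
        with pytest.raises(ValueError, match="removed every gene"):
            filter_low_counts(counts, min_total=100)


class TestTMM:
    def test_identical_samples_unit_factors(self):
        col = np.arange(1, 201)
        counts = pd.DataFrame({f"s{k}": col for k in range(4)})
        norm = tmm_normalize(counts)
        np.testing.assert_allclose(norm.factors, 1.0)

    def test_scaled_sample_unit_factors(self):
        # doubling every count is absorbed by the library size; M-values 0
        rng = np.random.default_rng(1)
        base = rng.poisson(50, 500) + 1
        counts = pd.DataFrame({"a": base, "b": 2 * base, "c": base})
        norm = tmm_normalize(counts)
        np.testing.assert_allclose(norm.factors, 1.0, atol=1e-12)

    def test_geometric_mean_one(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.negative_binomial(5, 0.05, size=(400, 6)))
        counts.columns = [f"s{k}" for k in range(6)]
        f = tmm_normalize(counts).factors
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)

    def test_composition_bias_compensated_matches_edger(self, tmp_path):
        # 5% of genes 8-fold up in one sample: that sample's factor must
        # shrink its effective library; cross-check against edgeR's TMM
        rng = np.random.default_rng(4)
        mu = rng.lognormal(4, 1.5, size=(800, 1)) * np.ones((800, 6))
        counts = pd.DataFrame(
            rng.negative_binomial(10, 10 / (10 + mu)),
            columns=[f"s{k}" for k in range(6)])
        counts.iloc[:40, 0] *= 8
        ours = tmm_normalize(counts).factors.to_numpy()
        assert ours[0] < 1.0
        path = tmp_path / "counts.tsv"
        counts.to_csv(path, sep="\t", index=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(edgeR))
            x <- as.matrix(read.delim("{path}"))
            cat(sprintf("%.8f", calcNormFactors(x, method="TMM")), sep=" ")
        """)
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        theirs = np.array([float(v) for v in out.stdout.split()])
        np.testing.assert_allclose(ours, theirs, rtol=0.01)

    def test_nonpositive_library_rejected(self):
        counts = pd.DataFrame({"s0": [1, 2], "s1": [0, 0]})
        with pytest.raises(ValueError, match="positive library size"):
            tmm_normalize(counts)


class TestLogCpm:
    def test_direct_formula_value(self):
        counts = pd.DataFrame({"s0": [0] + [1] * 10}, index=range(11))
        lib = pd.Series([1_000_000.0], index=["s0"])
        factors = pd.Series([1.0], index=["s0"])
        from hierflux.dge import NormalizedMatrix

        norm = log_cpm(counts, NormalizedMatrix(factors=factors, lib_sizes=lib))
        expected = np.log2(0.5 / (1_000_000 + 1) * 1e6)
        assert norm.logcpm.iloc[0, 0] == pytest.approx(expected)
        assert norm.logcpm.iloc[0, 0] == pytest.approx(-1.0, abs=1e-5)

    def test_scale_invariance_and_monotonicity(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(rng.poisson(20, size=(50, 3)) + 1,
                              columns=list("abc"))
        f = pd.Series(1.0, index=counts.columns)
        one = log_cpm(counts, f).logcpm
        ten = log_cpm(counts * 10, f).logcpm
        # invariant up to the fixed prior count's shrinking effect
        np.testing.assert_allclose(one, ten, atol=0.1)
        col = log_cpm(counts, f).logcpm["a"]
        assert (col[counts["a"].sort_values().index].diff().dropna() >= 0).all()


class TestContrastFit:
    def test_identical_groups_null(self):
        logcpm = pd.DataFrame(
            [[5.0, 5.0, 5.0, 5.0, 3.0, 3.0]] * 3,
            columns=[f"s{k}" for k in range(6)])
        meta = tiny_meta(["A", "A", "B", "B", "C", "C"])
        res = contrast_fit(logcpm, meta, "A:B")
        assert np.allclose(res["log2fc"], 0.0)
        assert np.allclose(res["p"], 1.0)

    def test_estimate_is_difference_of_group_means(self):
        rng = np.random.default_rng(5)
        logcpm = pd.DataFrame(rng.normal(5, 1, size=(40, 8)),
                              columns=[f"s{k}" for k in range(8)])
        meta = tiny_meta(["A"] * 3 + ["B"] * 3 + ["C"] * 2)
        res = contrast_fit(logcpm, meta, "A:B")
        manual = logcpm.iloc[:, :3].mean(1) - logcpm.iloc[:, 3:6].mean(1)
        np.testing.assert_allclose(res["log2fc"], manual)

    def test_matches_per_gene_ols_oracle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(6)
        logcpm = pd.DataFrame(rng.normal(0, 1, size=(20, 10)),
                              columns=[f"s{k}" for k in range(10)])
        conditions = ["A"] * 3 + ["B"] * 3 + ["C"] * 4
        meta = tiny_meta(conditions)
        res = contrast_fit(logcpm, meta, "A:C")
        dummies = pd.get_dummies(pd.Series(conditions), dtype=float)
        L = np.array([1.0, 0.0, -1.0])
        for g in range(20):
            fit = sm.OLS(logcpm.iloc[g].to_numpy(), dummies.to_numpy()).fit()
            tt = fit.t_test(L)
            assert res["log2fc"].iloc[g] == pytest.approx(float(tt.effect.squeeze()))
            assert res["p"].iloc[g] == pytest.approx(float(tt.pvalue.squeeze()))

    def test_planted_shift_recovered(self, small_counts):
        counts, meta, truth = small_counts
        model = DifferentialExpressionModel(counts, meta)
        res = contrast_fit(model.logcpm, meta, "DES:DOM")
        plus = [g for g, l in truth.deg_truth["DES:DOM"].items() if l > 0]
        plus = [g for g in plus if g in res.index]
        assert res.loc[plus, "log2fc"].mean() == pytest.approx(1.0, abs=0.1)

    def test_too_few_samples_rejected(self):
        logcpm = pd.DataFrame([[1.0, 2.0, 3.0]], columns=["s0", "s1", "s2"])
        meta = tiny_meta(["A", "B", "B"])
        with pytest.raises(ValueError, match="fewer than 2 samples"):
            contrast_fit(logcpm, meta, "A:B")


class TestEmpiricalFdr:
    def test_hand_enumerated_instance(self):
        # 10 genes, 3 permutations; expected values from exhaustive counting
        p_obs = np.array([0.001, 0.01, 0.02, 0.05, 0.1, 0.2, 0.3, 0.5, 0.8, 0.9])
        null = np.array([
            [0.005, 0.15, 0.25, 0.35, 0.45, 0.55, 0.65, 0.75, 0.85, 0.95],
            [0.02, 0.04, 0.06, 0.08, 0.30, 0.40, 0.60, 0.70, 0.80, 0.90],
            [0.001, 0.10, 0.12, 0.5, 0.52, 0.54, 0.56, 0.58, 0.60, 0.62]])
        expected = np.array([1 / 3, 1 / 3, 1 / 3, 1 / 3, 7 / 15, 1 / 2,
                             11 / 21, 5 / 8, 29 / 30, 29 / 30])
        np.testing.assert_allclose(empirical_fdr(p_obs, null), expected)
        # independent brute-force recount of the same estimator
        brute = []
        for p in p_obs:
            avg_null = np.mean([(row <= p).sum() for row in null])
            brute.append(min(avg_null / (p_obs <= p).sum(), 1.0))
        running = np.inf
        for i in np.argsort(-p_obs):
            running = min(running, brute[i])
            brute[i] = running
        np.testing.assert_allclose(empirical_fdr(p_obs, null), brute)

    def test_extreme_cases(self):
        p_obs = np.array([1e-6, 2e-6, 3e-6])
        null = np.full((4, 3), 0.5)
        assert np.allclose(empirical_fdr(p_obs, null), 0.0)
        # observed drawn from the null itself: eFDR near 1 in the bulk
        rng = np.random.default_rng(7)
        p_obs = rng.uniform(size=2000)
        null = rng.uniform(size=(20, 2000))
        efdr = empirical_fdr(p_obs, null)
        assert np.median(efdr) > 0.9

    def test_monotone_in_p(self):
        rng = np.random.default_rng(8)
        p_obs = rng.uniform(size=500)
        null = rng.uniform(size=(5, 500))
        efdr = empirical_fdr(p_obs, null)
        order = np.argsort(p_obs)
        assert (np.diff(efdr[order]) >= -1e-12).all()

    def test_permutation_reproducibility(self, small_counts):
        counts, meta, _ = small_counts
        model = DifferentialExpressionModel(counts, meta)
        a = permutation_null_pvalues(model.logcpm.iloc[:100], meta, "DES:DOM",
                                     n_perm=20, seed=5)
        b = permutation_null_pvalues(model.logcpm.iloc[:100], meta, "DES:DOM",
                                     n_perm=20, seed=5)
        np.testing.assert_array_equal(a, b)


class TestCalls:
    def test_threshold_boundaries(self):
        table = pd.DataFrame({
            "log2fc": [0.19, 0.20, -0.50, 1.0],
            "p": [0.001] * 4,
            "efdr": [0.01, 0.01, 0.05, 0.01],
        }, index=list("abcd"))
        calls = call_degs(table)
        # 0.19 fails |lfc|; efdr 0.05 fails the strict < 0.05 rule
        assert calls["table"]["call"].tolist() == ["none", "up", "none", "up"]
        assert calls["up"] == {"b", "d"}

    def test_bin_counts_sum_to_total(self):
        rng = np.random.default_rng(9)
        table = pd.DataFrame({
            "log2fc": rng.normal(0, 1, 500),
            "p": rng.uniform(size=500),
            "efdr": rng.uniform(size=500),
        })
        calls = call_degs(table)
        bins = calls["bins"]
        for col in ("up", "down"):
            assert bins.loc[">=0.20", col] == bins.iloc[1:][col].sum()
        assert bins.loc[">=0.20", "up"] == len(calls["up"])

    def test_asymmetry_ratios(self):
        ratio, p = deg_asymmetry_ratio(2255, 1357)
        assert ratio == 1.7 and p < 0.001
        ratio, p = deg_asymmetry_ratio(51, 15)
        assert ratio == 3.4 and p < 0.001
        ratio, p = deg_asymmetry_ratio(10, 10)
        assert ratio == 1.0 and p == 1.0
        assert deg_asymmetry_ratio(5, 0)[0] == float("inf")


class TestPipeline:
    def test_scale_free_calls(self, small_counts):
        # multiplying all library sizes by a constant leaves calls unchanged
        counts, meta, _ = small_counts
        res1 = DifferentialExpressionModel(counts, meta).fit(
            "DES:DOM", n_perm=60, seed=3)
        res2 = DifferentialExpressionModel(counts * 4, meta).fit(
            "DES:DOM", n_perm=60, seed=3)
        # invariant up to the fixed prior count: at most a boundary gene or
        # two may flip
        assert len(res1.up ^ res2.up) + len(res1.down ^ res2.down) <= 2

    def test_planted_recovery_and_error_control(self, small_counts):
        counts, meta, truth = small_counts
        res = DifferentialExpressionModel(counts, meta).fit(
            "DES:DOM", n_perm=300, seed=2)
        truth_set = set(truth.deg_truth["DES:DOM"])
        called = res.up | res.down
        recall = len(called & truth_set) / len(truth_set)
        fdp = len(called - truth_set) / max(len(called), 1)
        assert recall > 0.8
        assert fdp < 0.15
        # directions match the planted signs
        for g, lfc in truth.deg_truth["DES:DOM"].items():
            if g in res.up:
                assert lfc > 0
            if g in res.down:
                assert lfc < 0
        assert "DEGs" in res.summary()
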