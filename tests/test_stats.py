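import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import statsmodels.formula.api as smf

from reciprosim.stats import (
    MODEL_TERM_SCHEMA,
    ModelSpec,
    StatResult,
    bonferroni,
    fit_random_intercept_model,
    spearman,
    wilcoxon_rank_sum,
    wilcoxon_signed_rank,
)

# ---------------------------------------------------------------------------
# Brute-force oracles (independent of scipy's exact machinery)
# ---------------------------------------------------------------------------


def exact_signed_rank_p(diffs):
    """Enumerate all 2^n sign assignments of the ranked |diffs|."""
    diffs = np.asarray(diffs, dtype=float)
    ranks = sps.rankdata(np.abs(diffs))
    observed = ranks[diffs > 0].sum()
    n = len(diffs)
    total = ranks.sum()
    stats = []
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, keep in zip(ranks, signs) if keep)
        stats.append(w)
    stats = np.array(stats)
    # Two-tailed: distance of W+ from its mean.
    center = total / 2
    return np.mean(np.abs(stats - center) >= abs(observed - center) - 1e-12)


def exact_rank_sum_p(x, y):
    """Enumerate all choose(n1+n2, n1) group assignments of the pooled ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n1 = len(x)
    observed = ranks[:n1].sum()
    center = n1 * (len(pooled) + 1) / 2
    stats = [
        sum(ranks[list(idx)])
        for idx in itertools.combinations(range(len(pooled)), n1)
    ]
    stats = np.array(stats)
    return np.mean(np.abs(stats - center) >= abs(observed - center) - 1e-12)


def exact_spearman_p(x, y):
    rho_obs = sps.spearmanr(x, y).statistic
    ry = sps.rankdata(y)
    rx = sps.rankdata(x)
    count = total = 0
    for perm in itertools.permutations(ry):
        r = np.corrcoef(rx, perm)[0, 1]
        if abs(r) >= abs(rho_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


# ---------------------------------------------------------------------------
# StatResult identities
# ---------------------------------------------------------------------------


class TestEffectSizes:
    def test_r_from_z_n25(self):
        res = StatResult.from_z("t", 0.0, z=3.51, p=0.001, n=25)
        assert res.r == pytest.approx(0.702)
        assert res.eta_sq == pytest.approx(res.r**2)

    def test_r_from_z_n50(self):
        res = StatResult.from_z("t", 0.0, z=1.00, p=0.318, n=50)
        assert res.r == pytest.approx(0.1414, abs=1e-3)

    def test_identities_hold_generally(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            z = rng.normal(0, 2)
            n = int(rng.integers(5, 100))
            res = StatResult.from_z("t", 0.0, z=z, p=0.5, n=n)
            assert res.eta_sq == pytest.approx(res.r**2, rel=1e-12)
            assert res.r == pytest.approx(abs(z) / np.sqrt(n), rel=1e-12)


class TestWilcoxonSignedRank:
    def test_symmetric_sample_null(self):
        x = np.array([0.4, -0.4, 1.3, -1.3, 2.2, -2.2, 0.9, -0.9, 3.1, -3.1])
        res = wilcoxon_signed_rank(x)
        assert res.p > 0.9
        assert abs(res.r) < 0.05

    def test_exact_p_matches_enumeration_n6(self):
        x = np.array([1.2, -0.7, 2.5, 0.4, 1.9, -0.2])
        res = wilcoxon_signed_rank(x)
        assert res.note == "exact"
        assert res.p == pytest.approx(exact_signed_rank_p(x), abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_p_random_samples(self, seed):
        rng = np.random.default_rng(seed)
        x = np.round(rng.normal(0.5, 1.0, size=7), 3)
        while len(np.unique(np.abs(x))) < len(x) or (x == 0).any():
            x = np.round(rng.normal(0.5, 1.0, size=7), 3)
        res = wilcoxon_signed_rank(x)
        assert res.p == pytest.approx(exact_signed_rank_p(x), abs=1e-9)

    def test_paired_equals_one_sample_of_differences(self):
        rng = np.random.default_rng(1)
        a = rng.normal(10, 2, 12)
        b = rng.normal(9, 2, 12)
        assert wilcoxon_signed_rank(a, b).p == pytest.approx(
            wilcoxon_signed_rank(a - b).p
        )

    def test_against_null_constant(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 0.4, 25)  # far below 0.5
        res = wilcoxon_signed_rank(x, mu=0.5)
        assert res.p < 0.001
        assert res.z < 0

    def test_all_zero_differences_degenerate(self):
        res = wilcoxon_signed_rank(np.full(10, 0.5), mu=0.5)
        assert "degenerate" in res.note
        assert res.p == 1.0

    def test_too_few_nonzero(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([0.1, -0.2, 0.0, 0.0, 0.0])


class TestWilcoxonRankSum:
    def test_identical_multisets_z_zero(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0]
        res = wilcoxon_rank_sum(x, list(reversed(x)))
        assert res.z == pytest.approx(0.0, abs=1e-9)

    def test_exact_p_matches_enumeration(self):
        x = [1.1, 3.4, 5.2, 0.7]
        y = [2.2, 6.1, 4.4, 8.0, 7.3]
        res = wilcoxon_rank_sum(x, y)
        assert res.note == "exact"
        assert res.p == pytest.approx(exact_rank_sum_p(x, y), abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_p_random_samples(self, seed):
        rng = np.random.default_rng(seed + 10)
        x = np.round(rng.normal(0, 1, 5), 3)
        y = np.round(rng.normal(0.8, 1, 6), 3)
        if len(np.unique(np.concatenate([x, y]))) < 11:
            pytest.skip("tie in random draw")
        res = wilcoxon_rank_sum(x, y)
        assert res.p == pytest.approx(exact_rank_sum_p(x, y), abs=1e-9)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 15)
        y = rng.normal(0.5, 1, 18)
        res1 = wilcoxon_rank_sum(x, y)
        res2 = wilcoxon_rank_sum(np.exp(x), np.exp(y))
        assert res1.z == pytest.approx(res2.z, abs=1e-9)
        assert res1.p == pytest.approx(res2.p, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestSpearman:
    def test_monotone_increasing(self):
        rho, _ = spearman([1, 2, 3, 4, 5], [2, 4, 9, 16, 30])
        assert rho == pytest.approx(1.0)

    def test_monotone_decreasing(self):
        rho, _ = spearman([1, 2, 3, 4, 5], [10, 8, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_small_n_matches_permutation_oracle(self, seed):
        rng = np.random.default_rng(seed + 20)
        x = rng.permutation(6).astype(float)
        y = rng.normal(0, 1, 6)
        rho, p = spearman(x, y)
        assert p == pytest.approx(exact_spearman_p(x, y), abs=1e-9)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 2, 3], [1, 2, 3])


class TestBonferroni:
    def test_two_comparisons(self):
        assert bonferroni([0.03, 0.01], m=2) == [False, True]

    def test_identity_at_m1(self):
        assert bonferroni([0.049, 0.051], m=1) == [True, False]

    def test_invalid_m(self):
        with pytest.raises(ValueError):
            bonferroni([0.01], m=0)


# ---------------------------------------------------------------------------
# Random-intercept models
# ---------------------------------------------------------------------------


def make_mixed_data(
    n_participants=30,
    n_trials=10,
    slope=0.0,
    intercept_sd=0.3,
    noise_sd=0.5,
    seed=0,
):
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_participants):
        u = rng.normal(0, intercept_sd)
        x = rng.uniform(0, 1, n_trials)
        y = 0.5 + u + slope * x + rng.normal(0, noise_sd, n_trials)
        for xi, yi in zip(x, y):
            rows.append({"participant_id": f"p{p}", "x": xi, "y": yi})
    return pd.DataFrame(rows)


class TestRandomInterceptModel:
    def test_matches_ols_with_zero_between_variance(self):
        # OLS oracle: when the generative between-participant variance is
        # zero the mixed-model coefficients converge to plain OLS.
        df = make_mixed_data(intercept_sd=0.0, slope=-0.4, seed=1)
        spec = ModelSpec(model_id=1, response="y", formula="y ~ x")
        results = fit_random_intercept_model(df, spec)
        ols = smf.ols("y ~ x", data=df).fit()
        by_term = {r.name.split(":")[1]: r for r in results}
        assert by_term["Intercept"].estimate == pytest.approx(
            ols.params["Intercept"], abs=0.01
        )
        assert by_term["x"].estimate == pytest.approx(ols.params["x"], abs=0.01)

    def test_parameter_recovery_slope(self):
        # Generative slope -0.44 recovered within its 95% interval.
        df = make_mixed_data(slope=-0.44, seed=2)
        spec = ModelSpec(model_id=1, response="y", formula="y ~ x")
        results = fit_random_intercept_model(df, spec)
        slope_res = next(r for r in results if r.name.endswith(":x"))
        se = abs(slope_res.estimate / slope_res.z)
        assert slope_res.estimate - 1.96 * se <= -0.44 <= slope_res.estimate + 1.96 * se

    def test_type_one_error_rate(self):
        # 500 null simulations: Wald z at alpha = 0.05 rejects at the
        # nominal rate within 3 Monte-Carlo SEs.
        n_sim = 500
        rejections = 0
        spec = ModelSpec(model_id=1, response="y", formula="y ~ x")
        for seed in range(n_sim):
            df = make_mixed_data(
                n_participants=20, n_trials=8, slope=0.0, seed=seed + 1000
            )
            results = fit_random_intercept_model(df, spec)
            slope_res = next(r for r in results if r.name.endswith(":x"))
            if slope_res.p < 0.05:
                rejections += 1
        rate = rejections / n_sim
        bound = 3 * np.sqrt(0.05 * 0.95 / n_sim)
        assert rate == pytest.approx(0.05, abs=bound)

    def test_missing_column_raises(self):
        df = make_mixed_data()
        spec = ModelSpec(model_id=1, response="z", formula="z ~ x")
        with pytest.raises(ValueError, match="missing columns"):
            fit_random_intercept_model(df, spec)

    def test_single_participant_rejected(self):
        df = make_mixed_data(n_participants=1)
        spec = ModelSpec(model_id=1, response="y", formula="y ~ x")
        with pytest.raises(ValueError, match="participants"):
            fit_random_intercept_model(df, spec)


def test_model_term_schema_frozen():
    assert set(MODEL_TERM_SCHEMA) == {1, 2, 3, 4, 5, 6}
    assert "distance[Computer]" in MODEL_TERM_SCHEMA[1]
    assert "Susceptible-Unsusceptible[Robot]" in MODEL_TERM_SCHEMA[5]
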