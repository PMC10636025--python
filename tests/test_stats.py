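import itertools

import numpy as np
import pytest
from scipy import stats as sps

from lymphspect.datasets import reference_staging_table
from lymphspect.stats import (
    bonferroni_adjust,
    dunn_bonferroni,
    kappa_band,
    kruskal_wallis,
    linear_by_linear,
    mann_whitney,
    mcnemar,
    spearman,
    summarize_numeric,
    weighted_kappa,
)


class TestMcnemar:
    def test_2x2_symmetric_discordance_exact_p_one(self):
        res = mcnemar([[10, 5], [5, 10]], exact=True)
        assert res.p_value == pytest.approx(1.0)

    def test_all_diagonal_statistic_zero(self):
        res = mcnemar(np.diag([3, 4, 5]))
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_bowker_matches_direct_summation_oracle(self):
        t = reference_staging_table().counts.astype(float)
        res = mcnemar(t)
        # direct summation over discordant symmetric pairs
        stat, df = 0.0, 0
        for i in range(6):
            for j in range(i + 1, 6):
                if t[i, j] + t[j, i] > 0:
                    stat += (t[i, j] - t[j, i]) ** 2 / (t[i, j] + t[j, i])
                    df += 1
        assert df == 4  # exactly four discordant symmetric pairs
        assert res.statistic == pytest.approx(stat, abs=1e-12)
        assert res.df == df

    def test_bowker_agrees_with_statsmodels_when_no_zero_pairs(self):
        from statsmodels.stats.contingency_tables import SquareTable
        rng = np.random.default_rng(8)
        t = rng.integers(1, 20, (4, 4)).astype(float)
        res = mcnemar(t)
        sm = SquareTable(t).symmetry(method="bowker")
        assert res.statistic == pytest.approx(float(sm.statistic), rel=1e-12)
        assert res.p_value == pytest.approx(float(sm.pvalue), rel=1e-9)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError, match="square"):
            mcnemar(np.ones((2, 3)))


class TestKruskalWallis:
    def test_constant_groups_h_zero(self):
        res = kruskal_wallis([[5, 5, 5], [5, 5, 5], [5, 5]])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_statistic_matches_rank_formula_oracle(self):
        rng = np.random.default_rng(9)
        groups = [rng.normal(size=n) for n in (4, 5, 3)]
        res = kruskal_wallis(groups)
        # direct tie-corrected H from the rank definition
        pooled = np.concatenate(groups)
        ranks = sps.rankdata(pooled)
        n = pooled.size
        h = 0.0
        start = 0
        for g in groups:
            r = ranks[start:start + g.size]
            h += r.sum() ** 2 / g.size
            start += g.size
        h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
        _, ties = np.unique(pooled, return_counts=True)
        h /= 1 - (ties ** 3 - ties).sum() / (n ** 3 - n)
        assert res.statistic == pytest.approx(h, abs=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            kruskal_wallis([[1, 2], []])


class TestDunnBonferroni:
    def test_adjusted_never_below_raw_and_capped(self):
        rng = np.random.default_rng(10)
        groups = [rng.normal(loc=mu, size=12) for mu in (0, 0.3, 2.0)]
        post = dunn_bonferroni(groups)
        assert (post["p_bonferroni"] >= post["p_raw"] - 1e-15).all()
        assert (post["p_bonferroni"] <= 1.0).all()
        assert len(post) == 3  # k(k-1)/2 pairs

    def test_identical_groups_z_zero(self):
        g = list(range(10))
        post = dunn_bonferroni([g, g])
        assert post["z"].abs().max() == pytest.approx(0.0, abs=1e-12)
        assert post["p_bonferroni"].iloc[0] == 1.0

    def test_shifted_group_flagged(self):
        rng = np.random.default_rng(11)
        groups = [rng.normal(0, 1, 20), rng.normal(0, 1, 20), rng.normal(4, 1, 20)]
        post = dunn_bonferroni(groups, labels=["a", "b", "c"])
        sig = post[post["p_bonferroni"] < 0.01]
        assert set(sig["group_b"]) == {"c"}

    def test_bonferroni_adjust(self):
        assert bonferroni_adjust(0.01, 3) == pytest.approx(0.03)
        assert bonferroni_adjust(0.5, 10) == 1.0


class TestMannWhitney:
    def test_statistic_matches_pair_count_oracle(self):
        rng = np.random.default_rng(12)
        a = rng.integers(0, 6, 7).astype(float)  # ties on purpose
        b = rng.integers(0, 6, 6).astype(float)
        res = mann_whitney(a, b)
        u = sum(1.0 if x > y else 0.5 if x == y else 0.0 for x in a for y in b)
        assert res.statistic == pytest.approx(u, abs=1e-9)

    def test_sample_against_itself_p_one(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = mann_whitney(a, a)
        assert res.p_value == pytest.approx(1.0, abs=1e-6)

    def test_exact_p_matches_permutation_oracle(self):
        a = np.array([1.2, 3.4, 0.5, 2.2])
        b = np.array([4.1, 5.0, 2.9])
        res = mann_whitney(a, b, method="exact")
        # enumerate all label assignments
        pooled = np.concatenate([a, b])
        u_obs = sum((x > y) for x in a for y in b)
        us = []
        for combo in itertools.combinations(range(7), 4):
            ga = pooled[list(combo)]
            gb = pooled[[i for i in range(7) if i not in combo]]
            us.append(sum((x > y) for x in ga for y in gb))
        us = np.array(us)
        mu = len(a) * len(b) / 2
        p_perm = np.mean(np.abs(us - mu) >= abs(u_obs - mu))
        assert res.p_value == pytest.approx(p_perm, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestSpearman:
    def test_monotone_sequences(self):
        assert spearman([1, 5, 9, 20], [2, 3, 10, 50]).statistic == pytest.approx(1.0)
        assert spearman([1, 2, 3, 4], [4, 3, 2, 1]).statistic == pytest.approx(-1.0)

    def test_statistic_matches_rank_pearson_oracle(self):
        rng = np.random.default_rng(13)
        x = rng.integers(0, 5, 8).astype(float)
        y = rng.integers(0, 5, 8).astype(float)
        res = spearman(x, y)
        rho = np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1]
        assert res.statistic == pytest.approx(rho, abs=1e-9)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="mismatch"):
            spearman([1, 2, 3], [1, 2])
        with pytest.raises(ValueError, match="n >= 3"):
            spearman([1, 2], [1, 2])


class TestLinearByLinear:
    def test_zero_correlation_table(self):
        # symmetric cross table: scores uncorrelated by construction
        t = [[5, 5], [5, 5]]
        assert linear_by_linear(t).statistic == pytest.approx(0.0, abs=1e-12)

    def test_2x2_identity_with_pearson_chi2(self):
        t = np.array([[12, 5], [7, 17]], float)
        n = t.sum()
        chi2 = sps.chi2_contingency(t, correction=False).statistic
        m2 = linear_by_linear(t).statistic
        assert m2 == pytest.approx((n - 1) / n * chi2, abs=1e-9)

    def test_monotone_5x2_table_significant(self):
        # 41 subjects, proportion in column 0 falls monotonically
        t = [[8, 1], [7, 2], [4, 5], [2, 6], [0, 6]]
        res = linear_by_linear(t)
        assert res.p_value < 0.01

    def test_custom_scores_change_statistic(self):
        t = [[10, 2], [3, 9], [8, 4]]
        default = linear_by_linear(t).statistic
        flipped = linear_by_linear(t, row_scores=[0, 2, 1]).statistic
        assert default != pytest.approx(flipped)

    def test_tiny_total_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            linear_by_linear([[1, 0], [0, 0]])


class TestWeightedKappa:
    def test_identical_vectors(self):
        res = weighted_kappa([1, 2, 3, 2, 1], [1, 2, 3, 2, 1])
        assert res.kappa == pytest.approx(1.0) and res.band == "almost perfect"

    def test_independent_ratings_near_zero(self):
        rng = np.random.default_rng(14)
        a = rng.integers(1, 6, 5000)
        b = rng.permutation(a)
        res = weighted_kappa(list(a), list(b))
        assert abs(res.kappa) <= 0.05

    @pytest.mark.parametrize("scheme", ["linear", "quadratic"])
    def test_agrees_with_sklearn(self, scheme):
        from sklearn.metrics import cohen_kappa_score
        rng = np.random.default_rng(15)
        a = rng.integers(0, 5, 200)
        b = np.clip(a + rng.integers(-1, 2, 200), 0, 4)
        res = weighted_kappa(list(a), list(b), scheme=scheme)
        ref = cohen_kappa_score(a, b, weights=scheme)
        assert res.kappa == pytest.approx(float(ref), abs=1e-12)

    def test_reported_agreement_band(self):
        assert kappa_band(0.896) == "almost perfect"

    def test_disjoint_categories_rejected(self):
        with pytest.raises(ValueError, match="categories"):
            weighted_kappa([1, 1, 2], [5, 6, 6])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            weighted_kappa([1, 2], [1, 2, 3])


class TestSummarizeNumeric:
    def test_skewed_sample_selects_median_form(self):
        rng = np.random.default_rng(16)
        values = np.exp(rng.normal(size=80) * 1.5)  # heavy right skew
        s = summarize_numeric(values)
        assert s.shapiro_p < 0.05 and s.display == "median_iqr"

    def test_large_normal_sample_selects_mean_form(self):
        hits = 0
        for seed in range(10):
            values = np.random.default_rng(100 + seed).normal(10, 2, 200)
            if summarize_numeric(values).display == "mean_sd":
                hits += 1
        assert hits >= 9

    def test_constant_vector_degenerate(self):
        s = summarize_numeric([3.0, 3.0, 3.0, 3.0])
        assert "degenerate_constant" in s.flags and s.display == "median_iqr"

    def test_tiny_sample_skips_gate(self):
        s = summarize_numeric([1.0, 2.0])
        assert s.shapiro_p is None and "too_few_for_normality_gate" in s.flags

    def test_render_forms(self):
        rng = np.random.default_rng(17)
        s = summarize_numeric(rng.normal(0, 1, 50))
        assert ("+/-" in s.render()) == (s.display == "mean_sd")
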