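import numpy as np
import pytest
from scipy import stats as sps

from pessaryfit import (
    GroupSummary,
    baseline_table,
    exact_contingency_test,
    mann_whitney_u,
    pooled_mean_sd,
    summarize,
    t_test_independent,
)


class TestPooled:
    def test_whole_sample_tvl_mean(self):
        pooled = pooled_mean_sd(
            [GroupSummary(9, 8.6, 1.5), GroupSummary(6, 8.2, 0.8)]
        )
        assert round(pooled.mean, 1) == 8.4

    def test_whole_sample_bmi_mean(self):
        pooled = pooled_mean_sd(
            [GroupSummary(9, 27.8, 3.8), GroupSummary(6, 23.9, 3.2)]
        )
        assert round(pooled.mean, 1) == 26.2

    def test_identical_groups_idempotent(self):
        g = GroupSummary(8, 5.0, 2.0)
        pooled = pooled_mean_sd([g, g])
        assert pooled.mean == 5.0
        assert pooled.sd == pytest.approx(2.0, rel=0.05)  # (n-1) bookkeeping

    def test_pooled_sd_reconstructs_raw_sample(self):
        rng = np.random.default_rng(1)
        a, b = rng.standard_normal(9) + 1, rng.standard_normal(6)
        pooled = pooled_mean_sd([summarize(a), summarize(b)])
        both = np.concatenate([a, b])
        assert pooled.mean == pytest.approx(both.mean())
        assert pooled.sd == pytest.approx(both.std(ddof=1))


class TestTTest:
    def test_null_identity(self):
        res = t_test_independent(GroupSummary(9, 5.0, 1.0), GroupSummary(6, 5.0, 1.0))
        assert res["t"] == 0.0
        assert res["p"] == 1.0

    def test_bmi_summaries_land_near_printed_value(self):
        # rounded summaries bound, not pin, the raw-data p-value (0.055)
        res = t_test_independent(GroupSummary(9, 27.8, 3.8), GroupSummary(6, 23.9, 3.2))
        assert 0.04 <= res["p"] <= 0.07
        assert res["df"] == 13.0

    def test_raw_and_summary_inputs_agree(self):
        rng = np.random.default_rng(2)
        a, b = rng.standard_normal(9), rng.standard_normal(6) + 0.5
        r_raw = t_test_independent(a, b)
        r_sum = t_test_independent(summarize(a), summarize(b))
        assert r_raw["t"] == pytest.approx(r_sum["t"], abs=1e-10)
        assert r_raw["p"] == pytest.approx(r_sum["p"], abs=1e-10)

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(3)
        a, b = rng.standard_normal(7), rng.standard_normal(5) + 1
        r1, r2 = t_test_independent(a, b), t_test_independent(b, a)
        assert r1["t"] == pytest.approx(-r2["t"])
        assert r1["p"] == r2["p"]
        assert 0 < r1["p"] <= 1

    def test_welch_differs_from_pooled_for_unequal_variances(self):
        g1, g2 = GroupSummary(9, 1.0, 0.5), GroupSummary(6, 0.0, 3.0)
        pooled = t_test_independent(g1, g2)
        welch = t_test_independent(g1, g2, welch=True)
        assert welch["df"] < pooled["df"]
        assert welch["p"] != pooled["p"]

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            t_test_independent(GroupSummary(1, 0.0, 0.0), GroupSummary(6, 1.0, 1.0))
        with pytest.raises(ValueError, match="zero variance"):
            t_test_independent(GroupSummary(5, 0.0, 0.0), GroupSummary(6, 1.0, 0.0))


class TestMannWhitney:
    def test_tied_singletons_midrank_u(self):
        assert mann_whitney_u([1], [1]) == {"U": 0.5, "p": 1.0}

    def test_fully_separated_groups_exact_p(self):
        # brute force over all C(6,3)=20 rank splits gives 2/20
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res["U"] == 0.0
        assert res["p"] == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        res = mann_whitney_u([1, 2, 5], [1, 2, 5])
        assert res["p"] == 1.0

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            pool = rng.choice(10000, size=15, replace=False).astype(float)
            a, b = pool[:8], pool[8:]
            mine = mann_whitney_u(a, b)
            ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert mine["p"] == pytest.approx(float(ref.pvalue), abs=1e-12)

    def test_large_samples_use_tie_corrected_normal_approximation(self):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 5, 15).astype(float)
        b = rng.integers(1, 6, 15).astype(float)
        mine = mann_whitney_u(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert mine["p"] == pytest.approx(float(ref.pvalue), abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestExactContingency:
    def test_popq_stage_split(self):
        # 3/9 fitting vs 5/6 non-fitting at stage 3
        assert exact_contingency_test([[3, 6], [5, 1]])["p"] == pytest.approx(
            0.119, abs=5e-4
        )

    def test_diagonal_two_by_two(self):
        # 3 margin-fixed tables; the two extremes each have probability 1/6
        assert exact_contingency_test([[2, 0], [0, 2]])["p"] == pytest.approx(1 / 3)

    def test_degenerate_margins_give_p_one(self):
        assert exact_contingency_test([[0, 0], [3, 4]])["p"] == 1.0

    def test_transpose_and_row_swap_invariance(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            t = rng.integers(0, 6, (2, 3))
            if (t.sum(0) == 0).any() or (t.sum(1) == 0).any():
                continue
            p = exact_contingency_test(t)["p"]
            assert exact_contingency_test(t.T)["p"] == pytest.approx(p, abs=1e-12)
            assert exact_contingency_test(t[::-1])["p"] == pytest.approx(p, abs=1e-12)

    def test_two_by_two_matches_scipy_fisher(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            t = rng.integers(0, 8, (2, 2))
            if (t.sum(0) == 0).any() or (t.sum(1) == 0).any():
                continue
            assert exact_contingency_test(t)["p"] == pytest.approx(
                float(sps.fisher_exact(t)[1]), abs=1e-12
            )

    def test_generic_enumerator_agrees_with_hypergeometric(self):
        # route a 2x2 through the r x c path by stacking a zero-free column split
        import math

        from pessaryfit.stats import _enumerate_tables, _log_table_prob

        rng = np.random.default_rng(8)
        for _ in range(10):
            t = rng.integers(1, 7, (2, 2))
            row_m, col_m = t.sum(1), t.sum(0)
            lfm = sum(math.lgamma(v + 1) for v in np.concatenate([row_m, col_m]))
            lfn = math.lgamma(t.sum() + 1)
            p_obs = math.exp(_log_table_prob(t, lfm, lfn))
            total = sum(
                pt
                for tab in _enumerate_tables(row_m.tolist(), col_m.tolist())
                if (pt := math.exp(_log_table_prob(np.asarray(tab), lfm, lfn)))
                <= p_obs * (1 + 1e-7)
            )
            assert min(1.0, total) == pytest.approx(
                exact_contingency_test(t)["p"], abs=1e-12
            )

    def test_enumeration_limit_enforced(self):
        with pytest.raises(ValueError, match="limit"):
            exact_contingency_test(np.full((2, 3), 20))


def test_baseline_table_shapes_and_pvalues(small_cohort):
    table = baseline_table(small_cohort)
    assert set(table["test"]) == {"t", "mann_whitney", "exact"}
    assert ((table["p"] > 0) & (table["p"] <= 1)).all()
    assert "BMI (kg/m2)" in set(table["variable"])
    assert len(table) == 9
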