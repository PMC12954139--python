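"""The five test procedures against brute-force enumeration oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st_h

from omam import stat_tests as st

import oracles


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0])
        assert st.spearman(x, x * 2 + 1).statistic == pytest.approx(1.0)
        assert st.spearman(x, -x).statistic == pytest.approx(-1.0)

    def test_small_sample_matches_permutation_oracle(self):
        x = [1, 2, 3, 4, 5]
        y = [2, 1, 4, 3, 5]
        res = st.spearman(x, y)
        rho_o, p_o = oracles.spearman_exact(x, y)
        assert res.method == "exact"
        # rho = 1 - 6*sum(d^2)/(n(n^2-1)) with d = (-1,1,-1,1,0) -> 0.8
        assert res.statistic == pytest.approx(0.8)
        assert rho_o == pytest.approx(0.8)
        assert res.p_value == pytest.approx(p_o)

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_p_equals_enumeration_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 8))
        x = rng.integers(0, 4, n).astype(float)
        y = rng.integers(0, 4, n).astype(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        res = st.spearman(x, y)
        rho_o, p_o = oracles.spearman_exact(x, y)
        assert res.statistic == pytest.approx(rho_o)
        assert res.p_value == pytest.approx(p_o)

    def test_zero_variance_not_computable(self):
        res = st.spearman([1, 1, 1, 1, 1], [1, 2, 3, 4, 5])
        assert res.status == "not_computable"
        assert np.isnan(res.p_value)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(25)
        y = rng.standard_normal(25)
        base = st.spearman(x, y)
        warped = st.spearman(np.exp(x), y**3 + 5 * y)
        assert warped.statistic == pytest.approx(base.statistic)
        assert warped.p_value == pytest.approx(base.p_value)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            st.spearman([1, 2, 3], [1, 2, 3])


class TestMannWhitney:
    def test_separated_groups(self):
        res = st.mann_whitney([1, 2], [3, 4])
        assert res.statistic == 0.0
        assert res.method == "exact"
        assert res.p_value == pytest.approx(2 / 6)

    def test_identical_multisets_give_p_one(self):
        res = st.mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(1.0)

    def test_tied_singletons_midrank_u(self):
        res = st.mann_whitney([1.0], [1.0])
        assert res.statistic == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(25))
    def test_exact_matches_labeling_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        na = int(rng.integers(1, 5))
        nb = int(rng.integers(1, 9 - na))
        a = rng.integers(0, 5, na).astype(float)
        b = rng.integers(0, 5, nb).astype(float)
        res = st.mann_whitney(a, b)
        u_o, p_o = oracles.mann_whitney_exact(a, b)
        assert res.statistic == pytest.approx(u_o)
        assert res.p_value == pytest.approx(p_o)

    def test_rank_invariance_under_monotone_maps(self):
        rng = np.random.default_rng(9)
        a = rng.standard_normal(20)
        b = rng.standard_normal(22) + 0.5
        base = st.mann_whitney(a, b)
        warped = st.mann_whitney(np.expm1(a), np.expm1(b))
        assert warped.statistic == pytest.approx(base.statistic)
        assert warped.p_value == pytest.approx(base.p_value)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            st.mann_whitney([], [1.0])


class TestWilcoxon:
    def test_all_positive_differences(self):
        res = st.wilcoxon_signed_rank([1, 2, 3, 4, 5])
        assert res.statistic == 15.0
        assert res.method == "exact"
        assert res.p_value == pytest.approx(2 / 32)

    def test_symmetric_pair(self):
        assert st.wilcoxon_signed_rank([1.0, -1.0]).p_value == pytest.approx(1.0)

    def test_zero_differences_dropped(self):
        res = st.wilcoxon_signed_rank([0.0, 1.0, 2.0, -1.5])
        assert res.n == 3
        assert res.detail["n_zeros_dropped"] == 1

    def test_all_zero_not_computable(self):
        res = st.wilcoxon_signed_rank([0.0, 0.0])
        assert res.status == "not_computable"

    @pytest.mark.parametrize("seed", range(25))
    def test_exact_matches_sign_enumeration(self, seed):
        rng = np.random.default_rng(200 + seed)
        n = int(rng.integers(2, 9))
        d = rng.integers(-4, 5, n).astype(float)
        if np.all(d == 0):
            d[0] = 1.0
        res = st.wilcoxon_signed_rank(d)
        w_o, p_o = oracles.wilcoxon_exact(d)
        assert res.statistic == pytest.approx(w_o)
        assert res.p_value == pytest.approx(p_o)


class TestBinomial:
    def test_zero_successes_small_null(self):
        res = st.binomial_test(0, 40, 0.025)
        assert res.p_value == pytest.approx(min(1.0, 2 * 0.975**40))
        assert res.p_value == pytest.approx(0.7264, abs=5e-4)

    def test_boundary_all_successes(self):
        res = st.binomial_test(10, 10, 0.999)
        assert res.p_value == pytest.approx(1.0)

    def test_reference_tail_count_not_significant(self):
        # 9 of 367 above a 97.5th-percentile cutoff is compatible with 2.5%
        res = st.binomial_test(9, 367, 0.025)
        assert res.p_value > 0.05
        assert res.detail["proportion"] == pytest.approx(0.0245, abs=5e-4)

    @pytest.mark.parametrize("k,n,p0", [(0, 8, 0.3), (3, 8, 0.5), (7, 8, 0.4),
                                        (2, 5, 0.025), (5, 5, 0.9)])
    def test_matches_pmf_summation_oracle(self, k, n, p0):
        assert st.binomial_test(k, n, p0).p_value == pytest.approx(
            oracles.binomial_two_sided(k, n, p0))

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            st.binomial_test(5, 4, 0.5)
        with pytest.raises(ValueError):
            st.binomial_test(1, 4, 1.0)


class TestMcNemar:
    def test_no_discordance(self):
        res = st.mcnemar(0, 0)
        assert res.p_value == 1.0
        assert res.status == "no_discordance"

    def test_small_discordance_exact(self):
        assert st.mcnemar(5, 1).p_value == pytest.approx(14 / 64)

    def test_symmetric_capped_at_one(self):
        assert st.mcnemar(7, 7).p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("b,c", [(0, 3), (2, 2), (1, 6), (4, 0), (3, 5)])
    def test_exact_matches_oracle(self, b, c):
        assert st.mcnemar(b, c).p_value == pytest.approx(
            oracles.mcnemar_exact(b, c))

    def test_large_counts_use_continuity_corrected_chi_square(self):
        from scipy.stats import chi2
        res = st.mcnemar(30, 12)
        assert res.method == "chi_square_cc"
        expected = chi2.sf((abs(30 - 12) - 1) ** 2 / 42, df=1)
        assert res.p_value == pytest.approx(expected)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            st.mcnemar(-1, 2)


@given(k=st_h.integers(0, 30), n=st_h.integers(1, 30),
       p0=st_h.floats(0.01, 0.99))
def test_two_sided_p_values_always_capped(k, n, p0):
    if k > n:
        return
    assert 0.0 <= st.binomial_test(k, n, p0).p_value <= 1.0


@given(b=st_h.integers(0, 60), c=st_h.integers(0, 60))
def test_mcnemar_p_in_unit_interval(b, c):
    assert 0.0 <= st.mcnemar(b, c).p_value <= 1.0


def test_type_one_error_rates_near_nominal():
    """Under null simulations each test rejects at 5% at a rate in [.03, .07]."""
    rng = np.random.default_rng(5)
    reps = 1000
    rej = {"spearman": 0, "mann_whitney": 0, "wilcoxon": 0,
           "binomial": 0, "mcnemar": 0}
    for _ in range(reps):
        rej["spearman"] += st.spearman(rng.standard_normal(30),
                                       rng.standard_normal(30)).significant
        rej["mann_whitney"] += st.mann_whitney(
            rng.standard_normal(25), rng.standard_normal(25)).significant
        rej["wilcoxon"] += st.wilcoxon_signed_rank(
            rng.standard_normal(40)).significant
        rej["binomial"] += st.binomial_test(
            int(rng.binomial(400, 0.3)), 400, 0.3).significant
        pair = rng.random((150, 2)) < 0.3
        b = int(np.sum(pair[:, 0] & ~pair[:, 1]))
        c = int(np.sum(~pair[:, 0] & pair[:, 1]))
        rej["mcnemar"] += st.mcnemar(b, c).significant
    for name, count in rej.items():
        assert 0.03 <= count / reps <= 0.07, (name, count / reps)
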