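import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from regulon_coupler.io import ValidationError
from regulon_coupler.stats import (
    bh_fdr,
    bonferroni,
    fisher_exact_2x2,
    mann_whitney_u,
    pearson_rows,
    pearson_with_p,
)

from oracles import (
    bh_reject_oracle,
    bh_stepup_oracle,
    fisher_two_sided_oracle,
    mwu_exact_two_sided_oracle,
)


class TestPearson:
    def test_identity_is_perfect_correlation(self):
        x = [1.0, 2.0, 5.0, 9.0]
        r, p = pearson_with_p(x, x)
        assert r == 1.0 and p == 0.0

    def test_negation_flips_sign(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        r, p = pearson_with_p(x, -x)
        assert r == -1.0 and p == 0.0

    def test_hand_computed_example(self):
        # product-moment formula by hand: cov = 1.5, sd_x*sd_y = 1.875
        r, p = pearson_with_p([1, 2, 3, 4], [1, 3, 2, 4])
        assert r == pytest.approx(0.8, abs=1e-12)
        # two-sided p from t = r*sqrt((n-2)/(1-r^2)) on n-2 df
        from scipy.stats import t as tdist

        t = 0.8 * np.sqrt(2 / (1 - 0.64))
        assert p == pytest.approx(2 * tdist.sf(t, 2), rel=1e-9)

    def test_pairwise_missing_removal(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [1.1, 2.2, 3.0, 4.1, np.nan]
        r, p = pearson_with_p(x, y)
        r2, p2 = pearson_with_p([1, 2, 4], [1.1, 2.2, 4.1])
        assert r == pytest.approx(r2) and p == pytest.approx(p2)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError, match="variance"):
            pearson_with_p([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValidationError, match="pairs"):
            pearson_with_p([1.0, 2.0], [3.0, 4.0])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.integers(0, 2**31 - 1),
        st.floats(0.1, 10),
        st.floats(-5, 5),
    )
    def test_invariant_under_positive_affine_transform(self, seed, scale, shift):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        r0, p0 = pearson_with_p(x, y)
        r1, p1 = pearson_with_p(scale * x + shift, y)
        assert r1 == pytest.approx(r0, abs=1e-9)
        assert p1 == pytest.approx(p0, abs=1e-9)
        r2, _ = pearson_with_p(-x, y)
        assert r2 == pytest.approx(-r0, abs=1e-9)

    def test_vectorized_rows_agree_with_scalar_kernel(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=25)
        Y = rng.normal(size=(10, 25))
        Y[2, 3] = np.nan  # exercise the pairwise-missing path
        x_miss = x.copy()
        x_miss[7] = np.nan
        for xv in (x, x_miss):
            r, p, n = pearson_rows(xv, Y)
            for i in range(Y.shape[0]):
                ri, pi = pearson_with_p(xv, Y[i])
                assert r[i] == pytest.approx(ri, abs=1e-12)
                assert p[i] == pytest.approx(pi, rel=1e-9, abs=1e-300)


class TestBhFdr:
    def test_worked_example_rejects_exactly_two(self):
        p = [0.001, 0.012, 0.04, 0.8]
        q = bh_fdr(p)
        assert (q < 0.05).sum() == 2
        np.testing.assert_allclose(q, bh_stepup_oracle(p))

    def test_all_zero_and_singleton(self):
        np.testing.assert_array_equal(bh_fdr([0.0, 0.0, 0.0]), 0.0)
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.2])

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 40))
    def test_agrees_with_stepup_oracle_and_rejection_rule(self, seed, m):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=m)
        q = bh_fdr(p)
        np.testing.assert_allclose(q, bh_stepup_oracle(p), atol=1e-12)
        for alpha in (0.01, 0.05, 0.2):
            np.testing.assert_array_equal(q <= alpha, bh_reject_oracle(p, alpha))


class TestFisherExact:
    def test_identical_proportions_give_p_one(self):
        odds, p = fisher_exact_2x2(5, 5, 5, 5)
        assert p == pytest.approx(1.0)
        assert odds == pytest.approx(1.0)

    def test_diagonal_table_enumerated_by_hand(self):
        # margins 3/3; only a=0 and a=3 are as extreme: p = 2/20
        odds, p = fisher_exact_2x2(3, 0, 0, 3)
        assert p == pytest.approx(0.1)
        assert odds == np.inf

    def test_printed_contingency_is_highly_significant(self):
        odds, p = fisher_exact_2x2(48, 87, 8, 127)
        assert p < 1e-4
        assert odds == pytest.approx(48 * 127 / (87 * 8))

    def test_cohort_swap_symmetry(self):
        _, p1 = fisher_exact_2x2(7, 3, 2, 9)
        _, p2 = fisher_exact_2x2(2, 9, 7, 3)
        assert p1 == pytest.approx(p2)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValidationError):
            fisher_exact_2x2(1, -1, 2, 3)

    def test_matches_enumeration_on_small_tables(self):
        # exhaustive check over all tables with total <= 18
        for n in range(1, 19):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    for c in range(n - a - b + 1):
                        d = n - a - b - c
                        _, p = fisher_exact_2x2(a, b, c, d)
                        assert p == pytest.approx(
                            fisher_two_sided_oracle(a, b, c, d), rel=1e-9
                        ), (a, b, c, d)


class TestMannWhitney:
    def test_complete_separation_small_sample(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_groups_with_ties(self):
        _, p = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p >= 0.99

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney_u([], [1.0])

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 5), st.integers(2, 5))
    def test_exact_branch_matches_label_enumeration(self, seed, nx, ny):
        rng = np.random.default_rng(seed)
        pooled = rng.permutation(np.arange(1.0, nx + ny + 1.0))
        x, y = pooled[:nx], pooled[nx:]
        u, p = mann_whitney_u(x, y)
        u_oracle, p_oracle = mwu_exact_two_sided_oracle(x, y)
        assert u == u_oracle
        assert p == pytest.approx(p_oracle, rel=1e-9)

    def test_large_shifted_gaussians_detected(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            x = rng.normal(1.0, 1.0, 81)
            y = rng.normal(0.0, 1.0, 234)
            _, p = mann_whitney_u(x, y)
            assert p < 1e-3


class TestBonferroni:
    def test_worked_examples(self):
        np.testing.assert_allclose(bonferroni([0.01], m=9), [0.09])
        np.testing.assert_allclose(bonferroni([0.5], m=9), [1.0])
        np.testing.assert_allclose(bonferroni([0.3, 0.7], m=2), [0.6, 1.0])
        np.testing.assert_allclose(bonferroni([0.123], m=1), [0.123])

    def test_family_smaller_than_tests_rejected(self):
        with pytest.raises(ValidationError):
            bonferroni([0.1, 0.2, 0.3], m=2)
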