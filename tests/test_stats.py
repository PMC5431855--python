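import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

import fibroscore as fs
from fibroscore.errors import (
    DegenerateInputError,
    DomainError,
    EmptySelectionError,
    MissingDataError,
    PairingError,
    SizeError,
)
from fibroscore.stats import _exact_pmf_doubled

from conftest import make_pair


def two_sided_p_from_pmf(support, pmf, w):
    """Independent recomputation of the two-sided exact p from a null PMF."""
    p_le = pmf[support <= w].sum()
    p_ge = pmf[support >= w].sum()
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestShapiroScreen:
    def test_constant_vector_is_degenerate(self):
        with pytest.raises(DegenerateInputError, match="zero variance"):
            fs.shapiro_wilk_screen([5, 5, 5, 5])

    def test_too_few_values(self):
        with pytest.raises(DegenerateInputError):
            fs.shapiro_wilk_screen([1.0, 2.0])

    def test_lognormal_rejected_at_large_n(self, rng):
        values = rng.lognormal(0.0, 1.0, size=5000)
        _, p = fs.shapiro_wilk_screen(values)
        assert p < 0.05

    def test_minimal_input_contract(self):
        w, p = fs.shapiro_wilk_screen([1.0, 2.0, 3.0])
        assert 0 < w <= 1
        assert 0 <= p <= 1


class TestFriedman:
    def test_identical_blocks_give_zero_statistic(self):
        data = np.full((4, 3), 7.0)
        assert fs.friedman_test(data) == (0.0, 1.0)

    def test_perfect_concordance_three_by_three(self):
        # hand computation: column rank sums 3, 6, 9 ->
        # 12/(3*3*4) * ((3-6)^2 + 0 + (9-6)^2 * ... ) = 6.0
        data = np.array([[1, 2, 3], [1, 2, 3], [1, 2, 3]], dtype=float)
        stat, p = fs.friedman_test(data)
        assert stat == pytest.approx(6.0)
        assert p == pytest.approx(scipy.stats.chi2.sf(6.0, df=2))

    def test_block_permutation_invariance(self, rng):
        data = rng.normal(size=(6, 4))
        base = fs.friedman_test(data)
        perm = fs.friedman_test(data[rng.permutation(6)])
        assert base == pytest.approx(perm)

    def test_incomplete_blocks_name_donors(self):
        data = np.array([[1, 2, 3], [1, np.nan, 3]])
        with pytest.raises(MissingDataError, match="1"):
            fs.friedman_test(data)

    def test_two_groups_redirects_to_pairwise(self):
        with pytest.raises(DomainError, match="pairwise"):
            fs.friedman_test(np.ones((5, 2)))


class TestWilcoxonSignedRank:
    def test_identical_samples(self):
        x = np.arange(10, dtype=float)
        res = fs.wilcoxon_signed_rank(make_pair(x, x))
        assert res.p_value == 1.0
        assert res.mean_diff == 0.0
        assert res.n_used == 0
        assert res.statistic == 0.0

    def test_n10_all_positive_exact(self):
        x = np.arange(1.0, 11.0)
        res = fs.wilcoxon_signed_rank(make_pair(x, x - 1.0))
        assert res.statistic == 55.0
        assert res.p_value == pytest.approx(2 / 1024, abs=0)
        assert res.method == "exact"

    def test_n4_all_positive_exact(self):
        x = np.arange(1.0, 5.0)
        res = fs.wilcoxon_signed_rank(make_pair(x, x - 1.0))
        assert res.p_value == pytest.approx(2 / 16, abs=0)

    def test_length_mismatch_is_pairing_error(self):
        with pytest.raises(PairingError):
            fs.PairedSample(("a", "b"), [1.0, 2.0], [1.0], ["d1", "d2"])

    def test_zero_differences_dropped(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([1.0, 2.0, 2.0, 3.0, 4.0])  # two zero differences
        res = fs.wilcoxon_signed_rank(make_pair(x, y))
        assert res.n_used == 3

    @pytest.mark.parametrize("with_ties", [False, True])
    def test_exact_p_matches_brute_force(self, rng, with_ties):
        """The DP convolution must agree to full precision with literal
        enumeration of all sign assignments, tied or not."""
        for _ in range(60):
            n = int(rng.integers(2, 13))
            d = rng.normal(size=n)
            if with_ties:
                d = np.round(d * 2) / 2
                if np.all(d == 0):
                    continue
            x = rng.lognormal(size=n)
            y = x - d
            res = fs.wilcoxon_signed_rank(make_pair(x, y))
            dd = x - y
            nz = dd[dd != 0]
            if len(nz) == 0:
                continue
            ranks = scipy.stats.rankdata(np.abs(nz))
            support, pmf = fs.exact_signed_rank_null(ranks)
            assert res.p_value == two_sided_p_from_pmf(support, pmf, res.statistic)

    def test_tie_free_agrees_with_scipy_exact(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 13))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            res = fs.wilcoxon_signed_rank(make_pair(x, y))
            ref = scipy.stats.wilcoxon(x, y, method="exact", alternative="two-sided")
            assert res.p_value == pytest.approx(ref.pvalue, rel=1e-12)

    def test_approximate_branch_above_threshold(self, rng):
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        res = fs.wilcoxon_signed_rank(make_pair(x, y))
        assert res.method == "approximate"
        ref = scipy.stats.wilcoxon(
            x, y, method="approx", correction=False, alternative="two-sided"
        )
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=12))
    @settings(max_examples=80)
    def test_swap_antisymmetry(self, diffs):
        """Swapping x and y negates mean_diff and preserves p exactly."""
        d = np.asarray(diffs)
        x = np.abs(d) + 1.0
        sample = make_pair(x, x - d)
        a = fs.wilcoxon_signed_rank(sample)
        b = fs.wilcoxon_signed_rank(sample.swapped())
        assert a.p_value == b.p_value
        assert a.mean_diff == pytest.approx(-b.mean_diff)

    def test_monotone_power_in_shift(self):
        """Rejection frequency is nondecreasing in the planted shift."""
        rng = np.random.default_rng(11)
        rates = []
        for delta in (0.0, 0.5, 1.0, 2.0):
            rej = 0
            for _ in range(150):
                x = rng.normal(delta, 0.6, size=10)
                y = np.zeros(10)
                if fs.wilcoxon_signed_rank(make_pair(x, y)).p_value <= 0.05:
                    rej += 1
            rates.append(rej / 150)
        assert all(b >= a - 0.05 for a, b in zip(rates, rates[1:]))
        assert rates[-1] > rates[0]


class TestExactNullOracle:
    def test_ranks_123_enumeration(self):
        support, pmf = fs.exact_signed_rank_null([1, 2, 3])
        assert list(support) == [0, 1, 2, 3, 4, 5, 6]
        assert pmf[-1] == pytest.approx(1 / 8)
        assert pmf[0] == pytest.approx(1 / 8)

    @given(st.lists(st.integers(1, 8), min_size=1, max_size=10))
    @settings(max_examples=60)
    def test_pmf_normalized_and_symmetric(self, ranks):
        support, pmf = fs.exact_signed_rank_null(ranks)
        assert pmf.sum() == pytest.approx(1.0)
        # sign-flip symmetry: P(W = w) = P(W = sum - w)
        total = sum(ranks)
        lookup = dict(zip(support, pmf))
        for w, p in lookup.items():
            assert lookup[total - w] == pytest.approx(p)

    def test_enumeration_guard(self):
        with pytest.raises(SizeError):
            fs.exact_signed_rank_null(np.arange(1, 22))

    def test_dp_pmf_matches_enumeration_with_midranks(self):
        ranks = [1.5, 1.5, 3.0, 4.5, 4.5]
        support, pmf = fs.exact_signed_rank_null(ranks)
        dp = _exact_pmf_doubled(tuple(int(2 * r) for r in ranks))
        dp_support = np.nonzero(dp)[0] / 2.0
        assert np.array_equal(support, dp_support)
        assert np.allclose(pmf, dp[np.nonzero(dp)])


class TestConditionDependency:
    def test_five_conditions_give_ten_pairs(self, lit_table):
        res = fs.condition_dependency_tests(lit_table, "glass", "IL-6")
        assert len(res.pairwise) == 10
        assert res.friedman_p is not None

    def test_missing_slice_errors(self, lit_table):
        with pytest.raises(EmptySelectionError):
            fs.condition_dependency_tests(lit_table, "vibranium", "IL-6")

    def test_planted_condition_effect_detected(self):
        """A +3 log-unit condition stands out from all four others."""
        cfg = fs.default_config(seed=21)
        cfg = fs.null_scenario(cfg)
        cfg.noise_sd = {r: 0.3 for r in cfg.readouts}
        cfg.condition_log_effect = {"IL-6": {"LPS": 3.0}}
        table = fs.generate_dataset(cfg)
        res = fs.condition_dependency_tests(table, "glass", "IL-6")
        lps = [t for t in res.pairwise if "LPS" in t.labels]
        assert len(lps) == 4
        assert all(t.significant for t in lps)

    def test_null_pairwise_rate_near_alpha(self):
        """Under the null the significant-pair fraction tracks the exact
        test's attainable size at alpha = 0.05 (n = 10 donors)."""
        base = fs.default_config(seed=33)
        base.lod = {r: 0.0 for r in base.readouts}
        null = fs.null_scenario(base)
        hits = total = 0
        for seed in range(12):
            null.seed = 40000 + seed
            table = fs.generate_dataset(null)
            for readout in ("IL-6", "IL-8"):
                res = fs.condition_dependency_tests(table, "glass", readout)
                hits += sum(t.significant for t in res.pairwise)
                total += len(res.pairwise)
        # attainable size for n=10 is ~0.02; 99.9% binomial envelope at most
        rate = hits / total
        assert rate < 0.12
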