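"""Exact binomial test and BH adjustment against independent oracles."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from asbscan.as_test import (
    bh_adjust,
    binom_two_sided,
    binom_two_sided_many,
    run_binomial_tests,
    select_as_snps,
)
from asbscan.model import AlleleCountRecord, HetSNP


def enumeration_p_value(k: int, n: int) -> float:
    """Exact-arithmetic oracle for the symmetric null: sum the probability of
    every outcome no more likely than the observed one, using integer
    binomial coefficients (pmf ordering is exact, no floating point)."""
    row = [comb(n, i) for i in range(n + 1)]
    total = sum(c for c in row if c <= row[k])
    return float(Fraction(total, 2**n))


class TestBinomTwoSided:
    def test_mode_of_symmetric_null_is_one(self):
        assert binom_two_sided(5, 10) == 1.0

    def test_all_successes_tail(self):
        # 2 * (1/2)^10, enumerable by hand
        assert binom_two_sided(0, 10) == pytest.approx(0.001953125, abs=1e-15)

    def test_against_enumeration_oracle_spot(self):
        assert binom_two_sided(15, 20) == pytest.approx(
            enumeration_p_value(15, 20), abs=1e-12
        )

    @pytest.mark.parametrize("n", [1, 2, 7, 30, 101, 200])
    def test_against_scipy_binomtest(self, n):
        # independent cross-check with the established implementation
        for k in range(n + 1):
            expected = stats.binomtest(k, n, 0.5).pvalue
            assert binom_two_sided(k, n) == pytest.approx(expected, abs=1e-12)

    def test_asymmetric_null_against_scipy(self):
        for k, n, p0 in [(3, 20, 0.3), (18, 20, 0.7), (0, 15, 0.9)]:
            expected = stats.binomtest(k, n, p0).pvalue
            assert binom_two_sided(k, n, p0) == pytest.approx(expected, rel=1e-9)

    def test_vectorised_matches_scalar(self):
        rng = np.random.default_rng(5)
        n = rng.integers(1, 120, size=200)
        k = rng.integers(0, n + 1)
        many = binom_two_sided_many(k, n)
        for ki, ni, pi in zip(k, n, many):
            assert pi == binom_two_sided(int(ki), int(ni))

    @pytest.mark.parametrize("k,n", [(-1, 10), (11, 10), (0, 0)])
    def test_invalid_inputs_rejected(self, k, n):
        with pytest.raises(ValueError):
            binom_two_sided(k, n)

    @given(st.integers(min_value=1, max_value=150), st.data())
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_symmetry_exact(self, n, data):
        k = data.draw(st.integers(min_value=0, max_value=n))
        assert binom_two_sided(k, n) == binom_two_sided(n - k, n)

    @given(st.integers(min_value=2, max_value=150))
    @settings(deadline=None, derandomize=True, max_examples=40)
    def test_monotone_away_from_center(self, n):
        ps = [binom_two_sided(k, n) for k in range(n // 2, n + 1)]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))


class TestBhAdjust:
    def test_single_p_identity(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_worked_step_up(self):
        # ranks 1..4 give quotients 0.04, 0.04, 0.04, 0.04 after the running min
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_preserves_input_order(self):
        q = bh_adjust([0.04, 0.01, 0.03, 0.02])
        assert np.argmin(q) in (0, 1, 2, 3)  # order preserved, values paired
        assert q[1] <= q[0]

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_empty(self):
        assert bh_adjust([]).size == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_statsmodels_on_random_vectors(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(rng.integers(1, 400))
        expected = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=60))
    @settings(deadline=None, derandomize=True, max_examples=80)
    def test_definitional_bounds(self, p):
        q = bh_adjust(p)
        assert (q >= np.asarray(p) - 1e-15).all() and q.max() <= 1.0


class TestSelection:
    def _results(self, counts, alpha=0.05):
        records = [
            AlleleCountRecord(HetSNP(f"s{i}", "c", 10 * (i + 1), "A", "C"), g1, g2)
            for i, (g1, g2) in enumerate(counts)
        ]
        return run_binomial_tests(records, alpha=alpha)

    def test_all_null_empty_selection(self):
        results = self._results([(5, 5), (6, 4), (4, 6)])
        assert select_as_snps(results) == []

    def test_alpha_one_selects_everything(self):
        results = self._results([(5, 5), (20, 1)], alpha=1.0)
        assert len(select_as_snps(results, alpha=1.0)) == 2

    def test_selection_matches_independent_filter_and_sort(self):
        rng = np.random.default_rng(7)
        counts = [
            (int(g1), int(n - g1))
            for n, g1 in (
                (n, rng.binomial(n, p))
                for n, p in zip(
                    rng.integers(10, 80, size=50),
                    rng.choice([0.5, 0.9], size=50, p=[0.8, 0.2]),
                )
            )
        ]
        results = self._results(counts)
        picked = select_as_snps(results)
        expected = sorted(
            (r for r in results if r.q_value < 0.05),
            key=lambda r: (r.q_value, -abs(r.allelic_ratio - 0.5)),
        )
        assert [r.snp.snp_id for r in picked] == [r.snp.snp_id for r in expected]
        assert all(r.selected for r in picked)

    def test_q_never_below_p(self):
        for r in self._results([(0, 30), (10, 10), (25, 5), (3, 17)]):
            assert r.q_value >= r.p_value - 1e-15

    def test_raw_method_selects_on_p(self):
        records = [
            AlleleCountRecord(HetSNP(f"s{i}", "c", i + 1, "A", "C"), 9, 1)
            for i in range(30)
        ]
        raw = run_binomial_tests(records, method="raw")
        assert all(r.selected == (r.p_value < 0.05) for r in raw)
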