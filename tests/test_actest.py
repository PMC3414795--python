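"""Unit and property tests for the exact two-library count test."""
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracle
from twolib import (
    GenePairCounts,
    InputDomainError,
    InputFormatError,
    LibraryPair,
    ac_probability,
    ac_pvalue,
    ac_pvalues,
    bh_fdr,
    run_ac_tests,
)


class TestMassFunction:
    @pytest.mark.parametrize(
        "y, x, n1, n2, expected",
        [
            (0, 0, 100, 100, 0.5),      # collapses to (1+1)^-1
            (1, 0, 100, 100, 0.25),     # 1 * 1 * 2^-2
            (0, 0, 7, 7, 0.5),
        ],
    )
    def test_small_closed_forms(self, y, x, n1, n2, expected):
        assert ac_probability(y, x, LibraryPair(n1, n2)) == pytest.approx(expected, rel=1e-12)

    def test_matches_exact_rational_evaluation(self):
        """Log-gamma evaluation agrees with the exact rational formula to
        12 significant digits on an asymmetric deep-library case."""
        libs = LibraryPair(10**6, 2 * 10**6)
        got = ac_probability(30, 5, libs)
        expected = float(oracle.mass_exact(30, 5, 10**6, 2 * 10**6))
        assert oracle.rel_err(got, expected) < 1e-12

    def test_deep_counts_do_not_underflow(self):
        """Counts around 1e6 must stay representable (log-space evaluation)."""
        libs = LibraryPair(10**7, 10**7)
        p = ac_probability(10**6, 10**6, libs)
        assert 0.0 < p < 1.0

    @pytest.mark.parametrize("ratio", [0.1, 0.5, 1.0, 2.0, 10.0])
    @pytest.mark.parametrize("x", [0, 3, 17, 50])
    def test_normalizes_to_one(self, x, ratio):
        """The conditional mass function is a distribution over y."""
        n1 = 10**6
        libs = LibraryPair(n1, int(n1 * ratio))
        mean = (x + 1) * libs.ratio
        y_max = int(mean + 20 * math.sqrt(mean * (1 + libs.ratio)) + 200)
        total = sum(ac_probability(y, x, libs) for y in range(y_max))
        assert total == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("bad_y, bad_x", [(-1, 0), (0, -2), (1.5, 0), (0, 2.5)])
    def test_rejects_bad_counts(self, bad_y, bad_x, equal_libs):
        with pytest.raises(InputDomainError):
            ac_probability(bad_y, bad_x, equal_libs)

    def test_rejects_zero_library(self):
        with pytest.raises(InputDomainError):
            LibraryPair(0, 100)


class TestPvalue:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            (0, 0, 1.0),   # F = 0.5 exactly -> 2F branch
            (0, 1, 0.5),   # F = 0.75 -> complement branch 2(1 - 0.75)
        ],
    )
    def test_equal_library_examples(self, x, y, expected, equal_libs):
        assert ac_pvalue(x, y, equal_libs) == pytest.approx(expected, rel=1e-12)

    def test_matches_exact_rational_summation(self, equal_libs):
        got = ac_pvalue(5, 30, equal_libs)
        expected = float(oracle.pvalue_exact(5, 30, 10**6, 10**6))
        assert oracle.rel_err(got, expected) < 1e-10

    @pytest.mark.parametrize("n2_mult", [1, 3])
    def test_oracle_grid(self, n2_mult):
        """Spot-check a small grid against the exact rational oracle (the
        full 41x41 grid runs in the acceptance suite)."""
        n1 = 10**5
        libs = LibraryPair(n1, n2_mult * n1)
        for x in range(0, 13, 3):
            for y in range(0, 13, 3):
                got = ac_pvalue(x, y, libs)
                expected = float(oracle.pvalue_exact(x, y, n1, n2_mult * n1))
                assert oracle.rel_err(got, expected) < 1e-10, (x, y)

    def test_equal_library_symmetry(self, equal_libs):
        """With N1 = N2 the test cannot distinguish which library is which."""
        x, y = np.meshgrid(np.arange(201), np.arange(201), indexing="ij")
        p, _ = ac_pvalues(x.ravel(), y.ravel(), equal_libs)
        p = p.reshape(201, 201)
        np.testing.assert_allclose(p, p.T, rtol=1e-11)

    def test_cumulative_monotone_in_y(self, unequal_libs):
        for x in (0, 7, 40):
            _, tails = ac_pvalues(
                np.full(120, x, dtype=np.int64), np.arange(120, dtype=np.int64), unequal_libs
            )
            assert np.all(np.diff(tails) >= 0)

    @given(
        x=st.integers(0, 500),
        y=st.integers(0, 500),
        n1=st.integers(1, 10**7),
        mult=st.integers(1, 20),
    )
    @settings(max_examples=200, derandomize=True)
    def test_always_a_valid_probability(self, x, y, n1, mult):
        p = ac_pvalue(x, y, LibraryPair(n1, n1 * mult))
        assert 0.0 < p <= 1.0

    def test_clamped_never_zero(self):
        """Extremely incompatible counts clamp at the float floor, not 0."""
        p = ac_pvalue(0, 100_000, LibraryPair(10**6, 10**6))
        assert p > 0.0
        assert math.isfinite(math.log(p))

    def test_fractional_count_arrays_rejected(self, equal_libs):
        with pytest.raises(InputDomainError):
            ac_pvalues(np.array([1.5]), np.array([2.0]), equal_libs)


class TestBhFdr:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.01], [0.01]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([1.0] * 10, [1.0] * 10),
        ],
    )
    def test_stepup_examples(self, p, expected):
        np.testing.assert_allclose(bh_fdr(p), expected, rtol=1e-12)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=60))
    @settings(max_examples=150, derandomize=True)
    def test_matches_hand_stepup(self, p):
        np.testing.assert_allclose(bh_fdr(p), oracle.bh_stepup(p), rtol=1e-10, atol=1e-12)

    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=40), st.randoms(use_true_random=False))
    @settings(max_examples=100, derandomize=True)
    def test_permutation_equivariance(self, p, rnd):
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        q = bh_fdr(p)
        q_perm = bh_fdr([p[i] for i in perm])
        np.testing.assert_allclose(q_perm, [q[i] for i in perm], rtol=1e-12)

    def test_sorted_q_values_nondecreasing(self):
        rng = np.random.default_rng(7)
        p = rng.random(500)
        q = bh_fdr(p)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-15)

    @pytest.mark.parametrize("bad", [[-0.1], [1.2], [float("nan")], []])
    def test_rejects_invalid_input(self, bad):
        with pytest.raises(InputDomainError):
            bh_fdr(bad)


class TestRunAcTests:
    def test_single_gene_q_equals_p(self, equal_libs):
        (res,) = run_ac_tests([GenePairCounts("g1", 4, 9)], equal_libs)
        assert res.q_value == pytest.approx(res.p_value)

    def test_duplicate_gene_ids_rejected(self, equal_libs):
        genes = [GenePairCounts("g1", 1, 1), GenePairCounts("g1", 2, 2)]
        with pytest.raises(InputFormatError, match="g1"):
            run_ac_tests(genes, equal_libs)

    def test_equal_count_table_has_no_discoveries(self, equal_libs):
        """x = y with equal libraries is the most null-compatible data
        possible: every p-value is the symmetric-case value and nothing can
        clear FDR 0.001."""
        genes = [GenePairCounts(f"g{i}", i, i) for i in range(100)]
        results = run_ac_tests(genes, equal_libs)
        for res, gene in zip(results, genes):
            expected = float(oracle.pvalue_exact(gene.x, gene.y, 10**6, 10**6))
            assert oracle.rel_err(res.p_value, expected) < 1e-10
        assert all(r.q_value > 0.001 for r in results)

    def test_simulated_null_genes_yield_no_discoveries(self, null_run):
        counts, _ = null_run
        libs = LibraryPair(int(counts["count_a"].sum()), int(counts["count_b"].sum()))
        genes = [
            GenePairCounts(g, int(a), int(b))
            for g, a, b in zip(counts["gene_id"], counts["count_a"], counts["count_b"])
        ]
        results = run_ac_tests(genes, libs)
        assert sum(r.q_value <= 0.001 for r in results) == 0
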