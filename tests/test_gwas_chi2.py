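"""Tests for the chi-square front end, plaintext and encrypted."""

import math
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats
from scipy.special import erfc

from foresee.approx_div import build_plan
from foresee.exceptions import InputError, ParameterError
from foresee.gwas_chi2 import (
    SNPCounts,
    allele_count_table,
    approx_relative_error_bound,
    build_chi2_lookup,
    chi2_equal_groups,
    chi2_general,
    chi2_pvalue,
    evaluate_accuracy,
    feasible_pairs,
    secure_chi2_approx,
    secure_chi2_errorless,
)
from foresee.modmath import smallest_prime_above


def table_from_pair(o11, o21, n, sid="s"):
    return SNPCounts(sid, o11, 2 * n - o11, o21, 2 * n - o21)


class TestAlleleCounting:
    def test_two_individuals(self):
        tables = allele_count_table([[2, 0]], ["case", "control"])
        t = tables[0]
        assert (t.o11, t.o12, t.o21, t.o22) == (0, 2, 2, 0)

    def test_all_reference_is_monomorphic(self):
        t = allele_count_table([[0, 0, 0, 0]], ["case"] * 2 + ["control"] * 2)[0]
        assert (t.o12, t.o22) == (0, 0)
        assert (t.o11, t.o21) == (4, 4)
        assert t.monomorphic

    def test_permutation_within_groups_invariant(self):
        rng = np.random.default_rng(7)
        G = rng.integers(0, 3, size=(5, 8))
        groups = ["case"] * 4 + ["control"] * 4
        base = allele_count_table(G, groups)
        perm = np.concatenate([rng.permutation(4), 4 + rng.permutation(4)])
        shuffled = allele_count_table(G[:, perm], groups)
        for a, b in zip(base, shuffled):
            assert (a.o11, a.o12, a.o21, a.o22) == (b.o11, b.o12, b.o21, b.o22)

    def test_bad_genotype_value_rejected(self):
        with pytest.raises(InputError):
            allele_count_table([[3]], ["case"])

    def test_empty_group_rejected(self):
        with pytest.raises(InputError):
            allele_count_table([[1, 2]], ["case", "case"])


class TestExactStatistic:
    def test_four_cell_example(self):
        # n=1, perfectly separated alleles: all E = 1, four unit terms
        assert chi2_general(SNPCounts("s", 2, 0, 0, 2)) == pytest.approx(4.0)

    def test_equal_rows_give_zero(self):
        assert chi2_general(SNPCounts("s", 3, 5, 3, 5)) == pytest.approx(0.0)
        assert chi2_equal_groups(3, 3, 4) == 0

    def test_statistic_scales_linearly(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            o11, o21 = rng.integers(1, 20, size=2)
            n = 25
            base = chi2_general(table_from_pair(int(o11), int(o21), n))
            k = 3
            scaled = chi2_general(
                SNPCounts("s", 3 * int(o11), 3 * (2 * n - int(o11)),
                          3 * int(o21), 3 * (2 * n - int(o21)))
            )
            assert scaled == pytest.approx(k * base, rel=1e-12)

    def test_monomorphic_raises(self):
        with pytest.raises(ParameterError):
            chi2_general(SNPCounts("s", 4, 0, 4, 0))
        with pytest.raises(ParameterError):
            chi2_equal_groups(0, 0, 2)
        with pytest.raises(ParameterError):
            chi2_equal_groups(4, 4, 2)

    def test_matches_scipy_contingency(self):
        """Independent route: scipy's chi-square without Yates correction."""
        rng = np.random.default_rng(11)
        for _ in range(30):
            t = SNPCounts("s", *(int(v) for v in rng.integers(1, 50, size=4)))
            expected = stats.chi2_contingency(
                [[t.o11, t.o12], [t.o21, t.o22]], correction=False
            ).statistic
            assert chi2_general(t) == pytest.approx(expected, rel=1e-10)

    @pytest.mark.parametrize("n", range(1, 11))
    def test_single_division_form_equals_four_cell_form(self, n):
        """The equal-group simplification, exhaustively for n <= 10."""
        for o11, o21 in feasible_pairs(n):
            full = chi2_general(table_from_pair(o11, o21, n))
            short = chi2_equal_groups(o11, o21, n)
            assert full == pytest.approx(float(short), rel=1e-12)

    def test_equality_at_larger_random_n(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            n = int(rng.integers(11, 501))
            o11 = int(rng.integers(0, 2 * n + 1))
            o21 = int(rng.integers(0, 2 * n + 1))
            if o11 + o21 in (0, 4 * n):
                continue
            assert chi2_general(table_from_pair(o11, o21, n)) == pytest.approx(
                float(chi2_equal_groups(o11, o21, n)), rel=1e-12
            )

    def test_allele_coding_flip_preserves_statistic(self):
        """Swapping which allele is counted flips columns but not chi2."""
        for o11, o21 in [(5, 1), (8, 8), (0, 3)]:
            n = 5
            t = table_from_pair(o11, o21, n)
            flipped = SNPCounts("s", t.o12, t.o11, t.o22, t.o21)
            assert chi2_general(t) == pytest.approx(chi2_general(flipped))


class TestPValue:
    def test_zero_statistic(self):
        assert chi2_pvalue(0.0) == 1.0

    def test_95th_percentile(self):
        assert chi2_pvalue(3.841459) == pytest.approx(0.05, rel=1e-5)

    def test_matches_erfc_route(self):
        for x in (0.5, 1.0, 3.84, 10.0, 30.0):
            assert chi2_pvalue(x) == pytest.approx(
                float(erfc(math.sqrt(x / 2))), rel=1e-12
            )

    def test_monotone_decreasing(self):
        xs = [0.0, 0.5, 1.0, 2.0, 5.0, 10.0]
        ps = [chi2_pvalue(x) for x in xs]
        assert ps == sorted(ps, reverse=True)

    def test_negative_rejected(self):
        with pytest.raises(InputError):
            chi2_pvalue(-0.1)


class TestApproxPipeline:
    def test_zero_numerator_is_exact(self):
        plan = build_plan(1, 13, 12)
        (res,) = secure_chi2_approx([1], [1], 1, plan)
        assert res.chi2_protocol == 0.0 == res.chi2_exact

    def test_hand_traced_n1(self):
        """A=4, B=4, q=floor(12/4)=3, val=12, chi2 = 4*12/12 = 4."""
        plan = build_plan(1, 13, 12)
        (res,) = secure_chi2_approx([2], [0], 1, plan)
        assert res.chi2_protocol == pytest.approx(4.0)
        assert res.chi2_exact == pytest.approx(4.0)

    def test_exhaustive_error_bound_n10(self):
        """All feasible pairs at n=10 respect the 4n^2/M relative bound."""
        n = 10
        p = smallest_prime_above(16 * n**3)
        M = p - 1
        plan = build_plan(n, p, M)
        bound = approx_relative_error_bound(n, M)
        pairs = list(feasible_pairs(n))
        res = secure_chi2_approx(
            [a for a, _ in pairs], [b for _, b in pairs], n, plan
        )
        for r in res:
            if r.chi2_exact == 0:
                assert r.chi2_protocol == 0
            else:
                rel = abs(r.chi2_protocol - r.chi2_exact) / r.chi2_exact
                assert rel <= bound

    def test_monomorphic_pair_rejected_before_encryption(self):
        plan = build_plan(1, 13, 12)
        with pytest.raises(ParameterError):
            secure_chi2_approx([0], [0], 1, plan)

    def test_out_of_range_counts_rejected(self):
        plan = build_plan(1, 13, 12)
        with pytest.raises(InputError):
            secure_chi2_approx([5], [0], 1, plan)


class TestErrorlessPipeline:
    def test_exhaustive_exactness_n5(self):
        """Decoded chi2 equals the exact rational at every feasible pair."""
        n = 5
        lookup = build_chi2_lookup(n)
        pairs = list(feasible_pairs(n))
        res = secure_chi2_errorless(
            [a for a, _ in pairs], [b for _, b in pairs], n, lookup=lookup
        )
        for (o11, o21), r in zip(pairs, res):
            assert r.chi2_protocol == float(chi2_equal_groups(o11, o21, n))

    def test_boundary_maximal_statistic(self):
        """O11 = 2n, O21 = 0 attains the maximum value 4n."""
        n = 4
        (res,) = secure_chi2_errorless([2 * n], [0], n)
        assert res.chi2_protocol == pytest.approx(4 * n)

    def test_equal_counts_give_zero(self):
        (res,) = secure_chi2_errorless([3], [3], 3)
        assert res.chi2_protocol == 0.0


class TestEvaluateAccuracy:
    def test_identity_protocol(self):
        vals = [0.5, 4.2, 11.0, 0.0]
        rep = evaluate_accuracy(vals, vals)
        assert rep.mse == 0.0 and rep.max_abs_error == 0.0
        for _, precision, recall in rep.by_cutoff.values():
            assert precision == 1.0 and recall == 1.0

    def test_default_cutoffs(self):
        rep = evaluate_accuracy([1.0], [1.0])
        assert set(rep.by_cutoff) == {0.05, 0.01, 0.005}

    def test_detects_disagreement(self):
        # exact significant (chi2=5 -> p~0.025), protocol not (chi2=1)
        rep = evaluate_accuracy([5.0], [1.0])
        n_sig, precision, recall = rep.by_cutoff[0.05]
        assert n_sig == 1 and recall == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            evaluate_accuracy([1.0], [1.0, 2.0])


class TestCloudPhaseIsolation:
    def test_cloud_functions_never_decrypt(self):
        """The ciphertext-only phase has no access to decryption."""
        import inspect

        from foresee import approx_div, errorless_div, gwas_chi2

        cloud_funcs = [
            gwas_chi2.cloud_chi2_approx,
            gwas_chi2.cloud_chi2_errorless,
            gwas_chi2._numerator_denominator,
            approx_div.secure_integer_divide,
            approx_div.binary_tree_powers,
            errorless_div.secure_map,
        ]
        import ast
        import textwrap

        for fn in cloud_funcs:
            tree = ast.parse(textwrap.dedent(inspect.getsource(fn)))
            called = {
                node.func.attr if isinstance(node.func, ast.Attribute)
                else getattr(node.func, "id", None)
                for node in ast.walk(tree)
                if isinstance(node, ast.Call)
            }
            assert not {"decrypt", "decrypt_vector"} & called, fn.__name__
            assert "session" not in inspect.signature(fn).parameters
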