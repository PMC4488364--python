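"""Per-pair estimators: zygotic LD, HWD, composite LD, d statistic."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import zygoscan as z
from zygoscan import _bulk

counts_strategy = st.lists(st.integers(0, 200), min_size=9, max_size=9).filter(
    lambda c: sum(c) >= 30 and sum(c) > 0
)


def table_from(counts):
    return z.TwoLocusTable(np.array(counts).reshape(3, 3))


class TestCounting:
    def test_two_homozygote_individuals(self):
        with pytest.warns(UserWarning, match="n=2"):
            t = z.count_two_locus(np.array([2, 2]), np.array([2, 2]))
        assert t.counts[0, 0] == 2 and t.n == 2

    def test_missing_excluded_pairwise(self):
        c1 = np.array([2, 1, 0, 2])
        c2 = np.array([2, -1, 0, 1])
        with pytest.warns(UserWarning):
            t = z.count_two_locus(c1, c2)
        assert t.n == 3  # individual 2 missing at locus B drops out

    def test_matches_naive_tally(self):
        rng = np.random.default_rng(0)
        c1 = rng.integers(-1, 3, size=500)
        c2 = rng.integers(-1, 3, size=500)
        t = z.count_two_locus(c1, c2)
        naive = np.zeros((3, 3), dtype=int)
        for a, b in zip(c1, c2):
            if a >= 0 and b >= 0:
                naive[2 - a, 2 - b] += 1
        assert (t.counts == naive).all()

    def test_empty_table_is_error(self):
        with pytest.raises(z.ld.DegenerateTableError):
            z.count_two_locus(np.array([-1, -1]), np.array([2, 2]))


class TestZygoticLD:
    def test_reference_table_values(self, f1_table):
        zy = z.zygotic_ld(f1_table)
        assert zy.tracked["AABB"] == pytest.approx(0.14)
        assert zy.chi2["AABB"] == pytest.approx(34.0278, abs=1e-4)
        assert zy.r2["AABB"] == pytest.approx(0.3403, abs=1e-4)
        assert zy.tracked["AaBb"] == pytest.approx(0.0975)
        assert zy.tracked["AABb"] == pytest.approx(-0.08)
        assert zy.tracked["AaBB"] == pytest.approx(-0.08)
        # constraint closes the AA row with D_AAbb = -0.06
        assert zy.D[0, 2] == pytest.approx(-0.06)

    def test_independence_table_all_zero(self, independence_table):
        zy = z.zygotic_ld(independence_table)
        assert np.allclose(zy.D, 0, atol=1e-12)
        assert all(c == pytest.approx(0, abs=1e-9) for c in zy.chi2.values())

    def test_perfect_coupling_r2_is_one(self):
        t = table_from([50, 0, 0, 0, 0, 0, 0, 0, 50])
        zy = z.zygotic_ld(t)
        assert zy.tracked["AABB"] == pytest.approx(0.25)
        assert zy.chi2["AABB"] == pytest.approx(100)
        assert zy.r2["AABB"] == pytest.approx(1.0)

    def test_monomorphic_marginal_flagged_not_nan_propagated(self):
        # locus B has no bb and no Bb in two tracked pairs? make p_BB = 1
        t = table_from([40, 0, 0, 30, 0, 0, 30, 0, 0])
        zy = z.zygotic_ld(t)
        assert not zy.defined["AABB"]
        assert zy.significant["AABB"] is False

    @given(counts_strategy)
    def test_constraint_conservation(self, counts):
        t = table_from(counts)
        zy = z.zygotic_ld(t)
        assert np.allclose(zy.D.sum(axis=0), 0, atol=1e-12)
        assert np.allclose(zy.D.sum(axis=1), 0, atol=1e-12)

    @given(counts_strategy)
    def test_scale_property(self, counts):
        """Doubling counts doubles chi2, leaves D and r2 unchanged."""
        t = table_from(counts)
        t2 = table_from([2 * c for c in counts])
        z1, z2 = z.zygotic_ld(t), z.zygotic_ld(t2)
        assert np.allclose(z1.D, z2.D, atol=1e-12)
        for g in _bulk.TRACKED:
            if z1.defined[g]:
                assert z2.chi2[g] == pytest.approx(2 * z1.chi2[g])
                assert z2.r2[g] == pytest.approx(z1.r2[g])
                assert z1.chi2[g] == pytest.approx(t.n * z1.r2[g])


class TestHwd:
    def test_hwe_exact_counts_zero(self):
        t = table_from([6, 13, 6, 13, 24, 13, 6, 13, 6])
        res = z.hwd_test(t, "A")
        assert res.D_hw == pytest.approx(0.0)
        assert res.chi2 == pytest.approx(0.0)

    def test_reference_table_locus_a(self, f1_table):
        res = z.hwd_test(f1_table, "A")
        assert res.D_hw == pytest.approx(0.40 - 0.625**2)

    def test_maximal_heterozygote_excess(self):
        t = table_from([0, 0, 0, 25, 50, 25, 0, 0, 0])
        res = z.hwd_test(t, "A")
        assert res.D_hw == pytest.approx(-0.25)
        assert res.chi2 == pytest.approx(100)


class TestCompositeLD:
    def test_reference_table(self, f1_table):
        assert z.composite_ld(f1_table) == pytest.approx(0.16875)

    def test_independence_zero(self, independence_table):
        assert z.composite_ld(independence_table) == pytest.approx(0, abs=1e-12)

    def test_perfect_coupling(self):
        t = table_from([50, 0, 0, 0, 0, 0, 0, 0, 50])
        assert z.composite_ld(t) == pytest.approx(0.5)

    @given(counts_strategy)
    def test_zygotic_decomposition_identity(self, counts):
        """Counting formula equals 2 D_AABB + D_AABb + D_AaBB + D_AaBb / 2."""
        t = table_from(counts)
        d = z.zygotic_ld(t).tracked
        assert z.composite_ld(t) == pytest.approx(
            2 * d["AABB"] + d["AABb"] + d["AaBB"] + d["AaBb"] / 2, abs=1e-12
        )

    def test_reduced_null_variance(self):
        """With every optional term zeroed, V = p_A p_a p_B p_b / n."""
        t = table_from([6, 13, 6, 13, 24, 13, 6, 13, 6])  # p_A = p_B = 0.5, n=100
        zy = z.zygotic_ld(t, alpha=1e-30)     # nothing significant
        ha = z.hwd_test(t, "A", alpha=1e-30)
        hb = z.hwd_test(t, "B", alpha=1e-30)
        res = z.composite_ld_test(t, zy, ha, hb, alpha=0.05)
        assert res.variance == pytest.approx(0.25 * 0.25 / 100)
        assert res.chi2 == pytest.approx(res.delta**2 / res.variance)
        assert res.r2_delta == pytest.approx(res.chi2 / 100)

    def test_literal_bracket_reading_matches_exact_gradient_variance(self):
        """The closed-form variance bracket (literal reading) equals the delta-method variance of
        Delta computed from the multinomial covariance and gradient."""
        rng = np.random.default_rng(4)
        for _ in range(20):
            p = rng.dirichlet(np.ones(9)).reshape(3, 3)
            c = _bulk._delta_gradient(p.reshape(9))
            v_grad = _bulk.multinomial_quadratic_variance(p.reshape(9), c, 1.0)
            v_closed = _bulk.composite_variance_truth(p, 1.0)
            assert v_closed == pytest.approx(float(v_grad), rel=1e-10)


class TestDifferenceD:
    def test_reference_table_sign_case(self, f1_table):
        d, comp, case = z.difference_d(f1_table)
        assert d == pytest.approx(0.02875)
        assert comp == "AABB" and case == "same"

    def test_epistatic_fixture(self, epistatic_table):
        d, comp, _ = z.difference_d(epistatic_table)
        assert d == pytest.approx(-0.24)
        assert comp == "AaBb"

    def test_independence_zero(self, independence_table):
        d, _, _ = z.difference_d(independence_table)
        assert d == pytest.approx(0, abs=1e-12)

    @given(counts_strategy)
    def test_d_never_exceeds_abs_delta(self, counts):
        t = table_from(counts)
        d, _, _ = z.difference_d(t)
        assert d <= abs(z.composite_ld(t)) + 1e-12

    def test_epistatic_classification_at_large_n(self, epistatic_table):
        t = z.TwoLocusTable(epistatic_table.counts * 100)  # n = 10^4
        res = z.difference_d_test(t)
        assert res.classification == "epistatic"
        assert res.p < 1e-9
        assert res.d == pytest.approx(-0.24)

    def test_additive_classification_at_large_n(self):
        t = z.TwoLocusTable(np.array([[50, 0, 0], [0, 0, 0], [0, 0, 50]]) * 100)
        res = z.difference_d_test(t, seed=0)
        assert res.d == pytest.approx(0.25)
        # the gradient vanishes at p=0.5 for this two-class table, so the
        # variance comes from the bootstrap fallback
        assert res.method == "bootstrap"
        assert res.classification == "additive"

    def test_tie_falls_back_to_bootstrap(self):
        # symmetric table with the maximum attained jointly by AABb and AaBB
        t = table_from([10, 40, 0, 40, 0, 0, 0, 0, 10])
        zy = z.zygotic_ld(t)
        assert zy.tracked["AABb"] == pytest.approx(zy.tracked["AaBB"])
        res = z.difference_d_test(t, seed=1)
        assert res.tie
        assert res.method == "bootstrap"
        assert res.max_component == "AABb"  # fixed tracked order breaks the tie

    def test_delta_and_bootstrap_agree_where_smooth(self):
        from zygoscan.models import model_from_haplotypes, sample_pair
        m = model_from_haplotypes(0.3, 0.3, 0.15)
        t = sample_pair(m, 2000, seed=1)
        r_delta = z.difference_d_test(t, method="delta")
        r_boot = z.difference_d_test(t, method="bootstrap", n_boot=4000, seed=2)
        assert r_delta.variance == pytest.approx(r_boot.variance, rel=0.25)


class TestBootstrapVariance:
    def test_single_class_table_zero(self):
        t = table_from([100, 0, 0, 0, 0, 0, 0, 0, 0])
        for stat in ("delta", "d", "AABB"):
            assert z.bootstrap_variance(t, stat, B=200, seed=0) == 0.0

    def test_reproducible_and_seed_stable(self, f1_table):
        v1 = z.bootstrap_variance(f1_table, "delta", B=2000, seed=5)
        v2 = z.bootstrap_variance(f1_table, "delta", B=2000, seed=5)
        v3 = z.bootstrap_variance(f1_table, "delta", B=2000, seed=6)
        assert v1 == v2
        assert v1 == pytest.approx(v3, rel=0.15)

    def test_matches_closed_form_full_evaluation(self, f1_table):
        v_boot = z.bootstrap_variance(f1_table, "delta", B=10_000, seed=3)
        v_closed = float(_bulk.composite_variance_truth(f1_table.p, f1_table.n))
        assert v_boot == pytest.approx(v_closed, rel=0.15)

    def test_small_b_rejected(self, f1_table):
        with pytest.raises(ValueError):
            z.bootstrap_variance(f1_table, "delta", B=50)
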