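"""Differential-abundance test panel: exactness, calibration and dispatch."""

import numpy as np
import pytest
from scipy import stats

import countdesign as cd
from countdesign.dat import nb_exact_pvalue, welch_t
from countdesign.generators import SimConfig


class TestNBExactPvalue:
    def test_balanced_equal_counts_give_p_one(self):
        assert nb_exact_pvalue(50, 50, 3, 3, 0.0) == 1.0
        assert nb_exact_pvalue(50, 50, 3, 3, 0.4) == 1.0

    def test_poisson_limit_equals_exact_binomial(self):
        """At phi=0 with equal sizes, the conditional test is Binomial(s, 1/2)."""
        for s1, s2 in [(5, 15), (2, 30), (10, 12)]:
            s = s1 + s2
            dist = stats.binom(s, 0.5)
            expected = min(1.0, 2 * min(dist.cdf(s1), dist.sf(s1 - 1)))
            assert nb_exact_pvalue(s1, s2, 4, 4, 0.0) == pytest.approx(expected, abs=1e-9)

    def test_conditional_distribution_is_betabinomial(self):
        """Enumerating NB products matches scipy's beta-binomial conditional law."""
        n1, n2, phi, s = 3, 5, 0.4, 60
        a, b = n1 / phi, n2 / phi
        k = np.arange(s + 1)
        # independent oracle: normalized product of the two NB pmfs at fixed total
        p_marg = 0.3  # arbitrary shared NB success probability cancels out
        f1 = stats.nbinom.logpmf(k, a, p_marg)
        f2 = stats.nbinom.logpmf(s - k, b, p_marg)
        pmf = np.exp(f1 + f2 - (f1 + f2).max())
        pmf /= pmf.sum()
        np.testing.assert_allclose(pmf, stats.betabinom.pmf(k, s, a, b), atol=1e-12)
        # and the doubled smaller tail agrees with the implementation
        for s1 in (10, 22, 45):
            lower, upper = pmf[: s1 + 1].sum(), pmf[s1:].sum()
            expected = min(1.0, 2 * min(lower, upper))
            assert nb_exact_pvalue(s1, s - s1, n1, n2, phi) == pytest.approx(
                expected, abs=1e-9)

    def test_large_total_beta_limit_is_continuous(self):
        # p-values straddling the exact/approximate switch stay close
        phi, n1, n2 = 0.5, 4, 4
        p_small = nb_exact_pvalue(3500, 6400, n1, n2, phi)
        p_large = nb_exact_pvalue(35000, 64000, n1, n2, phi)
        assert p_small == pytest.approx(p_large, rel=0.05)

    def test_zero_total(self):
        assert nb_exact_pvalue(0, 0, 3, 3, 0.5) == 1.0


class TestNBExactTest:
    def test_result_schema_and_qvalues(self, null_pair_small):
        cm = cd.simulate(null_pair_small, SimConfig(NR=3, ND=300, SM="nb", SV=0.3, seed=1))
        res = cd.nb_exact_test(cm)
        assert len(res.pvalue) == cm.n_entities
        assert ((res.pvalue >= 0) & (res.pvalue <= 1)).all()
        assert ((res.qvalue >= 0) & (res.qvalue <= 1)).all()
        order = np.argsort(res.pvalue)
        assert (np.diff(res.qvalue[order]) >= -1e-12).all()

    def test_label_swap_negates_log2fc_keeps_p(self, null_pair_small):
        cm = cd.simulate(null_pair_small, SimConfig(NR=3, ND=300, SM="nb", SV=0.3, seed=2))
        swapped = cd.CountMatrix(cm.counts, cm.entity_ids, cm.sample_ids,
                                 np.where(cm.condition == 1, 2, 1), truth=cm.truth)
        f = cd.totalcount_normalize(cm)
        fs = cd.totalcount_normalize(swapped)
        a = cd.nb_exact_test(cm, f, dispersion=0.3)
        b = cd.nb_exact_test(swapped, fs, dispersion=0.3)
        np.testing.assert_allclose(a.pvalue, b.pvalue, atol=1e-12)
        np.testing.assert_allclose(a.log2fc, -b.log2fc, atol=1e-9)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            cd.CountMatrix(np.array([[-1, 2]]), ["G0"], ["a", "b"], np.array([1, 2]))


class TestWilcoxon:
    def test_separated_groups_exact_enumeration(self, cm_factory):
        cm = cm_factory(np.array([[1, 2, 3, 4, 5, 6]]), condition=[1, 1, 1, 2, 2, 2])
        res = cd.wilcoxon_test(cm)
        assert res.pvalue[0] == pytest.approx(0.1, abs=1e-12)

    def test_identical_groups(self, cm_factory):
        cm = cm_factory(np.array([[5, 5, 5, 5, 5, 5]]), condition=[1, 1, 1, 2, 2, 2])
        assert cd.wilcoxon_test(cm).pvalue[0] == 1.0

    def test_minimum_samples_enforced(self, cm_factory):
        cm = cm_factory(np.array([[1, 2, 3, 4]]), condition=[1, 1, 2, 2])
        with pytest.raises(ValueError, match="3"):
            cd.wilcoxon_test(cm)


class TestWelch:
    def test_hand_computed_case(self):
        t, df, p = welch_t(np.array([1.0, 2, 3]), np.array([4.0, 5, 6]))
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert df == pytest.approx(4.0, abs=1e-9)
        assert p == pytest.approx(0.0213, abs=5e-4)

    def test_identical_groups_p_one(self, cm_factory):
        cm = cm_factory(np.array([[2, 4, 6, 2, 4, 6]]), condition=[1, 1, 1, 2, 2, 2])
        assert cd.welch_t_test(cm).pvalue[0] == 1.0

    def test_zero_variance_distinct_means_flagged(self, cm_factory):
        cm = cm_factory(np.array([[3, 3, 9, 9]]), condition=[1, 1, 2, 2])
        with pytest.warns(UserWarning, match="zero variance"):
            res = cd.welch_t_test(cm)
        assert res.pvalue[0] == 0.0

    def test_log_transform_applied(self, cm_factory):
        # on a log scale, multiplying both groups by a constant shifts both
        # means equally: p must be unchanged
        cm1 = cm_factory(np.array([[10, 20, 30, 45, 55, 65]]),
                         condition=[1, 1, 1, 2, 2, 2])
        big = np.array([[10, 20, 30, 45, 55, 65]]) * 64
        cm2 = cm_factory(big, condition=[1, 1, 1, 2, 2, 2])
        p1 = cd.welch_t_test(cm1).pvalue[0]
        p2 = cd.welch_t_test(cm2).pvalue[0]
        # +1 offset breaks exact equality at small counts; loose agreement only
        assert p1 == pytest.approx(p2, rel=0.2)


class TestFisherPooled:
    def test_hand_table_matches_hypergeometric(self, cm_factory):
        cm = cm_factory(np.array([[1, 9], [9, 1]]), condition=[1, 2])
        res = cd.fisher_exact_pooled(cm)
        expected = stats.fisher_exact(np.array([[1, 9], [9, 1]]))[1]
        assert res.pvalue[0] == pytest.approx(expected, abs=1e-12)

    def test_symmetric_table_p_one(self, cm_factory):
        cm = cm_factory(np.array([[5, 5], [5, 5]]), condition=[1, 2])
        np.testing.assert_allclose(cd.fisher_exact_pooled(cm).pvalue, 1.0)

    def test_chi_square_fallback_warns(self, cm_factory):
        counts = np.array([[2 * 10**8, 10**8], [10**8, 2 * 10**8]])
        cm = cm_factory(counts, condition=[1, 2])
        with pytest.warns(UserWarning, match="chi-square"):
            res = cd.fisher_exact_pooled(cm)
        assert (res.pvalue <= 1).all()


class TestBHAdjust:
    def test_hand_stepup(self):
        np.testing.assert_allclose(cd.bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_single_p(self):
        assert cd.bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_all_ones(self):
        np.testing.assert_allclose(cd.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cd.bh_adjust([0.5, 1.5])


class TestRunDat:
    def test_dispatch_records_normalization(self, null_pair_small):
        cm = cd.simulate(null_pair_small, SimConfig(NR=3, ND=300, SM="nb", SV=0.3, seed=3))
        res = cd.run_dat("nb_exact", cm, normalization="mode")
        assert res.normalization_used == "mode"
        assert res.test_name == "nb_exact"

    def test_unknown_name_lists_registered(self, null_pair_small):
        cm = cd.simulate(null_pair_small, SimConfig(NR=3, ND=300, SM="nb", SV=0.3, seed=4))
        with pytest.raises(ValueError, match="nb_exact"):
            cd.run_dat("bogus", cm)

    def test_duplicate_registration_rejected(self):
        with pytest.raises(ValueError):
            cd.register_dat("nb_exact", lambda c, f: None)

    def test_row_count_matches_filter(self, null_pair_small):
        cm = cd.simulate(null_pair_small, SimConfig(NR=3, ND=50, SM="nb", SV=0.3, seed=5))
        surviving = cd.filter_low_counts(cm, min_count=10).n_entities
        for name in ("nb_exact", "wilcoxon", "welch_t", "fisher"):
            assert len(cd.run_dat(name, cm).pvalue) == surviving


class TestNullCalibration:
    @pytest.mark.parametrize("name", ["nb_exact", "wilcoxon", "welch_t", "fisher"])
    def test_global_null_p_roughly_uniform(self, name):
        """Without perturbation or replicate variability, rejection at 0.05
        stays in a loose band around the nominal level."""
        fracs = []
        for s in range(3):
            profile = cd.make_powerlaw_profile(2000, 1.0, seed=10 + s)
            pair = cd.apply_perturbation(profile, cd.PerturbationSpec(0, 0), seed=20 + s)
            cm = cd.simulate(pair, SimConfig(NR=5, ND=100, SM="full", SV=0.0, seed=30 + s))
            res = cd.run_dat(name, cm, normalization="mode")
            fracs.append((res.pvalue < 0.05).mean())
        assert 0.02 <= np.mean(fracs) <= 0.10
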