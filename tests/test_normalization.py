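"""Normalization factors: mode normalization and classical baselines."""

import numpy as np
import pytest

import countdesign as cd
from countdesign.generators import SimConfig
from countdesign.normalization import condition_factor_ratio
from countdesign.profiles import filter_low_counts


def geomean(x):
    return np.exp(np.mean(np.log(x)))


class TestComputeUFC:
    def test_ratio_two_gives_log2_one(self, cm_factory):
        cm = cm_factory(np.array([[10, 10, 20, 20]]))
        ufc = cd.compute_ufc(cm)
        assert ufc.log_ufc[0] == pytest.approx(1.0)

    def test_identical_conditions_zero(self, cm_factory):
        cm = cm_factory(np.array([[7, 7], [123, 123]]), condition=[1, 2])
        np.testing.assert_allclose(cd.compute_ufc(cm).log_ufc, 0.0)

    def test_pseudocount_on_zero_mean(self, cm_factory):
        cm = cm_factory(np.array([[0, 8]]), condition=[1, 2])
        assert cd.compute_ufc(cm).log_ufc[0] == pytest.approx(np.log2(8.5 / 0.5))

    def test_one_condition_errors(self, cm_factory):
        cm = cm_factory(np.array([[1, 2]]), condition=[1, 1])
        with pytest.raises(ValueError):
            cd.compute_ufc(cm)


class TestModeNormalize:
    def test_identical_samples_unit_factors(self):
        rng = np.random.default_rng(0)
        col = rng.poisson(300, size=500)
        counts = np.column_stack([col, col, col, col])
        cm = cd.CountMatrix(counts, [f"G{i}" for i in range(500)],
                            list("abcd"), np.array([1, 1, 2, 2]))
        nf = cd.mode_normalize(cm)
        assert np.abs(nf.factors - 1).max() < 0.02

    def test_depth_doubled_recovers_factor_two(self):
        """Half the entities DA, condition-2 depth doubled: mode sits at log2(2)."""
        rng = np.random.default_rng(1)
        base = rng.poisson(rng.uniform(50, 500, size=600))
        null_part = np.column_stack([rng.poisson(base), rng.poisson(base),
                                     rng.poisson(2 * base), rng.poisson(2 * base)])
        da_base = rng.uniform(50, 500, size=600)
        da_fold = rng.uniform(4, 8, size=600)
        da_part = np.column_stack([rng.poisson(da_base), rng.poisson(da_base),
                                   rng.poisson(2 * da_fold * da_base),
                                   rng.poisson(2 * da_fold * da_base)])
        counts = np.vstack([null_part, da_part])
        cm = cd.CountMatrix(counts, [f"G{i}" for i in range(1200)],
                            list("abcd"), np.array([1, 1, 2, 2]))
        nf = cd.mode_normalize(cm)
        assert nf.flags["mode_location"] == pytest.approx(1.0, abs=0.15)
        assert condition_factor_ratio(nf, cm.condition) == pytest.approx(2.0, rel=0.05)

    def test_bimodal_flag_on_two_equal_da_blocks(self):
        """Two equal DA blocks and no nulls: selection is ambiguous and flagged."""
        rng = np.random.default_rng(2)
        up = rng.uniform(100, 400, size=400)
        down = rng.uniform(100, 400, size=400)
        counts = np.vstack([
            np.column_stack([rng.poisson(up), rng.poisson(up),
                             rng.poisson(8 * up), rng.poisson(8 * up)]),
            np.column_stack([rng.poisson(8 * down), rng.poisson(8 * down),
                             rng.poisson(down), rng.poisson(down)]),
        ])
        cm = cd.CountMatrix(counts, [f"G{i}" for i in range(800)],
                            list("abcd"), np.array([1, 1, 2, 2]))
        nf = cd.mode_normalize(cm)
        assert nf.flags["bimodal_warning"] is True
        assert nf.flags["n_modes"] == 2

    def test_too_few_entities(self, cm_factory):
        cm = cm_factory(np.ones((10, 4), dtype=int) * 50)
        with pytest.raises(ValueError, match="too few entities"):
            cd.mode_normalize(cm)

    def test_bandwidth_never_below_floor(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(200, size=(300, 4))
        cm = cd.CountMatrix(counts, [f"G{i}" for i in range(300)],
                            list("abcd"), np.array([1, 1, 2, 2]))
        nf = cd.mode_normalize(cm)
        assert nf.flags["bandwidth_used"] >= 0.02 - 1e-12

    def test_tracks_oracle_under_asymmetric_perturbation(self):
        """Mode factors stay near the non-DA oracle where library-size methods drift."""
        dist = {m: [] for m in ("mode", "totalcount", "upperquartile")}
        ratios = []
        for s in range(5):
            profile = cd.make_powerlaw_profile(1000, 1.0, seed=1)
            spec = cd.PerturbationSpec(pda_up=0.50, pda_down=0.25,
                                       fc_dist="uniform", fc_params=(3, 7))
            pair = cd.apply_perturbation(profile, spec, seed=50 + s)
            cm = filter_low_counts(
                cd.simulate(pair, SimConfig(NR=3, ND=500, SM="full", SV=0.5, seed=500 + s)))
            oracle = condition_factor_ratio(cd.oracle_nonda_normalize(cm), cm.condition)
            for m in dist:
                r = condition_factor_ratio(cd.get_factors(cm, m), cm.condition)
                dist[m].append(abs(r / oracle - 1))
                if m == "mode":
                    ratios.append(r / oracle)
        assert np.mean(dist["mode"]) < np.mean(dist["totalcount"])
        assert np.mean(dist["mode"]) < np.mean(dist["upperquartile"])
        assert abs(np.mean(ratios) - 1) < 0.10


class TestBaselines:
    def test_totalcount_example(self, cm_factory):
        counts = np.zeros((2, 2), dtype=int)
        counts[:, 0] = [400_000, 600_000]
        counts[:, 1] = [800_000, 1_200_000]
        nf = cd.totalcount_normalize(cm_factory(counts))
        np.testing.assert_allclose(nf.factors, [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-9)

    def test_totalcount_equal_sums(self, cm_factory):
        nf = cd.totalcount_normalize(cm_factory(np.array([[5, 5], [5, 5]])))
        np.testing.assert_allclose(nf.factors, 1.0)

    def test_totalcount_normalized_sums_equal(self, cm_factory):
        rng = np.random.default_rng(4)
        cm = cm_factory(rng.poisson(100, size=(50, 4)))
        nf = cd.totalcount_normalize(cm)
        sums = (cm.counts / nf.factors).sum(axis=0)
        np.testing.assert_allclose(sums, sums[0], rtol=1e-9)

    def test_upperquartile_scales_linearly(self, cm_factory):
        rng = np.random.default_rng(5)
        col = rng.poisson(80, size=200)
        cm = cm_factory(np.column_stack([col, 3 * col]), condition=[1, 2])
        nf = cd.upperquartile_normalize(cm)
        assert nf.factors[1] / nf.factors[0] == pytest.approx(3.0, rel=1e-9)

    def test_upperquartile_ignores_zeros(self, cm_factory):
        # adding zero rows must not move the nonzero-count percentile
        base = np.array([[10], [20], [30], [40]])
        with_zeros = np.vstack([base, np.zeros((20, 1), dtype=int)])
        f1 = cd.upperquartile_normalize(cm_factory(np.column_stack([base[:, 0]] * 2),
                                                   condition=[1, 2]))
        f2 = cd.upperquartile_normalize(cm_factory(np.column_stack([with_zeros[:, 0]] * 2),
                                                   condition=[1, 2]))
        np.testing.assert_allclose(f1.factors, f2.factors)

    def test_upperquartile_all_zero_sample_errors(self, cm_factory):
        with pytest.raises(ValueError):
            cd.upperquartile_normalize(cm_factory(np.array([[0, 5], [0, 5]]),
                                                  condition=[1, 2]))

    def test_medianratio_doubled_sample(self, cm_factory):
        rng = np.random.default_rng(6)
        col = rng.poisson(100, size=100) + 1
        cm = cm_factory(np.column_stack([col, 2 * col]), condition=[1, 2])
        nf = cd.medianratio_normalize(cm)
        np.testing.assert_allclose(nf.factors, [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-9)

    def test_medianratio_scale_equivariance(self, cm_factory):
        rng = np.random.default_rng(7)
        counts = rng.poisson(100, size=(100, 3)) + 1
        cm = cm_factory(counts, condition=[1, 1, 2])
        base = cd.medianratio_normalize(cm)
        scaled_counts = counts.copy()
        scaled_counts[:, 2] *= 5
        scaled = cd.medianratio_normalize(cm_factory(scaled_counts, condition=[1, 1, 2]))
        # before geomean-1 rescaling the third factor gains exactly 5x; after
        # rescaling the *ratios* to the other samples gain 5x
        np.testing.assert_allclose(
            scaled.factors[2] / scaled.factors[0],
            5 * base.factors[2] / base.factors[0], rtol=1e-9)

    def test_oracle_requires_truth(self, cm_factory):
        with pytest.raises(ValueError):
            cd.oracle_nonda_normalize(cm_factory(np.ones((5, 4), dtype=int)))

    def test_oracle_all_null_equals_totalcount(self, null_pair_small):
        cm = cd.simulate(null_pair_small, SimConfig(NR=2, ND=100, SM="nb", SV=0.2, seed=8))
        np.testing.assert_allclose(cd.oracle_nonda_normalize(cm).factors,
                                   cd.totalcount_normalize(cm).factors, rtol=1e-12)

    def test_oracle_differs_under_down_perturbation(self):
        profile = cd.make_powerlaw_profile(500, 1.0, seed=9)
        spec = cd.PerturbationSpec(pda_up=0.0, pda_down=0.4, fc_dist="uniform",
                                   fc_params=(4, 6))
        pair = cd.apply_perturbation(profile, spec, seed=10)
        cm = cd.simulate(pair, SimConfig(NR=3, ND=300, SM="nb", SV=0.2, seed=11))
        assert not np.allclose(cd.oracle_nonda_normalize(cm).factors,
                               cd.totalcount_normalize(cm).factors, rtol=0.01)


class TestFactorInvariants:
    @pytest.mark.parametrize("method", ["mode", "totalcount", "upperquartile",
                                        "medianratio"])
    def test_geometric_mean_one(self, method, null_pair_small):
        cm = cd.simulate(null_pair_small, SimConfig(NR=3, ND=300, SM="nb", SV=0.3, seed=12))
        nf = cd.get_factors(cm, method)
        assert geomean(nf.factors) == pytest.approx(1.0, abs=1e-9)
        assert (nf.factors > 0).all()

    def test_entity_order_invariance(self, null_pair_small):
        cm = cd.simulate(null_pair_small, SimConfig(NR=3, ND=300, SM="nb", SV=0.3, seed=13))
        perm = np.random.default_rng(0).permutation(cm.n_entities)
        shuffled = cm.subset_entities(perm)
        for method in ("mode", "totalcount", "upperquartile", "medianratio"):
            np.testing.assert_allclose(cd.get_factors(cm, method).factors,
                                       cd.get_factors(shuffled, method).factors,
                                       rtol=1e-9)

    def test_unknown_method(self, cm_factory):
        with pytest.raises(ValueError, match="unknown normalization"):
            cd.get_factors(cm_factory(np.ones((25, 4), dtype=int)), "bogus")
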