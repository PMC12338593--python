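import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import cdist

from neuroparti.enrichment import (bin_by_distance, enrich_all, fdr_bh,
                                   leave_one_out, rank_biserial)
from neuroparti.enrichment import test_boolean as boolean_bin_test
from neuroparti.enrichment import test_continuous as continuous_bin_test
from neuroparti.polytope_fit import distances_to_archetypes
from neuroparti.synthetic_data import plant_feature, sample_population


class TestBinning:
    @pytest.mark.parametrize("n,n_bins,expected", [
        (10, 5, [2, 2, 2, 2, 2]),
        (11, 5, [3, 2, 2, 2, 2]),
        (23, 10, [3, 3, 3, 2, 2, 2, 2, 2, 2, 2]),
    ])
    def test_sizes_remainder_to_closest_bins(self, n, n_bins, expected):
        bins = bin_by_distance(np.arange(n, dtype=float), n_bins)
        assert bins.sizes.tolist() == expected

    def test_zero_distance_subject_in_first_bin(self):
        d = np.array([3.0, 1.0, 0.0, 2.0, 5.0, 4.0])
        bins = bin_by_distance(d, 3)
        assert bins.labels[2] == 1

    def test_ties_broken_by_input_order(self):
        d = np.array([1.0, 1.0, 1.0, 1.0])
        bins = bin_by_distance(d, 2)
        assert bins.labels.tolist() == [1, 1, 2, 2]

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            bin_by_distance(np.arange(3, dtype=float), 4)


class TestContinuous:
    def make_bins(self, n1, n2):
        return bin_by_distance(np.arange(n1 + n2, dtype=float), 2 if n1 == n2
                               else max(2, (n1 + n2) // n1))

    def test_complete_separation(self):
        # closest bin strictly above the rest
        d = np.arange(6, dtype=float)
        bins = bin_by_distance(d, 2)
        f = np.array([10.0, 11, 12, 1, 2, 3])
        U, z, p_max, p_min = continuous_bin_test(f, bins)
        n1 = bins.sizes[0]
        n2 = len(f) - n1
        assert rank_biserial(n1 * n2 - U, n1, n2) == pytest.approx(1.0)
        assert p_max < p_min

    def test_constant_feature_is_null(self):
        bins = bin_by_distance(np.arange(10, dtype=float), 2)
        U, z, p_max, p_min = continuous_bin_test(np.ones(10), bins)
        assert z == 0.0 and p_max == 1.0 and p_min == 1.0

    def test_null_p_values_approximately_uniform(self):
        # identical distributions: one-sided p should be uniform
        rng = np.random.default_rng(0)
        n = 1000
        bins = bin_by_distance(np.arange(n, dtype=float), 10)
        ps = np.array([continuous_bin_test(rng.normal(size=n), bins)[2]
                       for _ in range(2000)])
        ks = stats.kstest(ps, "uniform").statistic
        assert ks < 0.05

    def test_small_sample_matches_exact_enumeration(self):
        rng = np.random.default_rng(1)
        d = np.arange(9, dtype=float)
        bins = bin_by_distance(d, 3)  # first bin size 3... need n1=4
        # construct a 4/5 split explicitly: 9 subjects, 2 bins -> sizes [5, 4]
        bins = bin_by_distance(d, 2)
        f = rng.normal(size=9)
        U_obs, _, p_max, _ = continuous_bin_test(f, bins)
        n1 = int(bins.sizes[0])
        mask = bins.bin_mask(1)
        pooled = f.copy()
        # exact null: all assignments of which 5 values form bin 1
        count = 0
        total = 0
        for combo in itertools.combinations(range(9), n1):
            x = pooled[list(combo)]
            y = np.delete(pooled, list(combo))
            ranks = stats.rankdata(np.concatenate([x, y]))
            U = ranks[:n1].sum() - n1 * (n1 + 1) / 2
            total += 1
            if U >= U_obs:
                count += 1
        p_exact = count / total
        assert abs(p_max - p_exact) < 0.05

    def test_normal_approximation_close_for_moderate_samples(self):
        rng = np.random.default_rng(2)
        n = 45
        bins = bin_by_distance(np.arange(n, dtype=float), 2)  # 23 vs 22
        f = rng.normal(size=n)
        U_obs, _, p_max, _ = continuous_bin_test(f, bins)
        res = stats.mannwhitneyu(f[bins.bin_mask(1)], f[~bins.bin_mask(1)],
                                 alternative="greater", method="exact")
        assert abs(p_max - res.pvalue) < 0.01


class TestRankBiserial:
    def test_midpoint_is_zero(self):
        assert rank_biserial(6.0, 3, 4) == 0.0

    def test_zero_u_is_one(self):
        assert rank_biserial(0, 5, 5) == 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            rank_biserial(26, 5, 5)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_pairwise_counting(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 6, size=8).astype(float)  # ties likely
        y = rng.integers(0, 6, size=11).astype(float)
        favorable = sum((xi > yj) for xi in x for yj in y)
        unfavorable = sum((xi < yj) for xi in x for yj in y)
        r_pairs = (favorable - unfavorable) / (len(x) * len(y))
        ranks = stats.rankdata(np.concatenate([x, y]))
        U1 = ranks[:len(x)].sum() - len(x) * (len(x) + 1) / 2
        r = rank_biserial(len(x) * len(y) - U1, len(x), len(y))
        assert r == pytest.approx(r_pairs)


class TestBoolean:
    def test_complete_concentration_closed_form(self):
        from math import comb

        d = np.arange(20, dtype=float)
        bins = bin_by_distance(d, 4)  # first bin = 5 closest
        flags = np.zeros(20)
        flags[:5] = 1  # all successes in bin 1
        overlap, p_max, p_min = boolean_bin_test(flags, bins)
        assert overlap == 5
        assert p_max == pytest.approx(1 / comb(20, 5))

    def test_uniform_success_never_significant(self):
        rng = np.random.default_rng(3)
        d = np.arange(2000, dtype=float)
        bins = bin_by_distance(d, 10)
        flags = rng.random(2000) < 0.3
        _, p_max, p_min = boolean_bin_test(flags.astype(float), bins)
        assert min(p_max, p_min) > 0.001

    def test_degenerate_flags_give_p_one(self):
        bins = bin_by_distance(np.arange(10, dtype=float), 2)
        assert boolean_bin_test(np.ones(10), bins)[1:] == (1.0, 1.0)
        assert boolean_bin_test(np.zeros(10), bins)[1:] == (1.0, 1.0)

    def test_matches_hypergeometric_summation(self):
        from math import comb

        d = np.arange(12, dtype=float)
        bins = bin_by_distance(d, 3)  # bin 1 size 4
        flags = np.array([1, 1, 0, 1, 0, 0, 1, 0, 1, 0, 0, 0], dtype=float)
        x, p_max, _ = boolean_bin_test(flags, bins)
        N, K, n1 = 12, 5, 4
        p_manual = sum(comb(K, i) * comb(N - K, n1 - i) for i in
                       range(x, min(K, n1) + 1)) / comb(N, n1)
        assert p_max == pytest.approx(p_manual, abs=1e-12)


class TestFDR:
    def test_single_small_p_significant(self):
        q, flags = fdr_bh(np.array([0.04]), 0.1)
        assert flags[0] and q[0] == pytest.approx(0.04)

    def test_equal_p_values_unchanged(self):
        q, _ = fdr_bh(np.array([0.2, 0.2, 0.2]))
        np.testing.assert_allclose(q, 0.2)

    def test_hand_computed_step_up(self):
        q, _ = fdr_bh(np.array([0.01, 0.02, 0.03, 0.5]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.5])


class TestEnrichAll:
    @pytest.fixture(scope="class")
    def planted(self):
        table, truth = sample_population(3, 19, 900, dirichlet_alpha=1.0,
                                         noise_sd=0.0, seed=50)
        dist = cdist(table.values, truth.vertices)
        features = pd.DataFrame({
            "planted": plant_feature(table.values, truth, 1, "max",
                                     effect_size=1.0, noise_sd=0.3, seed=51),
            "noise_a": np.random.default_rng(52).normal(size=900),
            "noise_b": np.random.default_rng(53).normal(size=900),
        }, index=table.subject_ids)
        return features, dist

    def test_planted_feature_found_at_its_archetype_only(self, planted):
        features, dist = planted
        result = enrich_all(features, dist)
        sig = result[result["significant"]]
        hits = sig[(sig["feature"] == "planted") & (sig["direction"] == "max")]
        assert hits["archetype"].tolist() == [1]

    def test_no_feature_both_max_and_min_significant(self, planted):
        features, dist = planted
        result = enrich_all(features, dist)
        sig = result[result["significant"]]
        dup = sig.groupby(["feature", "archetype"])["direction"].nunique()
        assert (dup <= 1).all()

    def test_missing_values_rejected(self, planted):
        features, dist = planted
        bad = features.copy()
        bad.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="impute"):
            enrich_all(bad, dist)

    def test_adjusted_confounds_rarely_enriched(self):
        # after residualization a confound is linearly orthogonal to every
        # component; chance distance associations should stay at the
        # false-positive level rather than being systematic
        from neuroparti.compositions import ConfoundTable, adjust_confounds
        from neuroparti.polytope_fit import fit_archetypes

        flagged = total = 0
        for rep in range(10):
            table, _ = sample_population(3, 10, 1000, dirichlet_alpha=1.0,
                                         noise_sd=0.01, seed=54 + rep)
            rng = np.random.default_rng(154 + rep)
            conf = ConfoundTable(list(table.subject_ids), ["mFD"],
                                 rng.normal(size=(1000, 1)))
            adjusted = adjust_confounds(table, conf)
            _, _, sol = fit_archetypes(adjusted.values, 3, seed=254 + rep)
            dist = distances_to_archetypes(adjusted.values, sol.vertices_full)
            features = pd.DataFrame({"confound_mFD": conf.values[:, 0]},
                                    index=table.subject_ids)
            result = enrich_all(features, dist)
            flagged += int(result["significant"].sum())
            total += len(result)
        assert flagged / total <= 0.15


class TestLeaveOneOut:
    def test_one_iteration_per_component(self):
        table, truth = sample_population(3, 8, 400, noise_sd=0.0, seed=60)
        features = pd.DataFrame(
            {"f": np.random.default_rng(61).normal(size=400)},
            index=table.subject_ids)
        per, summary = leave_one_out(table.values, features, 3, seed=62)
        assert len(per) + len(summary.attrs["failed_iterations"]) == 8

    def test_geometry_wide_feature_is_robust(self):
        table, truth = sample_population(3, 19, 900, dirichlet_alpha=1.0,
                                         noise_sd=0.0, seed=63)
        f = plant_feature(table.values, truth, 0, "max", effect_size=1.0,
                          noise_sd=0.1, seed=64)
        features = pd.DataFrame({"planted": f}, index=table.subject_ids)
        _, summary = leave_one_out(table.values, features, 3, seed=65)
        row = summary[(summary["feature"] == "planted") &
                      (summary["direction"] == "max") &
                      summary["reference_significant"]]
        assert len(row) == 1 and bool(row["robust"].iloc[0])

    def test_single_component_feature_not_robust(self):
        # the simplex geometry lives in columns 0-1; a feature equal to
        # column 0 loses its enrichment when that column is dropped
        rng = np.random.default_rng(66)
        n = 600
        V2 = np.array([[0.0, 0], [2, 0], [1, 1.8]])
        W = rng.dirichlet(np.ones(3), n)
        X = np.column_stack([W @ V2, rng.normal(scale=0.15, size=(n, 2))])
        features = pd.DataFrame({"col0": X[:, 0]}, index=range(n))
        _, summary = leave_one_out(X, features, 3, seed=67,
                                   component_ids=["c0", "c1", "c2", "c3"])
        assert summary["reference_significant"].any()
        assert not summary["robust"].any()

    def test_system_mode_drops_groups(self):
        table, _ = sample_population(3, 6, 300, noise_sd=0.0, seed=68)
        features = pd.DataFrame(
            {"f": np.random.default_rng(69).normal(size=300)},
            index=table.subject_ids)
        ids = [f"IC{j + 1:02d}" for j in range(6)]
        systems = {"sysA": ids[:3], "sysB": ids[3:]}
        per, _ = leave_one_out(table.values, features, 3, seed=70,
                               component_ids=ids, systems=systems,
                               mode="systems")
        assert set(per) <= {"sysA", "sysB"}


class TestEffectMonotonicity:
    def test_detection_rate_nondecreasing_in_effect_size(self):
        rates = []
        for effect in (0.0, 0.8, 2.5):
            hits = 0
            for rep in range(8):
                table, truth = sample_population(
                    3, 10, 400, dirichlet_alpha=1.0, noise_sd=0.0,
                    seed=100 + rep)
                f = plant_feature(table.values, truth, 0, "max",
                                  effect_size=effect, noise_sd=0.5,
                                  seed=200 + rep)
                dist = cdist(table.values, truth.vertices)
                features = pd.DataFrame({"f": f}, index=table.subject_ids)
                result = enrich_all(features, dist)
                hit = result[(result["archetype"] == 0) &
                             (result["direction"] == "max") &
                             result["significant"]]
                hits += int(len(hit) > 0)
            rates.append(hits / 8)
        assert rates == sorted(rates)
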