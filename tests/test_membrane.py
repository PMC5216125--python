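"""Distance distributions, band fractions and gold-vs-random tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mitogold.membrane import (
    DistanceSample,
    LocalizationComparison,
    band_fraction,
    bin_distances,
    chi_squared_binned,
    compare_to_null,
    cumulative_fraction,
    ks_two_sample,
    label_to_random_ratio,
    mann_whitney,
    measure_distances,
)
from mitogold.synthetic import (
    GoldPlacementLaw,
    generate_gold,
    matched_random_points,
    sample_random_points,
)


def _sample(values, label="A", kind="gold"):
    return DistanceSample(label=label, kind=kind, distances=np.asarray(values, float))


class TestMeasureDistances:
    def test_gold_at_circle_center(self, circle_profile):
        pts = pd.DataFrame(
            dict(
                point_id=["g0"], field_id=["F0"], profile_id=["c0"],
                label=["A"], kind=["gold"], x_nm=[0.0], y_nm=[0.0],
                diameter_nm=[10.0],
            )
        )
        out = measure_distances(pts, [circle_profile])
        assert out["distance_nm"].iloc[0] == pytest.approx(50.0)

    def test_random_point_distances_match_analytic_disc_law(self, circle_profile):
        """Uniform over a disc of radius R_out: the signed distance to the
        inner circle of radius R_in has CDF derivable from the radial law."""
        pts = sample_random_points(circle_profile, 10_000, seed=31)
        out = measure_distances(pts, [circle_profile])
        d = out["distance_nm"].to_numpy()
        R_out, R_in = 65.0, 50.0
        # d = R_in - r with r ~ sqrt-uniform on [0, R_out]
        cdf = lambda x: np.clip(1.0 - ((R_in - x) / R_out) ** 2, 0.0, 1.0)
        p = stats.ks_1samp(d, cdf).pvalue
        assert p > 0.01

    def test_unassigned_point_rejected(self, circle_profile):
        pts = pd.DataFrame(
            dict(
                point_id=["g0"], field_id=["F0"], profile_id=[""],
                label=["A"], kind=["gold"], x_nm=[0.0], y_nm=[0.0],
                diameter_nm=[10.0],
            )
        )
        with pytest.raises(ValueError, match="assignment"):
            measure_distances(pts, [circle_profile])


class TestBandFraction:
    def test_simple_count(self):
        bs = band_fraction(_sample([5.0, 10.0, 30.0]), 20.0)
        assert bs.fraction_inside == pytest.approx(2.0 / 3.0)
        assert bs.fraction_inside + bs.fraction_outside == pytest.approx(1.0)

    def test_all_negative_distances_outside(self):
        bs = band_fraction(_sample([-5.0, -1.0]), 20.0)
        assert bs.fraction_inside == 0.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            band_fraction(_sample([]), 20.0)

    def test_uniform_matrix_circle_expectation(self, circle_profile):
        """Uniform in a 50-nm inner disc: E[band_20] = 1-(30/50)^2 = 0.64."""
        law = GoldPlacementLaw(law="matrix_uniform", counts_per_label={"A": 10_000})
        gold = generate_gold([circle_profile], law, seed=41)
        d = measure_distances(gold, [circle_profile])["distance_nm"].to_numpy()
        bs = band_fraction(_sample(d), 20.0)
        se = math.sqrt(0.64 * 0.36 / 10_000)
        assert abs(bs.fraction_inside - 0.64) < 3 * se


class TestBinning:
    def test_counts_in_stated_bins(self):
        bd = bin_distances(_sample([-5.0, 5.0, 15.0]), [-10, 0, 10, 20])
        assert list(bd.counts) == [1, 1, 1]
        assert bd.underflow == 0 and bd.overflow == 0

    def test_internal_edge_goes_to_upper_bin(self):
        bd = bin_distances(_sample([0.0]), [-10, 0, 10])
        assert list(bd.counts) == [0, 1]

    def test_frequencies_sum_to_one_with_flagged_overflow(self):
        bd = bin_distances(_sample([-50.0, 5.0, 90.0]), [-10, 0, 10, 20])
        assert bd.underflow == 1 and bd.overflow == 1
        assert bd.all_counts.sum() == 3
        assert bd.frequencies.sum() + (bd.underflow + bd.overflow) / bd.n == pytest.approx(1.0)

    def test_unsorted_edges_rejected(self):
        with pytest.raises(ValueError):
            bin_distances(_sample([1.0]), [0, 10, 5])


class TestRatios:
    def test_per_bin_ratio(self):
        g = bin_distances(_sample(np.arange(0.5, 20.0, 1.0)), [0, 10, 20])  # 10 + 10
        r = bin_distances(_sample([1] * 5 + [11] * 15), [0, 10, 20])
        ratios, defined = label_to_random_ratio(g, r)
        assert ratios[0] == pytest.approx(10 / 5)
        assert ratios[1] == pytest.approx(10 / 15)
        assert defined.all()

    def test_equal_distributions_unit_ratio(self):
        g = bin_distances(_sample([1, 11]), [0, 10, 20])
        ratios, _ = label_to_random_ratio(g, g)
        assert np.allclose(ratios, 1.0)

    def test_zero_random_bin_flagged_not_infinite(self):
        g = bin_distances(_sample([1, 11]), [0, 10, 20])
        r = bin_distances(_sample([1, 2]), [0, 10, 20])
        ratios, defined = label_to_random_ratio(g, r)
        assert not defined[1]
        assert np.isnan(ratios[1])

    def test_mismatched_edges_rejected(self):
        g = bin_distances(_sample([1]), [0, 10])
        r = bin_distances(_sample([1]), [0, 20])
        with pytest.raises(ValueError):
            label_to_random_ratio(g, r)


class TestCumulativeFraction:
    def test_ecdf_reaches_one(self):
        x, f = cumulative_fraction(_sample([3.0, 1.0, 2.0]))
        assert f[-1] == 1.0
        assert np.all(np.diff(x) >= 0)

    def test_pooled_size_is_sum_of_labels(self):
        samples = [
            _sample(np.arange(n), label=l)
            for l, n in [("ThIsu1", 79), ("ThNfs1", 66), ("ThYah1", 37), ("ThYfh1", 63), ("ThIsd11", 50)]
        ]
        x, f = cumulative_fraction(samples, pool=True)
        assert len(x) == 295

    def test_single_value_steps_to_one(self):
        x, f = cumulative_fraction(_sample([4.2]))
        assert list(f) == [1.0]


def _enumerate_ks_p(a, b):
    """Full enumeration of all C(n+m, n) label assignments."""
    pooled = np.sort(np.concatenate([a, b]))
    n = len(a)
    d_obs = stats.ks_2samp(a, b).statistic
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n):
        aa = pooled[list(idx)]
        bb = np.delete(pooled, list(idx))
        total += 1
        if stats.ks_2samp(aa, bb, method="asymp").statistic >= d_obs - 1e-12:
            hits += 1
    return hits / total


def _enumerate_mw_p(a, b):
    pooled = np.sort(np.concatenate([a, b]))
    n = len(a)
    u_obs = stats.mannwhitneyu(a, b).statistic
    n_b = len(b)
    mid = n * n_b / 2.0
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n):
        aa = pooled[list(idx)]
        bb = np.delete(pooled, list(idx))
        total += 1
        u = stats.mannwhitneyu(aa, bb, method="asymptotic").statistic
        if abs(u - mid) >= abs(u_obs - mid) - 1e-12:
            hits += 1
    return hits / total


class TestKolmogorovSmirnov:
    def test_identical_samples_zero_statistic(self):
        d, p = ks_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0.0

    def test_fully_separated_small_samples_exact_p(self):
        """D = 1 for disjoint supports; p = 2/C(6,3) = 0.1 by enumeration."""
        d, p = ks_two_sample([1, 2, 3], [4, 5, 6])
        assert d == 1.0
        assert p == pytest.approx(0.1)

    def test_exact_branch_matches_enumeration(self, rng):
        for n_a in range(1, 5):
            for n_b in range(n_a, 6):
                a = rng.standard_normal(n_a)
                b = rng.standard_normal(n_b)
                _, p = ks_two_sample(a, b)
                assert p == pytest.approx(_enumerate_ks_p(a, b), abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])


class TestMannWhitney:
    def test_small_sample_exact_p(self):
        """[1,2] vs [3,4]: U = 0, two-sided p = 2/C(4,2) = 1/3."""
        u, p = mann_whitney([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(1.0 / 3.0)

    def test_identical_samples_midrank_u(self):
        a = [2.0, 2.0, 2.0]
        u, p = mann_whitney(a, a)
        assert u == pytest.approx(len(a) ** 2 / 2.0)

    def test_exact_branch_matches_enumeration(self, rng):
        for n_a in range(1, 5):
            for n_b in range(n_a, 6):
                a = rng.standard_normal(n_a)
                b = rng.standard_normal(n_b)
                _, p = mann_whitney(a, b)
                assert p == pytest.approx(_enumerate_mw_p(a, b), abs=1e-12)


class TestChiSquared:
    def test_hand_computed_statistic(self):
        """Observed [10, 0] vs expected [5, 5]: chi2 = 25/5 + 25/5 = 10."""
        g = bin_distances(_sample([1.0] * 10), [0, 10, 20])
        r = bin_distances(_sample([1.0] * 5 + [11.0] * 5), [0, 10, 20])
        chi2, df, p = chi_squared_binned(g, r)
        assert chi2 == pytest.approx(10.0)
        assert df == 1
        assert p == pytest.approx(stats.chi2.sf(10.0, 1))

    def test_equal_distributions_zero_statistic(self):
        g = bin_distances(_sample([1.0] * 6 + [11.0] * 6), [0, 10, 20])
        chi2, df, _ = chi_squared_binned(g, g)
        assert chi2 == pytest.approx(0.0)

    def test_merging_leaves_expected_at_least_five(self, circle_profile):
        law = GoldPlacementLaw(law="profile_uniform", counts_per_label={"A": 60})
        gold = generate_gold([circle_profile], law, seed=3)
        rand = matched_random_points(gold, [circle_profile], seed=4)
        gd = measure_distances(gold, [circle_profile])["distance_nm"].to_numpy()
        rd = measure_distances(rand, [circle_profile])["distance_nm"].to_numpy()
        from mitogold.membrane import _merge_small_expected

        g = bin_distances(_sample(gd))
        r = bin_distances(_sample(rd))
        expected = r.all_counts / r.all_counts.sum() * g.all_counts.sum()
        keep = (g.all_counts > 0) | (expected > 0)
        _, exp = _merge_small_expected(g.all_counts[keep].astype(float), expected[keep])
        assert np.all(exp >= 5.0)

    def test_homogeneity_variant_runs(self):
        g = bin_distances(_sample([1.0] * 30 + [11.0] * 10), [0, 10, 20])
        r = bin_distances(_sample([1.0] * 20 + [11.0] * 20), [0, 10, 20])
        chi2, df, p = chi_squared_binned(g, r, homogeneity=True)
        assert chi2 > 0 and 0 <= p <= 1


class TestCompareToNull:
    def test_identical_samples_null_result(self):
        d = _sample(np.linspace(-5, 45, 60))
        r = _sample(np.linspace(-5, 45, 60), kind="random")
        tests, bg, br = compare_to_null(d, r)
        assert tests.ks_statistic == 0.0
        assert tests.chi2_statistic == pytest.approx(0.0)
        assert bg.fraction_inside == br.fraction_inside

    def test_mismatched_sizes_rejected(self):
        with pytest.raises(ValueError, match="equal sizes"):
            compare_to_null(_sample([1.0, 2.0]), _sample([1.0]))

    def test_matrix_uniform_beats_profile_uniform_band(self, circle_profile):
        """Matrix-uniform gold concentrates in the band relative to
        whole-profile random points (the inset annulus dilutes the null)."""
        gold = generate_gold(
            [circle_profile],
            GoldPlacementLaw(law="matrix_uniform", counts_per_label={"A": 2000}),
            seed=5,
        )
        rand = matched_random_points(gold, [circle_profile], seed=6)
        gd = measure_distances(gold, [circle_profile])["distance_nm"].to_numpy()
        rd = measure_distances(rand, [circle_profile])["distance_nm"].to_numpy()
        assert band_fraction(_sample(gd)).fraction_inside > band_fraction(_sample(rd)).fraction_inside


class TestLocalizationModel:
    def test_fit_produces_per_label_and_pooled_rows(self, circle_profile, ellipse_profile):
        profiles = [circle_profile, ellipse_profile]
        law = GoldPlacementLaw(
            law="membrane_proximal", scale_nm=10.0,
            counts_per_label={"ThIsu1": 79, "ThYah1": 37},
        )
        gold = generate_gold(profiles, law, seed=8)
        rand = matched_random_points(gold, profiles, seed=9)
        model = LocalizationComparison.from_points(gold, rand, profiles)
        res = model.fit()
        summary = res.summary()
        assert set(summary["label"]) == {"ThIsu1", "ThYah1", "pooled"}
        assert summary.loc[summary["label"] == "ThIsu1", "n"].iloc[0] == 79
        report = res.to_dict()
        assert report["pooled"]["n"] == 116
        assert 0 <= report["pooled"]["tests"]["ks"]["p"] <= 1

    def test_bonferroni_inflates_per_label_p(self, circle_profile):
        law = GoldPlacementLaw(
            law="membrane_proximal", counts_per_label={"A": 40, "B": 40}
        )
        gold = generate_gold([circle_profile], law, seed=10)
        rand = matched_random_points(gold, [circle_profile], seed=11)
        raw = LocalizationComparison.from_points(gold, rand, [circle_profile]).fit()
        adj = LocalizationComparison.from_points(
            gold, rand, [circle_profile], bonferroni=True
        ).fit()
        p_raw = raw.summary().set_index("label").loc["A", "ks_p"]
        p_adj = adj.summary().set_index("label").loc["A", "ks_p"]
        assert p_adj == pytest.approx(min(1.0, 2 * p_raw))


class TestBandRecovery:
    def test_band_fraction_recovers_generator_truth(self, circle_profile):
        """Mixture placement with known band probability f*: the estimated
        inside fraction falls within 3 binomial s.e. of f* across seeds."""
        R, band = 50.0, 20.0
        f_star = 0.8
        n = 400
        for seed in range(5):
            rng = np.random.default_rng(seed)
            in_band = rng.uniform(size=n) < f_star
            # band points area-uniform within [R-band, R], off-band points
            # area-uniform within [0, R-band]
            u = rng.uniform(size=n)
            r_band = np.sqrt((R - band) ** 2 + u * (R**2 - (R - band) ** 2))
            r_off = np.sqrt(u) * (R - band)
            r = np.where(in_band, r_band, r_off)
            th = rng.uniform(0, 2 * math.pi, size=n)
            d = measure_distances(
                pd.DataFrame(
                    dict(
                        point_id=[f"g{i}" for i in range(n)],
                        field_id="F0", profile_id="c0", label="A", kind="gold",
                        x_nm=r * np.cos(th), y_nm=r * np.sin(th), diameter_nm=10.0,
                    )
                ),
                [circle_profile],
            )["distance_nm"].to_numpy()
            est = band_fraction(_sample(d), band).fraction_inside
            se = math.sqrt(f_star * (1 - f_star) / n)
            assert abs(est - f_star) < 3 * se
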