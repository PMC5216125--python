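"""Synthetic field, gold-placement and random-point generators."""

import numpy as np
import pytest
from scipy import stats

from mitogold.geometry import signed_distances
from mitogold.synthetic import (
    DEFAULT_GOLD_COUNTS,
    FieldConfig,
    GoldPlacementLaw,
    generate_field,
    generate_fields,
    generate_gold,
    matched_random_points,
    sample_fields_sur,
    sample_random_points,
)


class TestGenerateField:
    def test_seeded_runs_are_identical(self):
        cfg = FieldConfig(n_fields=2, profiles_per_field=5, rng_seed=1)
        p1, _ = generate_fields(cfg)
        p2, _ = generate_fields(cfg)
        assert [(p.center.x, p.center.y, p.semi_major_outer) for p in p1] == [
            (p.center.x, p.center.y, p.semi_major_outer) for p in p2
        ]

    def test_axes_within_published_ranges_and_near_means(self):
        """10^4 profiles: every minor diameter in [47, 119] nm, every major
        in [78, 267] nm, with means close to 80 / 127 nm."""
        cfg = FieldConfig(n_fields=1, profiles_per_field=0, rng_seed=3)
        from mitogold.synthetic import _sample_axes

        rng = np.random.default_rng(3)
        semi_minor, semi_major = _sample_axes(cfg, 10_000, rng)
        minor_d, major_d = 2 * semi_minor, 2 * semi_major
        assert minor_d.min() >= 47.0 and minor_d.max() <= 119.0
        assert major_d.min() >= 78.0 and major_d.max() <= 267.0
        assert np.all(semi_major >= semi_minor)
        # redrawing the major axis where major < minor skews its mean
        # slightly upward from 127; allow a few nm on both
        assert abs(minor_d.mean() - 80.0) < 3.0
        assert abs(major_d.mean() - 127.0) < 6.0

    def test_zero_profiles_gives_valid_compartments(self):
        profiles, comps = generate_field(FieldConfig(profiles_per_field=0, rng_seed=0))
        assert profiles == []
        assert comps["cytoplasm"].area > 0
        assert comps["nucleus"].area > 0

    def test_profiles_do_not_overlap(self):
        profiles, _ = generate_field(FieldConfig(profiles_per_field=10, rng_seed=7))
        for i, p in enumerate(profiles):
            for q in profiles[i + 1 :]:
                dist = np.hypot(p.center.x - q.center.x, p.center.y - q.center.y)
                assert dist >= p.semi_major_outer + q.semi_major_outer

    def test_infeasible_layout_raises(self):
        with pytest.raises(RuntimeError, match="infeasible"):
            generate_field(
                FieldConfig(profiles_per_field=500, cell_radius=400.0, rng_seed=0)
            )


class TestGenerateGold:
    def test_counts_honoured_exactly(self, circle_profile):
        law = GoldPlacementLaw(counts_per_label={"A": 5, "B": 3})
        gold = generate_gold([circle_profile], law, seed=0)
        assert (gold["label"] == "A").sum() == 5
        assert (gold["label"] == "B").sum() == 3

    def test_default_counts_match_published_per_protein_numbers(self, circle_profile):
        gold = generate_gold([circle_profile], GoldPlacementLaw(), seed=0)
        for label, n in DEFAULT_GOLD_COUNTS.items():
            assert (gold["label"] == label).sum() == n
        assert len(gold) == 295

    def test_matrix_uniform_band_fraction_matches_disc_geometry(self, circle_profile):
        """Uniform points in a 50-nm inner disc: P(d <= 20) = 1-(30/50)^2 = 0.64."""
        law = GoldPlacementLaw(law="matrix_uniform", counts_per_label={"A": 1000})
        gold = generate_gold([circle_profile], law, seed=11)
        d = signed_distances(gold["x_nm"], gold["y_nm"], circle_profile)
        assert np.all(d >= -1e-9)  # matrix placement never leaves the matrix
        frac = np.mean(d <= 20.0)
        se = np.sqrt(0.64 * 0.36 / 1000)
        assert abs(frac - 0.64) < 3 * se

    def test_membrane_proximal_distances_follow_truncated_exponential(self, circle_profile):
        """KS agreement with the analytic law: density of the signed
        distance d under exp(-d/lam) thinning of a uniform disc is
        proportional to (R-d) * exp(-d/lam) on [0, R]."""
        lam, R = 10.0, 50.0
        law = GoldPlacementLaw(
            law="membrane_proximal", scale_nm=lam, counts_per_label={"A": 10_000}
        )
        gold = generate_gold([circle_profile], law, seed=13)
        d = signed_distances(gold["x_nm"], gold["y_nm"], circle_profile)
        grid = np.linspace(0.0, R, 4001)
        pdf = (R - grid) * np.exp(-grid / lam)
        cdf = np.cumsum(pdf)
        cdf /= cdf[-1]
        p = stats.ks_1samp(d, lambda x: np.interp(x, grid, cdf)).pvalue
        assert p > 0.01

    def test_membrane_proximal_small_scale_hugs_the_membrane(self, circle_profile):
        law = GoldPlacementLaw(
            law="membrane_proximal", scale_nm=1e-3, counts_per_label={"A": 200}
        )
        gold = generate_gold([circle_profile], law, seed=5)
        d = signed_distances(gold["x_nm"], gold["y_nm"], circle_profile)
        assert np.all(d < 0.1)

    def test_requires_profiles_for_intramitosomal_laws(self):
        with pytest.raises(ValueError, match="profile"):
            generate_gold([], GoldPlacementLaw(counts_per_label={"A": 1}), seed=0)


class TestRandomPoints:
    def test_zero_points(self, circle_profile):
        assert len(sample_random_points(circle_profile, 0, seed=0)) == 0

    def test_seeded_determinism(self, circle_profile):
        p1 = sample_random_points(circle_profile, 50, seed=9)
        p2 = sample_random_points(circle_profile, 50, seed=9)
        assert np.array_equal(p1["x_nm"], p2["x_nm"])

    def test_mean_radius_matches_uniform_disc_moment(self, circle_profile):
        """Uniform over a disc of radius R: E[r] = 2R/3."""
        pts = sample_random_points(circle_profile, 100_000, seed=21)
        r = np.hypot(pts["x_nm"], pts["y_nm"])
        R = circle_profile.semi_major_outer
        se = R * np.sqrt(1.0 / 18.0) / np.sqrt(len(pts))  # sd(r) = R/sqrt(18)
        assert abs(r.mean() - 2.0 * R / 3.0) < 4 * se

    def test_matched_random_points_equal_sizes_per_label(self, circle_profile, ellipse_profile):
        profiles = [circle_profile, ellipse_profile]
        law = GoldPlacementLaw(counts_per_label={"A": 40, "B": 25})
        gold = generate_gold(profiles, law, seed=2)
        rand = matched_random_points(gold, profiles, seed=3)
        for label in ("A", "B"):
            g = gold[gold["label"] == label]
            r = rand[rand["label"] == label]
            assert len(g) == len(r)
            assert sorted(g["profile_id"].value_counts().items()) == sorted(
                r["profile_id"].value_counts().items()
            )


class TestSURSampling:
    def test_step_one_returns_all_fields(self):
        fields = list("abcdefghi")
        assert sample_fields_sur(fields, 1, seed=0) == fields

    def test_step_three_of_nine_returns_three(self):
        assert len(sample_fields_sur(list(range(9)), 3, seed=4)) == 3

    def test_empty_field_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sample_fields_sur([], 2, seed=0)

    def test_each_field_selected_with_frequency_one_over_step(self):
        """Uniform random start: selection probability 1/step per field."""
        fields = list(range(12))
        step, reps = 3, 10_000
        hits = np.zeros(len(fields))
        for s in range(reps):
            for f in sample_fields_sur(fields, step, seed=s):
                hits[f] += 1
        freq = hits / reps
        se = np.sqrt((1 / step) * (1 - 1 / step) / reps)
        assert np.all(np.abs(freq - 1.0 / step) < 4 * se)
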