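"""Pattern-set generator: calibration, structure, similarity, I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lesionlab import patterns as pg


class TestProfiles:
    @pytest.mark.parametrize("profile_id, category, expected", [
        ("P1-like", "birds", 42.250),
        ("P1-like", "household", 22.500),
        ("P2-like", "birds", 35.875),
        ("P2-like", "tools", 24.250),
    ])
    def test_closed_form_expectations_match_reference_counts(
            self, profile_id, category, expected):
        prof = pg.build_profile(profile_id)
        assert prof.expected_feature_count(category) == pytest.approx(
            expected, abs=1e-9)

    def test_all_categories_calibrated_within_half_feature(self):
        for pid in ("P1-like", "P2-like"):
            prof = pg.build_profile(pid)
            for c in pg.CATEGORIES:
                assert abs(prof.expected_feature_count(c)
                           - prof.target_means[c]) < 0.5

    def test_unknown_profile_rejected(self):
        with pytest.raises(pg.UnknownProfileError):
            pg.build_profile("P3-like")

    def test_three_categories_per_domain(self):
        prof = pg.build_profile("P1-like")
        domains = [pg.DOMAIN_OF[c] for c in prof.probabilities]
        assert domains.count("animal") == 3
        assert domains.count("artefact") == 3


class TestGeneration:
    def test_dimensions_and_binary(self, small_pattern_set):
        ps = small_pattern_set
        assert ps.vectors.shape == (48, 216)
        assert set(np.unique(ps.vectors)) <= {0, 1}
        for c in pg.CATEGORIES:
            assert ps.categories.count(c) == 8

    def test_name_block_is_localist(self, small_pattern_set):
        ps = small_pattern_set
        # exactly the designated unit is active in each item's name block
        assert (ps.name_block.sum(axis=1) == 1).all()
        assert (ps.name_block[np.arange(48), ps.name_units] == 1).all()
        # paired-localist scheme: 40 name units cover 48 items, 8 shared pairs
        assert len(set(ps.name_units.tolist())) == 40

    def test_same_seed_bit_identical(self, p2_profile):
        a = pg.generate_patterns(p2_profile, 7)
        b = pg.generate_patterns(p2_profile, 7)
        assert (a.vectors == b.vectors).all()
        assert (a.name_units == b.name_units).all()

    def test_different_seeds_differ(self, p2_profile):
        a = pg.generate_patterns(p2_profile, 7)
        b = pg.generate_patterns(p2_profile, 8)
        assert (a.vectors != b.vectors).any()

    def test_sample_means_converge_to_closed_form(self):
        """Law of large numbers: realized bird means match the profile's
        closed-form expectation over 200 generated sets."""
        prof = pg.build_profile("P1-like")
        expect = prof.expected_feature_count("birds")
        means = [pg.generate_patterns(prof, s).category_mean_features()["birds"]
                 for s in range(200)]
        p = prof.probabilities["birds"]
        mc_sd = np.sqrt(np.sum(p * (1 - p)) / (200 * 8))
        assert np.mean(means) == pytest.approx(expect, abs=4 * mc_sd)

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=2**31 - 1))
    def test_structural_invariants_hold_for_any_seed(self, seed):
        ps = pg.generate_patterns(pg.build_profile("P2-like"), seed)
        assert ps.vectors.shape == (48, 216)
        assert (ps.name_block.sum(axis=1) == 1).all()
        assert ps.domains.count("animal") == 24


class TestSimilarity:
    def test_matrix_symmetric_unit_diagonal(self, small_pattern_set):
        ss = pg.similarity_summary(small_pattern_set)
        m = ss.correlation_matrix
        assert np.allclose(m, m.T, equal_nan=True)
        assert np.allclose(np.diag(m), 1.0)

    def test_block_ordering(self, p2_profile):
        for seed in range(5):
            ss = pg.similarity_summary(pg.generate_patterns(p2_profile, seed))
            b = ss.block_means
            assert b["within_category"] >= b["within_domain"] >= b["cross_domain"]
            assert -0.1 <= b["cross_domain"] <= 0.1
            assert b["within_category"] - b["cross_domain"] >= 0.2

    def test_identical_items_fully_correlated(self, small_pattern_set):
        ps = small_pattern_set
        vec = ps.vectors.copy()
        vec[1] = vec[0]
        dup = pg.PatternSet(vec, ps.categories, ps.domains, ps.name_units,
                            ps.seed)
        ss = pg.similarity_summary(dup)
        assert ss.correlation_matrix[0, 1] == pytest.approx(1.0)

    def test_zero_variance_item_flagged(self, small_pattern_set):
        ps = small_pattern_set
        vec = ps.vectors.copy()
        vec[3] = 0
        degen = pg.PatternSet(vec, ps.categories, ps.domains, ps.name_units,
                              ps.seed)
        ss = pg.similarity_summary(degen)
        assert 3 in ss.degenerate_items
        assert np.isnan(ss.correlation_matrix[3, 10])


class TestBoost:
    def test_boost_hits_target_and_leaves_other_domain(self):
        prof = pg.build_profile("P2-like")
        boosted = pg.boost_domain_norms(prof, "animal", 42.0)
        for c in ("birds", "mammals", "fruits"):
            assert boosted.expected_feature_count(c) == pytest.approx(42.0)
        for c in ("tools", "vehicles", "household"):
            assert np.allclose(boosted.probabilities[c],
                               prof.probabilities[c])

    def test_boost_to_current_expectation_is_fixed_point(self):
        prof = pg.build_profile("P2-like")
        current = prof.expected_feature_count("birds")
        same = pg.boost_domain_norms(prof, "animal", current)
        assert np.allclose(same.probabilities["birds"],
                           prof.probabilities["birds"], atol=1e-6)

    def test_unachievable_target_rejected(self):
        prof = pg.build_profile("P2-like")
        with pytest.raises(ValueError):
            pg.boost_domain_norms(prof, "animal", 300.0)

    def test_boosted_sample_mean(self):
        boosted = pg.boost_domain_norms(pg.build_profile("P2-like"),
                                        "animal", 42.0)
        means = [np.mean([pg.generate_patterns(boosted, s)
                          .category_mean_features()[c]
                          for c in ("birds", "mammals", "fruits")])
                 for s in range(100)]
        assert np.mean(means) == pytest.approx(42.0, abs=0.5)


class TestIO:
    def test_round_trip(self, tmp_path, small_pattern_set):
        path = tmp_path / "ps.csv"
        pg.write_patterns(path, small_pattern_set)
        back = pg.read_patterns(path)
        assert (back.vectors == small_pattern_set.vectors).all()
        assert back.categories == small_pattern_set.categories
        assert (back.name_units == small_pattern_set.name_units).all()
        assert back.seed == small_pattern_set.seed

    def test_wrong_column_count_rejected(self, tmp_path, small_pattern_set):
        path = tmp_path / "ps.csv"
        pg.write_patterns(path, small_pattern_set)
        import pandas as pd
        df = pd.read_csv(path)
        df.drop(columns=["u215"]).to_csv(path, index=False)
        with pytest.raises(pg.PatternFormatError, match="215"):
            pg.read_patterns(path)

    def test_non_binary_value_rejected(self, tmp_path, small_pattern_set):
        path = tmp_path / "ps.csv"
        pg.write_patterns(path, small_pattern_set)
        import pandas as pd
        df = pd.read_csv(path)
        df.loc[5, "u100"] = 2
        df.to_csv(path, index=False)
        with pytest.raises(pg.PatternFormatError, match="row 5"):
            pg.read_patterns(path)
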