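import numpy as np
import pandas as pd
import pytest

from proximap.abundance import DifferentialResult
from proximap.screens import (
    ScreenProfile,
    classify_essentials,
    classify_sensitizers,
    cluster_profiles,
    differential_hu_hits,
    rank_essentiality,
)
from proximap.synthetic import GeneratorConfig, generate_screen


def profile_from(matrix, genes, screens):
    return ScreenProfile(pd.DataFrame(matrix, index=genes, columns=screens))


def diff(prey, log2fc):
    return DifferentialResult(prey=prey, bait="RAD51B", log2fc=log2fc,
                              avg_spec_untreated=1.0, avg_spec_hu=1.0)


class TestRankEssentiality:
    def test_null_screen_is_finite_and_centered(self):
        rows = [
            {"guide": f"g{i}", "gene": f"G{i // 4}", "replicate": "rep1",
             "count_d0": 100, "count_d14": 100}
            for i in range(40)
        ]
        nz = rank_essentiality(pd.DataFrame(rows))
        assert np.isfinite(nz).all()
        assert abs(nz.mean()) < 0.2

    def test_planted_essentials_recalled_in_bottom_k(self):
        config = GeneratorConfig(seed=21, n_genes=400, n_essential=20)
        guides, truth = generate_screen(config)
        nz = rank_essentiality(guides)
        bottom = set(nz.nsmallest(len(truth.essentials)).index)
        recall = len(bottom & truth.essentials) / len(truth.essentials)
        assert recall >= 0.9
        assert nz[list(truth.essentials)].mean() < -1

    def test_permuting_guide_gene_map_destroys_signal(self):
        config = GeneratorConfig(seed=22, n_genes=400, n_essential=20)
        guides, truth = generate_screen(config)
        rng = np.random.default_rng(0)
        gene_of_guide = guides.drop_duplicates("guide").set_index("guide")["gene"]
        permuted = pd.Series(
            rng.permutation(gene_of_guide.to_numpy()), index=gene_of_guide.index
        )
        shuffled = guides.assign(gene=guides["guide"].map(permuted))
        nz = rank_essentiality(shuffled)
        bottom = set(nz.nsmallest(len(truth.essentials)).index)
        recall = len(bottom & truth.essentials) / len(truth.essentials)
        assert recall <= 0.3

    def test_depth_normalization_makes_scores_scale_invariant(self):
        config = GeneratorConfig(seed=23, n_genes=100, n_essential=5)
        guides, _ = generate_screen(config)
        nz = rank_essentiality(guides)
        scaled = guides.copy()
        rep1 = scaled["replicate"] == "rep1"
        scaled.loc[rep1, "count_d0"] *= 10
        nz_scaled = rank_essentiality(scaled)
        pd.testing.assert_series_equal(nz, nz_scaled)

    def test_zero_total_counts_errors(self):
        rows = pd.DataFrame(
            [{"guide": "g", "gene": "G", "replicate": "r",
              "count_d0": 0, "count_d14": 5}]
        )
        with pytest.raises(ValueError, match="zero total"):
            rank_essentiality(rows)

    def test_guide_mapped_to_two_genes_errors(self):
        rows = pd.DataFrame(
            [
                {"guide": "g", "gene": "A", "replicate": "r",
                 "count_d0": 5, "count_d14": 5},
                {"guide": "g", "gene": "B", "replicate": "r",
                 "count_d0": 5, "count_d14": 5},
            ]
        )
        with pytest.raises(ValueError, match="more than one gene"):
            rank_essentiality(rows)


class TestThresholdClassifiers:
    def test_hand_case_two_of_three_screens(self):
        p = profile_from([[-1.2, -0.5, -3.0]], ["g1"], ["s1", "s2", "s3"])
        assert classify_sensitizers(p, ["s1", "s2", "s3"], min_screens=2) == {"g1"}

    def test_boundary_is_strict(self):
        p = profile_from([[-1.0, -1.0]], ["g1"], ["s1", "s2"])
        assert classify_sensitizers(p, ["s1", "s2"], min_screens=1) == set()
        p2 = profile_from([[-1.5]], ["g1"], ["s1"])
        assert classify_essentials(p2, "s1") == set()

    def test_positive_scores_never_classified(self):
        p = profile_from([[2.8]], ["TP53"], ["essential"])
        assert classify_essentials(p, "essential") == set()

    def test_missing_cells_never_count(self):
        p = profile_from([[np.nan, -2.0]], ["g1"], ["s1", "s2"])
        assert classify_sensitizers(p, ["s1", "s2"], min_screens=2) == set()

    def test_matches_brute_force_counting(self):
        rng = np.random.default_rng(31)
        genes = [f"g{i}" for i in range(200)]
        screens = ["s1", "s2", "s3", "s4"]
        m = rng.normal(size=(200, 4))
        m[rng.random(m.shape) < 0.1] = np.nan
        p = profile_from(m, genes, screens)
        for threshold, min_screens in [(-1.0, 2), (-0.5, 1), (-2.0, 3)]:
            expected = {
                g
                for i, g in enumerate(genes)
                if sum(
                    1 for j in range(4)
                    if not np.isnan(m[i, j]) and m[i, j] < threshold
                )
                >= min_screens
            }
            got = classify_sensitizers(p, screens, threshold, min_screens)
            assert got == expected

    def test_relaxing_threshold_never_removes_genes(self):
        rng = np.random.default_rng(32)
        p = profile_from(rng.normal(size=(100, 3)), [f"g{i}" for i in range(100)],
                         ["a", "b", "c"])
        strict = classify_sensitizers(p, ["a", "b", "c"], threshold=-2.0,
                                      min_screens=1)
        lax = classify_sensitizers(p, ["a", "b", "c"], threshold=-1.0,
                                   min_screens=1)
        assert strict <= lax

    def test_min_screens_exceeding_named_screens_errors(self):
        p = profile_from([[-2.0]], ["g1"], ["s1"])
        with pytest.raises(ValueError):
            classify_sensitizers(p, ["s1"], min_screens=2)


class TestDifferentialHuHits:
    def test_included_when_both_rules_pass(self):
        p = profile_from([[-2.5]], ["P"], ["hu"])
        assert differential_hu_hits([diff("P", 1.5)], p, "hu") == {"P"}

    def test_excluded_when_screen_rule_fails(self):
        p = profile_from([[-1.0]], ["P"], ["hu"])
        assert differential_hu_hits([diff("P", 1.5)], p, "hu") == set()

    def test_excluded_when_fc_rule_fails(self):
        p = profile_from([[-3.0]], ["P"], ["hu"])
        assert differential_hu_hits([diff("P", 0.5)], p, "hu") == set()

    def test_cut_boundaries_are_strict(self):
        p = profile_from([[2.0]], ["P"], ["hu"])
        assert differential_hu_hits([diff("P", 1.0)], p, "hu") == set()


class TestClusterProfiles:
    def test_two_blobs_recovered_exactly(self):
        rng = np.random.default_rng(41)
        a = rng.normal(0, 0.3, size=(20, 5))
        b = rng.normal(5, 0.3, size=(15, 5))
        genes = [f"g{i}" for i in range(35)]
        p = profile_from(np.vstack([a, b]), genes, list("ABCDE"))
        ca = cluster_profiles(p, k=2)
        assert ca.members(1) == set(genes[:20])
        assert ca.members(2) == set(genes[20:])

    def test_k_one_puts_all_genes_together(self):
        rng = np.random.default_rng(42)
        p = profile_from(rng.normal(size=(10, 3)), [f"g{i}" for i in range(10)],
                         ["a", "b", "c"])
        ca = cluster_profiles(p, k=1)
        assert set(ca.labels.values()) == {1}

    def test_duplicating_rows_keeps_memberships(self):
        rng = np.random.default_rng(43)
        x = rng.normal(size=(12, 4))
        genes = [f"g{i}" for i in range(12)]
        p = profile_from(x, genes, list("WXYZ"))
        ca = cluster_profiles(p, k=3)
        doubled = profile_from(
            np.vstack([x, x]), genes + [f"dup_{g}" for g in genes], list("WXYZ")
        )
        ca2 = cluster_profiles(doubled, k=3)
        # co-membership of the original genes is preserved
        for g1 in genes:
            for g2 in genes:
                same = ca.labels[g1] == ca.labels[g2]
                same2 = ca2.labels[g1] == ca2.labels[g2]
                assert same == same2

    def test_k_exceeding_genes_errors(self):
        p = profile_from([[1.0, 2.0]], ["g1"], ["a", "b"])
        with pytest.raises(ValueError):
            cluster_profiles(p, k=5)

    def test_all_missing_rows_dropped_with_warning(self):
        m = np.array([[1.0, 2.0], [np.nan, np.nan], [3.0, 4.0]])
        p = profile_from(m, ["g1", "g2", "g3"], ["a", "b"])
        with pytest.warns(UserWarning, match="dropping 1"):
            ca = cluster_profiles(p, k=2)
        assert "g2" not in ca.labels

    def test_correlation_distance_and_ward_guard(self):
        rng = np.random.default_rng(44)
        p = profile_from(rng.normal(size=(8, 5)), [f"g{i}" for i in range(8)],
                         list("ABCDE"))
        ca = cluster_profiles(p, k=2, distance="correlation", linkage="average")
        assert set(ca.labels.values()) == {1, 2}
        with pytest.raises(ValueError, match="ward"):
            cluster_profiles(p, k=2, distance="correlation", linkage="ward")


class TestScreenProfileIO:
    def test_long_tsv_round_trip(self, tmp_path):
        rng = np.random.default_rng(51)
        p = profile_from(rng.normal(size=(6, 3)), [f"g{i}" for i in range(6)],
                         ["s1", "s2", "s3"])
        path = tmp_path / "normz.tsv"
        p.write_tsv(path)
        back = ScreenProfile.read_tsv(path)
        pd.testing.assert_frame_equal(
            p.normz, back.normz, check_names=False
        )
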