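"""Diversity indices against hand-computed values, weighted UniFrac on toy
trees, PCoA reconstruction, PERMANOVA and Kruskal-Wallis/Dunn behaviour, and
the ANCOM-style W statistic."""

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode
from skbio.stats.distance import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova

from conftest import make_feature_table
from edufacsseq import community as cm
from edufacsseq.synthetic import CommunitySimConfig, simulate_fraction_tables, simulate_tree


def tree_from(newick: str) -> TreeNode:
    from io import StringIO

    return TreeNode.read(StringIO(newick), convert_underscores=False)


class TestAlpha:
    def test_shannon_uniform_four_features_is_two_bits(self):
        assert cm.shannon([5, 5, 5, 5]) == pytest.approx(2.0)

    def test_shannon_singleton_is_zero(self):
        assert cm.shannon([42]) == pytest.approx(0.0)

    def test_shannon_hand_computed(self):
        # proportions (0.5, 0.25, 0.25): -sum p log2 p = 1.5 bits
        assert cm.shannon([2, 1, 1]) == pytest.approx(1.5)

    def test_shannon_permutation_invariant(self):
        assert cm.shannon([7, 2, 9, 1]) == pytest.approx(cm.shannon([9, 1, 7, 2]))

    def test_shannon_maximal_at_uniformity(self, rng):
        counts = rng.integers(1, 50, size=8)
        assert cm.shannon(counts) <= np.log2(8) + 1e-12

    def test_simpson_evenness_uniform_is_one(self):
        assert cm.simpson_evenness([3, 3, 3, 3, 3]) == pytest.approx(1.0)

    def test_simpson_evenness_hand_computed(self):
        # proportions (0.75, 0.25): (1 / 0.625) / 2 = 0.8
        assert cm.simpson_evenness([3, 1]) == pytest.approx(0.8)

    def test_simpson_evenness_singleton_is_one(self):
        assert cm.simpson_evenness([10]) == pytest.approx(1.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            cm.shannon([0, 0])
        with pytest.raises(ValueError):
            cm.simpson_evenness([0, 0])

    def test_observed_features(self):
        assert cm.observed_features([0, 0, 0]) == 0
        assert cm.observed_features([1, 0, 7]) == 2

    def test_alpha_diversity_table(self):
        tbl = make_feature_table(
            {"s1": {"a": 2, "b": 1, "c": 1}, "s2": {"a": 4, "b": 0, "c": 0}},
            {"s1": "whole", "s2": "whole"},
        )
        df = cm.alpha_diversity(tbl)
        assert df.loc["s1", "shannon"] == pytest.approx(1.5)
        assert df.loc["s2", "observed_features"] == 1


class TestRarefactionCurve:
    def test_full_depth_matches_observed_features(self):
        tbl = make_feature_table({"s": {"a": 5, "b": 3, "c": 2}}, {"s": "whole"})
        curve = cm.rarefaction_curve(tbl, depths=[10], reps=5, seed=0)
        assert curve.loc["s", 10] == 3.0

    def test_non_decreasing_in_depth(self):
        tbl = simulate_fraction_tables(CommunitySimConfig(seed=2, depth_per_sample=2000))
        curve = cm.rarefaction_curve(tbl, depths=[50, 200, 800, 2000], reps=10, seed=1)
        diffs = curve.diff(axis=1).iloc[:, 1:]
        assert (diffs >= -1e-9).all().all()

    def test_shallow_samples_get_nan(self):
        tbl = make_feature_table({"s": {"a": 5}}, {"s": "whole"})
        curve = cm.rarefaction_curve(tbl, depths=[3, 10], reps=2, seed=0)
        assert not np.isnan(curve.loc["s", 3])
        assert np.isnan(curve.loc["s", 10])


class TestWeightedUnifrac:
    def test_two_leaf_star_tree_hand_value(self):
        # branches of length 1 each; samples (1,0) vs (0,1):
        # sum b|A-B| = 1*|1-0| + 1*|0-1| = 2
        tbl = make_feature_table(
            {"s1": {"a": 1, "b": 0}, "s2": {"a": 0, "b": 1}},
            {"s1": "whole", "s2": "whole"},
        )
        dm = cm.weighted_unifrac(tbl, tree_from("(a:1,b:1);"))
        assert dm["s1", "s2"] == pytest.approx(2.0)

    def test_identical_samples_at_zero_distance(self):
        tbl = make_feature_table(
            {"s1": {"a": 3, "b": 1}, "s2": {"a": 3, "b": 1}},
            {"s1": "whole", "s2": "whole"},
        )
        dm = cm.weighted_unifrac(tbl, tree_from("(a:1,b:2);"))
        assert dm["s1", "s2"] == pytest.approx(0.0)

    def test_symmetric_nonnegative_zero_diagonal(self, rng):
        counts = {
            f"s{i}": {f"t{j}": int(rng.integers(0, 50)) for j in range(6)}
            for i in range(4)
        }
        tbl = make_feature_table(counts, {f"s{i}": "whole" for i in range(4)})
        tree = simulate_tree([f"t{j}" for j in range(6)], seed=1)
        dm = cm.weighted_unifrac(tbl, tree)
        assert np.allclose(dm.data, dm.data.T)
        assert np.allclose(np.diag(dm.data), 0.0)
        assert (dm.data >= 0).all()

    def test_zero_length_internal_branch_contributes_nothing(self):
        # distances on ((a,b):0.0, c) equal the star-tree hand value
        # sum_i b_i |A_i - B_i| over the three terminal branches only:
        # 1*|2/6-1/6| + 2*|1/6-4/6| + 1*|3/6-1/6| = 1.5
        tbl = make_feature_table(
            {"s1": {"a": 2, "b": 1, "c": 3}, "s2": {"a": 1, "b": 4, "c": 1}},
            {"s1": "whole", "s2": "whole"},
        )
        with_zero = cm.weighted_unifrac(tbl, tree_from("((a:1,b:2):0.0,c:1);"))
        assert with_zero["s1", "s2"] == pytest.approx(1.5)

    def test_missing_feature_error_lists_ids(self):
        tbl = make_feature_table(
            {"s1": {"a": 1, "zzz": 2}, "s2": {"a": 2, "zzz": 0}},
            {"s1": "whole", "s2": "whole"},
        )
        with pytest.raises(ValueError, match="zzz"):
            cm.weighted_unifrac(tbl, tree_from("(a:1,b:1);"))


class TestPcoa:
    def test_points_on_a_line_reconstructed(self):
        x = np.array([0.0, 1.0, 3.0, 7.0])
        dm = DistanceMatrix(np.abs(x[:, None] - x[None, :]), ids=list("abcd"))
        res = cm.pcoa(dm)
        coords = res.samples.to_numpy()
        d_hat = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
        np.testing.assert_allclose(d_hat, dm.data, atol=1e-9)
        # axis 1 carries all the variance: it recovers the line up to
        # sign/translation
        gaps = np.diff(coords[:, 0])
        np.testing.assert_allclose(np.abs(gaps), np.diff(x), atol=1e-9)

    def test_equilateral_triangle_has_two_equal_eigenvalues(self):
        dm = DistanceMatrix(np.ones((3, 3)) - np.eye(3), ids=list("abc"))
        res = cm.pcoa(dm)
        eig = np.sort(res.eigvals.to_numpy())[::-1]
        assert eig[0] == pytest.approx(eig[1], rel=1e-9)
        assert eig[0] > 0

    def test_duplicate_samples_coincide(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 0.0], [0.0, 2.0]])
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        res = cm.pcoa(DistanceMatrix(d, ids=list("abcd")))
        coords = res.samples.to_numpy()
        np.testing.assert_allclose(coords[1], coords[2], atol=1e-9)

    def test_too_few_samples_rejected(self):
        dm = DistanceMatrix(np.array([[0.0, 1.0], [1.0, 0.0]]), ids=list("ab"))
        with pytest.raises(ValueError):
            cm.pcoa(dm)


def clustered_dm(rng, separation=10.0, n_per=5):
    a = rng.normal(0, 1, size=(n_per, 3))
    b = rng.normal(separation, 1, size=(n_per, 3))
    pts = np.vstack([a, b])
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
    ids = [f"s{i}" for i in range(2 * n_per)]
    return DistanceMatrix(d, ids=ids), ["a"] * n_per + ["b"] * n_per


class TestPermanova:
    def test_separated_clusters_hit_p_floor(self, rng):
        dm, groups = clustered_dm(rng)
        res = cm.permanova_pairwise(dm, groups, n_permutations=999, seed=0)
        assert len(res) == 1
        assert res[0].p_value == pytest.approx(1 / 1000)

    def test_pseudo_f_matches_skbio(self, rng):
        dm, groups = clustered_dm(rng, separation=2.0)
        ours = cm.permanova_pairwise(dm, groups, n_permutations=99, seed=1)[0]
        ref = skbio_permanova(dm, list(groups), permutations=99)
        assert ours.pseudo_f == pytest.approx(ref["test statistic"], rel=1e-9)

    def test_sample_order_leaves_f_unchanged(self, rng):
        dm, groups = clustered_dm(rng, separation=2.0)
        perm = rng.permutation(len(dm.ids))
        ids = [dm.ids[i] for i in perm]
        dm2 = dm.filter(ids)
        groups2 = [groups[i] for i in perm]
        f1 = cm.permanova_pairwise(dm, groups, n_permutations=9, seed=0)[0].pseudo_f
        f2 = cm.permanova_pairwise(dm2, groups2, n_permutations=9, seed=0)[0].pseudo_f
        assert f1 == pytest.approx(f2, rel=1e-9)

    def test_singleton_group_skipped_with_warning(self, rng):
        dm, groups = clustered_dm(rng, n_per=2)
        groups = ["a", "a", "b", "c"]
        with pytest.warns(UserWarning, match="skipped"):
            res = cm.permanova_pairwise(dm, groups, n_permutations=99, seed=0)
        assert [(r.group_a, r.group_b) for r in res] == []

    def test_three_groups_give_three_pairs_with_bh_q(self, rng):
        pts = np.vstack([rng.normal(m, 1, size=(4, 2)) for m in (0.0, 0.5, 8.0)])
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(12)])
        groups = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        res = cm.permanova_pairwise(dm, groups, n_permutations=999, seed=3)
        assert len(res) == 3
        # q preserves p ordering
        by_p = sorted(res, key=lambda r: r.p_value)
        qs = [r.q_value for r in by_p]
        assert qs == sorted(qs)
        assert all(r.q_value >= r.p_value for r in res)


class TestKruskalWallis:
    def test_identical_groups_not_significant(self):
        vals = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        groups = ["a"] * 3 + ["b"] * 3
        res = cm.kruskal_wallis_pairwise(vals, groups)
        assert res[0].p > 0.9

    def test_hand_ranked_three_groups(self):
        # ranks 1..9 in blocks of 3: H = 12/(N(N+1)) * sum n_g (rbar_g - rbar)^2
        #   = 12/90 * 3 * ((2-5)^2 + 0 + (8-5)^2) = 7.2, p = chi2.sf(7.2, 2)
        vals = [1, 2, 3, 101, 102, 103, 201, 202, 203]
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        res = cm.kruskal_wallis_pairwise(vals, groups)
        assert res[0].statistic == pytest.approx(7.2)
        assert res[0].p == pytest.approx(0.0273, abs=0.0005)

    def test_pairwise_family_has_bh_q_at_least_p(self):
        vals = [1, 2, 3, 101, 102, 103, 201, 202, 203]
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        res = cm.kruskal_wallis_pairwise(vals, groups)
        pairs = res[1:]
        assert len(pairs) == 3
        assert all(r.q >= r.p for r in pairs)

    def test_all_identical_values_give_p_one(self):
        res = cm.kruskal_wallis_pairwise([5.0] * 6, ["a"] * 3 + ["b"] * 3)
        assert res[0].p == 1.0

    def test_extreme_separation_gives_large_dunn_z(self):
        vals = [1, 2, 3, 4, 101, 102, 103, 104]
        groups = ["a"] * 4 + ["b"] * 4
        res = cm.kruskal_wallis_pairwise(vals, groups)
        assert abs(res[1].statistic) > 2


def two_group_table(counts_a, counts_b):
    n_a, n_b = len(counts_a), len(counts_b)
    idx = [f"s{i}" for i in range(n_a + n_b)]
    counts = pd.DataFrame(
        np.vstack([counts_a, counts_b]), index=idx,
        columns=[f"f{j}" for j in range(np.shape(counts_a)[1])],
    )
    meta = pd.DataFrame(
        {"fraction": "whole", "experiment": "e1", "treatment": "none", "replicate": "r"},
        index=idx,
    )
    from edufacsseq.filtering import FeatureTable

    return FeatureTable(counts, meta), np.array(["a"] * n_a + ["b"] * n_b)


class TestAncomW:
    def test_three_feature_spike_reaches_maximum_w(self, rng):
        p_a = np.array([0.1, 0.45, 0.45])
        p_b = np.array([0.8, 0.1, 0.1])
        a = np.vstack([rng.multinomial(5000, p_a) for _ in range(8)])
        b = np.vstack([rng.multinomial(5000, p_b) for _ in range(8)])
        tbl, groups = two_group_table(a, b)
        res = cm.ancom_w(tbl, groups)
        assert res.table.loc["f0", "W"] == 2  # n_features - 1

    def test_spiked_feature_detected_in_twenty_feature_design(self, rng):
        p = np.ones(20) / 20
        p_spiked = p.copy()
        p_spiked[0] *= 10
        p_spiked /= p_spiked.sum()
        a = np.vstack([rng.multinomial(5000, p) for _ in range(8)])
        b = np.vstack([rng.multinomial(5000, p_spiked) for _ in range(8)])
        tbl, groups = two_group_table(a, b)
        res = cm.ancom_w(tbl, groups)
        assert res.table.loc["f0", "detected"]
        assert res.table.loc["f0", "W"] == res.table["W"].max()

    def test_null_run_detects_nothing(self, rng):
        p = np.ones(10) / 10
        a = np.vstack([rng.multinomial(5000, p) for _ in range(8)])
        b = np.vstack([rng.multinomial(5000, p) for _ in range(8)])
        tbl, groups = two_group_table(a, b)
        res = cm.ancom_w(tbl, groups)
        assert not res.table["detected"].any()

    def test_structural_zero_shortcut(self, rng):
        p_a = np.array([0.0, 0.5, 0.3, 0.2])
        p_b = np.array([0.4, 0.3, 0.2, 0.1])
        a = np.vstack([rng.multinomial(2000, p_a) for _ in range(6)])
        b = np.vstack([rng.multinomial(2000, p_b) for _ in range(6)])
        tbl, groups = two_group_table(a, b)
        res = cm.ancom_w(tbl, groups)
        assert res.table.loc["f0", "structural_zero"]
        assert res.table.loc["f0", "detected"]

    def test_too_few_features_rejected(self, rng):
        a = np.vstack([rng.multinomial(100, [0.5, 0.5]) for _ in range(4)])
        tbl, groups = two_group_table(a[:2], a[2:])
        with pytest.raises(ValueError, match="3 features"):
            cm.ancom_w(tbl, groups)

    def test_blocked_test_absorbs_experiment_shift(self, rng):
        # a strong block effect (composition differs between experiments) with
        # no group effect: the blocked test must not detect anything
        p1 = np.array([0.6, 0.2, 0.1, 0.1])
        p2 = np.array([0.1, 0.1, 0.2, 0.6])
        rows, groups, blocks = [], [], []
        for block, p in (("e1", p1), ("e2", p2)):
            for g in ("a", "b"):
                for _ in range(4):
                    rows.append(rng.multinomial(3000, p))
                    groups.append(g)
                    blocks.append(block)
        idx = [f"s{i}" for i in range(len(rows))]
        from edufacsseq.filtering import FeatureTable

        counts = pd.DataFrame(rows, index=idx, columns=list("wxyz"))
        meta = pd.DataFrame(
            {"fraction": "whole", "experiment": blocks, "treatment": "none",
             "replicate": "r"},
            index=idx,
        )
        tbl = FeatureTable(counts, meta)
        res = cm.ancom_w(tbl, groups, block=blocks)
        assert not res.table["detected"].any()


class TestFractionEnrichment:
    def test_fast_replicator_detected_and_enriched(self):
        w = np.ones(12)
        w[0] = 5.0
        cfg = CommunitySimConfig(
            n_taxa=12, replication_weights=w, incubation_loss_rate=0.0,
            n_replicates=6, n_experiments=2, seed=8,
        )
        tbl = simulate_fraction_tables(cfg)
        report = cm.fraction_enrichment_report(tbl)
        row = report.loc["taxon_01"]
        assert row["detected"]
        assert row["mean_edu_pos"] > row["mean_whole"]

    def test_uniform_weights_detect_nothing(self):
        cfg = CommunitySimConfig(
            n_taxa=12, replication_weights=np.ones(12), incubation_loss_rate=0.0,
            n_replicates=6, n_experiments=2, seed=9,
        )
        tbl = simulate_fraction_tables(cfg)
        report = cm.fraction_enrichment_report(tbl)
        community_taxa = [f for f in report.index if f.startswith("taxon")]
        assert not report.loc[community_taxa, "detected"].any()

    def test_single_sample_fractions_report_means_without_sd(self):
        cfg = CommunitySimConfig(n_taxa=8, n_replicates=1, incubation_loss_rate=0.0, seed=1)
        tbl = simulate_fraction_tables(cfg)
        report = cm.fraction_enrichment_report(tbl)
        assert report["mean_edu_pos"].notna().all()
        assert report["sd_edu_pos"].isna().all()
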