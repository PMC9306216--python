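import itertools

import numpy as np
import pandas as pd
import pytest

from vitacap.stats import (
    amova,
    bh_adjust,
    bray_curtis,
    differential_enrichment,
    lda_effect_size,
    pcoa,
    rank_sum_test,
    richness,
    shannon,
)

from .oracles import exact_ranksum_p, procrustes_residual


class TestAlphaDiversity:
    def test_uniform_shannon_is_log_n(self):
        assert shannon([5, 5, 5, 5]) == pytest.approx(np.log(4))

    def test_single_entity(self):
        assert richness([0, 7.0, 0]) == 1
        assert shannon([0, 7.0, 0]) == 0.0

    def test_hand_computed_mix(self):
        assert shannon([0.5, 0.25, 0.25]) == pytest.approx(1.5 * np.log(2))

    def test_all_zero_convention(self):
        assert richness([0, 0]) == 0
        assert shannon([0, 0]) == 0.0


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        df = pd.DataFrame({"a": [1, 2, 0], "b": [1, 2, 0], "c": [0, 0, 5]})
        d = bray_curtis(df)
        assert d.loc["a", "b"] == 0.0
        assert d.loc["a", "c"] == 1.0

    def test_hand_computed_pair(self):
        df = pd.DataFrame({"x": [1, 0, 3], "y": [0, 2, 1]})
        assert bray_curtis(df).loc["x", "y"] == pytest.approx(5 / 7)

    def test_two_empty_samples_have_distance_zero(self):
        df = pd.DataFrame({"a": [0, 0], "b": [0, 0], "c": [1, 1]})
        d = bray_curtis(df)
        assert d.loc["a", "b"] == 0.0
        assert d.loc["a", "c"] == 1.0

    @pytest.mark.parametrize("seed", range(4))
    def test_metric_properties_on_random_pairs(self, seed):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(rng.lognormal(0, 1, size=(30, 40)))
        df.columns = [f"s{i}" for i in range(40)]
        d = bray_curtis(df).to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        assert (d >= 0).all() and (d <= 1).all()


class TestPcoa:
    def test_points_on_a_line_are_reproduced(self):
        pts = np.array([0.0, 1.0, 3.0, 7.0])
        dist = pd.DataFrame(np.abs(pts[:, None] - pts[None, :]))
        axis1 = pcoa(dist, k=1).coordinates.to_numpy()[:, 0]
        np.testing.assert_allclose(
            np.abs(axis1[:, None] - axis1[None, :]), dist, atol=1e-9
        )

    def test_equilateral_triangle(self):
        dist = pd.DataFrame(1.0 - np.eye(3))
        ord_ = pcoa(dist, k=2)
        assert ord_.eigenvalues[0] == pytest.approx(ord_.eigenvalues[1])
        coords = ord_.coordinates.to_numpy()
        for i, j in itertools.combinations(range(3), 2):
            assert np.linalg.norm(coords[i] - coords[j]) == pytest.approx(1.0)

    def test_zero_matrix_embeds_at_origin(self):
        ord_ = pcoa(pd.DataFrame(np.zeros((4, 4))), k=2)
        assert (ord_.coordinates.to_numpy() == 0).all()

    def test_planar_configuration_recovered(self):
        """Euclidean distances from random 2-D points embed back onto the
        original configuration up to rotation/reflection."""
        rng = np.random.default_rng(42)
        pts = rng.normal(size=(50, 2))
        dist = pd.DataFrame(
            np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        )
        coords = pcoa(dist, k=2).coordinates.to_numpy()
        assert procrustes_residual(pts, coords) < 1e-8

    def test_excess_axes_warns_and_truncates(self):
        pts = np.array([0.0, 1.0, 2.0])
        dist = pd.DataFrame(np.abs(pts[:, None] - pts[None, :]))
        with pytest.warns(UserWarning, match="positive eigenvalues"):
            ord_ = pcoa(dist, k=3)
        assert ord_.coordinates.shape[1] == 1

    def test_agrees_with_skbio_on_euclidean_input(self):
        from skbio import DistanceMatrix
        from skbio.stats.ordination import pcoa as skbio_pcoa

        rng = np.random.default_rng(7)
        pts = rng.normal(size=(12, 3))
        dist = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        ours = pcoa(pd.DataFrame(dist), k=3)
        theirs = skbio_pcoa(DistanceMatrix(dist), number_of_dimensions=3)
        np.testing.assert_allclose(
            ours.eigenvalues, theirs.eigvals.to_numpy()[:3], rtol=1e-8
        )
        assert (
            procrustes_residual(
                ours.coordinates.to_numpy(), theirs.samples.to_numpy()[:, :3]
            )
            < 1e-8
        )


class TestAmova:
    def two_pair_distance(self):
        d = np.array(
            [[0.0, 0.1, 1.0, 1.0],
             [0.1, 0.0, 1.0, 1.0],
             [1.0, 1.0, 0.0, 0.1],
             [1.0, 1.0, 0.1, 0.0]]
        )
        return pd.DataFrame(d, index=list("abcd"), columns=list("abcd"))

    def test_exhaustive_two_tight_pairs(self):
        """Only the true labeling and its complement attain the maximal Fs
        among the 6 balanced labelings, so exhaustive p = 2/6."""
        res = amova(
            self.two_pair_distance(),
            {"a": "A", "b": "A", "c": "B", "d": "B"},
            exhaustive=True,
        )
        assert res.p_value == pytest.approx(2 / 6)
        assert res.n_permutations == 6
        assert res.fs > 1

    def test_single_group_raises(self):
        with pytest.raises(ValueError, match="2 groups"):
            amova(self.two_pair_distance(), dict.fromkeys("abcd", "A"))

    def test_undersized_group_raises(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            amova(self.two_pair_distance(), {"a": "A", "b": "B", "c": "B", "d": "B"})

    def test_label_mismatch_raises(self):
        with pytest.raises(ValueError, match="sample ids"):
            amova(self.two_pair_distance(), {"a": "A", "b": "A", "x": "B", "y": "B"})

    def test_invariant_to_label_names_and_sample_order(self):
        d = self.two_pair_distance()
        res1 = amova(d, {"a": "A", "b": "A", "c": "B", "d": "B"}, seed=9)
        res2 = amova(d, {"a": "G2", "b": "G2", "c": "G1", "d": "G1"}, seed=9)
        shuffled = d.loc[list("dcba"), list("dcba")]
        res3 = amova(shuffled, {"a": "A", "b": "A", "c": "B", "d": "B"}, seed=9)
        assert res1.fs == pytest.approx(res2.fs) == pytest.approx(res3.fs)
        assert res1.p_value == res2.p_value

    def test_null_rejection_rate_is_calibrated(self):
        """Exchangeable samples should be rejected at ~alpha."""
        rng = np.random.default_rng(0)
        rejections = 0
        n_reps = 200
        for rep in range(n_reps):
            profile = pd.DataFrame(
                rng.lognormal(0, 1, size=(25, 16)),
                columns=[f"s{i}" for i in range(16)],
            )
            groups = pd.Series(["A"] * 8 + ["B"] * 8, index=profile.columns)
            res = amova(bray_curtis(profile), groups, n_permutations=500, seed=rep)
            rejections += res.p_value < 0.05
        assert 0.02 <= rejections / n_reps <= 0.08

    def test_seeded_reproducibility(self):
        d = self.two_pair_distance()
        groups = {"a": "A", "b": "A", "c": "B", "d": "B"}
        assert (
            amova(d, groups, seed=3).p_value == amova(d, groups, seed=3).p_value
        )


class TestRankSum:
    def test_fully_separated_n3(self):
        res = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(0.1)
        assert res.statistic == 6.0  # ranks 1+2+3

    def test_perfect_symmetry_with_ties(self):
        res = rank_sum_test([1, 2], [1, 2])
        assert res.p_value == 1.0
        assert res.method == "normal-approximation"
        assert res.tie_corrected

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1])

    def test_large_samples_use_normal_approximation(self):
        res = rank_sum_test(list(range(10)), [x + 0.5 for x in range(10)])
        assert res.method == "normal-approximation"
        assert not res.tie_corrected

    def test_exact_branch_matches_enumeration_oracle(self):
        """All tie-free configurations with 2 <= n, m <= 5."""
        for n in range(2, 6):
            for m in range(2, 6):
                pooled = list(range(1, n + m + 1))
                for x_idx in itertools.combinations(range(n + m), n):
                    x = [pooled[i] for i in x_idx]
                    y = [pooled[i] for i in range(n + m) if i not in x_idx]
                    res = rank_sum_test(x, y)
                    assert res.method == "exact"
                    assert res.p_value == pytest.approx(
                        exact_ranksum_p(x, y), abs=1e-12
                    )


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.05]).tolist() == [0.05]

    def test_step_up_arithmetic(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_ones_stay_ones(self):
        assert bh_adjust([1.0, 1.0]).tolist() == [1.0, 1.0]

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


def _two_group_profile(rng, n_features=10, n_per_group=10, fold=1.0, feature=0):
    genes = [f"f{i}" for i in range(n_features)]
    samples = [f"A{i}" for i in range(n_per_group)] + [
        f"B{i}" for i in range(n_per_group)
    ]
    base = rng.lognormal(mean=np.log(100), sigma=0.2, size=(n_features, 2 * n_per_group))
    base[feature, n_per_group:] *= fold
    df = pd.DataFrame(base, index=genes, columns=samples)
    groups = pd.Series(["A"] * n_per_group + ["B"] * n_per_group, index=samples)
    return df, groups


class TestLdaEffectSize:
    def test_constant_feature_never_significant(self):
        rng = np.random.default_rng(0)
        df, groups = _two_group_profile(rng)
        df.iloc[3] = 42.0
        results = {r.feature: r for r in lda_effect_size(df, groups, seed=1)}
        assert results["f3"].score == 0.0
        assert not results["f3"].significant

    def test_huge_fold_change_is_significant(self):
        rng = np.random.default_rng(1)
        df, groups = _two_group_profile(rng, fold=1000.0)
        results = {r.feature: r for r in lda_effect_size(df, groups, seed=2)}
        assert abs(results["f0"].score) > 3
        assert results["f0"].significant
        assert results["f0"].direction == "B"

    def test_undersized_group_raises(self):
        rng = np.random.default_rng(2)
        df, groups = _two_group_profile(rng, n_per_group=3)
        groups.iloc[0] = "B"
        with pytest.raises(ValueError, match="3 samples"):
            lda_effect_size(df, groups)

    def test_scores_monotone_in_fold_change(self):
        """Median |score| of the planted feature never decreases with fold."""
        medians = []
        for fold in (2, 10, 100, 1000):
            scores = []
            for seed in range(10):
                rng = np.random.default_rng(seed)
                df, groups = _two_group_profile(rng, fold=fold)
                res = {r.feature: r for r in lda_effect_size(df, groups, seed=seed)}
                scores.append(abs(res["f0"].score))
            medians.append(np.median(scores))
        assert all(b >= a - 1e-9 for a, b in zip(medians, medians[1:]))


class TestDifferentialEnrichment:
    def test_exclusive_presence_forces_direction(self):
        df = pd.DataFrame(
            {"A1": [5.0], "A2": [6.0], "A3": [7.0], "B1": [0.0], "B2": [0.0], "B3": [0.0]},
            index=["only_in_A"],
        )
        groups = pd.Series(["A", "A", "A", "B", "B", "B"], index=df.columns)
        res = differential_enrichment(df, groups)
        assert res.table.loc["only_in_A", "direction"] == "A"

    def test_planted_direction_split_recovered_exactly(self):
        """A noise-free 60/40 split of enriched entities is recovered."""
        rng = np.random.default_rng(3)
        n_a, n_b = 6, 4
        rows, truth = {}, {}
        for i in range(10):
            up_in_a = i < 6
            hi = rng.uniform(10, 20, size=5)
            lo = rng.uniform(1, 2, size=5)
            rows[f"e{i}"] = np.concatenate([hi, lo] if up_in_a else [lo, hi])
            truth[f"e{i}"] = "A" if up_in_a else "B"
        df = pd.DataFrame(rows).T
        df.columns = [f"s{i}" for i in range(10)]
        groups = pd.Series(["A"] * 5 + ["B"] * 5, index=df.columns)
        res = differential_enrichment(df, groups)
        assert res.summary == {"A": 6, "B": 4}
        assert (res.table["direction"] == pd.Series(truth)).all()

    def test_null_false_positive_rate(self):
        """Identical distributions are rarely flagged at alpha = 0.05."""
        rng = np.random.default_rng(4)
        flagged = 0
        n_runs = 400
        for _ in range(n_runs):
            df = pd.DataFrame(
                rng.lognormal(0, 1, size=(1, 12)),
                index=["e"], columns=[f"s{i}" for i in range(12)],
            )
            groups = pd.Series(["A"] * 6 + ["B"] * 6, index=df.columns)
            res = differential_enrichment(df, groups)
            flagged += bool(res.table.loc["e", "significant"])
        assert flagged / n_runs <= 0.07

    def test_undersized_group_raises(self):
        df = pd.DataFrame({"a": [1.0], "b": [1.0], "c": [1.0]}, index=["e"])
        with pytest.raises(ValueError):
            differential_enrichment(
                df, pd.Series(["A", "B", "B"], index=["a", "b", "c"])
            )
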