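"""Evaluation metrics and the nested score arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hypermatch.matching import MatchingPairs
from hypermatch.metrics import (
    clustering_scores,
    combine_scores,
    foscttm,
    graph_connectivity,
    matching_accuracy,
    overall_score,
    silhouette_scores,
)


def pairs_of(x, y, d=None):
    x = np.asarray(x)
    return MatchingPairs(x, np.asarray(y), np.zeros(len(x)) if d is None else np.asarray(d))


class TestMatchingAccuracy:
    def test_perfect(self):
        m = pairs_of([0, 1, 2], [0, 1, 2])
        labs = np.array(["a", "b", "c"], object)
        assert matching_accuracy(m, labs, labs) == 1.0

    def test_three_of_four(self):
        m = pairs_of([0, 0, 1, 1], [0, 1, 0, 2])
        assert matching_accuracy(m, np.array(["a", "a"], object),
                                 np.array(["a", "a", "b"], object)) == 0.75

    def test_adversarial_zero(self):
        m = pairs_of([0, 1], [0, 1])
        assert matching_accuracy(m, np.array(["a", "b"], object),
                                 np.array(["b", "a"], object)) == 0.0

    def test_missing_label_rejected(self):
        m = pairs_of([0], [0])
        with pytest.raises(ValueError):
            matching_accuracy(m, np.array([None], object), np.array(["a"], object))


class TestFoscttm:
    def test_perfect_alignment(self, rng):
        e = rng.normal(size=(20, 4))
        assert foscttm(e, e) == 0.0

    def test_worst_case_two_cells(self):
        x = np.array([[0.0, 0.0], [10.0, 10.0]])
        y = x[::-1]  # true match is always the farther cell
        assert foscttm(x, y) == 1.0

    def test_random_embeddings_near_half(self, rng):
        vals = []
        for _ in range(20):
            x = rng.normal(size=(200, 5))
            y = rng.normal(size=(200, 5))
            vals.append(foscttm(x, y))
        assert np.mean(vals) == pytest.approx(0.5, abs=0.05)


class TestClusteringScores:
    def test_separated_clusters_recovered(self, rng):
        centers = np.array([[0, 0], [30, 0], [0, 30]])
        labels = np.repeat(["a", "b", "c"], 40)
        emb = centers[np.repeat(np.arange(3), 40)] + rng.normal(size=(120, 2))
        nmi, ari = clustering_scores(emb, labels, seed=0)
        assert nmi > 0.95 and ari > 0.95

    def test_random_labels_near_zero_ari(self, rng):
        aris = []
        for seed in range(20):
            emb = rng.normal(size=(300, 3))
            labels = rng.choice(["a", "b", "c"], size=300)
            _, ari = clustering_scores(emb, labels, seed=seed,
                                       resolutions=np.array([1.0]))
            aris.append(ari)
        assert abs(np.mean(aris)) < 0.05

    def test_single_class_degenerate(self, rng):
        nmi, ari = clustering_scores(rng.normal(size=(20, 2)), ["a"] * 20)
        assert nmi == 0.0


class TestSilhouettes:
    def test_separated_labels_mixed_batches(self, rng):
        emb = np.vstack([rng.normal(size=(60, 2)), rng.normal(size=(60, 2)) + 40])
        labels = np.repeat(["a", "b"], 60)
        batches = np.tile(["x", "y"], 60)
        asw_l, asw_b = silhouette_scores(emb, labels, batches)
        assert asw_l > 0.85 and asw_b > 0.85

    def test_separated_batches_score_low(self, rng):
        emb = np.vstack([rng.normal(size=(40, 2)), rng.normal(size=(40, 2)) + 40])
        labels = np.tile(["a", "b"], 40)
        batches = np.repeat(["x", "y"], 40)
        _, asw_b = silhouette_scores(emb, labels, batches)
        assert asw_b < 0.25

    def test_random_labels_one_blob_near_half(self, rng):
        emb = rng.normal(size=(200, 3))
        labels = rng.choice(["a", "b"], 200)
        batches = rng.choice(["x", "y"], 200)
        asw_l, _ = silhouette_scores(emb, labels, batches)
        assert asw_l == pytest.approx(0.5, abs=0.05)

    def test_single_batch_rejected(self, rng):
        with pytest.raises(ValueError, match="single batch"):
            silhouette_scores(rng.normal(size=(10, 2)),
                              np.repeat(["a", "b"], 5), ["x"] * 10)


class TestGraphConnectivity:
    def test_compact_class_fully_connected(self, rng):
        emb = rng.normal(size=(50, 2))
        assert graph_connectivity(emb, ["a"] * 50) == 1.0

    def test_split_class_half(self, rng):
        island1 = rng.normal(size=(25, 2))
        island2 = rng.normal(size=(25, 2)) + 1000
        emb = np.vstack([island1, island2])
        gc = graph_connectivity(emb, ["a"] * 50, k_gc=3)
        assert gc == pytest.approx(0.5)

    def test_never_exceeds_one(self, rng):
        emb = rng.normal(size=(30, 3))
        labels = rng.choice(["a", "b", "c"], 30)
        assert graph_connectivity(emb, labels, k_gc=3) <= 1.0


class TestOverallScore:
    def test_published_component_arithmetic(self):
        # weak-linkage full-model row of the ablation table
        assert combine_scores(0.7449, 0.9822) == pytest.approx(0.8398, abs=1e-4)

    def test_all_ones_paired(self):
        s_bio, s_batch, s_over = overall_score(1, 1, 1, 1, 1, 1, 0.0, paired=True)
        assert s_bio == s_batch == s_over == 1.0

    def test_hand_case_with_negative_ari(self):
        s_bio, _, _ = overall_score(0.5, 0.5, -0.2, 0.5, 1, 1, 0.5, paired=True)
        assert s_bio == pytest.approx(0.4)

    def test_unpaired_ignores_foscttm(self):
        s_bio, _, _ = overall_score(0.8, 0.6, 0.5, 0.7, 1, 1, paired=False)
        assert s_bio == pytest.approx((0.8 + 0.6 + 0.5 + 0.7) / 4)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            overall_score(1.5, 0.5, 0.5, 0.5, 0.5, 0.5)

    @given(
        st.floats(0, 1), st.floats(0, 1), st.floats(-1, 1), st.floats(0, 1),
        st.floats(0, 1), st.floats(0, 1), st.floats(0, 1), st.booleans(),
    )
    @settings(max_examples=500, deadline=None)
    def test_outputs_bounded(self, acc, nmi, ari, aswl, gc, aswb, fos, paired):
        s_bio, s_batch, s_over = overall_score(acc, nmi, ari, aswl, gc, aswb,
                                               fos, paired)
        for s in (s_bio, s_batch, s_over):
            assert -1e-9 <= s <= 1 + 1e-9

    @given(
        st.floats(0, 1), st.floats(0, 1), st.floats(-1, 1), st.floats(0, 1),
        st.floats(0, 1), st.floats(0, 1), st.floats(0, 1),
        st.integers(0, 6), st.floats(0.01, 0.3),
    )
    @settings(max_examples=300, deadline=None)
    def test_monotone_in_each_base_metric(self, acc, nmi, ari, aswl, gc, aswb,
                                          fos, which, bump):
        args = [acc, nmi, ari, aswl, gc, aswb, fos]
        hi = list(args)
        # FOSCTTM enters as (1 - value): improving it means decreasing it
        hi[which] = (max(args[which] - bump, 0.0) if which == 6
                     else min(args[which] + bump, 1.0))
        lo_s = overall_score(*args[:6], args[6], paired=True)[2]
        hi_s = overall_score(*hi[:6], hi[6], paired=True)[2]
        assert hi_s >= lo_s - 1e-12
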