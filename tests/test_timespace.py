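"""Phase space, fuzzy c-means, fuzzy recurrence plots and their entropies."""

import numpy as np
import pytest

from tftslstm.core import EmbeddingConfig
from tftslstm.timespace import (
    FCMResult,
    embed,
    frp_image_entropy,
    fuzzy_c_means,
    fuzzy_recurrence_entropy,
    fuzzy_recurrence_plot,
    recurrence_plot,
)


class TestEmbed:
    def test_scalar_embedding_is_identity(self):
        x = np.arange(7.0)
        pss = embed(x, EmbeddingConfig(1, 1))
        assert len(pss) == 7
        np.testing.assert_array_equal(pss.vectors.ravel(), x)

    def test_worked_example_d3(self):
        pss = embed(np.array([1.0, 2, 3, 4, 5]), EmbeddingConfig(3, 1))
        np.testing.assert_array_equal(pss.vectors, [[1, 2, 3], [2, 3, 4], [3, 4, 5]])

    def test_vector_count_formula(self):
        x = np.random.default_rng(0).normal(size=2000)
        assert len(embed(x, EmbeddingConfig(3, 1))) == 1998

    def test_too_short_series_names_minimum(self):
        with pytest.raises(ValueError, match="at least 21"):
            embed(np.ones(10), EmbeddingConfig(5, 5))


class TestFCM:
    def test_membership_rows_sum_to_one(self, rng):
        res = fuzzy_c_means(rng.normal(size=(40, 2)), c=3, seed=1)
        np.testing.assert_allclose(res.memberships.sum(axis=1), 1.0, atol=1e-9)

    def test_point_at_center_gets_crisp_membership(self):
        pts = np.concatenate([[0.0], np.ones(5) * 10.0, np.zeros(5)])[:, None]
        res = fuzzy_c_means(pts, c=2, seed=0)
        # some center coincides (numerically) with the repeated value 10;
        # instead test the documented convention directly on a point equal to a center
        d = np.abs(pts[:, 0][:, None] - res.centers[:, 0][None, :])
        for i in range(len(pts)):
            if d[i].min() < 1e-13:
                row = res.memberships[i]
                assert row[d[i].argmin()] == 1.0 and row.sum() == 1.0

    def test_two_separated_clusters_recovered(self, two_cluster_points):
        pts, labels = two_cluster_points
        res = fuzzy_c_means(pts, c=2, seed=3)
        top = res.memberships.max(axis=1)
        assign = res.memberships.argmax(axis=1)
        assert np.all(top >= 0.95)
        # cluster index permutation-free check: same assignment within each class
        assert len(set(assign[labels == 0])) == 1
        assert len(set(assign[labels == 1])) == 1
        assert assign[0] != assign[-1]

    def test_objective_non_increasing(self, rng):
        res = fuzzy_c_means(rng.normal(size=(60, 3)), c=4, seed=5)
        hist = res.objective_history
        assert np.all(np.diff(hist) <= 1e-8 * np.maximum(1.0, hist[:-1]))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fuzzy_c_means(np.ones((2, 1)), c=3)


class TestFRP:
    def test_worked_max_min_case(self):
        """Memberships (0.3, 0.7) and (0.6, 0.4) compose to 0.4."""
        u = np.array([[0.3, 0.7], [0.6, 0.4]])
        fcm = FCMResult(
            centers=np.zeros((2, 1)),
            memberships=u,
            n_iter=1,
            objective=0.0,
            objective_history=np.zeros(1),
        )
        r = fuzzy_recurrence_plot(fcm)
        # direct max-min evaluation
        expected = max(min(0.3, 0.6), min(0.7, 0.4))
        assert r[0, 1] == pytest.approx(expected) == pytest.approx(0.4)
        assert r[1, 0] == r[0, 1]
        np.testing.assert_array_equal(np.diag(r), [1.0, 1.0])

    def test_invariants_on_random_memberships(self, rng):
        u = rng.uniform(size=(30, 3))
        u /= u.sum(axis=1, keepdims=True)
        fcm = FCMResult(np.zeros((3, 1)), u, 1, 0.0, np.zeros(1))
        r = fuzzy_recurrence_plot(fcm)
        np.testing.assert_array_equal(np.diag(r), np.ones(30))
        np.testing.assert_allclose(r, r.T, atol=0)
        assert np.all((r >= 0) & (r <= 1))

    def test_block_structure_for_separated_clusters(self, two_cluster_points):
        pts, labels = two_cluster_points
        r = fuzzy_recurrence_plot(fuzzy_c_means(pts, c=2, seed=3))
        within = np.concatenate(
            [r[labels == 0][:, labels == 0].ravel(), r[labels == 1][:, labels == 1].ravel()]
        )
        between = r[labels == 0][:, labels == 1].ravel()
        assert within.mean() > between.mean()


class TestRecurrencePlot:
    def test_matches_brute_force(self, rng):
        pts = rng.normal(size=(20, 3))
        eps = 1.5
        rp = recurrence_plot(pts, eps)
        for i in range(20):
            for j in range(20):
                assert rp[i, j] == (np.linalg.norm(pts[i] - pts[j]) <= eps)

    def test_large_epsilon_all_ones(self, rng):
        pts = rng.normal(size=(10, 2))
        assert recurrence_plot(pts, 1e6).all()


class TestEntropies:
    def test_constant_image_entropy_zero(self):
        assert frp_image_entropy(np.full((50, 50), 0.37)) == 0.0

    def test_uniform_256_levels_gives_8_bits(self):
        vals = np.repeat(np.arange(256) / 255.0, 4)
        assert frp_image_entropy(vals.reshape(32, 32)) == pytest.approx(8.0)

    def test_image_entropy_matches_literal_histogram(self, rng):
        r = rng.uniform(size=(40, 40))
        levels = np.floor(255 * r + 0.5).astype(int)
        p = np.bincount(levels.ravel(), minlength=256) / levels.size
        literal = -sum(pk * np.log2(pk) for pk in p if pk > 0)
        assert frp_image_entropy(r) == pytest.approx(literal, abs=1e-12)

    def test_image_entropy_invariant_under_gray_relabeling(self, rng):
        levels = rng.integers(0, 256, size=(30, 30))
        perm = rng.permutation(256)
        assert frp_image_entropy(levels / 255.0) == pytest.approx(
            frp_image_entropy(perm[levels] / 255.0), abs=1e-12
        )

    def test_crisp_matrix_fuzzy_entropy_zero(self, rng):
        r = (rng.uniform(size=(25, 25)) > 0.5).astype(float)
        assert fuzzy_recurrence_entropy(r) == 0.0

    def test_all_half_matrix_is_maximal(self):
        assert fuzzy_recurrence_entropy(np.full((128, 128), 0.5)) == pytest.approx(16384.0)

    def test_fuzzy_entropy_matches_literal_double_sum(self, rng):
        r = rng.uniform(0.01, 0.99, size=(20, 20))
        literal = 0.0
        for mu in r.ravel():
            literal += -mu * np.log2(mu) - (1 - mu) * np.log2(1 - mu)
        assert fuzzy_recurrence_entropy(r) == pytest.approx(literal, rel=1e-9)

    def test_fuzzy_entropy_decreases_toward_crisp(self, rng):
        r = rng.uniform(0.05, 0.95, size=(15, 15))
        sharpened = np.where(r > 0.5, r + 0.5 * (1 - r), 0.5 * r)  # push toward {0,1}
        assert fuzzy_recurrence_entropy(sharpened) < fuzzy_recurrence_entropy(r)


def test_frp_image_export_roundtrip(tmp_path, rng):
    from PIL import Image

    from tftslstm.timespace import frp_to_image

    r = rng.uniform(size=(16, 16))
    path = tmp_path / "frp.png"
    frp_to_image(r, str(path))
    img = np.asarray(Image.open(path))
    assert img.shape == (16, 16)
    np.testing.assert_array_equal(img, 255 - np.floor(255 * r + 0.5).astype(np.uint8))
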