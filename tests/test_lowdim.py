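import numpy as np
import pytest
from scipy import stats

from hemiclass import (EmbeddingResult, compare_score_sets, embed_2d, svm_cv,
                       variance_ftest)
from conftest import random_matrix


def emb_of(coords, sides):
    return EmbeddingResult(np.asarray(coords, float), np.asarray(sides), {})


class TestEmbed:
    def test_too_few_rows(self):
        dm = random_matrix(np.random.default_rng(0), n_subjects=4, V=20)
        dm.X = dm.X[:8]; dm.side_labels = dm.side_labels[:8]
        dm.subject_ids = dm.subject_ids[:8]
        with pytest.raises(ValueError, match="at least 10"):
            embed_2d(dm)

    def test_duplicated_rows_embed_compactly(self):
        """Identical rows have no neighborhood structure; the embedding
        collapses them into a compact cloud far tighter than separated
        classes would produce."""
        rng = np.random.default_rng(0)
        dm = random_matrix(rng, n_subjects=10, V=40)
        dm.X = np.tile(dm.X[0], (20, 1))
        emb = embed_2d(dm, seed=0)
        spread = np.linalg.norm(emb.coords - emb.coords.mean(0), axis=1).max()
        assert spread < 3.0

    def test_separated_blobs_resolve(self):
        from sklearn.metrics import silhouette_score
        rng = np.random.default_rng(1)
        dm = random_matrix(rng, n_subjects=30, V=50)
        dm.X[dm.side_labels == "right"] += 4.0
        emb = embed_2d(dm, seed=0)
        assert silhouette_score(emb.coords, emb.side_labels) > 0.5

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(2)
        dm = random_matrix(rng, n_subjects=15, V=30)
        a = embed_2d(dm, seed=5)
        b = embed_2d(dm, seed=5)
        np.testing.assert_array_equal(a.coords, b.coords)


class TestSvmCV:
    def separable(self, n=60, gap=9.0, seed=0):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(n, 2))
        pts[n // 2:, 0] += gap
        sides = np.array(["left"] * (n // 2) + ["right"] * (n // 2))
        return emb_of(pts, sides)

    def test_separable_classes_perfect(self):
        rep = svm_cv(self.separable(), seed=0)
        assert rep.mean_accuracy == 1.0
        assert len(rep.fold_accuracies) == 25

    def test_permuted_labels_at_chance(self):
        rng = np.random.default_rng(3)
        emb = self.separable(n=100)
        emb.side_labels = rng.permutation(emb.side_labels)
        rep = svm_cv(emb, seed=0)
        lo, hi = stats.binom.interval(0.95, 100, 0.5)
        assert lo / 100 <= rep.mean_accuracy <= hi / 100

    def test_class_swap_swaps_precisions(self):
        emb = self.separable(n=40, gap=1.5, seed=4)
        rep = svm_cv(emb, seed=1)
        swapped = emb_of(emb.coords,
                         np.where(emb.side_labels == "left", "right", "left"))
        rep2 = svm_cv(swapped, seed=1)
        np.testing.assert_allclose(rep.precision_left, rep2.precision_right)
        np.testing.assert_allclose(rep.precision_right, rep2.precision_left)

    def test_single_class_rejected(self):
        emb = emb_of(np.random.default_rng(0).normal(size=(20, 2)),
                     np.array(["left"] * 20))
        with pytest.raises(ValueError):
            svm_cv(emb)


class TestVarianceFTest:
    def test_identical_spreads(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(30, 2))
        emb = emb_of(np.vstack([pts, pts]),
                     np.array(["left"] * 30 + ["right"] * 30))
        F, p = variance_ftest(emb, 1)
        assert F == 1.0
        assert p == pytest.approx(1.0)

    def test_scaled_copy_gives_f4(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(25, 2))
        emb = emb_of(np.vstack([pts, 2 * pts]),
                     np.array(["left"] * 25 + ["right"] * 25))
        F, _ = variance_ftest(emb, 2)
        np.testing.assert_allclose(F, 4.0)

    def test_simulation_with_sd_ratio(self):
        rng = np.random.default_rng(12345)
        left = rng.normal(0, 1.0, size=(100, 2))
        right = rng.normal(0, 1.5, size=(100, 2))
        emb = emb_of(np.vstack([left, right]),
                     np.array(["left"] * 100 + ["right"] * 100))
        F, p = variance_ftest(emb, 1)
        assert 1.6 < F < 3.2          # around the true ratio 2.25
        assert p < 0.01

    def test_zero_denominator(self):
        emb = emb_of(np.vstack([np.zeros((5, 2)), np.ones((5, 2))]),
                     np.array(["left"] * 5 + ["right"] * 5))
        with pytest.raises(ValueError, match="zero variance"):
            variance_ftest(emb, 1)


class TestCompareScoreSets:
    def test_identical_sets(self):
        t, p = compare_score_sets([0.8, 0.9, 0.85], [0.8, 0.9, 0.85])
        assert t == 0.0 and p == 1.0

    def test_df_of_two_25_fold_reports(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0.84, 0.02, 25), rng.normal(0.85, 0.02, 25)
        t, p = compare_score_sets(a, b)
        df = len(a) + len(b) - 2
        assert df == 48
        # consistency with the t distribution at that df
        np.testing.assert_allclose(p, 2 * stats.t.sf(abs(t), df), rtol=1e-10)

    def test_closed_form(self):
        t, _ = compare_score_sets([1, 2, 3], [4, 5, 6])
        np.testing.assert_allclose(t, -3.674, atol=1e-3)
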