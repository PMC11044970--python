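"""Moment-matching loss, trainer behaviour, and CV evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mopcv.deeptda import (StateCountError, StateDataset, TDATargets,
                           TrainingConfig, tda_loss, train_cv)


class TestLoss:
    def test_perfect_match_gives_zero(self):
        # per-state mean/std equal to targets exactly: symmetric pairs around
        # the centers with spread equal to the target width
        t = TDATargets((-7.0, 7.0), (0.2, 0.2))
        lat = np.array([-7.2, -6.8, 6.8, 7.2])
        lab = np.array([0, 0, 1, 1])
        assert tda_loss(lat, lab, t, alpha=1.0, beta_loss=250.0) == pytest.approx(0.0)

    def test_hand_computed_zero_sigma_batch(self):
        # all-equal latents per state: sigma_k = 0, so only the width terms
        # contribute: 2 * 250 * 0.2^2 = 20
        t = TDATargets.two_state()
        lat = np.array([-7.0, -7.0, -7.0, 7.0, 7.0, 7.0])
        lab = np.array([0, 0, 0, 1, 1, 1])
        assert tda_loss(lat, lab, t) == pytest.approx(20.0)

    @given(c=st.floats(0.1, 10.0))
    @settings(max_examples=20, deadline=None)
    def test_alpha_scales_mean_term_linearly(self, c):
        t = TDATargets((-7.0, 7.0), (0.2, 0.2))
        lat = np.array([-6.0, -6.4, 6.1, 6.9])
        lab = np.array([0, 0, 1, 1])
        base_mean_term = (tda_loss(lat, lab, t, alpha=1.0, beta_loss=1.0)
                          - tda_loss(lat, lab, t, alpha=1e-12, beta_loss=1.0))
        scaled = (tda_loss(lat, lab, t, alpha=c, beta_loss=1.0)
                  - tda_loss(lat, lab, t, alpha=1e-12, beta_loss=1.0))
        assert scaled == pytest.approx(c * base_mean_term, rel=1e-9)

    def test_loss_nonnegative(self, rng):
        t = TDATargets.three_state()
        lat = rng.normal(0, 10, 300)
        lab = rng.integers(0, 3, 300)
        assert tda_loss(lat, lab, t) >= 0

    def test_undersampled_state_raises_with_name(self):
        t = TDATargets.two_state()
        with pytest.raises(StateCountError, match="state 1"):
            tda_loss(np.array([-7.0, -7.0, 7.0]), np.array([0, 0, 1]), t)


@pytest.fixture(scope="module")
def planted_clusters():
    gen = np.random.default_rng(8)
    X = np.concatenate([gen.normal([-1.0, 0.0], 0.05, (500, 2)),
                        gen.normal([1.0, 1.0], 0.05, (500, 2))])
    y = np.repeat([0, 1], 500)
    return StateDataset(X, y)


class TestTraining:
    def test_two_cluster_parameter_recovery(self, planted_clusters):
        model = train_cv(planted_clusters, TDATargets.two_state(),
                         TrainingConfig(seed=1, max_epochs=800))
        z = model.latent(planted_clusters.X)
        y = planted_clusters.labels
        for k, target in enumerate((-7.0, 7.0)):
            assert abs(z[y == k].mean() - target) < 0.5
            assert abs(z[y == k].std() - 0.2) < 0.1

    def test_normalization_endpoints_exact(self, planted_clusters):
        model = train_cv(planted_clusters, TDATargets.two_state(),
                         TrainingConfig(seed=2, max_epochs=400))
        s = model.evaluate(planted_clusters.X)
        assert s.min() == -1.0
        assert s.max() == 1.0

    def test_monotone_state_embedding_three_clusters(self):
        gen = np.random.default_rng(3)
        centers = [[-2.0, 0.0], [0.0, 0.5], [2.0, 0.0]]
        X = np.concatenate([gen.normal(c, 0.05, (300, 2)) for c in centers])
        y = np.repeat([0, 1, 2], 300)
        model = train_cv(StateDataset(X, y), TDATargets.three_state(),
                         TrainingConfig(seed=4, max_epochs=800))
        mus = [model.state_moments[k][0] for k in range(3)]
        assert mus[0] < mus[1] < mus[2]

    def test_row_permutation_leaves_fit_equivalent(self, planted_clusters):
        # same data in a different row order must give an equally converged
        # model: both full-data losses tiny on the target scale (~49) and
        # both recover the target moments
        cfg = TrainingConfig(seed=6, max_epochs=400)
        targets = TDATargets.two_state()
        m1 = train_cv(planted_clusters, targets, cfg)
        perm = np.random.default_rng(0).permutation(len(planted_clusters.X))
        shuffled = StateDataset(planted_clusters.X[perm],
                                planted_clusters.labels[perm])
        m2 = train_cv(shuffled, targets, cfg)
        for model, ds in ((m1, planted_clusters), (m2, shuffled)):
            full = tda_loss(model.latent(ds.X), ds.labels, targets)
            assert full < 1.0
            z = model.latent(ds.X)
            for k, c in enumerate(targets.centers):
                assert abs(z[ds.labels == k].mean() - c) < 0.5

    def test_missing_target_state_rejected(self, planted_clusters):
        with pytest.raises(ValueError, match="missing"):
            train_cv(planted_clusters, TDATargets.three_state(),
                     TrainingConfig(seed=0))


class TestEvaluation:
    def test_gradient_matches_finite_differences(self, two_cluster_cv, rng):
        h = 1e-5
        for x in rng.uniform(-1.5, 1.5, size=(20, 2)):
            s, g = two_cluster_cv.value_and_gradient(x)
            for i in range(2):
                e = np.zeros(2)
                e[i] = h
                fd = (two_cluster_cv.evaluate((x + e)[None])[0]
                      - two_cluster_cv.evaluate((x - e)[None])[0]) / (2 * h)
                assert g[i] == pytest.approx(fd, rel=1e-4, abs=1e-7)

    def test_evaluation_deterministic(self, two_cluster_cv):
        x = np.array([0.3, 0.4])
        vals = {two_cluster_cv.value_and_gradient(x)[0] for _ in range(5)}
        assert len(vals) == 1

    def test_batched_matches_single(self, two_cluster_cv, rng):
        X = rng.uniform(-1, 1, size=(10, 2))
        s_batch, g_batch = two_cluster_cv.values_and_gradients(X)
        for i, x in enumerate(X):
            s, g = two_cluster_cv.value_and_gradient(x)
            assert s_batch[i] == pytest.approx(s, abs=1e-14)
            assert np.allclose(g_batch[i], g, atol=1e-14)

    def test_dimension_mismatch_rejected(self, two_cluster_cv):
        with pytest.raises(ValueError):
            two_cluster_cv.value_and_gradient(np.array([1.0, 2.0, 3.0]))

    def test_normalization_is_affine_not_idempotent(self, two_cluster_cv):
        # applying the affine map to an already-normalized value must shift it
        # again (bookkeeping guard against double normalization)
        z = 0.37
        once = two_cluster_cv.normalize(z)
        twice = two_cluster_cv.normalize(once)
        assert once != pytest.approx(twice)
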