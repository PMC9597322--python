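"""Siamese growth model: weight sharing, loss, sharpening, training."""

import numpy as np
import pytest

from ssngrowth.nn.autodiff import Tensor
from ssngrowth.siam import (ModelConfig, SiamGrowthModel, select_threshold,
                            sharpen, train_model, weighted_smooth_l1)

TINY = ModelConfig(voi_size=16, patch_size=8, embed_dim=32, depth=1, heads=2,
                   seed=0)


@pytest.fixture(scope="module")
def tiny_model():
    return SiamGrowthModel(TINY)


def rand_vois(n, size=16, seed=0):
    return np.random.default_rng(seed).normal(-650.0, 80.0, (n, size, size, size))


class TestEncodePair:
    def test_siamese_symmetry_identical_inputs(self, tiny_model):
        v = rand_vois(2)
        b = tiny_model.encode_pair(v, prior=v)
        np.testing.assert_array_equal(b.fl_t.data, b.fl_prev.data)

    def test_missing_prior_uses_substitute_exactly(self, tiny_model):
        v = rand_vois(3, seed=1)
        b = tiny_model.encode_pair(v, prior=None)
        expected = np.repeat(tiny_model.fl_substitute.data, 3, axis=0)
        np.testing.assert_array_equal(b.fl_prev.data, expected)

    def test_substitute_independent_of_current_voi(self, tiny_model):
        b1 = tiny_model.encode_pair(rand_vois(1, seed=2), prior=None)
        b2 = tiny_model.encode_pair(rand_vois(1, seed=3), prior=None)
        np.testing.assert_array_equal(b1.fl_prev.data, b2.fl_prev.data)

    def test_mixed_present_rows_scattered_correctly(self, tiny_model):
        cur = rand_vois(4, seed=4)
        pri = rand_vois(2, seed=5)
        present = np.array([True, False, True, False])
        b = tiny_model.encode_pair(cur, pri, present)
        full = tiny_model.encode_pair(
            np.asarray(pri), prior=None)  # encode priors alone
        enc = tiny_model.encoder(tiny_model._patch(pri))
        fl_real = tiny_model.encoder.local_embedding(enc).data
        np.testing.assert_array_equal(b.fl_prev.data[[0, 2]], fl_real)
        np.testing.assert_array_equal(
            b.fl_prev.data[[1, 3]],
            np.repeat(tiny_model.fl_substitute.data, 2, axis=0))

    def test_batch_permutation_invariance(self, tiny_model):
        v = rand_vois(4, seed=6)
        p = tiny_model.forward(v, v).data
        perm = np.array([2, 0, 3, 1])
        p2 = tiny_model.forward(v[perm], v[perm]).data
        np.testing.assert_allclose(p2, p[perm], rtol=1e-5, atol=1e-6)


class TestFuseAndPredict:
    def test_zeroed_head_returns_bias(self, tiny_model):
        import copy
        m = SiamGrowthModel(TINY)
        m.head.w.data = np.zeros_like(m.head.w.data)
        m.head.b.data = np.array([0.37], dtype=np.float32)
        p = m.forward(rand_vois(2, seed=7)).data
        np.testing.assert_allclose(p, 0.37, rtol=1e-6)

    def test_head_linearity(self):
        m = SiamGrowthModel(TINY)
        v = rand_vois(2, seed=8)
        p1 = m.forward(v).data.copy()
        m.head.w.data *= 2.0
        m.head.b.data *= 2.0
        p2 = m.forward(v).data
        np.testing.assert_allclose(p2, 2.0 * p1, rtol=1e-5)

    def test_all_three_embeddings_influence_output(self, tiny_model):
        rng = np.random.default_rng(9)
        from ssngrowth.siam import FeatureBundle
        embs = [Tensor(rng.normal(size=(1, 32)).astype(np.float32),
                       requires_grad=True) for _ in range(3)]
        p = tiny_model.fuse_and_predict(FeatureBundle(*embs))
        p.backward(np.ones_like(p.data))
        for e in embs:
            assert np.abs(e.grad).max() > 0


class TestWeightedSmoothL1:
    def test_zero_at_equality(self):
        assert weighted_smooth_l1(0.3, 0.3) == 0.0

    def test_alpha_branch_ratio_is_exact(self):
        hi = weighted_smooth_l1(0.25, 0.2, alpha=3.0, r=0.1, beta=1.0)
        lo = weighted_smooth_l1(0.10, 0.05, alpha=3.0, r=0.1, beta=1.0)
        assert hi / lo == pytest.approx(3.0)

    def test_linear_branch_value(self):
        # residual 2, beta 1, y below r -> |d| - beta/2 = 1.5
        assert weighted_smooth_l1(2.05, 0.05, alpha=3.0, r=0.1, beta=1.0) \
            == pytest.approx(1.5)

    def test_alpha_one_reduces_to_plain_smooth_l1(self):
        rng = np.random.default_rng(0)
        p = rng.normal(size=50)
        y = rng.normal(size=50)
        d = np.abs(p - y)
        plain = np.where(d < 1.0, 0.5 * d * d, d - 0.5)
        np.testing.assert_allclose(
            weighted_smooth_l1(p, y, alpha=1.0), plain, rtol=1e-12)

    def test_continuity_across_beta_transition(self):
        beta, y = 0.5, 0.0
        eps = 1e-7
        below = weighted_smooth_l1(y + beta - eps, y, beta=beta)
        above = weighted_smooth_l1(y + beta + eps, y, beta=beta)
        assert abs(above - below) < 1e-5

    def test_tensor_and_numpy_paths_agree(self):
        rng = np.random.default_rng(1)
        p = rng.normal(size=20)
        y = rng.normal(size=20)
        t = weighted_smooth_l1(Tensor(p), y).data
        np.testing.assert_allclose(t, weighted_smooth_l1(p, y), rtol=1e-6)

    def test_gradient_matches_finite_difference(self):
        for p0 in [0.1, 0.45, 0.55, 2.0, -1.7]:
            pt = Tensor(np.array([p0]), requires_grad=True)
            loss = weighted_smooth_l1(pt, np.array([0.2]), beta=0.5).sum()
            loss.backward()
            eps = 1e-6
            fd = (weighted_smooth_l1(p0 + eps, 0.2, beta=0.5)
                  - weighted_smooth_l1(p0 - eps, 0.2, beta=0.5)) / (2 * eps)
            assert pt.grad[0] == pytest.approx(float(fd), abs=1e-4)


class TestSharpen:
    def test_boundary_probability(self):
        assert sharpen(0.42, th=0.42) == pytest.approx(0.5)

    def test_one_tau_above_threshold(self):
        assert sharpen(0.52, th=0.42, tau=0.1) == \
            pytest.approx(1.0 / (1.0 + np.exp(-1.0)))

    def test_saturates(self):
        assert sharpen(100.0, 0.0) == pytest.approx(1.0)
        assert sharpen(-100.0, 0.0) == pytest.approx(0.0, abs=1e-12)

    def test_strictly_monotone(self):
        ps = np.linspace(-1, 2, 101)
        probs = sharpen(ps, th=0.3)
        assert np.all(np.diff(probs) > 0)

    def test_decision_depends_only_on_sign(self):
        th = 0.25
        for p in [-5.0, 0.2499, 0.25, 0.2501, 7.0]:
            assert (sharpen(p, th) >= 0.5) == (p >= th)


class TestSelectThreshold:
    def test_separated_scores_smallest_midpoint(self):
        th = select_threshold([0.0, 0.1, 0.8, 0.9], [0, 0, 1, 1])
        assert th == pytest.approx(0.45)  # midpoint of (0.1, 0.8)

    def test_all_equal_scores_j_zero(self):
        th = select_threshold([0.5] * 6, [0, 1, 0, 1, 0, 1])
        assert np.isfinite(th)

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(0)
        scores = rng.uniform(0, 1, 20)
        labels = rng.integers(0, 2, 20)
        labels[:2] = [0, 1]
        th = select_threshold(scores, labels)
        # exhaustive sweep over a fine grid must not find a better J
        y = labels.astype(int)

        def j_at(t):
            pred = scores >= t
            return (pred & (y == 1)).sum() / y.sum() \
                + (~pred & (y == 0)).sum() / (1 - y).sum() - 1

        best = max(j_at(t) for t in np.linspace(-0.1, 1.1, 5000))
        assert j_at(th) == pytest.approx(best, abs=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            select_threshold([0.1, 0.9], [1, 1])


class TestTraining:
    def test_loss_decreases_on_learnable_toy_problem(self):
        cfg = ModelConfig(voi_size=16, patch_size=8, embed_dim=32, depth=1,
                          heads=2, seed=3, warmup_epochs=1)
        m = SiamGrowthModel(cfg)
        rng = np.random.default_rng(4)
        n = 48
        y = np.r_[np.full(n // 2, 0.5), np.zeros(n // 2)]
        # growth class has a bright centre; non-growth does not
        cur = rng.normal(-850, 20, (n, 16, 16, 16))
        cur[:n // 2, 6:10, 6:10, 6:10] = -400.0
        h = train_model(m, cur, y, epochs=6)
        assert h["loss"][-1] < h["loss"][0]

    def test_training_is_seed_reproducible(self):
        cfg = ModelConfig(voi_size=16, patch_size=8, embed_dim=16, depth=1,
                          heads=2, seed=5)
        rng = np.random.default_rng(6)
        cur = rng.normal(-650, 50, (8, 16, 16, 16))
        y = rng.uniform(0, 0.5, 8)
        h1 = train_model(SiamGrowthModel(cfg), cur, y, epochs=2)
        h2 = train_model(SiamGrowthModel(cfg), cur, y, epochs=2)
        assert h1["loss"] == h2["loss"]

    def test_empty_dataset_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            train_model(tiny_model, np.empty((0, 16, 16, 16)), np.empty(0))


def test_predict_pair_consistent_with_batch_path():
    from ssngrowth import NoduleMask, VoxelGrid
    from ssngrowth.pairing import ExamPair

    m = SiamGrowthModel(TINY)
    cur = rand_vois(1, seed=20)[0]
    pri = rand_vois(1, seed=21)[0]
    mask = NoduleMask(np.ones_like(cur, bool), (1, 1, 1))
    pair = ExamPair(current=(VoxelGrid(cur, (1, 1, 1)), mask),
                    prior=(VoxelGrid(pri, (1, 1, 1)), mask),
                    interval_days=365.0)
    out = m.predict_pair(pair, th=0.1)
    p = m.predict_rates(cur[None], pri[None])[0]
    assert out.p == pytest.approx(p)
    assert out.decision == (out.prob >= 0.5)


class TestPersistence:
    def test_save_load_roundtrip(self, tmp_path, tiny_model):
        v = rand_vois(2, seed=10)
        p1 = tiny_model.predict_rates(v)
        path = tmp_path / "model"
        tiny_model.save(path)
        m2 = SiamGrowthModel.load(path)
        np.testing.assert_allclose(m2.predict_rates(v), p1, rtol=1e-6)
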