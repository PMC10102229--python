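import numpy as np
import pytest

from sycbct.nn.layers import BatchNorm3d, Conv3d, TrilinearUpsample
from sycbct.nn.network import (
    NetworkSpec,
    UNetReferenceSpec,
    build_network,
    count_parameters,
    count_parameters_unet_reference,
)
from sycbct.nn.train import (
    Adam,
    TrainConfig,
    lr_at_iteration,
    load_checkpoint,
    save_checkpoint,
    smooth_l1,
    smooth_l1_grad,
    train,
)

#: a two-stage miniature of the architecture for fast training tests
TINY = NetworkSpec(
    stem_channels=4,
    stem_kernel=3,
    stage_repeats=(1, 1),
    stage_mid_channels=(2, 4),
    stage_strides=((1, 1, 1), (2, 2, 2)),
    decoder_channels=(8, 4),
    skip_connections=frozenset({1}),
)


class TestParameterCounting:
    def test_single_conv_counts_weights_plus_bias(self):
        conv = Conv3d(1, 1, kernel=3, bias=True)
        assert sum(p.size for p in conv.params) == 28  # 27 weights + 1 bias

    def test_count_is_pure_function_of_spec(self):
        assert count_parameters(NetworkSpec()) == count_parameters(NetworkSpec())
        assert count_parameters(TINY) != count_parameters(NetworkSpec())

    def test_proposed_network_near_ten_million(self):
        assert round(count_parameters(NetworkSpec()) / 1e6) == 10

    def test_reference_unet_near_thirty_one_million(self):
        assert round(count_parameters_unet_reference() / 1e6) == 31

    def test_proposed_smaller_than_baseline(self):
        assert count_parameters(NetworkSpec()) < count_parameters_unet_reference()

    def test_built_model_matches_declared_count(self):
        model = build_network(TINY, seed=0)
        assert model.n_parameters == count_parameters(TINY)

    def test_restoring_last_skip_adds_exactly_one_connection(self):
        spec = NetworkSpec()
        restored = spec.with_last_skip()
        assert restored.skip_connections - spec.skip_connections == {0}
        assert count_parameters(restored) > count_parameters(spec)


class TestForward:
    def test_shape_contract_on_zero_patch(self):
        model = build_network(TINY, seed=0)
        out = model.forward(np.zeros((1, 1, 8, 8, 8)), train=False)
        assert out.shape == (1, 1, 8, 8, 8)
        assert np.isfinite(out).all()

    def test_full_spec_shape_contract_small_patch(self):
        # the real architecture maps a 64x64x16 patch to the same shape
        model = build_network(NetworkSpec().scaled(8), seed=0)
        out = model.forward(np.zeros((1, 1, 64, 64, 16)), train=False)
        assert out.shape == (1, 1, 64, 64, 16)
        assert np.isfinite(out).all()

    def test_indivisible_patch_rejected_naming_axis(self):
        model = build_network(TINY, seed=0)
        with pytest.raises(ValueError, match="axis y"):
            model.forward(np.zeros((1, 1, 8, 7, 8)))

    def test_skip_toggle_changes_output(self, rng):
        x = rng.normal(size=(1, 1, 8, 8, 8))
        with_skip = build_network(
            NetworkSpec(
                stem_channels=4, stem_kernel=3, stage_repeats=(1, 1),
                stage_mid_channels=(2, 4), stage_strides=((1, 1, 1), (2, 2, 2)),
                decoder_channels=(8, 4), skip_connections=frozenset({0, 1}),
            ),
            seed=0,
        )
        without = build_network(TINY, seed=0)
        assert with_skip.n_parameters > without.n_parameters
        a = with_skip.forward(x, train=False)
        b = without.forward(x, train=False)
        assert not np.allclose(a, b)

    def test_inference_deterministic(self, rng):
        model = build_network(TINY, seed=0)
        x = rng.normal(size=(8, 8, 8))
        np.testing.assert_array_equal(model.predict(x), model.predict(x))


class TestGradients:
    def test_backward_matches_finite_differences(self, rng):
        model = build_network(TINY, seed=1)
        x = rng.normal(size=(2, 1, 8, 8, 8))
        target = rng.normal(size=(2, 1, 8, 8, 8))
        model.zero_grad()
        pred = model.forward(x, train=True)
        model.backward(smooth_l1_grad(pred, target, 4.0))
        check = rng.choice(len(model.parameters()), size=4, replace=False)
        params = model.parameters()
        for pi in check:
            p = params[pi]
            i = int(rng.integers(0, p.size))
            eps = 1e-6
            orig = p.value.flat[i]
            p.value.flat[i] = orig + eps
            lp = smooth_l1(model.forward(x, train=True), target, 4.0)
            p.value.flat[i] = orig - eps
            lm = smooth_l1(model.forward(x, train=True), target, 4.0)
            p.value.flat[i] = orig
            num = (lp - lm) / (2 * eps)
            ana = p.grad.flat[i]
            assert num == pytest.approx(ana, rel=2e-3, abs=1e-9), p.name

    def test_upsample_backward_is_transpose(self, rng):
        up = TrilinearUpsample((2, 2, 1))
        x = rng.normal(size=(1, 2, 4, 4, 3))
        y = up.forward(x)
        dy = rng.normal(size=y.shape)
        dx = up.backward(dy)
        # <Ux, dy> == <x, U^T dy> for the linear operator U
        assert np.vdot(y, dy) == pytest.approx(np.vdot(x, dx), rel=1e-12)


class TestSmoothL1:
    def test_zero_at_equality(self, rng):
        v = rng.normal(size=(4, 4))
        assert smooth_l1(v, v) == 0.0

    @pytest.mark.parametrize("beta", [0.5, 1.0, 2.0])
    def test_closed_form_branches(self, beta):
        # |d| = 2*beta -> linear branch |d| - beta/2; |d| = beta/2 -> quadratic beta/8
        assert smooth_l1(np.array([2 * beta]), np.array([0.0]), beta) == pytest.approx(1.5 * beta)
        assert smooth_l1(np.array([beta / 2]), np.array([0.0]), beta) == pytest.approx(beta / 8)

    def test_limits(self, rng):
        d = rng.normal(size=100)
        zero = np.zeros(100)
        # beta -> 0: approaches mean |d|
        assert smooth_l1(d, zero, 1e-9) == pytest.approx(np.abs(d).mean(), rel=1e-6)
        # |d| << beta: approaches 0.5 * mean(d^2) / beta
        big = 1e6
        assert smooth_l1(d, zero, big) == pytest.approx(0.5 * (d**2).mean() / big, rel=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            smooth_l1(np.zeros(3), np.zeros(4))


class TestSchedule:
    @pytest.mark.parametrize("it,expected", [(0, 2.5e-4), (199, 2.5e-4), (200, 2.0e-4), (400, 1.6e-4)])
    def test_exponential_decay_closed_form(self, it, expected):
        assert lr_at_iteration(TrainConfig(), it) == pytest.approx(expected, rel=1e-12)

    def test_invalid_gamma_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(decay_gamma=1.5)


class TestTraining:
    @staticmethod
    def _identity_patches(n=48, shape=(8, 8, 8), seed=0):
        # smooth random fields: representable through the decoder's
        # half-resolution feature path (iid noise would not be)
        from scipy import ndimage

        rng = np.random.default_rng(seed)
        out = []
        for _ in range(n):
            x = ndimage.gaussian_filter(rng.normal(0, 1.0, size=shape), 2.0)
            x = x / np.abs(x).max()
            out.append((x, x))
        return out

    def test_identity_task_converges(self):
        # target = input: val loss falls an order of magnitude below the
        # untrained model's loss within 500 iterations
        spec = NetworkSpec(
            stem_channels=8, stem_kernel=3, stage_repeats=(1, 1),
            stage_mid_channels=(4, 8), stage_strides=((1, 1, 1), (2, 2, 2)),
            decoder_channels=(16, 8), skip_connections=frozenset({1}),
        )
        model = build_network(spec, seed=3)
        data = self._identity_patches()
        init = np.mean(
            [smooth_l1(model.forward(x[None, None], train=False), y[None, None]) for x, y in data[-6:]]
        )
        cfg = TrainConfig(lr0=5e-3, batch_size=8, max_iterations=500, eval_every=50, patience=10, seed=1)
        model, hist = train(model, data, cfg)
        assert hist.best_val_loss < 0.1 * init

    def test_early_stopping_contract(self):
        # patience 1 with a worsening validation signal stops at the
        # first non-improving evaluation
        model = build_network(TINY, seed=0)
        data = self._identity_patches(n=12)
        cfg = TrainConfig(
            lr0=0.0, batch_size=4, max_iterations=400, eval_every=10, patience=1, seed=0
        )
        # lr 0 freezes weights, so every evaluation after the first ties
        # (no improvement) -> stop at evaluation 2
        model, hist = train(model, data, cfg)
        assert hist.stopped_early
        assert len(hist.val_loss) == 2

    def test_training_is_deterministic(self):
        data = self._identity_patches(n=16)
        cfg = TrainConfig(batch_size=4, max_iterations=40, eval_every=20, seed=5)
        _, h1 = train(build_network(TINY, seed=2), data, cfg)
        _, h2 = train(build_network(TINY, seed=2), data, cfg)
        assert h1.train_loss == h2.train_loss
        assert h1.val_loss == h2.val_loss

    def test_empty_stream_rejected(self):
        with pytest.raises(ValueError):
            train(build_network(TINY, seed=0), [], TrainConfig())

    def test_checkpoint_round_trip(self, tmp_path, rng):
        model = build_network(TINY, seed=4)
        data = self._identity_patches(n=12)
        cfg = TrainConfig(batch_size=4, max_iterations=20, eval_every=10, seed=0)
        model, hist = train(model, data, cfg)
        save_checkpoint(tmp_path / "m.npz", model, hist)
        back, hist_d = load_checkpoint(tmp_path / "m.npz")
        x = rng.normal(size=(8, 8, 8))
        np.testing.assert_array_equal(back.predict(x), model.predict(x))
        assert hist_d["best_val_loss"] == hist.best_val_loss


class TestBatchNorm:
    def test_train_mode_normalises_batch(self, rng):
        bn = BatchNorm3d(3)
        x = rng.normal(5.0, 2.0, size=(4, 3, 4, 4, 4))
        y = bn.forward(x, train=True)
        np.testing.assert_allclose(y.mean(axis=(0, 2, 3, 4)), 0, atol=1e-10)
        np.testing.assert_allclose(y.std(axis=(0, 2, 3, 4)), 1, atol=1e-3)

    def test_eval_mode_uses_running_stats(self, rng):
        bn = BatchNorm3d(2)
        for _ in range(50):
            bn.forward(rng.normal(1.0, 1.0, size=(8, 2, 2, 2, 2)), train=True)
        y = bn.forward(np.ones((1, 2, 2, 2, 2)), train=False)
        # running mean ~1, var ~1 -> output ~0
        assert np.abs(y).max() < 0.3
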