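"""MMD, freeze/fine-tune scheduling and sequential unfreezing."""

import numpy as np
import pytest
from scipy.special import expit

from fermxfer import network as nn
from fermxfer.transfer import (
    TransferPlan,
    extract_features,
    fine_tune,
    freeze_plan,
    mmd,
    sequential_unfreeze,
)


def make_net(widths, seed=0, init_range=0.5):
    arch = nn.NetworkArch(n_inputs=widths[0], hidden_widths=tuple(widths[1:-1]),
                          n_outputs=widths[-1])
    return nn.init_params(arch, init_range, seed)


class TestExtractFeatures:
    def test_output_layer_equals_forward(self, rng):
        params = make_net([3, 4, 2], seed=1)
        X = rng.normal(size=(5, 3))
        feats = extract_features(params, X, params.arch.n_layers)
        np.testing.assert_array_equal(feats, nn.forward(params, X)[0])

    def test_zero_weight_net_features_are_half(self):
        params = make_net([2, 3, 1])
        for w in params.weights:
            w[:] = 0.0
        for b in params.biases:
            b[:] = 0.0
        feats = extract_features(params, np.ones((4, 2)), 1)
        assert np.allclose(feats, 0.5)

    def test_matches_cached_activations(self, rng):
        params = make_net([2, 4, 3, 1], seed=2)
        X = rng.normal(size=(6, 2))
        _, acts = nn.forward(params, X)
        for layer in (1, 2, 3):
            np.testing.assert_array_equal(
                extract_features(params, X, layer), acts[layer])

    def test_invalid_layer_raises(self):
        params = make_net([2, 2, 1])
        with pytest.raises(ValueError):
            extract_features(params, np.zeros((1, 2)), 4)


class TestMMD:
    def test_identical_sets_give_zero(self, rng):
        Z = rng.normal(size=(8, 3))
        assert mmd(Z, Z.copy()) == 0.0

    def test_analytic_one_dimensional(self):
        assert mmd(np.array([[0.0]]), np.array([[1.0]])) == pytest.approx(1.0)

    def test_analytic_two_dimensional(self):
        Zs = np.array([[0.0, 0.0], [2.0, 0.0]])
        Zt = np.array([[1.0, 1.0]])
        assert mmd(Zs, Zt) == pytest.approx(1.0)

    def test_nonnegative_and_zero_iff_equal_means(self, rng):
        for _ in range(20):
            Zs = rng.normal(size=(6, 4))
            Zt = rng.normal(size=(9, 4))
            v = mmd(Zs, Zt)
            assert v >= 0.0
            gap = np.linalg.norm(Zs.mean(0) - Zt.mean(0))
            assert (v < 1e-12) == (gap < 1e-6)
        # constructed equal-mean pair
        Zt = rng.normal(size=(5, 4))
        Zt_shifted = Zt - Zt.mean(0) + Zs.mean(0)
        assert mmd(Zs, Zt_shifted) == pytest.approx(0.0, abs=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError):
            mmd(np.zeros((0, 2)), np.zeros((3, 2)))
        with pytest.raises(ValueError):
            mmd(np.zeros((2, 2)), np.zeros((2, 3)))


class TestFreezePlan:
    def test_all_frozen_and_all_free(self):
        plan = TransferPlan(lr_frozen=0.0, lr_finetune=0.1)
        assert np.all(freeze_plan(4, 4, plan) == 0.0)
        assert np.all(freeze_plan(4, 0, plan) == 0.1)

    def test_split_by_depth(self):
        plan = TransferPlan(lr_frozen=0.0, lr_finetune=0.3)
        np.testing.assert_allclose(freeze_plan(5, 3, plan),
                                   [0.0, 0.0, 0.0, 0.3, 0.3])

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            freeze_plan(3, 4, TransferPlan())

    def test_frozen_rate_cannot_exceed_finetune(self):
        with pytest.raises(ValueError):
            TransferPlan(lr_frozen=0.1, lr_finetune=0.01)


class TestFineTune:
    def _data(self, rng, n=12, d=3):
        Xs = rng.normal(size=(20, d))
        Xt = rng.normal(size=(n, d)) + 0.5
        Yt = rng.uniform(0.2, 0.8, size=(n, 1))
        return Xs, Xt, Yt

    def test_frozen_layers_bit_identical(self, rng):
        params = make_net([3, 4, 4, 1], seed=3)
        Xs, Xt, Yt = self._data(rng)
        plan = TransferPlan(frozen_depth=2, lr_finetune=0.05, epochs=20)
        out, _ = fine_tune(params, Xs, Xt, Yt, plan)
        for l in range(2):
            assert np.array_equal(out.weights[l], params.weights[l])
            assert np.array_equal(out.biases[l], params.biases[l])
        assert not np.array_equal(out.weights[2], params.weights[2])

    def test_reduces_to_plain_training_bitwise(self, rng):
        params = make_net([3, 4, 1], seed=4)
        Xs, Xt, Yt = self._data(rng)
        plan = TransferPlan(frozen_depth=0, mmd_weight=0.0,
                            lr_finetune=0.05, epochs=30)
        tuned, hist = fine_tune(params, Xs, Xt, Yt, plan)
        trained, train_hist = nn.train(params, Xt, Yt, epochs=30, lr=0.05,
                                       loss="mse")
        for a, b in zip(tuned.weights, trained.weights):
            assert np.array_equal(a, b)
        assert [h[0] for h in hist] == train_hist

    def test_single_neuron_analytic_gradient(self):
        # combined objective: mse + w * mmd on the (output) feature layer
        params = make_net([1, 1])
        w0 = params.weights[0][0, 0]
        b0 = params.biases[0][0]
        xs, xt, yt = 0.4, -0.3, 0.7
        weight = 0.8
        lr = 0.1
        plan = TransferPlan(frozen_depth=0, lr_finetune=lr, epochs=1,
                            mmd_weight=weight, feature_layer=1)
        out, _ = fine_tune(params, [[xs]], [[xt]], [[yt]], plan)

        st = expit(w0 * xt + b0)
        ss = expit(w0 * xs + b0)
        # d mse / d w, plus d mmd / d w via both feature streams
        dmse_dw = 2 * (st - yt) * st * (1 - st) * xt
        diff = ss - st
        dmmd_dw = 2 * diff * (ss * (1 - ss) * xs - st * (1 - st) * xt)
        expected_w = w0 - lr * (dmse_dw + weight * dmmd_dw)
        assert out.weights[0][0, 0] == pytest.approx(expected_w, abs=1e-10)

    def test_mmd_decreases_on_mean_shifted_pair(self):
        # median relative decrease over 10 seeded runs must exceed 5 %
        drops = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            params = make_net([3, 5, 5, 1], seed=seed, init_range=0.8)
            Xs = rng.normal(size=(30, 3))
            Xt = rng.normal(size=(20, 3)) + 1.5   # covariate shift
            Yt = rng.uniform(0.2, 0.8, size=(20, 1))
            plan = TransferPlan(frozen_depth=0, lr_finetune=0.05, epochs=60,
                                mmd_weight=1.0)
            _, hist = fine_tune(params, Xs, Xt, Yt, plan)
            first_mmd = hist[0][1]
            last_mmd = hist[-1][1]
            drops.append((first_mmd - last_mmd) / first_mmd)
        assert np.median(drops) >= 0.05

    def test_zero_epochs_is_identity(self, rng):
        params = make_net([3, 2, 1], seed=5)
        Xs, Xt, Yt = self._data(rng)
        out, hist = fine_tune(params, Xs, Xt, Yt,
                              TransferPlan(epochs=0))
        assert hist == []
        for a, b in zip(out.weights, params.weights):
            assert np.array_equal(a, b)

    def test_empty_target_raises(self, rng):
        params = make_net([3, 2, 1], seed=6)
        with pytest.raises(ValueError):
            fine_tune(params, rng.normal(size=(5, 3)), np.zeros((0, 3)),
                      np.zeros((0, 1)), TransferPlan())


class TestSequentialUnfreeze:
    def _setup(self, seed=0, n=20):
        rng = np.random.default_rng(seed)
        params = make_net([3, 4, 4, 1], seed=seed)
        Xs = rng.normal(size=(30, 3))
        Xt = rng.normal(size=(n, 3))
        Yt = rng.uniform(0.2, 0.8, size=(n, 1))
        return params, Xs, Xt, Yt

    def test_infinite_tolerance_stops_after_first_stage(self):
        params, Xs, Xt, Yt = self._setup()
        plan = TransferPlan(lr_finetune=0.05, epochs=10,
                            unfreeze_tol=float("inf"))
        _, k_final, report = sequential_unfreeze(params, Xs, Xt, Yt, plan)
        assert len(report["stages"]) == 1
        assert report["stages"][0][0] == params.arch.n_layers - 1

    def test_identical_domain_stops_early(self, rng):
        # target drawn from the source distribution and already well fitted:
        # unfreezing extra layers cannot improve much
        params, Xs, _, _ = self._setup(seed=1)
        Yt_full = nn.forward(params, Xs)[0]
        plan = TransferPlan(lr_finetune=1e-4, epochs=10, unfreeze_tol=1e-3)
        _, k_final, report = sequential_unfreeze(
            params, Xs, Xs, Yt_full, plan)
        assert len(report["stages"]) <= 2
        assert k_final >= params.arch.n_layers - 2

    def test_strong_shift_unfreezes_deeper(self):
        # output-only tuning cannot fix a representation-level shift,
        # so at least one additional layer should be unfrozen
        rng = np.random.default_rng(3)
        teacher = make_net([3, 4, 4, 1], seed=10)
        params = make_net([3, 4, 4, 1], seed=3)
        Xs = rng.normal(size=(30, 3))
        Xt = rng.normal(size=(40, 3)) * 2.0 + 1.0
        Yt = nn.forward(teacher, Xt)[0]
        plan = TransferPlan(lr_finetune=0.2, epochs=150, unfreeze_tol=1e-4)
        _, k_final, report = sequential_unfreeze(params, Xs, Xt, Yt, plan,
                                                 seed=3)
        assert len(report["stages"]) >= 2
        assert k_final < params.arch.n_layers - 1

    def test_best_validation_params_returned(self):
        params, Xs, Xt, Yt = self._setup(seed=4)
        plan = TransferPlan(lr_finetune=0.05, epochs=20, unfreeze_tol=-np.inf)
        best, k_final, report = sequential_unfreeze(params, Xs, Xt, Yt, plan,
                                                    seed=4)
        vals = [v for _, v in report["stages"]]
        assert report["best_val_mse"] <= min(vals) + 1e-15

    def test_too_few_samples_raise(self):
        params, Xs, _, _ = self._setup()
        with pytest.raises(ValueError):
            sequential_unfreeze(params, Xs, np.zeros((1, 3)),
                                np.zeros((1, 1)), TransferPlan())
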