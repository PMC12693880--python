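"""Firefly operators, Mantegna Levy flight and the full search loop."""

import math

import numpy as np
import pytest

from fermxfer.firefly import (
    HyperparamEncoding,
    IFAConfig,
    attractiveness,
    brightness,
    crossover,
    crossover_prob,
    default_dnn_encoding,
    firefly_distance,
    levy_sigma,
    levy_step,
    move,
    optimize,
    perturb,
)


BOUNDS_2D = ((-5.0, 5.0), (-5.0, 5.0))


def sphere(x):
    return float((x ** 2).sum())


def rastrigin(x):
    return float(10 * len(x) + (x ** 2 - 10 * np.cos(2 * np.pi * x)).sum())


class TestOperators:
    @pytest.mark.parametrize("loss,expected", [
        (0.0, 1.0), (1.0, 0.5), (3.0, 0.25),
    ])
    def test_brightness_reciprocal_form(self, loss, expected):
        assert brightness(loss) == pytest.approx(expected)

    def test_brightness_rejects_negative_loss(self):
        with pytest.raises(ValueError):
            brightness(-0.1)

    def test_attractiveness_limits(self):
        assert attractiveness(0.0, 2.0, 1.0) == pytest.approx(2.0)
        assert attractiveness(7.0, 2.0, 0.0) == pytest.approx(2.0)
        assert attractiveness(1.0, 1.0, 1.0) == pytest.approx(math.exp(-1))

    def test_distance_euclidean(self, rng):
        assert firefly_distance(np.zeros(3), np.zeros(3)) == 0.0
        assert firefly_distance(np.array([0.0, 0.0]),
                                np.array([3.0, 4.0])) == pytest.approx(5.0)
        a, b = rng.normal(size=4), rng.normal(size=4)
        assert firefly_distance(a, b) == pytest.approx(
            math.sqrt(sum((x - y) ** 2 for x, y in zip(a, b))))
        with pytest.raises(ValueError):
            firefly_distance(np.zeros(2), np.zeros(3))

    def test_move_is_pure_random_walk_at_zero_separation(self):
        cfg = IFAConfig(bounds=BOUNDS_2D, alpha=0.2)
        x = np.array([1.0, -1.0])
        rng = np.random.default_rng(0)
        out = move(x, x.copy(), cfg, rng)
        eps = np.random.default_rng(0).uniform(0.0, 1.0, size=2)
        np.testing.assert_allclose(out, x + 0.2 * eps, atol=1e-12)

    def test_move_attraction_vanishes_at_large_gamma(self):
        cfg = IFAConfig(bounds=BOUNDS_2D, gamma=1e9, alpha=0.2)
        xi = np.array([0.0, 0.0])
        xj = np.array([3.0, 3.0])
        rng = np.random.default_rng(1)
        out = move(xi, xj, cfg, rng)
        eps = np.random.default_rng(1).uniform(0.0, 1.0, size=2)
        np.testing.assert_allclose(out, xi + 0.2 * eps, atol=1e-9)

    def test_move_reproducible_and_clipped(self):
        cfg = IFAConfig(bounds=((0.0, 1.0),), alpha=0.9)
        a = move(np.array([0.99]), np.array([0.99]), cfg,
                 np.random.default_rng(3))
        b = move(np.array([0.99]), np.array([0.99]), cfg,
                 np.random.default_rng(3))
        assert a == b
        assert a[0] <= 1.0

    def test_perturb_duplicate_population_is_identity(self):
        cfg = IFAConfig(bounds=BOUNDS_2D)
        pop = np.tile([0.5, 0.5], (4, 1))
        out = perturb(np.array([1.0, 1.0]), pop, 0, cfg,
                      np.random.default_rng(0))
        np.testing.assert_allclose(out, [1.0, 1.0])

    def test_perturb_matches_replayed_stream(self, rng):
        cfg = IFAConfig(bounds=((-10.0, 10.0),) * 2)
        pop = rng.normal(size=(5, 2))
        x = np.array([0.1, 0.2])
        out = perturb(x, pop, 2, cfg, np.random.default_rng(7))
        replay = np.random.default_rng(7)
        others = [k for k in range(5) if k != 2]
        p, q = replay.choice(others, size=2, replace=False)
        delta = replay.uniform(0.0, 1.0)
        np.testing.assert_allclose(out, np.clip(
            x + delta * (pop[p] - pop[q]), -10, 10), atol=1e-12)

    def test_perturb_needs_three_fireflies(self):
        cfg = IFAConfig(bounds=BOUNDS_2D)
        with pytest.raises(ValueError):
            perturb(np.zeros(2), np.zeros((2, 2)), 0, cfg,
                    np.random.default_rng(0))

    def test_crossover_prob_normalizes(self, rng):
        p = crossover_prob(np.array([0.25, 0.25, 0.25, 0.25]))
        np.testing.assert_allclose(p, 0.25)
        b = rng.uniform(0.1, 1.0, size=6)
        assert crossover_prob(b).sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(
            crossover_prob(np.array([0.5, 0.25, 0.25])), [0.5, 0.25, 0.25])

    def test_crossover_extreme_probabilities(self, rng):
        x = rng.normal(size=4)
        best = rng.normal(size=4)
        g = np.random.default_rng(0)
        np.testing.assert_array_equal(crossover(x, best, 0.0, g), x)
        np.testing.assert_array_equal(crossover(x, best, 1.0, g), best)

    def test_crossover_mask_replayable(self, rng):
        x = rng.normal(size=4)
        best = rng.normal(size=4)
        out = crossover(x, best, 0.5, np.random.default_rng(9))
        mask = np.random.default_rng(9).uniform(size=4) < 0.5
        np.testing.assert_array_equal(out, np.where(mask, best, x))


class TestLevy:
    def test_sigma_is_one_at_lambda_one(self):
        # Gamma(2) sin(pi/2) / (Gamma(1) * 1 * 2^0) = 1
        assert levy_sigma(1.0) == pytest.approx(1.0)

    def test_step_deterministic_for_seed(self):
        cfg = IFAConfig(bounds=BOUNDS_2D, levy_lambda=1.5)
        a = levy_step(cfg, np.random.default_rng(5))
        b = levy_step(cfg, np.random.default_rng(5))
        assert a == b

    def test_invalid_lambda_raises(self):
        with pytest.raises(ValueError):
            IFAConfig(bounds=BOUNDS_2D, levy_lambda=2.5)

    def test_tail_exponent_matches_lambda(self):
        # Hill estimator on the top order statistics of |s|
        cfg = IFAConfig(bounds=BOUNDS_2D, levy_lambda=1.5)
        s = np.abs(levy_step(cfg, np.random.default_rng(11), size=100_000))
        top = np.sort(s)[-2000:]
        hill = 1.0 / np.mean(np.log(top[1:] / top[0]))
        assert hill == pytest.approx(1.5, abs=0.2)


class TestOptimize:
    def test_sphere_converges(self):
        cfg = IFAConfig(bounds=BOUNDS_2D, n_fireflies=15, max_iter=50, seed=0)
        res = optimize(sphere, cfg)
        assert res.best_loss < 1e-2

    def test_constant_objective_flat_history(self):
        cfg = IFAConfig(bounds=BOUNDS_2D, n_fireflies=5, max_iter=10, seed=1)
        res = optimize(lambda x: 1.0, cfg)
        assert all(h == 1.0 for h in res.history)

    def test_zero_iterations_returns_best_initial(self):
        cfg = IFAConfig(bounds=BOUNDS_2D, n_fireflies=8, max_iter=0, seed=2)
        res = optimize(sphere, cfg)
        assert res.n_evals == 8
        pop = np.random.default_rng(
            np.random.SeedSequence([2])).uniform(-5, 5, size=(8, 2))
        assert res.best_loss == pytest.approx(
            min(sphere(x) for x in pop))

    def test_history_monotone_and_reproducible(self):
        cfg = IFAConfig(bounds=BOUNDS_2D, n_fireflies=10, max_iter=30, seed=3)
        r1 = optimize(rastrigin, cfg)
        r2 = optimize(rastrigin, cfg)
        assert r1.history == r2.history
        assert np.all(np.diff(r1.history) <= 0.0)

    def test_positions_respect_bounds(self):
        seen = []

        def spy(x):
            seen.append(x.copy())
            return sphere(x)

        cfg = IFAConfig(bounds=((-1.0, 2.0), (0.0, 1.0)), n_fireflies=6,
                        max_iter=15, seed=4)
        optimize(spy, cfg)
        pts = np.array(seen)
        assert pts[:, 0].min() >= -1.0 and pts[:, 0].max() <= 2.0
        assert pts[:, 1].min() >= 0.0 and pts[:, 1].max() <= 1.0

    def test_non_finite_objective_raises(self):
        cfg = IFAConfig(bounds=BOUNDS_2D, n_fireflies=4, max_iter=2, seed=5)
        with pytest.raises(FloatingPointError):
            optimize(lambda x: float("nan"), cfg)

    def test_plateau_early_stop(self):
        cfg = IFAConfig(bounds=BOUNDS_2D, n_fireflies=5, max_iter=200, seed=6,
                        plateau_patience=3, plateau_tol=1e-3)
        res = optimize(lambda x: 1.0, cfg)
        assert res.n_iter < 200

    def test_improved_beats_plain_on_multimodal(self):
        # the added perturbation/crossover/Levy stages should not hurt:
        # compare median final loss over seeds on sphere and Rastrigin
        for fn in (sphere, rastrigin):
            ifa, fa = [], []
            for seed in range(10):
                base = dict(bounds=BOUNDS_2D, n_fireflies=15, max_iter=60,
                            seed=seed)
                ifa.append(optimize(fn, IFAConfig(**base)).best_loss)
                fa.append(optimize(fn, IFAConfig(
                    **base, use_perturbation=False, use_crossover=False,
                    use_levy=False)).best_loss)
            assert np.median(ifa) <= np.median(fa)


class TestHyperparamEncoding:
    def test_decode_encode_round_trip(self):
        enc = default_dnn_encoding()
        values = {"lr": 1e-3, "width": 8, "init_range": 0.5, "epochs": 300}
        pos = enc.encode(values)
        decoded = enc.decode(pos)
        assert decoded["lr"] == pytest.approx(1e-3)
        assert decoded["width"] == 8
        assert decoded["epochs"] == 300

    def test_decode_respects_ranges(self, rng):
        enc = default_dnn_encoding()
        lows = np.array([d[1] for d in enc.dims])
        highs = np.array([d[2] for d in enc.dims])
        for _ in range(20):
            hp = enc.decode(rng.uniform(lows, highs))
            assert 1e-4 <= hp["lr"] <= 10 ** -0.5
            assert 6 <= hp["width"] <= 16
            assert 200 <= hp["epochs"] <= 1000

    def test_center_is_midpoint(self):
        enc = HyperparamEncoding(dims=(("a", 0.0, 2.0, "linear"),
                                       ("b", 0.0, 4.0, "int")))
        c = enc.center()
        assert c == {"a": 1.0, "b": 2}

    def test_invalid_dims_raise(self):
        with pytest.raises(ValueError):
            HyperparamEncoding(dims=(("a", 1.0, 0.0, "linear"),))
        with pytest.raises(ValueError):
            HyperparamEncoding(dims=(("a", 0.0, 1.0, "exp"),))
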