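"""WOA, DE and hybrid search behavior."""

import math

import numpy as np
import pytest

from entroseg.objectives import compute_histogram, make_objective
from entroseg.optimizers import (
    OptimizerConfig,
    a_schedule,
    de_crossover,
    de_mutation,
    de_selection,
    decode_thresholds,
    optimize,
    woa_move,
)
from entroseg.synthetic import generate_image, random_mixture

from conftest import make_hist

LN2 = math.log(2.0)


class SeqRng:
    """Deterministic stand-in for a Generator: returns a scripted sequence."""

    def __init__(self, seq):
        self.seq = list(seq)

    def random(self):
        return self.seq.pop(0)

    def uniform(self, lo, hi):
        return self.seq.pop(0)  # scripted value used verbatim


class TestASchedule:
    def test_linear_decay_endpoints(self):
        assert a_schedule(0, 500) == 2.0
        assert a_schedule(500, 500) == 0.0

    def test_confinement_at_half_budget(self):
        """|A| <= a, so A is confined to [-1, 1] from iteration 250 of 500."""
        ts = [t for t in range(501) if a_schedule(t, 500) <= 1.0]
        assert min(ts) == 250

    def test_amplitude_midpoint(self):
        a = 1.0
        r = 0.5
        assert 2 * a * r - a == 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            a_schedule(-1, 500)
        with pytest.raises(ValueError):
            a_schedule(501, 500)


class TestDecode:
    def test_sorts_and_rounds(self):
        assert list(decode_thresholds([200.6, 10.2])) == [10, 201]

    def test_duplicates_pushed_up(self):
        assert list(decode_thresholds([50.0, 50.4, 49.9])) == [50, 51, 52]

    def test_spills_down_at_255(self):
        assert list(decode_thresholds([255.0, 255.0, 255.0])) == [253, 254, 255]

    def test_always_valid(self, rng):
        for _ in range(200):
            k = int(rng.integers(1, 13))
            pos = rng.uniform(1, 255, size=k)
            th = decode_thresholds(pos)
            assert th[0] >= 1 and th[-1] <= 255 and np.all(np.diff(th) > 0)


class TestWoaMove:
    def test_encircling_fixed_point(self):
        """x = x* with C = 1 reproduces x* exactly in the encircling branch."""
        x = np.array([100.0])
        # p=0.4 -> encircle path; r_A=0.75 with a=1 -> A=0.5; r_C=0.5 -> C=1
        new = woa_move(x, x, x, a=1.0, rng=SeqRng([0.4, 0.75, 0.5]))
        assert np.allclose(new, x)

    def test_spiral_fixed_point(self):
        """D' = 0 makes the spiral move return x* for any spiral angle."""
        x = np.array([42.0])
        new = woa_move(x, x, np.array([7.0]), a=0.5, rng=SeqRng([0.9, 0.3]))
        assert np.allclose(new, x)

    def test_encircling_hand_evaluation(self):
        # a=1, p=0.2; r_A=0.75 -> A=0.5; r_C=0.5 -> C=1
        # x' = x* - A|C x* - x| = 50 - 0.5|50 - 30| = 40
        new = woa_move(np.array([30.0]), np.array([50.0]), np.array([0.0]),
                       a=1.0, rng=SeqRng([0.2, 0.75, 0.5]))
        assert np.allclose(new, [40.0])

    def test_search_hand_evaluation(self):
        # a=2, p=0.2; r_A=1.0 -> A=2 (|A|>=1); r_C=0.25 -> C=0.5
        # x' = x_r - A|C x_r - x| = 30 - 2|15 - 10| = 20
        new = woa_move(np.array([10.0]), np.array([200.0]), np.array([30.0]),
                       a=2.0, rng=SeqRng([0.2, 1.0, 0.25]))
        assert np.allclose(new, [20.0])

    def test_spiral_hand_evaluation(self):
        # p=0.9 -> spiral; l=0.5: x' = |x*-x| e^{b l} cos(2 pi l) + x*
        x, xs, l, b = 10.0, 20.0, 0.5, 1.0
        expected = abs(xs - x) * math.exp(b * l) * math.cos(2 * math.pi * l) + xs
        new = woa_move(np.array([x]), np.array([xs]), np.array([0.0]),
                       a=1.0, rng=SeqRng([0.9, l]), b=b, lower=-100, upper=255)
        assert np.allclose(new, [expected])

    def test_replays_real_rng_stream(self):
        """The move consumes draws in the documented order (p, then branch draws)."""
        x, xs, xr = np.array([30.0]), np.array([90.0]), np.array([150.0])
        a = 1.5
        new = woa_move(x, xs, xr, a, np.random.default_rng(7))
        replay = np.random.default_rng(7)
        p = replay.random()
        if p >= 0.5:
            l = replay.uniform(-1, 1)
            expected = abs(xs[0] - x[0]) * math.exp(l) * math.cos(2 * math.pi * l) + xs[0]
        else:
            A = 2 * a * replay.random() - a
            C = 2 * replay.random()
            ref = xs if abs(A) < 1 else xr
            expected = ref[0] - A * abs(C * ref[0] - x[0])
        assert np.allclose(new, [np.clip(expected, 1, 255)])

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            woa_move(np.zeros(2), np.zeros(3), np.zeros(2), 1.0, np.random.default_rng(0))

    def test_result_respects_bounds(self, rng):
        for _ in range(100):
            k = int(rng.integers(1, 6))
            new = woa_move(rng.uniform(1, 255, k), rng.uniform(1, 255, k),
                           rng.uniform(1, 255, k), float(rng.uniform(0, 2)), rng)
            assert np.all(new >= 1.0) and np.all(new <= 255.0)


class TestDeOperators:
    def test_zero_difference_vector(self):
        m = de_mutation(np.array([33.0]), np.array([50.0]), np.array([50.0]), 0.5)
        assert np.allclose(m, [33.0])

    def test_direct_evaluation(self):
        m = de_mutation(np.array([10.0]), np.array([20.0]), np.array([12.0]), 0.5)
        assert np.allclose(m, [14.0])

    def test_clamping(self):
        m = de_mutation(np.array([250.0]), np.array([255.0]), np.array([1.0]), 0.5)
        assert np.allclose(m, [255.0])

    def test_crossover_extremes(self):
        rng = np.random.default_rng(0)
        x = np.arange(4.0)
        m = x + 100
        assert np.allclose(de_crossover(x, m, 1.0, rng), m)
        assert np.allclose(de_crossover(x, m, 0.0, np.random.default_rng(0)), x)

    def test_crossover_pattern_matches_replayed_draws(self):
        x = np.zeros(4)
        m = np.ones(4)
        trial = de_crossover(x, m, 0.9, np.random.default_rng(5))
        draws = np.random.default_rng(5).random(4)
        assert np.array_equal(trial, np.where(draws <= 0.9, 1.0, 0.0))

    def test_selection_contract(self):
        f = lambda v: float(v[0])
        assert de_selection(np.array([1.0]), np.array([2.0]), f)[0] == 2.0
        assert de_selection(np.array([2.0]), np.array([1.0]), f)[0] == 2.0
        # ties keep the incumbent
        assert de_selection(np.array([3.0]), np.array([3.0]), lambda v: 0.0)[0] == 3.0


class TestOptimize:
    @pytest.mark.parametrize("algorithm", ["woa_de", "woa", "de"])
    def test_constant_objective_flat_history(self, algorithm):
        cfg = OptimizerConfig(n_agents=6, max_iter=20, seed=3)
        res = optimize(lambda th: 2.5, K=2, config=cfg, algorithm=algorithm)
        assert res.best_fitness == 2.5
        assert np.all(res.history == 2.5)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_reaches_known_optimum(self, seed):
        h = make_hist([1, 1, 1, 1])
        cfg = OptimizerConfig(n_agents=30, max_iter=50, seed=seed)
        res = optimize(make_objective(h, "kapur"), K=1, config=cfg)
        assert res.best_fitness == pytest.approx(2 * LN2, rel=1e-12)

    @pytest.mark.parametrize("algorithm", ["woa_de", "woa", "de"])
    def test_history_non_decreasing_and_thresholds_valid(self, algorithm):
        img = generate_image(random_mixture(9, n_modes=3, size=(64, 64)))
        obj = make_objective(compute_histogram(img), "kapur")
        res = optimize(obj, K=4, config=OptimizerConfig(max_iter=60, seed=4),
                       algorithm=algorithm)
        assert np.all(np.diff(res.history) >= 0)
        assert res.best_fitness == res.history[-1]
        th = res.best_thresholds
        assert th[0] >= 1 and th[-1] <= 255 and np.all(np.diff(th) > 0)

    def test_equal_fitness_population_only_takes_woa_moves(self):
        """f_i <= f_bar for every agent when the landscape is flat."""
        cfg = OptimizerConfig(n_agents=8, max_iter=10, seed=0)
        res = optimize(lambda th: 1.0, K=2, config=cfg, algorithm="woa_de")
        assert res.n_de_moves == 0
        assert res.n_woa_moves == 8 * 10

    def test_woa_matches_standalone_algorithm_trace(self):
        """The woa mode reproduces a from-scratch transcription of the plain
        whale update loop, draw for draw, on a 1-D objective."""
        h = make_hist({10: 3, 60: 5, 200: 2})
        obj = make_objective(h, "kapur")
        cfg = OptimizerConfig(n_agents=5, max_iter=30, seed=11)
        res = optimize(obj, K=1, config=cfg, algorithm="woa")

        rng = np.random.default_rng(11)
        n, d = cfg.n_agents, 1
        X = rng.uniform(1, 255, size=(n, d))
        fit = np.array([obj(decode(x)) for x, decode in
                        zip(X, [lambda p: np.array([int(np.floor(np.sort(p)[0] + 0.5))])] * n)])
        best = float(fit.max())
        best_pos = X[int(np.argmax(fit))].copy()
        history = []
        for t in range(cfg.max_iter):
            a = 2 - 2 * t / cfg.max_iter
            X_old = X.copy()
            x_star = best_pos.copy()
            for i in range(n):
                i_rand = int(rng.integers(n))
                p = rng.random()
                if p >= 0.5:
                    l = rng.uniform(-1, 1)
                    new = np.abs(x_star - X_old[i]) * np.exp(l) * np.cos(2 * np.pi * l) + x_star
                else:
                    A = 2 * a * rng.random() - a
                    C = 2 * rng.random()
                    ref = x_star if abs(A) < 1 else X_old[i_rand]
                    new = ref - A * np.abs(C * ref - X_old[i])
                new = np.clip(new, 1, 255)
                X[i] = new
                th = np.array([int(np.clip(np.floor(new[0] + 0.5), 1, 255))])
                fit[i] = obj(th)
                if fit[i] > best:
                    best = float(fit[i])
                    best_pos = X[i].copy()
            history.append(best)
        assert np.allclose(res.history, history)
        assert res.best_fitness == pytest.approx(best)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            OptimizerConfig(n_agents=3)
        with pytest.raises(ValueError):
            OptimizerConfig(crossover_rate=1.5)
        with pytest.raises(ValueError):
            optimize(lambda th: 0.0, K=0)
        with pytest.raises(ValueError):
            optimize(lambda th: 0.0, K=1, algorithm="pso")
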