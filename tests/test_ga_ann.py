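import math

import numpy as np
import pytest
from scipy.optimize import least_squares

import ndvigap as ng
from ndvigap import ga_ann


def loop_forward(genes, h, x):
    """Independent explicit-loop forward pass for the 1-H-1 tanh network."""
    t = 2.0 * x - 1.0
    total = genes[3 * h]
    for j in range(h):
        total += genes[2 * h + j] * math.tanh(genes[j] * t + genes[h + j])
    return min(1.0, max(0.0, total))


def make_pairs(x, y):
    return ng.pairs_from_arrays(np.asarray(x), np.asarray(y))


class TestNetworkSpec:
    def test_weight_count_is_3h_plus_1(self):
        assert ng.NetworkSpec(n_hidden=5).weight_count == 16
        assert ng.NetworkSpec(n_hidden=3).weight_count == 10

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            ng.NetworkSpec(n_hidden=0)


class TestForward:
    def test_zero_network_outputs_constant(self):
        m = ng.GAANNModel(spec=ng.NetworkSpec(), weights=np.zeros(16))
        xs = np.array([0.0, 0.3, 1.0])
        np.testing.assert_array_equal(ng.forward(m, xs), np.zeros(3))

    def test_batch_consistency_and_shape(self, rng):
        m = ng.GAANNModel(spec=ng.NetworkSpec(), weights=rng.normal(0, 1, 16))
        a, b = 0.2, 0.7
        batch = ng.forward(m, np.array([[a, b]]))
        assert batch.shape == (1, 2)
        assert batch[0, 0] == ng.forward(m, a)
        assert batch[0, 1] == ng.forward(m, b)

    def test_matches_explicit_loop_oracle(self, rng):
        for h in (3, 5, 8):
            genes = rng.normal(0, 2, 3 * h + 1)
            m = ng.GAANNModel(spec=ng.NetworkSpec(n_hidden=h), weights=genes)
            for x in rng.uniform(0, 1, 10):
                assert ng.forward(m, float(x)) == pytest.approx(
                    loop_forward(genes, h, x), abs=1e-12
                )

    def test_output_clamped_to_unit_interval(self, rng):
        m = ng.GAANNModel(spec=ng.NetworkSpec(), weights=rng.normal(0, 10, 16))
        y = ng.forward(m, rng.uniform(0, 1, 100))
        assert np.all((y >= 0) & (y <= 1))

    def test_non_finite_input_rejected(self):
        m = ng.GAANNModel(spec=ng.NetworkSpec(), weights=np.zeros(16))
        with pytest.raises(ValueError, match="finite"):
            ng.forward(m, np.nan)


class TestFitness:
    def test_exact_reproduction_hits_epsilon_ceiling(self):
        # zero network predicts 0 everywhere; targets 0 -> zero MSE
        pairs = make_pairs([0.1, 0.9], [0.0, 0.0])
        f = ga_ann.fitness(np.zeros(16), pairs, ng.NetworkSpec())
        assert f == pytest.approx(1e12, rel=1e-9)

    def test_smaller_mse_gives_strictly_larger_fitness(self, rng):
        pairs = make_pairs(rng.uniform(0, 1, 50), rng.uniform(0, 1, 50))
        spec = ng.NetworkSpec()
        good = np.zeros(16)
        good[-1] = pairs.fine.mean()  # constant at the target mean
        bad = np.zeros(16)
        bad[-1] = pairs.fine.mean() + 0.5
        assert ga_ann.fitness(good, pairs, spec) > ga_ann.fitness(bad, pairs, spec)

    def test_matches_loop_mse_oracle(self, rng):
        x = rng.uniform(0, 1, 10)
        y = rng.uniform(0, 1, 10)
        genes = rng.normal(0, 1, 16)
        # oracle: explicit loop over the 10 pairs with the unclamped output
        def raw(xv):
            t = 2 * xv - 1
            return genes[15] + sum(
                genes[10 + j] * math.tanh(genes[j] * t + genes[5 + j])
                for j in range(5)
            )
        mse = sum((raw(xi) - yi) ** 2 for xi, yi in zip(x, y)) / 10
        f = ga_ann.fitness(genes, make_pairs(x, y), ng.NetworkSpec())
        assert f == pytest.approx(1.0 / (mse + 1e-12), rel=1e-9)

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError):
            ga_ann.fitness(np.zeros(16), make_pairs([], []), ng.NetworkSpec())


class TestRouletteSelect:
    def test_single_chromosome_always_selected(self):
        pop = np.array([[1.0, 2.0]])
        sel = ga_ann.roulette_select(pop, np.array([1.0]), 5, seed=0)
        assert (sel == pop[0]).all()

    def test_frequencies_match_exact_proportions(self):
        pop = np.array([[0.0], [1.0]])
        sel = ga_ann.roulette_select(pop, np.array([3.0, 1.0]), 40_000, seed=1)
        freq_first = np.mean(sel[:, 0] == 0.0)
        sigma = math.sqrt(0.75 * 0.25 / 40_000)
        assert abs(freq_first - 0.75) < 3 * sigma

    def test_equal_fitnesses_select_uniformly(self):
        pop = np.arange(4).reshape(4, 1).astype(float)
        sel = ga_ann.roulette_select(pop, np.ones(4), 40_000, seed=2)
        counts = np.bincount(sel[:, 0].astype(int), minlength=4) / 40_000
        sigma = math.sqrt(0.25 * 0.75 / 40_000)
        assert np.all(np.abs(counts - 0.25) < 3 * sigma)

    def test_nonpositive_fitness_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            ga_ann.roulette_select(np.zeros((2, 3)), np.array([1.0, 0.0]), 1, seed=0)


class TestCrossover:
    def test_zero_probability_copies_parents(self, rng):
        a, b = rng.normal(0, 1, 16), rng.normal(0, 1, 16)
        ca, cb = ga_ann.crossover(a, b, probability=0.0, seed=0)
        np.testing.assert_array_equal(ca, a)
        np.testing.assert_array_equal(cb, b)

    def test_forced_two_point_swap(self, rng):
        a, b = rng.normal(0, 1, 16), rng.normal(0, 1, 16)
        ca, cb = ga_ann.crossover(a, b, probability=1.0, seed=0, cut_points=(2, 5))
        np.testing.assert_array_equal(ca[2:5], b[2:5])
        np.testing.assert_array_equal(ca[:2], a[:2])
        np.testing.assert_array_equal(ca[5:], a[5:])
        np.testing.assert_array_equal(cb[2:5], a[2:5])

    @pytest.mark.parametrize("ctype", ["two-point", "single-point", "uniform"])
    def test_allele_conservation(self, rng, ctype):
        """Every offspring gene exists at the same locus in one parent."""
        for seed in range(20):
            a, b = rng.normal(0, 1, 16), rng.normal(0, 1, 16)
            ca, cb = ga_ann.crossover(a, b, probability=1.0, seed=seed,
                                      crossover_type=ctype)
            for child in (ca, cb):
                assert np.all((child == a) | (child == b))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            ga_ann.crossover(np.zeros(4), np.zeros(5))


class TestMutate:
    def test_zero_probability_is_identity(self, rng):
        c = rng.normal(0, 1, 16)
        np.testing.assert_array_equal(ga_ann.mutate(c, probability=0.0, seed=0), c)

    def test_gaussian_moments(self):
        """Forced mutation: perturbation mean ~0 and variance ~sigma^2."""
        sigma, n = 0.7, 10_000
        base = np.zeros(16)
        deltas = np.array([
            ga_ann.mutate(base, probability=1.0, sigma=sigma, seed=s)
            for s in range(n)
        ]).ravel()
        m = len(deltas)
        assert abs(deltas.mean()) < 3 * sigma / math.sqrt(m)
        var_sd = sigma**2 * math.sqrt(2.0 / (m - 1))
        assert abs(deltas.var() - sigma**2) < 3 * var_sd

    def test_mutated_gene_fraction(self):
        n = 10_000
        base = np.zeros(16)
        hits = np.array([
            ga_ann.mutate(base, probability=0.2, sigma=1.0, seed=s) != 0
            for s in range(n)
        ])
        frac = hits.mean()
        sigma = math.sqrt(0.2 * 0.8 / hits.size)
        assert abs(frac - 0.2) < 3 * sigma

    def test_bad_sigma(self):
        with pytest.raises(ValueError):
            ga_ann.mutate(np.zeros(4), sigma=0.0)


@pytest.mark.filterwarnings("ignore:elite_count")
class TestEvolve:
    def test_best_fitness_trace_non_decreasing(self, power_law_pairs):
        for seed in range(3):
            res = ga_ann.evolve(power_law_pairs, seed=seed)
            trace = res.fitness_trace
            assert all(a <= b + 1e-9 for a, b in zip(trace, trace[1:]))

    def test_generation_cap_respected(self, power_law_pairs):
        res = ga_ann.evolve(power_law_pairs, seed=0)
        assert res.model.training_summary["generations_run"] <= 50

    def test_bitwise_determinism(self, power_law_pairs):
        a = ga_ann.evolve(power_law_pairs, seed=7)
        b = ga_ann.evolve(power_law_pairs, seed=7)
        assert a.model.weights.tobytes() == b.model.weights.tobytes()
        assert a.fitness_trace == b.fitness_trace

    def test_insufficient_pairs_rejected(self):
        pairs = ng.pairs_from_arrays(np.linspace(0, 1, 5), np.linspace(0, 1, 5))
        with pytest.raises(ValueError, match="pairs"):
            ga_ann.evolve(pairs)

    def test_elite_warning_emitted(self, power_law_pairs):
        with pytest.warns(UserWarning, match="elite"):
            ga_ann.evolve(power_law_pairs, seed=0)


@pytest.mark.filterwarnings("ignore:elite_count")
class TestRefine:
    def test_zero_steps_is_identity(self, power_law_pairs):
        model = ga_ann.evolve(power_law_pairs, seed=0).model
        out = ga_ann.refine(model, power_law_pairs, steps=0)
        np.testing.assert_array_equal(out.weights, model.weights)

    def test_never_increases_training_mse(self, power_law_pairs):
        for method in ("lbfgs", "gd"):
            model = ga_ann.evolve(power_law_pairs, seed=1).model
            before = ga_ann._mse(model.weights, model.spec,
                                 power_law_pairs.coarse, power_law_pairs.fine)
            out = ga_ann.refine(model, power_law_pairs, steps=100, method=method)
            after = ga_ann._mse(out.weights, model.spec,
                                power_law_pairs.coarse, power_law_pairs.fine)
            assert after <= before + 1e-15

    def test_noiseless_linear_target_fit(self):
        """On y = 0.5x with no noise the refined net matches an independent
        least-squares fit of the same architecture to high accuracy."""
        x = np.linspace(0, 1, 200)
        y = 0.5 * x
        pairs = ng.pairs_from_arrays(x, y)
        model = ga_ann.refine(ga_ann.evolve(pairs, seed=0).model, pairs, steps=2000)
        ours = math.sqrt(ga_ann._mse(model.weights, model.spec, x, y))
        assert ours <= 1e-3

        # independent oracle: scipy least_squares on an independently coded net
        def resid(genes):
            t = 2 * x - 1
            pred = genes[15] + sum(
                genes[10 + j] * np.tanh(genes[j] * t + genes[5 + j])
                for j in range(5)
            )
            return pred - y

        oracle = least_squares(resid, np.full(16, 0.1))
        oracle_rmse = math.sqrt(np.mean(oracle.fun**2))
        assert ours <= max(oracle_rmse * 10, 1e-3)


@pytest.mark.filterwarnings("ignore:elite_count")
class TestTrain:
    def test_identity_mapping_learned(self):
        x = np.linspace(0, 1, 400)
        res = ga_ann.train(ng.pairs_from_arrays(x, x), seed=0)
        assert res.validation_metrics["rmse"] <= 0.01

    def test_constant_target_learned(self):
        gen = np.random.default_rng(0)
        x = gen.uniform(0, 1, 400)
        res = ga_ann.train(ng.pairs_from_arrays(x, np.full(400, 0.4)), seed=0)
        pred = ng.forward(res.model, np.linspace(0, 1, 50))
        assert np.all(np.abs(pred - 0.4) <= 0.01)

    def test_monotone_distortion_recovery(self, power_law_pairs):
        res = ga_ann.train(power_law_pairs, seed=0)
        assert res.validation_metrics["rmse"] <= max(1.5 * 0.02, 0.02)

    def test_validation_set_is_held_out(self, power_law_pairs):
        res = ga_ann.train(power_law_pairs, seed=3)
        assert res.validation_metrics["n"] == 200  # 20% of 1000

    def test_refine_flag_recorded(self, power_law_pairs):
        on = ga_ann.train(power_law_pairs, seed=0)
        off = ga_ann.train(power_law_pairs, seed=0, refine_flag=False)
        assert on.model.training_summary["refined"]
        assert not off.model.training_summary["refined"]


class TestSerialization:
    def test_model_round_trip_reproduces_predictions_bitwise(self, tmp_path,
                                                             trained_model):
        path = tmp_path / "model.json"
        ga_ann.save_model(trained_model, path)
        back = ga_ann.load_model(path)
        x = np.linspace(0, 1, 101)
        np.testing.assert_array_equal(ng.forward(back, x),
                                      ng.forward(trained_model, x))
        assert back.weights.tobytes() == trained_model.weights.tobytes()

    def test_wrong_format_rejected(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text('{"format": "something-else"}')
        with pytest.raises(ValueError, match="model file"):
            ga_ann.load_model(p)
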