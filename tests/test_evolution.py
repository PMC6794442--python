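"""Genetic algorithm: fitness, selection, exchange, reproducibility."""

import numpy as np
import pytest

from stereoevo import (
    EvolutionConfig,
    evolve_absolute,
    exchange_parameters,
    lifetime_error,
    mutate_population,
    place_monocular_pairs,
    roulette_select,
    success_scores,
)
from stereoevo.fixtures import constant_disparity_bank, constant_genome, zero_gain_genome
from stereoevo.network import init_population, param_bounds
from stereoevo.stimuli import make_absolute_bank, make_relative_bank


@pytest.fixture(scope="module")
def assembly():
    return place_monocular_pairs(stage="absolute")


class TestLifetimeError:
    def test_perfect_network_scores_zero(self, assembly):
        bank = constant_disparity_bank(0.1, n=6)
        assert lifetime_error(constant_genome(0.1), bank, assembly) == pytest.approx(0.0)

    def test_single_trial_absolute_difference(self, assembly):
        bank = constant_disparity_bank(0.12, n=1)
        assert lifetime_error(constant_genome(0.05), bank, assembly) == pytest.approx(0.07)

    def test_constant_zero_responder_expected_error(self, assembly):
        # labels uniform on (0, 0.18]: expected summed error 200 * 0.09 = 18
        bank = make_absolute_bank(200, "far", seed=31)
        err = lifetime_error(zero_gain_genome(), bank, assembly)
        assert err == pytest.approx(18.0, abs=2.5)

    def test_near_banks_train_on_magnitude(self, assembly):
        bank = constant_disparity_bank(0.1, n=4, polarity="near")
        assert np.all(bank.labels < 0)
        assert lifetime_error(constant_genome(0.1), bank, assembly) == pytest.approx(0.0)

    def test_stage_bank_mismatch_rejected(self, assembly):
        bank = make_relative_bank(5, seed=0)
        with pytest.raises(ValueError):
            lifetime_error(constant_genome(0.1), bank, assembly)


class TestSuccessScores:
    def test_max_minus_error_rule(self):
        scores = success_scores(np.array([0.1, 0.3, 0.6]))
        np.testing.assert_allclose(scores, [0.5, 0.3, 0.0])
        probs = scores / scores.sum()
        np.testing.assert_allclose(probs, [0.625, 0.375, 0.0])

    def test_equal_errors_fall_back_to_uniform(self):
        np.testing.assert_allclose(success_scores(np.array([2.0, 2.0, 2.0])), [1, 1, 1])

    def test_single_individual(self):
        scores = success_scores(np.array([5.0]))
        assert roulette_select(scores, 10, np.random.default_rng(0)).tolist() == [0] * 10

    def test_negative_errors_rejected(self):
        with pytest.raises(ValueError):
            success_scores(np.array([0.1, -0.2]))


class TestRouletteSelect:
    def test_degenerate_wheel_always_selects_winner(self):
        idx = roulette_select(np.array([1.0, 0.0, 0.0]), 50, np.random.default_rng(1))
        assert np.all(idx == 0)

    def test_frequencies_match_analytic_probabilities(self):
        # scores (2, 1, 1) -> probabilities (0.5, 0.25, 0.25); 3 s.e. bands
        n = 100_000
        idx = roulette_select(np.array([2.0, 1.0, 1.0]), n, np.random.default_rng(2))
        freq = np.bincount(idx, minlength=3) / n
        for f, p in zip(freq, (0.5, 0.25, 0.25)):
            assert abs(f - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_same_seed_gives_identical_draws(self):
        scores = np.array([0.3, 0.9, 0.1, 0.5])
        a = roulette_select(scores, 100, np.random.default_rng(3))
        b = roulette_select(scores, 100, np.random.default_rng(3))
        np.testing.assert_array_equal(a, b)

    def test_negative_scores_rejected(self):
        with pytest.raises(ValueError):
            roulette_select(np.array([0.5, -0.1]), 5, np.random.default_rng(4))


class TestExchange:
    def test_zero_probability_is_identity(self):
        params = init_population("second_order", "far", 40, np.random.default_rng(5))
        before = params.copy()
        exchange_parameters(params, 0.0, np.random.default_rng(6))
        np.testing.assert_array_equal(params, before)

    def test_population_multiset_is_conserved(self):
        rng = np.random.default_rng(7)
        params = init_population("second_order", "far", 60, rng)
        # the multiset of values in every (connection, parameter) slot across
        # the population is invariant under swapping
        before = np.sort(params.reshape(60, 16), axis=0).copy()
        for _ in range(5):
            exchange_parameters(params, 0.8, rng)
        after = np.sort(params.reshape(60, 16), axis=0)
        np.testing.assert_array_equal(before, after)

    def test_touched_fraction_tracks_probability(self):
        # initiators arise at rate p; partners add at most as many again
        p = 0.4
        rng = np.random.default_rng(8)
        fractions = []
        for _ in range(40):
            params = init_population("second_order", "far", 200, rng)
            before = params.copy()
            exchange_parameters(params, p, rng)
            changed = np.any(params != before, axis=(1, 2))
            fractions.append(changed.mean())
        mean_frac = float(np.mean(fractions))
        assert p * 0.9 <= mean_frac <= 2 * p

    def test_genome_list_interface(self):
        from stereoevo import init_genome

        rng = np.random.default_rng(9)
        pop = [init_genome("second_order", "far", rng) for _ in range(10)]
        out = exchange_parameters(pop, 1.0, rng)
        assert len(out) == 10
        assert all(g.stage == "second_order" for g in out)


class TestMutation:
    def test_respects_bounds(self):
        rng = np.random.default_rng(10)
        params = init_population("third_order", "rel_far", 100, rng)
        for _ in range(200):
            mutate_population(params, rng, probability=0.5, scale=0.2, stage="third_order")
        bounds = param_bounds("third_order")
        for k, name in enumerate(("gain", "slope", "offset")):
            lo, hi = bounds[name]
            assert params[:, :, k].min() >= lo
            assert params[:, :, k].max() <= hi
        assert set(np.unique(params[:, :, 3])) <= {-1.0, 1.0}

    def test_zero_probability_is_identity(self):
        rng = np.random.default_rng(11)
        params = init_population("second_order", "far", 20, rng)
        before = params.copy()
        mutate_population(params, rng, probability=0.0)
        np.testing.assert_array_equal(params, before)


class TestEvolveLoops:
    def test_run_is_bit_reproducible(self):
        cfg = EvolutionConfig(
            n_populations=2, population_size=25, lifetime_stimuli=20,
            generations=4, master_seed=77,
        )
        a = evolve_absolute(cfg, "far")
        b = evolve_absolute(cfg, "far")
        np.testing.assert_array_equal(a.traces, b.traces)
        for pa, pb in zip(a.final_params, b.final_params):
            np.testing.assert_array_equal(pa, pb)
        assert a.eval_bank_seeds == b.eval_bank_seeds

    def test_zero_generations_reports_random_baseline(self):
        cfg = EvolutionConfig(
            n_populations=1, population_size=50, lifetime_stimuli=100,
            generations=0, master_seed=5,
        )
        run = evolve_absolute(cfg, "far")
        assert run.traces.shape == (1, 0)
        # random weak genomes respond near zero: mean error per trial near
        # the mean training disparity (0.09 deg)
        assert run.final_errors[0].mean() / 100 == pytest.approx(0.09, abs=0.03)

    def test_result_roundtrips_through_disk(self, tmp_path):
        cfg = EvolutionConfig(
            n_populations=1, population_size=10, lifetime_stimuli=10,
            generations=2, master_seed=3,
        )
        run = evolve_absolute(cfg, "near")
        run.save(tmp_path / "run")
        from stereoevo import RunResult

        loaded = RunResult.load(tmp_path / "run")
        np.testing.assert_allclose(loaded.traces, run.traces, atol=1e-12)
        np.testing.assert_allclose(loaded.final_params[0], run.final_params[0])
        assert loaded.best_genomes == run.best_genomes
        assert loaded.config == run.config

    def test_relative_requires_frozen_genomes(self):
        cfg = EvolutionConfig(
            n_populations=1, population_size=10, lifetime_stimuli=10,
            generations=1, master_seed=3,
        )
        from stereoevo import evolve_relative

        with pytest.raises(ValueError):
            evolve_relative(cfg, "rel_far", [])

    def test_error_trace_declines_in_the_long_run(self, far_run):
        # smoothed median-population trend: late error well below early error
        trace = np.median(far_run.traces, axis=0)
        early = trace[:50].mean()
        late = trace[-50:].mean()
        assert late < 0.6 * early
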