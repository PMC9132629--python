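"""Intelligent Water Drops dynamics, wrapper fitness, and search behavior."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from emodrop.iwd import (
    Drop,
    FeatureSubset,
    FitnessConfig,
    IWDParams,
    construct_solution,
    fitness,
    global_soil_update,
    hud_scores,
    init_state,
    local_soil_update,
    run_iwd,
    select_features,
    soil_delta,
    transition_probabilities,
    update_velocity,
)
from emodrop.vectorize import FeatureMatrix


class TestInitState:
    def test_all_edges_at_init_soil(self):
        state = init_state(5, IWDParams(init_soil=1000.0, subset_size=2))
        off_diag = ~np.eye(6, dtype=bool)
        assert (state.soil[off_diag] == 1000.0).all()
        assert state.best_subset is None

    def test_zero_features_is_an_error(self):
        with pytest.raises(ValueError):
            init_state(0, IWDParams(subset_size=1))

    def test_subset_larger_than_feature_count_is_an_error(self):
        with pytest.raises(ValueError, match="exceeds"):
            init_state(3, IWDParams(subset_size=5))


class TestTransitionProbabilities:
    def test_equal_soils_give_uniform(self):
        params = IWDParams(subset_size=2)
        state = init_state(4, params)
        cands, probs = transition_probabilities(Drop(), state.start_node, state, params)
        assert cands.tolist() == [0, 1, 2, 3]
        np.testing.assert_allclose(probs, 0.25)

    def test_low_soil_edge_dominates(self):
        params = IWDParams(subset_size=1, epsilon_p=0.01)
        state = init_state(2, params)
        state.soil[2, 0] = state.soil[0, 2] = 0.0
        state.soil[2, 1] = state.soil[1, 2] = 1000.0
        _, probs = transition_probabilities(Drop(), state.start_node, state, params)
        expected = (1 / 0.01) / ((1 / 0.01) + (1 / 1000.01))
        assert probs[0] == pytest.approx(expected)
        assert expected > 0.9999

    def test_single_candidate_gets_probability_one(self):
        params = IWDParams(subset_size=2)
        state = init_state(3, params)
        cands, probs = transition_probabilities(Drop(visited=[0, 2]), 2, state, params)
        assert cands.tolist() == [1]
        assert probs.tolist() == [1.0]

    def test_no_candidates_is_an_error(self):
        params = IWDParams(subset_size=2)
        state = init_state(2, params)
        with pytest.raises(ValueError):
            transition_probabilities(Drop(visited=[0, 1]), 1, state, params)

    def test_probabilities_sum_to_one_for_random_soils(self):
        rng = np.random.default_rng(0)
        params = IWDParams(subset_size=3)
        for _ in range(50):
            state = init_state(6, params)
            soil = rng.normal(0, 100, size=(7, 7))
            state.soil = (soil + soil.T) / 2
            _, probs = transition_probabilities(Drop(visited=[1]), 0, state, params)
            assert probs.sum() == pytest.approx(1.0, abs=1e-12)
            assert (probs >= 0).all()


class TestVelocityAndSoil:
    def test_velocity_closed_form_without_soil_term(self):
        params = IWDParams(a_v=2.0, b_v=4.0, c_v=0.0, subset_size=1)
        assert update_velocity(Drop(velocity=1.0), 123.0, params) == pytest.approx(1.5)

    def test_velocity_hand_example(self):
        params = IWDParams(a_v=1.0, b_v=1.0, c_v=1.0, subset_size=1)
        assert update_velocity(Drop(velocity=4.0), 0.0, params) == pytest.approx(5.0)

    def test_velocity_increment_vanishes_for_huge_soil(self):
        params = IWDParams(subset_size=1)
        assert update_velocity(Drop(velocity=2.0), 1e12, params) == pytest.approx(2.0)

    def test_soil_delta_ignores_time_when_c_zero(self):
        params = IWDParams(a_s=3.0, b_s=2.0, c_s=0.0, subset_size=1)
        assert soil_delta(Drop(velocity=0.5), 7.0, params) == pytest.approx(1.5)

    def test_soil_delta_hand_example(self):
        params = IWDParams(a_s=1.0, b_s=0.01, c_s=1.0, subset_size=1)
        assert soil_delta(Drop(velocity=1.0), 2.0, params) == pytest.approx(1 / 4.01)

    def test_faster_drop_erodes_more(self):
        params = IWDParams(subset_size=1)
        slow = soil_delta(Drop(velocity=1.0), 1.0, params)
        fast = soil_delta(Drop(velocity=4.0), 1.0, params)
        assert fast > slow

    def test_zero_velocity_is_an_error(self):
        with pytest.raises(ValueError):
            soil_delta(Drop(velocity=0.0), 1.0, IWDParams(subset_size=1))

    def test_local_update_hand_example(self):
        params = IWDParams(rho_n=0.9, subset_size=1)
        state = init_state(2, params)
        state.soil[0, 1] = state.soil[1, 0] = 100.0
        drop = Drop()
        local_soil_update(state, (0, 1), 10.0, params, drop)
        assert state.soil[0, 1] == pytest.approx(1.0)  # 0.1*100 - 0.9*10
        assert state.soil[1, 0] == pytest.approx(1.0)
        assert drop.carried_soil == pytest.approx(10.0)

    def test_repeated_traversal_decreases_soil(self):
        params = IWDParams(rho_n=0.5, subset_size=1)
        state = init_state(2, params)
        prev = state.soil[0, 1]
        for _ in range(5):
            local_soil_update(state, (0, 1), 1.0, params)
            assert state.soil[0, 1] < prev
            prev = state.soil[0, 1]

    def test_global_update_hand_example(self):
        params = IWDParams(rho_iwd=0.9, subset_size=3)
        state = init_state(3, params)
        state.soil[:] = 10.0
        np.fill_diagonal(state.soil, 0.0)
        drop = Drop(visited=[0, 1, 2], carried_soil=18.0)
        global_soil_update(state, drop, FeatureSubset((0, 1, 2), fitness=0.5), params)
        # every tour edge: 1.9*10 - 0.9*(18/2) = 10.9
        for i, j in [(3, 0), (0, 1), (1, 2)]:
            assert state.soil[i, j] == pytest.approx(10.9)
        assert state.soil[0, 2] == pytest.approx(10.0)  # not on the tour

    def test_worse_iteration_best_keeps_incumbent(self):
        params = IWDParams(subset_size=2)
        state = init_state(3, params)
        state.best_subset = FeatureSubset((0, 1), fitness=0.9)
        drop = Drop(visited=[1, 2], carried_soil=1.0)
        global_soil_update(state, drop, FeatureSubset((1, 2), fitness=0.5), params)
        assert state.best_subset.indices == (0, 1)

    def test_tie_keeps_incumbent(self):
        params = IWDParams(subset_size=2)
        state = init_state(3, params)
        state.best_subset = FeatureSubset((0, 1), fitness=0.5)
        global_soil_update(
            state, Drop(visited=[1, 2]), FeatureSubset((1, 2), fitness=0.5), params
        )
        assert state.best_subset.indices == (0, 1)


class TestConstructSolution:
    def test_forced_tour_visits_everything(self):
        params = IWDParams(subset_size=4, seed=0)
        state = init_state(4, params)
        sub = construct_solution(state, params, np.random.default_rng(99))
        assert sub.indices == (0, 1, 2, 3)

    def test_deterministic_under_seed(self):
        params = IWDParams(subset_size=3)
        subs = []
        for _ in range(2):
            state = init_state(8, params)
            subs.append(construct_solution(state, params, np.random.default_rng(5)))
        assert subs[0].indices == subs[1].indices

    def test_velocity_non_decreasing_within_tour(self):
        params = IWDParams(subset_size=5, a_v=1.0)
        state = init_state(6, params)
        rng = np.random.default_rng(1)
        from emodrop.iwd import _run_drop

        drop = _run_drop(state, params, rng, np.ones(6), 5)
        assert drop.velocity > params.init_vel

    def test_reinforced_edges_are_followed(self):
        """Tours overwhelmingly pick the pair whose edges carry deeply eroded soil."""
        params = IWDParams(subset_size=2, epsilon_p=1.0)
        hits = 0
        rng = np.random.default_rng(42)
        for _ in range(1000):
            state = init_state(4, params)
            for i, j in [(4, 0), (4, 1), (0, 1)]:
                state.soil[i, j] = state.soil[j, i] = -500.0
            if construct_solution(state, params, rng).indices == (0, 1):
                hits += 1
        assert hits / 1000 > 0.95

    def test_uniform_sampling_with_equal_soils(self):
        """Fresh equal-soil states sample m-subsets uniformly (chi-square)."""
        params = IWDParams(subset_size=2)
        rng = np.random.default_rng(7)
        combos = list(itertools.combinations(range(5), 2))
        counts = dict.fromkeys(combos, 0)
        n_tours = 10_000
        for _ in range(n_tours):
            state = init_state(5, params)
            counts[construct_solution(state, params, rng).indices] += 1
        _, p = sps.chisquare(list(counts.values()))
        assert p > 0.001


class TestFitness:
    def test_perfectly_separable_scores_one(self, toy_matrix):
        fit = fitness(FeatureSubset((0, 1)), toy_matrix, FitnessConfig(seed=0))
        assert fit == pytest.approx(1.0)

    def test_shuffled_labels_score_near_half(self, toy_matrix):
        """Permutation baseline: destroying the labels leaves chance accuracy."""
        rng = np.random.default_rng(0)
        fits = []
        for s in range(20):
            shuffled = FeatureMatrix(
                values=toy_matrix.values,
                labels=rng.permutation(toy_matrix.labels),
                class_names=toy_matrix.class_names,
                feature_names=toy_matrix.feature_names,
            )
            fits.append(fitness(FeatureSubset((0, 1, 2)), shuffled, FitnessConfig(seed=s)))
        assert abs(np.mean(fits) - 0.5) < 0.1

    def test_size_penalty_arithmetic(self, toy_matrix):
        cfg0 = FitnessConfig(lambda_penalty=0.0, seed=0)
        cfg = FitnessConfig(lambda_penalty=0.5, seed=0)
        full = FeatureSubset((0, 1, 2))
        assert fitness(full, toy_matrix, cfg0) - fitness(full, toy_matrix, cfg) == (
            pytest.approx(0.5)
        )

    def test_all_zero_columns_still_score(self, toy_matrix):
        zeroed = FeatureMatrix(
            values=np.zeros_like(toy_matrix.values),
            labels=toy_matrix.labels,
            class_names=toy_matrix.class_names,
            feature_names=toy_matrix.feature_names,
        )
        fit = fitness(FeatureSubset((0, 1)), zeroed, FitnessConfig(seed=0))
        assert 0.0 <= fit <= 1.0


class TestHud:
    def test_label_associated_feature_has_lowest_hud(self, toy_matrix):
        hud = hud_scores(toy_matrix)
        assert hud.min() == 0.0
        assert hud[2] > hud[0] and hud[2] > hud[1]
        assert ((hud >= 0) & (hud <= 1)).all()


class TestSelectFeatures:
    def test_zero_iterations_is_an_error(self, toy_matrix):
        with pytest.raises(ValueError, match="n_iterations"):
            select_features(toy_matrix, IWDParams(subset_size=2, n_iterations=0))

    def test_forced_full_subset(self, toy_matrix):
        params = IWDParams(subset_size=3, n_iterations=2, n_drops=2, seed=0)
        best = select_features(toy_matrix, params)
        assert best.indices == (0, 1, 2)
        assert best.fitness == pytest.approx(
            fitness(FeatureSubset((0, 1, 2)), toy_matrix, FitnessConfig(seed=0))
        )

    def test_best_fitness_is_monotone_across_iterations(self, oracle_landscape):
        params = IWDParams(subset_size=3, n_iterations=30, n_drops=5, seed=2)
        _, trace, _ = run_iwd(oracle_landscape, params)
        best = [row["best_fitness"] for row in trace]
        assert best == sorted(best)
        assert all(row["best_fitness"] >= row["iteration_best_fitness"] for row in trace)

    def test_matches_exhaustive_optimum(self, oracle_landscape):
        """The search finds the unique optimum of all 120 subsets of size 3."""
        cfg = FitnessConfig(seed=0)

        def fit_fn(sub):
            return fitness(sub, oracle_landscape, cfg)

        scores = {
            combo: fit_fn(FeatureSubset(combo))
            for combo in itertools.combinations(range(10), 3)
        }
        optimum = max(scores.values())
        assert max(scores, key=scores.get) == (1, 4, 7)
        best, _, _ = run_iwd(
            oracle_landscape, IWDParams(subset_size=3, seed=0), fitness_fn=fit_fn
        )
        assert best.fitness == pytest.approx(optimum)
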