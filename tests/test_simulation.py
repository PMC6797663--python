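"""Virtual agents, response simulation, and worker-hour accounting."""

import numpy as np
import pytest
from scipy import stats

from psychembed import simulation
from psychembed.kernel import KernelParams
from psychembed.likelihood import (
    PsychEmbedding,
    log_likelihood,
    outcome_distribution,
)
from psychembed.simulation import (
    StrategyRun,
    VirtualAgent,
    generate_gaussian_ground_truth,
    hours_to_criterion,
    random_docket,
    run_collection_strategy,
    simulate,
    simulate_response,
    worker_hours,
)
from psychembed.trials import TrialConfiguration, validate


class TestGroundTruthGenerator:
    def test_study_scale_point_cloud(self):
        emb = generate_gaussian_ground_truth(100, 4, 0.03, seed=0)
        assert emb.z.shape == (100, 4)
        # chi-square bounds: sample variance of 100 iid normals
        assert np.all(emb.z.var(axis=0) > 0.02)
        assert np.all(emb.z.var(axis=0) < 0.04)

    def test_accepts_complementary_attention_rows(self):
        weights = np.array([[1.8, 1.8, 0.2, 0.2], [0.2, 0.2, 1.8, 1.8]])
        emb = generate_gaussian_ground_truth(10, 4, 0.03, weights=weights,
                                             seed=1)
        np.testing.assert_allclose(emb.weights.sum(axis=1), 4.0)
        assert emb.n_group == 2

    def test_deterministic_given_seed(self):
        a = generate_gaussian_ground_truth(20, 3, 0.03, seed=5)
        b = generate_gaussian_ground_truth(20, 3, 0.03, seed=5)
        np.testing.assert_array_equal(a.z, b.z)

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            generate_gaussian_ground_truth(1, 2, 0.03)
        with pytest.raises(ValueError):
            generate_gaussian_ground_truth(5, 2, 0.0)


class TestSimulateResponse:
    def test_near_deterministic_regime(self, rng):
        # one reference essentially on top of the query, huge beta
        z = np.array([[0.0, 0.0], [0.001, 0.0], [2.0, 0.0], [0.0, 2.0]])
        emb = PsychEmbedding(z, KernelParams(beta=200.0, tau=1.0))
        agent = VirtualAgent(emb)
        config = TrialConfiguration(3, 1, True)
        for _ in range(100):
            row, outcome = simulate_response(agent, 0, [1, 2, 3], config, rng)
            assert outcome == 0
            assert row[1] == 1

    def test_empirical_frequencies_match_distribution(self, rng):
        z = np.random.default_rng(0).normal(0, 0.25, size=(6, 2))
        emb = PsychEmbedding(z, KernelParams(beta=4.0))
        agent = VirtualAgent(emb)
        config = TrialConfiguration(4, 1, True)
        refs = [1, 2, 3, 4]
        expected = outcome_distribution(emb, 0, refs, config)
        n_draw = 20000
        counts = np.zeros(len(expected))
        for _ in range(n_draw):
            _, outcome = simulate_response(agent, 0, refs, config, rng)
            counts[outcome] += 1
        assert stats.chisquare(counts, expected * n_draw).pvalue > 0.001

    def test_reproducible_given_rng(self):
        z = np.random.default_rng(0).normal(0, 0.25, size=(6, 2))
        agent = VirtualAgent(PsychEmbedding(z, KernelParams(beta=4.0)))
        config = TrialConfiguration(4, 2, True)
        a = simulate_response(agent, 0, [1, 2, 3, 4], config,
                              np.random.default_rng(3))
        b = simulate_response(agent, 0, [1, 2, 3, 4], config,
                              np.random.default_rng(3))
        np.testing.assert_array_equal(a[0], b[0])

    def test_batch_simulation_rows_are_valid_and_tagged(self, rng):
        truth = generate_gaussian_ground_truth(
            12, 2, 0.03,
            weights=np.array([[1.5, 0.5], [0.5, 1.5]]), seed=4,
        )
        agent = VirtualAgent(truth, group_id=1)
        docket = random_docket(12, 40, TrialConfiguration(8, 2, True), rng)
        obs = simulate(agent, docket, rng)
        assert validate(obs) is obs
        assert np.all(obs.group_id == 1)
        # same stimuli per row, reordered
        for i in range(obs.n_trial):
            assert set(obs.references(i)) == set(docket.references(i))

    def test_true_embedding_beats_scrambled_on_agent_data(self, rng):
        truth = generate_gaussian_ground_truth(10, 2, 0.03, seed=9)
        agent = VirtualAgent(truth)
        docket = random_docket(10, 300, TrialConfiguration(8, 2, True), rng)
        obs = simulate(agent, docket, rng)
        scrambled = PsychEmbedding(
            truth.z[rng.permutation(10)], truth.kernel, truth.weights
        )
        assert log_likelihood(truth, obs) > log_likelihood(scrambled, obs)


class TestWorkerHours:
    def test_zero_trials(self):
        assert worker_hours({(2, 1, True): 0}) == 0.0

    def test_reference_conversions(self):
        assert worker_hours({(2, 1, True): 1000}) == pytest.approx(0.85)
        assert worker_hours({(8, 2, True): 1000}) == pytest.approx(
            2.4944, abs=1e-4
        )

    def test_mixed_configurations_sum(self):
        total = worker_hours(
            {TrialConfiguration(2, 1, True): 100,
             TrialConfiguration(8, 2, True): 100}
        )
        assert total == pytest.approx((100 * 3.06 + 100 * 8.98) / 3600)

    def test_unknown_configuration_rejected(self):
        with pytest.raises(KeyError):
            worker_hours({(5, 1, True): 10})

    def test_custom_rates(self):
        assert worker_hours({(5, 1, True): 60}, rates={(5, 1, True): 60.0}
                            ) == pytest.approx(1.0)


class TestStrategyRun:
    def test_non_increasing_counts_rejected(self):
        with pytest.raises(ValueError):
            StrategyRun("random-2c1", [10, 10], [0.1, 0.2], [0.5, 0.6])

    def test_hours_to_criterion_interpolates(self):
        run = StrategyRun("random-2c1", [100, 200], [1.0, 2.0], [0.90, 0.96])
        assert hours_to_criterion(run, 0.95) == pytest.approx(1.0 + 5.0 / 6.0)
        assert hours_to_criterion(run, 0.80) == 1.0
        assert np.isnan(hours_to_criterion(run, 0.99))


class TestRunCollectionStrategy:
    def test_zero_criterion_stops_after_first_increment(self):
        truth = generate_gaussian_ground_truth(15, 2, 0.03, seed=30)
        run = run_collection_strategy(
            VirtualAgent(truth), "random-8c2", criterion=0.0, seed=31
        )
        assert len(run.n_trials) == 1
        assert run.reached

    def test_curve_improves_and_reaches_criterion(self):
        truth = generate_gaussian_ground_truth(15, 2, 0.03, seed=32)
        run = run_collection_strategy(
            VirtualAgent(truth), "random-8c2", criterion=0.9, seed=33
        )
        assert run.reached
        assert run.correlation[-1] >= 0.9
        assert run.correlation[-1] > run.correlation[0]
        np.testing.assert_allclose(
            run.hours, run.n_trials * 8.98 / 3600
        )

    def test_run_fully_determined_by_seed(self):
        truth = generate_gaussian_ground_truth(15, 2, 0.03, seed=34)
        runs = [
            run_collection_strategy(
                VirtualAgent(truth), "random-8c2", criterion=0.8, seed=35
            )
            for _ in range(2)
        ]
        np.testing.assert_array_equal(runs[0].n_trials, runs[1].n_trials)
        np.testing.assert_array_equal(runs[0].correlation,
                                      runs[1].correlation)

    def test_unknown_strategy_rejected(self):
        truth = generate_gaussian_ground_truth(10, 2, 0.03, seed=0)
        with pytest.raises(ValueError):
            run_collection_strategy(VirtualAgent(truth), "oracle", seed=1)


@pytest.fixture(scope="module")
def two_group_truth():
    weights = np.array([[1.5, 0.5], [0.5, 1.5]])
    return generate_gaussian_ground_truth(12, 2, 0.03, weights=weights,
                                          seed=40)


class TestRunGroupStudy:
    def test_balanced_mixing_contract(self, two_group_truth):
        res = simulation.run_group_study(
            two_group_truth, "shared", novice_fraction=0.5, criterion=0.85,
            seed=41, batch=60, max_batches=20,
        )
        run = res.runs["shared"]
        novice_frac = res.novice_hours / res.total_hours
        # binomial noise around 0.5 for the realized mixture
        assert abs(novice_frac - 0.5) < 3 * 0.5 / np.sqrt(run.n_trials[-1])

    def test_criterion_met_for_both_groups(self, two_group_truth):
        res = simulation.run_group_study(
            two_group_truth, "shared", criterion=0.85, seed=42, batch=60,
            max_batches=25,
        )
        assert res.reached
        assert res.runs["novice_r"][-1] >= 0.85
        assert res.runs["expert_r"][-1] >= 0.85

    def test_independent_reports_both_groups(self, two_group_truth):
        res = simulation.run_group_study(
            two_group_truth, "independent", criterion=0.85, seed=43,
            batch=60, max_batches=25,
        )
        assert res.reached
        assert res.total_hours == pytest.approx(
            res.novice_hours + res.expert_hours
        )

    def test_single_group_truth_rejected(self):
        truth = generate_gaussian_ground_truth(10, 2, 0.03, seed=44)
        with pytest.raises(ValueError):
            simulation.run_group_study(truth, "shared", seed=0)
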