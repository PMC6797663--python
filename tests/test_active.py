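"""Active selection: information gain oracle, KL priorities, suggestion."""

import numpy as np
import pytest

from psychembed import simulation
from psychembed.active import (
    expected_information_gain,
    gaussian_kl,
    information_gains,
    query_priority,
    select_references,
    suggest_trials,
)
from psychembed.inference import fit
from psychembed.kernel import KernelParams, similarity, weighted_minkowski
from psychembed.likelihood import PsychEmbedding, outcome_probabilities
from psychembed.posterior import PosteriorSamples, sample_posterior
from psychembed.trials import TrialConfiguration, validate


def brute_force_mutual_information(per_sample_probs):
    """MI of (sample, outcome) with uniform sample weights, by enumeration."""
    p = np.asarray(per_sample_probs, dtype=float)
    n_sample, n_outcome = p.shape
    joint = p / n_sample  # p(s, y) with p(s) uniform
    marginal_y = joint.sum(axis=0)
    mi = 0.0
    for s in range(n_sample):
        for y in range(n_outcome):
            if joint[s, y] > 0:
                mi += joint[s, y] * np.log(
                    joint[s, y] / ((1.0 / n_sample) * marginal_y[y])
                )
    return mi


def build_case(zq_per_sample, refs, kernel):
    """Posterior samples moving only the query; fixed references."""
    n_sample = len(zq_per_sample)
    n = 1 + len(refs)
    samples = np.empty((n_sample, n, 2))
    for s, zq in enumerate(zq_per_sample):
        samples[s, 0] = zq
        samples[s, 1:] = refs
    emb = PsychEmbedding(samples[0], kernel)
    return PosteriorSamples(samples), emb


class TestExpectedInformationGain:
    def test_degenerate_posterior_gives_zero_gain(self, rng):
        z = rng.normal(0, 0.2, (6, 2))
        emb = PsychEmbedding(z, KernelParams(beta=5.0))
        samples = PosteriorSamples(np.repeat(z[None], 8, axis=0))
        score = expected_information_gain(
            0, [1, 2, 3], TrialConfiguration(3, 1, True), samples, emb
        )
        assert score.info_gain == pytest.approx(0.0, abs=1e-12)
        assert score.n_outcome == 3

    def test_hand_computed_two_sample_binary_case(self):
        """Per-sample outcome probs (.9,.1) and (.1,.9) give 0.36806 nats."""
        kernel = KernelParams(beta=1.0, tau=1.0, gamma=0.0)
        # place query so that exp(-d1)/ (exp(-d1)+exp(-d2)) = 0.9 / 0.1
        delta = np.log(9.0)  # d2 - d1
        refs = np.array([[0.0, 0.0], [delta + 1.0 - 1.0, 0.0]])
        # solve positions: query at x -> distances |x|, |x - r2x|
        r2 = delta + 0.2
        refs = np.array([[0.0, 0.0], [r2, 0.0]])
        x1 = (r2 - delta) / 2.0  # d1 = x1, d2 = r2 - x1 = x1 + delta
        x2 = (r2 + delta) / 2.0  # mirrored: probs flip
        samples, emb = build_case([[x1, 0.0], [x2, 0.0]], refs, kernel)
        score = expected_information_gain(
            0, [1, 2], TrialConfiguration(2, 1, True), samples, emb
        )
        expected = (np.log(2.0)) - (
            -(0.9 * np.log(0.9) + 0.1 * np.log(0.1))
        )
        assert score.info_gain == pytest.approx(0.36806, abs=1e-4)
        assert score.info_gain == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("config", [
        TrialConfiguration(2, 1, True),
        TrialConfiguration(3, 1, True),
        TrialConfiguration(3, 2, False),
    ])
    def test_matches_brute_force_mutual_information(self, config, rng):
        """Oracle identity on <=3-sample, <=3-outcome instances."""
        for _ in range(5):
            n_sample = int(rng.integers(2, 4))
            zqs = rng.normal(0, 0.5, (n_sample, 2))
            refs = rng.normal(0, 0.5, (config.n_reference, 2))
            kernel = KernelParams(beta=2.0)
            samples, emb = build_case(list(zqs), refs, kernel)
            score = expected_information_gain(
                0, np.arange(1, config.n_reference + 1), config, samples, emb
            )
            per_sample = np.array([
                outcome_probabilities(
                    similarity(
                        weighted_minkowski(zq, refs, rho=2.0), kernel
                    ),
                    config,
                )
                for zq in zqs
            ])
            per_sample /= per_sample.sum(axis=1, keepdims=True)
            assert score.info_gain == pytest.approx(
                brute_force_mutual_information(per_sample), abs=1e-12
            )

    def test_bounded_by_log_outcomes_and_nonnegative(self, rng):
        z = rng.normal(0, 0.3, (10, 2))
        emb = PsychEmbedding(z, KernelParams(beta=5.0))
        tensor = z[None] + rng.normal(0, 0.1, (30, 10, 2))
        samples = PosteriorSamples(tensor)
        for config in [TrialConfiguration(2, 1, True),
                       TrialConfiguration(8, 2, True)]:
            refs = np.arange(1, config.n_reference + 1)
            score = expected_information_gain(0, refs, config, samples, emb)
            assert -1e-9 <= score.info_gain <= np.log(config.n_outcome)


class TestQueryPriority:
    def test_closed_form_unit_gaussians(self):
        assert gaussian_kl([0.0], [[1.0]], [1.0], [[1.0]]) == (
            pytest.approx(0.5)
        )

    def test_identical_posteriors_give_uniform_weights(self, rng):
        cloud = rng.normal(0, 0.1, (40, 1, 2))
        samples = PosteriorSamples(np.repeat(cloud, 5, axis=1))
        np.testing.assert_allclose(query_priority(samples), np.full(5, 0.2))

    def test_inflated_covariance_stimulus_gets_maximum_weight(self, rng):
        # tight posteriors far apart on a square (symmetric geometry, so
        # summed mean distances match across stimuli); one inflated x100
        means = 3.0 * np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        draws = rng.standard_normal((200, 4, 2))
        scale = np.full(4, 0.01)
        scale[2] *= 10.0  # covariance inflated x100
        tensor = means[None] + draws * scale[None, :, None]
        weights = query_priority(PosteriorSamples(tensor))
        assert np.argmax(weights) == 2

    def test_weights_normalized(self, rng):
        tensor = rng.normal(0, 0.2, (50, 7, 2))
        weights = query_priority(PosteriorSamples(tensor))
        assert weights.sum() == pytest.approx(1.0)
        assert np.all(weights >= 0)


class TestSelectReferences:
    def test_forced_when_exactly_enough_stimuli(self, rng):
        z = np.random.default_rng(0).normal(0, 0.3, (4, 2))
        emb = PsychEmbedding(z, KernelParams(beta=5.0))
        refs = select_references(1, emb, TrialConfiguration(3, 1, True), rng)
        assert sorted(refs) == [0, 2, 3]

    def test_similar_neighbor_heavily_favored(self, rng):
        # stimulus 1 is ~100x more similar to the query than the rest
        z = np.array(
            [[0.0, 0.0], [0.05, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0],
             [-1.0, 0.5]]
        )
        emb = PsychEmbedding(z, KernelParams(beta=5.0, tau=1.0))
        hits = sum(
            1 in select_references(0, emb, TrialConfiguration(2, 1, True), rng)
            for _ in range(1000)
        )
        assert hits >= 990

    def test_deterministic_given_rng_state(self):
        z = np.random.default_rng(1).normal(0, 0.3, (8, 2))
        emb = PsychEmbedding(z, KernelParams(beta=5.0))
        config = TrialConfiguration(4, 1, True)
        a = select_references(0, emb, config, np.random.default_rng(5))
        b = select_references(0, emb, config, np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)

    def test_too_few_stimuli_rejected(self, rng):
        z = np.random.default_rng(0).normal(0, 0.3, (3, 2))
        emb = PsychEmbedding(z, KernelParams())
        with pytest.raises(ValueError):
            select_references(0, emb, TrialConfiguration(3, 1, True), rng)


@pytest.fixture(scope="module")
def fitted_state():
    truth = simulation.generate_gaussian_ground_truth(45, 2, 0.03, seed=20)
    rng = np.random.default_rng(21)
    docket = simulation.random_docket(
        45, 800, TrialConfiguration(8, 2, True), rng
    )
    obs = simulation.simulate(simulation.VirtualAgent(truth), docket, rng)
    result = fit(obs, 2, "exponential", n_restart=2, seed=22)
    samples = sample_posterior(
        result.embedding, obs, n_sample=30, seed=23, burn_in=10, thin=1
    )
    return result.embedding, obs, samples


class TestSuggestTrials:
    def test_unique_queries_when_reuse_capped_at_one(self, fitted_state):
        emb, obs, samples = fitted_state
        docket = suggest_trials(
            samples, emb, 40, TrialConfiguration(8, 2, True),
            max_query_reuse=1, seed=1, observations=obs,
        )
        queries = docket.stimulus_set[:, 0]
        assert docket.n_trial == 40
        assert len(np.unique(queries)) == 40

    def test_zero_trials_gives_empty_docket(self, fitted_state):
        emb, obs, samples = fitted_state
        docket = suggest_trials(
            samples, emb, 0, TrialConfiguration(8, 2, True), seed=1
        )
        assert docket.n_trial == 0

    def test_emitted_trials_are_valid(self, fitted_state):
        emb, obs, samples = fitted_state
        docket = suggest_trials(
            samples, emb, 25, TrialConfiguration(8, 2, True),
            max_query_reuse=1, seed=2, observations=obs,
        )
        assert validate(docket) is docket

    def test_infeasible_request_rejected(self, fitted_state):
        emb, obs, samples = fitted_state
        with pytest.raises(ValueError):
            suggest_trials(samples, emb, 46, TrialConfiguration(8, 2, True),
                           max_query_reuse=1, seed=3)

    def test_suggested_beat_random_trials_on_information_gain(
        self, fitted_state
    ):
        """The heuristic's whole point: higher mean IG than random content."""
        emb, obs, samples = fitted_state
        config = TrialConfiguration(8, 2, True)
        suggested = suggest_trials(samples, emb, 30, config,
                                   max_query_reuse=1, seed=4,
                                   observations=obs)
        random = simulation.random_docket(
            45, 30, config, np.random.default_rng(5)
        )
        ig_suggested = information_gains(suggested, samples, emb).mean()
        ig_random = information_gains(random, samples, emb).mean()
        assert ig_suggested > ig_random
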