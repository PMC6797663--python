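"""Synthetic test harness: virtual subjects and collection-strategy studies.

A *virtual agent* wraps a ground-truth embedding and answers trials by
sampling from the outcome distribution its embedding predicts, so the cost
and accuracy of whole data-collection pipelines can be studied without
human participants.  Embedding quality is tracked as the Pearson
correlation between the fitted and ground-truth similarity matrices, and
trial counts convert to worker hours through the median human response
duration of each trial configuration (3.06 s for 2-choose-1, 8.98 s for
ranked 8-choose-2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import active as active_mod
from . import posterior as posterior_mod
from .inference import fit, matrix_correlation, similarity_matrix
from .kernel import KernelParams, similarity, uniform_weights, validate_weights, weighted_minkowski
from .likelihood import PsychEmbedding, outcome_probabilities
from .trials import (
    PAD,
    Docket,
    Observations,
    TrialConfiguration,
    enumerate_outcomes,
    stack,
)

logger = logging.getLogger(__name__)

# median human response seconds per trial configuration
DEFAULT_SECONDS = {
    (2, 1, True): 3.06,
    (8, 2, True): 8.98,
}

STRATEGIES = ("random-2c1", "random-8c2", "active-8c2")

# ground-truth kernel used when a study does not supply one
DEFAULT_TRUTH_KERNEL = KernelParams(family="exponential", beta=10.0, tau=1.0,
                                    gamma=0.0)


@dataclass
class VirtualAgent:
    """A generative model of a participant: an embedding plus a group id."""

    embedding: PsychEmbedding
    group_id: int = 0

    @property
    def n_stimulus(self) -> int:
        return self.embedding.n_stimulus


@dataclass
class StrategyRun:
    """Learning curve of one collection strategy on one seed."""

    strategy: str
    n_trials: np.ndarray  # cumulative judged trials at each increment
    hours: np.ndarray  # cumulative worker hours
    correlation: np.ndarray  # similarity correlation with ground truth
    seed: int | None = None
    reached: bool = False

    def __post_init__(self):
        self.n_trials = np.asarray(self.n_trials)
        self.hours = np.asarray(self.hours, dtype=float)
        self.correlation = np.asarray(self.correlation, dtype=float)
        if (np.diff(self.n_trials) <= 0).any():
            raise ValueError("cumulative trial counts must strictly increase")


def generate_gaussian_ground_truth(
    n_stimulus: int,
    n_dim: int,
    variance: float = 0.03,
    kernel: KernelParams | None = None,
    weights: np.ndarray | None = None,
    seed: int | None = None,
) -> PsychEmbedding:
    """Ground-truth embedding: an isotropic Gaussian point cloud.

    Coordinates are iid Normal(0, variance) in every dimension; the given
    kernel (default exponential, beta=10, tau=1) and attention-weight rows
    are attached unchanged.
    """
    if n_stimulus < 2 or n_dim < 1:
        raise ValueError("need n_stimulus >= 2 and n_dim >= 1")
    if variance <= 0.0:
        raise ValueError("variance must be positive")
    rng = np.random.default_rng(seed)
    z = rng.normal(0.0, np.sqrt(variance), size=(n_stimulus, n_dim))
    if kernel is None:
        kernel = DEFAULT_TRUTH_KERNEL
    if weights is None:
        weights = uniform_weights(1, n_dim)
    return PsychEmbedding(z, kernel, validate_weights(weights, n_dim))


def generate_clustered_ground_truth(
    n_stimulus: int,
    n_dim: int,
    n_cluster: int = 4,
    between_variance: float = 0.03,
    within_variance: float = 0.03 / 16.0,
    kernel: KernelParams | None = None,
    weights: np.ndarray | None = None,
    seed: int | None = None,
) -> PsychEmbedding:
    """Ground truth with confusable clusters of look-alike stimuli.

    Cluster centers are placed deterministically on a circle in the first
    two dimensions, with radius chosen so the marginal coordinate variance
    of the centers equals ``between_variance``; members scatter around
    their center with ``within_variance``.  This emulates stimulus domains
    built from well-separated groups of look-alike items (e.g. several
    species per taxonomic family), where discriminating within-cluster
    structure requires comparisons against near neighbors.  Deterministic
    placement keeps the families distinct — random centers can land nearly
    coincident, silently collapsing the clustered structure.
    """
    if n_cluster < 1 or n_stimulus < 2 or n_dim < 2:
        raise ValueError("need n_cluster >= 1, n_stimulus >= 2, n_dim >= 2")
    rng = np.random.default_rng(seed)
    angles = 2.0 * np.pi * np.arange(n_cluster) / n_cluster
    centers = np.zeros((n_cluster, n_dim))
    radius = np.sqrt(2.0 * between_variance)
    centers[:, 0] = radius * np.cos(angles)
    centers[:, 1] = radius * np.sin(angles)
    assign = np.arange(n_stimulus) % n_cluster
    z = centers[assign] + rng.normal(
        0.0, np.sqrt(within_variance), (n_stimulus, n_dim)
    )
    if kernel is None:
        kernel = DEFAULT_TRUTH_KERNEL
    if weights is None:
        weights = uniform_weights(1, n_dim)
    return PsychEmbedding(z, kernel, validate_weights(weights, n_dim))


def random_docket(
    n_stimulus: int,
    n_trial: int,
    config: TrialConfiguration,
    rng: np.random.Generator,
) -> Docket:
    """Random trial content: distinct stimuli drawn uniformly per trial."""
    rows = np.full((n_trial, 9), PAD, dtype=np.int64)
    for t in range(n_trial):
        picks = rng.choice(n_stimulus, size=1 + config.n_reference,
                           replace=False)
        rows[t, : 1 + config.n_reference] = picks
    return Docket(
        rows,
        np.full(n_trial, config.n_select, dtype=np.int64),
        np.full(n_trial, config.is_ranked, dtype=bool),
    )


def simulate_response(
    agent: VirtualAgent,
    query: int,
    references,
    config: TrialConfiguration,
    rng: np.random.Generator,
):
    """Simulate one trial: returns (ordered stimulus row, outcome index).

    The outcome is drawn from the agent's predicted outcome distribution;
    the returned row lists the query, then the selected references in the
    drawn order, then the unselected references.
    """
    references = np.asarray(references, dtype=int)
    sim = agent.embedding.similarities(query, references, agent.group_id)
    p = outcome_probabilities(sim, config)
    p = p / p.sum()
    outcomes = enumerate_outcomes(config)
    idx = int(rng.choice(len(outcomes), p=p))
    chosen = outcomes[idx]
    rest = [j for j in range(config.n_reference) if j not in chosen]
    row = np.full(9, PAD, dtype=np.int64)
    row[0] = query
    order = list(chosen) + rest
    row[1 : 1 + config.n_reference] = references[order]
    return row, idx


def simulate(agent: VirtualAgent, docket: Docket,
             rng: np.random.Generator) -> Observations:
    """Simulate responses to a whole docket (vectorized per configuration)."""
    rows = np.full((docket.n_trial, 9), PAD, dtype=np.int64)
    n_ref = docket.n_reference
    emb = agent.embedding
    keys = np.stack(
        [n_ref, docket.n_select, docket.is_ranked.astype(np.int64)], axis=1
    )
    for key in np.unique(keys, axis=0):
        mask = np.all(keys == key, axis=1)
        idx = np.flatnonzero(mask)
        config = TrialConfiguration(int(key[0]), int(key[1]), bool(key[2]))
        m = config.n_reference
        queries = docket.stimulus_set[idx, 0]
        refs = docket.stimulus_set[idx, 1 : 1 + m]
        d = weighted_minkowski(
            emb.z[queries][:, None, :], emb.z[refs],
            w=emb.weights[agent.group_id], rho=emb.kernel.rho,
        )
        p = outcome_probabilities(similarity(d, emb.kernel), config)
        p = p / p.sum(axis=1, keepdims=True)
        cdf = np.cumsum(p, axis=1)
        draws = (cdf < rng.random((len(idx), 1))).sum(axis=1)
        outcomes = enumerate_outcomes(config)
        for local, (trial, outcome_i) in enumerate(zip(idx, draws)):
            chosen = outcomes[outcome_i]
            rest = [j for j in range(m) if j not in chosen]
            rows[trial, 0] = queries[local]
            rows[trial, 1 : 1 + m] = refs[local, list(chosen) + rest]
    return Observations(
        rows, docket.n_select.copy(), docket.is_ranked.copy(),
        np.full(docket.n_trial, agent.group_id, dtype=np.int64),
    )


def worker_hours(counts, rates=None) -> float:
    """Convert per-configuration trial counts to worker hours.

    ``counts`` maps a configuration — a :class:`TrialConfiguration` or a
    ``(n_reference, n_select, is_ranked)`` tuple — to a trial count.
    """
    if rates is None:
        rates = DEFAULT_SECONDS
    total_seconds = 0.0
    for config, count in counts.items():
        if count < 0:
            raise ValueError("trial counts must be nonnegative")
        if isinstance(config, TrialConfiguration):
            key = (config.n_reference, config.n_select, config.is_ranked)
        else:
            key = tuple(config)
        if key not in rates:
            raise KeyError(f"no response-time rate for configuration {key}")
        total_seconds += count * rates[key]
    return total_seconds / 3600.0


def hours_to_criterion(run: StrategyRun, criterion: float) -> float:
    """Worker hours at which the correlation curve first crosses criterion.

    Linear interpolation between increments; NaN if never reached.
    """
    r = run.correlation
    above = np.flatnonzero(r >= criterion)
    if above.size == 0:
        return float("nan")
    i = above[0]
    if i == 0:
        return float(run.hours[0])
    frac = (criterion - r[i - 1]) / (r[i] - r[i - 1])
    return float(run.hours[i - 1] + frac * (run.hours[i] - run.hours[i - 1]))


_STRATEGY_SETTINGS = {
    # (config, n_seed_trials, batch); batch None = scale with stimulus count
    "random-2c1": (TrialConfiguration(2, 1, True), 500, 250),
    "random-8c2": (TrialConfiguration(8, 2, True), 50, 250),
    "active-8c2": (TrialConfiguration(8, 2, True), 50, None),
}
# active schedule: kernel parameters are refit every fifth round
KERNEL_REFIT_PERIOD = 5
# full-scale active rounds hold 40 unique-query trials; smaller stimulus
# sets scale the round down so queries stay selective rather than forced
# to cycle through every stimulus
ACTIVE_ROUND_CAP = 40
# stimulus-set size at which the default batch/round sizes apply; smaller
# sets reach criterion after proportionally fewer trials, so batch sizes
# shrink in proportion to keep the measurement granularity comparable
FULL_SCALE_N = 208


def _active_round_size(n_stimulus: int) -> int:
    return min(ACTIVE_ROUND_CAP, max(8, n_stimulus // 2))


def _scaled_batch(default_batch: int, n_stimulus: int) -> int:
    return max(8, round(default_batch * min(1.0, n_stimulus / FULL_SCALE_N)))


def run_collection_strategy(
    agent: VirtualAgent,
    strategy: str,
    *,
    criterion: float = 0.95,
    seed: int | None = None,
    n_dim: int | None = None,
    kernel_family: str | None = None,
    max_rounds: int | None = None,
    n_seed_trials: int | None = None,
    batch: int | None = None,
    n_restart_first: int = 5,
    rates=None,
    posterior_settings: dict | None = None,
) -> StrategyRun:
    """Run one collection strategy against a virtual agent to criterion.

    Alternates trial generation (random content, or the active two-stage
    heuristic fed by fresh posterior samples), response simulation, and
    incremental refitting, recording the worker-hours learning curve.
    For the active strategy the posterior is refreshed every round while
    kernel parameters are refit only every fifth round.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    if not 0.0 <= criterion < 1.0:
        raise ValueError("criterion must be in [0, 1)")
    config, default_seed_trials, default_batch = _STRATEGY_SETTINGS[strategy]
    n_seed_trials = n_seed_trials or default_seed_trials
    truth = agent.embedding
    n = truth.n_stimulus
    if batch is None:
        batch = (_scaled_batch(default_batch, n) if default_batch
                 else _active_round_size(n))
    n_dim = n_dim or truth.n_dim
    if kernel_family is None:
        kernel_family = truth.kernel.family
    active = strategy.startswith("active")
    if max_rounds is None:
        # cheap 2-choose-1 trials need many more increments to criterion
        max_rounds = 100 if active else 400
    post_kw = dict(n_sample=40, burn_in=15, thin=1)
    if posterior_settings:
        post_kw.update(posterior_settings)
    rng = np.random.default_rng(seed)
    truth_s = similarity_matrix(truth, agent.group_id)
    rate_key = (config.n_reference, config.n_select, config.is_ranked)

    obs = simulate(agent, random_docket(n, n_seed_trials, config, rng), rng)
    # observations are single-group from the fit's perspective
    obs.group_id[:] = 0
    result = fit(obs, n_dim, kernel_family, n_restart=n_restart_first,
                 seed=int(rng.integers(2**31)), n_stimulus=n)
    counts, hours_list, corr_list = [], [], []

    def record():
        counts.append(obs.n_trial)
        hours_list.append(worker_hours({rate_key: obs.n_trial}, rates))
        corr_list.append(
            matrix_correlation(truth_s, similarity_matrix(result.embedding))
        )
        return corr_list[-1]

    reached = record() >= criterion
    rounds = 0
    while not reached and rounds < max_rounds:
        rounds += 1
        if active:
            samples = posterior_mod.sample_posterior(
                result.embedding, obs, seed=int(rng.integers(2**31)), **post_kw
            )
            cap = int(np.ceil(batch / n))
            docket = active_mod.suggest_trials(
                samples, result.embedding, batch, config,
                max_query_reuse=cap, seed=int(rng.integers(2**31)),
                observations=obs,
            )
            # refit the kernel every fifth round, starting immediately so
            # selections never run long on the seed-batch kernel
            train_kernel = rounds % KERNEL_REFIT_PERIOD == 1
        else:
            docket = random_docket(n, batch, config, rng)
            train_kernel = rounds % KERNEL_REFIT_PERIOD == 1
        new = simulate(agent, docket, rng)
        new.group_id[:] = 0
        obs = stack([obs, new])
        # identical refit policy across strategies so learning curves
        # differ only through trial content; extra restarts damp
        # fit-luck noise in the learning curve near the criterion
        n_restart = 3 if train_kernel else 2
        result = fit(
            obs, n_dim, result.embedding.kernel, n_restart=n_restart,
            seed=int(rng.integers(2**31)), n_stimulus=n,
            init=result.embedding, train_kernel=train_kernel,
        )
        reached = record() >= criterion
    if not reached:
        logger.warning("strategy %s did not reach criterion %.2f "
                       "(final r=%.3f)", strategy, criterion, corr_list[-1])
    return StrategyRun(strategy, np.array(counts), np.array(hours_list),
                       np.array(corr_list), seed=seed, reached=reached)


@dataclass
class GroupStudyResult:
    """Worker-hour accounting for a two-group (novice/expert) study."""

    condition: str  # 'independent' | 'shared'
    novice_hours: float
    expert_hours: float
    total_hours: float
    runs: dict = field(default_factory=dict)
    reached: bool = True


def run_group_study(
    truth: PsychEmbedding,
    condition: str,
    novice_fraction: float = 0.74,
    criterion: float = 0.95,
    seed: int | None = None,
    *,
    config: TrialConfiguration = TrialConfiguration(8, 2, True),
    batch: int = 250,
    max_batches: int = 60,
    n_dim: int | None = None,
    rates=None,
) -> GroupStudyResult:
    """Compare data-collection cost for two groups with complementary attention.

    ``truth`` must carry two attention-weight rows (novice = group 0,
    expert = group 1).  In the *independent* condition each group gets its
    own single-group embedding, fit on its own observation stream until its
    similarity matrix correlates with the group's ground truth at
    ``criterion``.  In the *shared* condition one two-group embedding with
    trainable attention-weight rows is fit on a mixed stream in which each
    trial is a novice trial with probability ``novice_fraction``; both
    group criteria must be met.  Reported worker hours interpolate
    linearly between increments.
    """
    if condition not in ("independent", "shared"):
        raise ValueError("condition must be 'independent' or 'shared'")
    if truth.n_group != 2:
        raise ValueError("ground truth must carry exactly two weight rows")
    rng = np.random.default_rng(seed)
    n = truth.n_stimulus
    n_dim = n_dim or truth.n_dim
    rate_key = (config.n_reference, config.n_select, config.is_ranked)
    truth_s = [similarity_matrix(truth, g) for g in (0, 1)]
    per_trial_hours = worker_hours({rate_key: 1}, rates)

    if condition == "independent":
        group_hours = []
        runs = {}
        reached_all = True
        for g in (0, 1):
            agent = VirtualAgent(truth, group_id=g)
            obs = simulate(agent, random_docket(n, batch, config, rng), rng)
            obs.group_id[:] = 0
            result = fit(obs, n_dim, truth.kernel.family, n_restart=5,
                         seed=int(rng.integers(2**31)), n_stimulus=n)
            counts, rs = [obs.n_trial], [
                matrix_correlation(truth_s[g],
                                   similarity_matrix(result.embedding))
            ]
            while rs[-1] < criterion and len(counts) <= max_batches:
                new = simulate(agent, random_docket(n, batch, config, rng), rng)
                new.group_id[:] = 0
                obs = stack([obs, new])
                result = fit(obs, n_dim, result.embedding.kernel, n_restart=2,
                             seed=int(rng.integers(2**31)), n_stimulus=n,
                             init=result.embedding)
                counts.append(obs.n_trial)
                rs.append(matrix_correlation(
                    truth_s[g], similarity_matrix(result.embedding)))
            run = StrategyRun(
                f"independent-group{g}", np.array(counts),
                np.array(counts) * per_trial_hours, np.array(rs),
                seed=seed, reached=rs[-1] >= criterion,
            )
            runs[g] = run
            reached_all &= run.reached
            h = hours_to_criterion(run, criterion)
            group_hours.append(float(run.hours[-1]) if np.isnan(h) else h)
        return GroupStudyResult(
            "independent", group_hours[0], group_hours[1],
            group_hours[0] + group_hours[1], runs, reached_all,
        )

    # shared condition: one embedding, two trainable weight rows; a group
    # stops contributing trials once its own criterion is met, so the
    # stream is mixed only while both groups still need data
    agents = [VirtualAgent(truth, group_id=g) for g in (0, 1)]

    def next_batch(size, active_groups):
        if len(active_groups) == 2:
            is_novice = rng.random(size) < novice_fraction
            sizes = {0: int(is_novice.sum()), 1: int((~is_novice).sum())}
        else:
            sizes = {active_groups[0]: size}
        parts = [
            simulate(agents[g], random_docket(n, count, config, rng), rng)
            for g, count in sizes.items() if count
        ]
        return stack(parts) if len(parts) > 1 else parts[0]

    obs = next_batch(batch, (0, 1))
    result = fit(obs, n_dim, truth.kernel.family, n_restart=5,
                 seed=int(rng.integers(2**31)), n_stimulus=n)
    counts = [obs.n_trial]
    group_counts = [[int((obs.group_id == g).sum()) for g in (0, 1)]]
    rs = [[], []]

    def record_rs(res):
        for g in (0, 1):
            rs[g].append(matrix_correlation(
                truth_s[g], similarity_matrix(res.embedding, group_id=g)))
        return min(rs[0][-1], rs[1][-1])

    worst = record_rs(result)
    while worst < criterion and len(counts) <= max_batches:
        lagging = tuple(g for g in (0, 1) if rs[g][-1] < criterion)
        new = next_batch(batch, lagging)
        obs = stack([obs, new])
        result = fit(obs, n_dim, result.embedding.kernel, n_restart=2,
                     seed=int(rng.integers(2**31)), n_stimulus=n,
                     init=result.embedding)
        counts.append(obs.n_trial)
        group_counts.append([int((obs.group_id == g).sum()) for g in (0, 1)])
        worst = record_rs(result)
    worst_curve = np.minimum(np.array(rs[0]), np.array(rs[1]))
    run = StrategyRun("shared", np.array(counts),
                      np.array(counts) * per_trial_hours, worst_curve,
                      seed=seed, reached=worst >= criterion)
    total = hours_to_criterion(run, criterion)
    if np.isnan(total):
        total = float(run.hours[-1])
    # per-group hours at the (interpolated) crossing point of the stream
    group_counts = np.array(group_counts, dtype=float)
    crossing_trials = total / per_trial_hours
    novice_hours = float(np.interp(
        crossing_trials, np.array(counts, dtype=float), group_counts[:, 0]
    )) * per_trial_hours
    runs = {"shared": run, "novice_r": np.array(rs[0]),
            "expert_r": np.array(rs[1])}
    return GroupStudyResult("shared", novice_hours, total - novice_hours,
                            total, runs, run.reached)
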