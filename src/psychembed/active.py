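"""Active trial selection by expected information gain.

The expected information gain of a candidate trial is the mutual
information between the embedding coordinates and the trial's (not yet
observed) outcome.  With posterior samples zeta it reduces to

    I = H( mean_s p(y | zeta_s) ) - mean_s H( p(y | zeta_s) ),

the entropy of the posterior-predictive outcome distribution minus the mean
per-sample entropy.  Exhaustively scoring all candidate trials is
prohibitive, so new trials come from a two-stage heuristic: queries are
drawn in proportion to their posterior uncertainty (summed Gaussian KL
divergence against all other stimuli), then references are drawn in
proportion to their similarity to the query.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .kernel import similarity, weighted_minkowski
from .likelihood import PsychEmbedding, outcome_probabilities
from .posterior import PosteriorSamples
from .trials import PAD, Docket, Observations, TrialConfiguration, validate

logger = logging.getLogger(__name__)

_RIDGE = 1e-10


@dataclass
class CandidateScore:
    """A candidate trial with its outcome count and expected info gain."""

    query: int
    references: np.ndarray
    config: TrialConfiguration
    n_outcome: int
    info_gain: float  # nats


def _entropy(p: np.ndarray, axis: int = -1) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0.0, p * np.log(p), 0.0)
    return -terms.sum(axis=axis)


def expected_information_gain(
    query: int,
    references,
    config: TrialConfiguration,
    samples: PosteriorSamples,
    emb: PsychEmbedding,
    group_id: int = 0,
) -> CandidateScore:
    """Score one candidate trial by mutual information in nats.

    Outcome probabilities are computed under every posterior sample of the
    coordinates, with the fitted kernel and attention weights held fixed.
    """
    references = np.asarray(references, dtype=int)
    config = TrialConfiguration(len(references), config.n_select,
                                config.is_ranked)
    zq = samples.samples[:, query, :]  # (S, D)
    zr = samples.samples[:, references, :]  # (S, m, D)
    d = weighted_minkowski(
        zq[:, None, :], zr, w=emb.weights[group_id], rho=emb.kernel.rho
    )
    p = outcome_probabilities(similarity(d, emb.kernel), config)  # (S, M)
    p = p / p.sum(axis=-1, keepdims=True)
    marginal = p.mean(axis=0)
    info = float(_entropy(marginal) - _entropy(p, axis=-1).mean())
    return CandidateScore(query, references, config, config.n_outcome, info)


def information_gains(docket: Docket, samples: PosteriorSamples,
                      emb: PsychEmbedding, group_id: int = 0) -> np.ndarray:
    """Expected information gain of every row of a docket."""
    return np.array(
        [
            expected_information_gain(
                int(docket.stimulus_set[i, 0]), docket.references(i),
                docket.config(i), samples, emb, group_id,
            ).info_gain
            for i in range(docket.n_trial)
        ]
    )


def gaussian_kl(mean0, cov0, mean1, cov1) -> float:
    """KL( N(mean0, cov0) || N(mean1, cov1) ), closed form, in nats."""
    mean0 = np.atleast_1d(np.asarray(mean0, dtype=float))
    mean1 = np.atleast_1d(np.asarray(mean1, dtype=float))
    cov0 = np.atleast_2d(np.asarray(cov0, dtype=float))
    cov1 = np.atleast_2d(np.asarray(cov1, dtype=float))
    d = mean0.shape[0]
    chol1 = np.linalg.cholesky(cov1)
    solved = np.linalg.solve(cov1, cov0)
    diff = mean1 - mean0
    maha = diff @ np.linalg.solve(cov1, diff)
    logdet0 = 2.0 * np.sum(np.log(np.diag(np.linalg.cholesky(cov0))))
    logdet1 = 2.0 * np.sum(np.log(np.diag(chol1)))
    return 0.5 * float(np.trace(solved) + maha - d + logdet1 - logdet0)


def _sample_moments(samples: PosteriorSamples):
    """Moment-matched Gaussian for each stimulus, ridge-regularized."""
    pts = samples.samples  # (S, n, D)
    means = pts.mean(axis=0)
    centered = pts - means
    covs = np.einsum("ski,skj->kij", centered, centered) / max(
        samples.n_sample - 1, 1
    )
    n_dim = samples.n_dim
    for k in range(samples.n_stimulus):
        # guard against singular sample covariance (few or collapsed draws)
        if np.linalg.matrix_rank(covs[k]) < n_dim or np.linalg.det(covs[k]) <= 0:
            logger.debug("ridge-regularizing covariance of stimulus %d", k)
            covs[k] += _RIDGE * np.eye(n_dim)
    covs += _RIDGE * np.eye(n_dim)
    return means, covs


def query_priority(samples: PosteriorSamples,
                   direction: str = "from") -> np.ndarray:
    """Per-stimulus query-selection weights from posterior uncertainty.

    Each stimulus's samples are summarized by a moment-matched Gaussian and
    scored by the summed KL divergence against every other stimulus;
    ``direction='from'`` (default) uses KL(N_k || N_j), which grows with
    stimulus k's own spread but is not inflated by uncertain neighbors;
    ``direction='to'`` uses KL(N_j || N_k).  The scores are normalized to a
    probability distribution, so higher-uncertainty stimuli are more likely
    to be chosen as the query.
    """
    if direction not in ("from", "to"):
        raise ValueError("direction must be 'from' or 'to'")
    means, covs = _sample_moments(samples)
    n = samples.n_stimulus
    scores = np.zeros(n)
    for k in range(n):
        for j in range(n):
            if j == k:
                continue
            if direction == "from":
                scores[k] += gaussian_kl(means[k], covs[k], means[j], covs[j])
            else:
                scores[k] += gaussian_kl(means[j], covs[j], means[k], covs[k])
    total = scores.sum()
    if total <= 0.0:
        return np.full(n, 1.0 / n)
    return scores / total


def select_references(
    query: int,
    emb: PsychEmbedding,
    config: TrialConfiguration,
    rng: np.random.Generator,
    group_id: int = 0,
) -> np.ndarray:
    """Draw a reference set, favoring near neighbors of the query.

    ``config.n_reference`` distinct non-query stimuli are sampled without
    replacement with probability proportional to their similarity to the
    query at the current point estimates.
    """
    n = emb.n_stimulus
    if n - 1 < config.n_reference:
        raise ValueError(
            f"need {config.n_reference} non-query stimuli, have {n - 1}"
        )
    candidates = np.array([i for i in range(n) if i != query])
    sim = emb.similarities(query, candidates, group_id)
    probs = sim / sim.sum()
    return rng.choice(candidates, size=config.n_reference, replace=False,
                      p=probs)


def suggest_trials(
    samples: PosteriorSamples,
    emb: PsychEmbedding,
    n_trial: int,
    config: TrialConfiguration,
    max_query_reuse: int = 1,
    seed: int | None = None,
    observations: Observations | None = None,
    group_id: int = 0,
) -> Docket:
    """Generate the next batch of trials via the two-stage heuristic.

    Stage 1 samples queries from :func:`query_priority` (stimuli that have
    never been observed, per ``observations``, get the maximal raw weight);
    stage 2 samples each query's references by similarity.  A query may be
    used at most ``max_query_reuse`` times within the batch.
    """
    n = emb.n_stimulus
    if n_trial > n * max_query_reuse:
        raise ValueError(
            f"cannot build {n_trial} trials with max_query_reuse="
            f"{max_query_reuse} over {n} stimuli"
        )
    rng = np.random.default_rng(seed)
    priority = query_priority(samples).copy()
    if observations is not None and observations.n_trial > 0:
        seen = np.zeros(n, dtype=bool)
        stim = observations.stimulus_set
        seen[np.unique(stim[stim >= 0])] = True
        if (~seen).any() and seen.any():
            priority[~seen] = priority.max()
            priority = priority / priority.sum()

    rows = np.full((n_trial, 1 + 8), PAD, dtype=np.int64)
    usage = np.zeros(n, dtype=int)
    weights = priority.copy()
    for t in range(n_trial):
        if weights.sum() <= 0.0:
            weights = (usage < max_query_reuse).astype(float)
        query = int(rng.choice(n, p=weights / weights.sum()))
        usage[query] += 1
        if usage[query] >= max_query_reuse:
            weights[query] = 0.0
        refs = select_references(query, emb, config, rng, group_id)
        rows[t, 0] = query
        rows[t, 1 : 1 + config.n_reference] = refs
    docket = Docket(
        rows,
        np.full(n_trial, config.n_select, dtype=np.int64),
        np.full(n_trial, config.is_ranked, dtype=bool),
    )
    return validate(docket)
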