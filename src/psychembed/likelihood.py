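"""Selection-function probabilities and the dataset log-likelihood.

The probability that a participant selects a particular reference is
proportional to its similarity to the query (Luce's choice rule).  Ranked
selections follow a sequential-removal scheme: the first selection competes
against all references, the second against the remainder, and so on.  An
unranked selection of a set is the sum of the ranked probabilities over all
orderings of that set.  Trials contribute independently, so the data
log-likelihood is the sum of per-trial log probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kernel import KernelParams, similarity, uniform_weights, validate_weights, weighted_minkowski
from .trials import Docket, Observations, TrialConfiguration, enumerate_outcomes

# floor applied inside logs; stochastic responses can hit vanishing model
# probabilities early in optimization
PROB_FLOOR = 2.2e-16
LOG_FLOOR = float(np.log(PROB_FLOOR))


@dataclass
class PsychEmbedding:
    """A psychological embedding: coordinates, kernel, attention weights.

    ``z`` is the n-stimulus x D-dimension coordinate matrix, ``kernel`` the
    similarity function parameters, and ``weights`` the K-group x D attention
    weight matrix (rows sum to D; a single row of ones for one group).
    """

    z: np.ndarray
    kernel: KernelParams = field(default_factory=KernelParams)
    weights: np.ndarray = None

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim != 2 or self.z.shape[0] < 2 or self.z.shape[1] < 1:
            raise ValueError("z must be an (n >= 2) x (D >= 1) matrix")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("coordinates must be finite")
        if self.weights is None:
            self.weights = uniform_weights(1, self.n_dim)
        self.weights = validate_weights(self.weights, self.n_dim)

    @property
    def n_stimulus(self) -> int:
        return self.z.shape[0]

    @property
    def n_dim(self) -> int:
        return self.z.shape[1]

    @property
    def n_group(self) -> int:
        return self.weights.shape[0]

    def copy(self) -> "PsychEmbedding":
        return PsychEmbedding(self.z.copy(), self.kernel, self.weights.copy())

    def similarities(self, query, references, group_id: int = 0) -> np.ndarray:
        """Query-reference similarities for one trial's stimuli."""
        d = weighted_minkowski(
            self.z[query], self.z[np.asarray(references)],
            w=self.weights[group_id], rho=self.kernel.rho,
        )
        return similarity(d, self.kernel)


def outcome_probabilities(sim: np.ndarray, config: TrialConfiguration) -> np.ndarray:
    """Probabilities of every outcome given query-reference similarities.

    ``sim`` has the reference similarities along its last axis (leading axes
    broadcast, e.g. over posterior samples).  Outcome order follows
    :func:`psychembed.trials.enumerate_outcomes`.
    """
    sim = np.asarray(sim, dtype=float)
    if sim.shape[-1] != config.n_reference:
        raise ValueError("similarity vector length != n_reference")
    outcomes = enumerate_outcomes(config)
    if config.is_ranked:
        sel = np.array(outcomes)  # (M, n_select)
        return _ranked_probs(sim, sel)
    # unranked: sum ranked probabilities over orderings of each selected set
    import itertools

    probs = []
    for outcome in outcomes:
        orderings = np.array(list(itertools.permutations(outcome)))
        probs.append(_ranked_probs(sim, orderings).sum(axis=-1))
    return np.stack(probs, axis=-1)


def _ranked_probs(sim: np.ndarray, sel: np.ndarray) -> np.ndarray:
    """Sequential-removal probabilities for ordered selections.

    ``sel`` is (M, n_select) reference positions; returns (..., M).
    """
    total = sim.sum(axis=-1)  # (...,)
    picked = sim[..., sel]  # (..., M, n_select)
    removed = np.cumsum(picked, axis=-1) - picked  # earlier selections
    denom = total[..., None, None] - removed
    return np.prod(picked / denom, axis=-1)


def outcome_distribution(emb: PsychEmbedding, query: int, references,
                         config: TrialConfiguration,
                         group_id: int = 0) -> np.ndarray:
    """Predicted distribution over the M possible outcomes of one trial."""
    sim = emb.similarities(query, references, group_id)
    p = outcome_probabilities(sim, config)
    total = p.sum(axis=-1)
    if not np.all(total > PROB_FLOOR):
        raise FloatingPointError(
            "degenerate kernel: total outcome probability underflowed"
        )
    return p


def trial_probability(emb: PsychEmbedding, obs: Observations, i: int) -> float:
    """Probability of the recorded outcome of trial ``i``.

    With the response layout (selected references first, in rank order) the
    recorded outcome is always outcome 0 of the enumeration.
    """
    config = obs.config(i)
    p = outcome_distribution(
        emb, int(obs.stimulus_set[i, 0]), obs.references(i), config,
        int(obs.group_id[i]) if isinstance(obs, Observations) else 0,
    )
    return float(p[0])


def docket_distributions(emb: PsychEmbedding, docket: Docket,
                         group_id=0) -> list[np.ndarray]:
    """Outcome distributions for every row of a docket (list of M_i vectors)."""
    group_id = np.broadcast_to(np.asarray(group_id), (docket.n_trial,))
    return [
        outcome_distribution(
            emb, int(docket.stimulus_set[i, 0]), docket.references(i),
            docket.config(i), int(group_id[i]),
        )
        for i in range(docket.n_trial)
    ]


def log_likelihood(emb: PsychEmbedding, obs: Observations) -> float:
    """Data log-likelihood in nats: sum over trials of floored log p_i."""
    from ._objective import compile_observations, total_log_likelihood

    compiled = compile_observations(obs)
    return total_log_likelihood(emb.z, emb.kernel, emb.weights, compiled)
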