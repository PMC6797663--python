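"""Posterior uncertainty over stimulus coordinates.

The location of each stimulus is given a Gaussian prior and the posterior
p(z_k | data, Z_notk, theta) — likelihood times prior, with the kernel
parameters and attention weights held fixed — is approximated by Gibbs
sweeps over the stimuli.  Because the prior is Gaussian, each within-sweep
update uses elliptical slice sampling, which is rejection-free and needs no
step-size tuning.  A stimulus touched by no trials has a constant
likelihood, so its samples simply follow the prior.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._objective import compile_observations, total_log_likelihood
from .likelihood import PsychEmbedding
from .trials import Observations

logger = logging.getLogger(__name__)

DEFAULT_N_SAMPLE = 100
DEFAULT_BURN_IN = 100
DEFAULT_THIN = 2


@dataclass
class PriorSpec:
    """Gaussian prior over stimulus coordinates.

    ``mean`` is (n, D) (a per-stimulus mean) or (D,) (shared); ``cov`` is a
    single (D, D) symmetric positive-definite matrix shared by all stimuli.
    """

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        if self.cov.ndim != 2 or self.cov.shape[0] != self.cov.shape[1]:
            raise ValueError("cov must be a square matrix")
        if not np.allclose(self.cov, self.cov.T):
            raise ValueError("cov must be symmetric")
        try:
            self._chol = np.linalg.cholesky(self.cov)
        except np.linalg.LinAlgError as err:
            raise ValueError("cov must be positive definite") from err

    @property
    def chol(self) -> np.ndarray:
        return self._chol

    def mean_for(self, k: int) -> np.ndarray:
        return self.mean if self.mean.ndim == 1 else self.mean[k]

    @classmethod
    def from_embedding(cls, emb: PsychEmbedding, scale: float | None = None
                       ) -> "PriorSpec":
        """Local prior centered on the current point estimates.

        The isotropic scale defaults to the mean nearest-neighbor distance
        of the embedding, which keeps posterior exploration at the spatial
        resolution that the data can actually distinguish.
        """
        if scale is None:
            d = np.linalg.norm(emb.z[:, None, :] - emb.z[None, :, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            scale = float(d.min(axis=1).mean())
            if not np.isfinite(scale) or scale <= 0.0:
                scale = 0.1
        return cls(emb.z.copy(), scale**2 * np.eye(emb.n_dim))


@dataclass
class PosteriorSamples:
    """Tensor of posterior draws: (n_sample, n_stimulus, n_dim)."""

    samples: np.ndarray
    burn_in: int = 0
    thin: int = 1
    seed: int | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 3 or self.samples.shape[0] < 1:
            raise ValueError("samples must be (S >= 1, n, D)")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def n_sample(self) -> int:
        return self.samples.shape[0]

    @property
    def n_stimulus(self) -> int:
        return self.samples.shape[1]

    @property
    def n_dim(self) -> int:
        return self.samples.shape[2]

    def moments(self, k: int):
        """Sample mean and covariance of stimulus ``k``'s draws."""
        pts = self.samples[:, k, :]
        return pts.mean(axis=0), np.cov(pts, rowvar=False, ddof=1)


def elliptical_slice_step(f, log_lik, prior_mean, prior_chol,
                          rng: np.random.Generator, cur_ll=None):
    """One elliptical slice sampling update of ``f`` under a Gaussian prior.

    ``log_lik`` maps a candidate vector to its data log-likelihood.  Returns
    the new state and its log-likelihood; never rejects.
    """
    f = np.asarray(f, dtype=float)
    nu = prior_chol @ rng.standard_normal(f.shape[0])
    if cur_ll is None:
        cur_ll = log_lik(f)
    log_y = cur_ll + np.log(rng.uniform())
    theta = rng.uniform(0.0, 2.0 * np.pi)
    lo, hi = theta - 2.0 * np.pi, theta
    centered = f - prior_mean
    while True:
        candidate = centered * np.cos(theta) + nu * np.sin(theta) + prior_mean
        cand_ll = log_lik(candidate)
        if cand_ll > log_y:
            return candidate, cand_ll
        if theta < 0.0:
            lo = theta
        else:
            hi = theta
        theta = rng.uniform(lo, hi)


def _stimulus_blocks(obs: Observations, n_stimulus: int):
    """Compiled likelihood blocks restricted to trials touching stimulus k."""
    touching = [[] for _ in range(n_stimulus)]
    for i in range(obs.n_trial):
        row = obs.stimulus_set[i]
        for stim in row[row >= 0]:
            touching[stim].append(i)
    return [
        compile_observations(obs.subset(np.array(rows, dtype=int)))
        if rows else None
        for rows in touching
    ]


def sample_posterior(
    emb: PsychEmbedding,
    obs: Observations,
    n_sample: int = DEFAULT_N_SAMPLE,
    prior: PriorSpec | None = None,
    seed: int | None = None,
    *,
    burn_in: int = DEFAULT_BURN_IN,
    thin: int = DEFAULT_THIN,
) -> PosteriorSamples:
    """Draw posterior samples of all stimulus coordinates.

    Gibbs sweeps visit the stimuli in a freshly randomized order each sweep;
    each visit performs one elliptical-slice update of that stimulus's
    coordinates, conditioning on the current positions of all others.
    Kernel parameters and attention weights stay at their fitted values.
    Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    n, n_dim = emb.n_stimulus, emb.n_dim
    if prior is None:
        prior = PriorSpec.from_embedding(emb)
    if prior.cov.shape[0] != n_dim:
        raise ValueError("prior covariance dimension != embedding dimension")
    blocks_by_stim = _stimulus_blocks(obs, n)
    untouched = [k for k, b in enumerate(blocks_by_stim) if b is None]
    if untouched:
        logger.info(
            "%d stimuli appear in no trials; their samples follow the prior",
            len(untouched),
        )

    z = emb.z.copy()
    kernel, weights = emb.kernel, np.atleast_2d(emb.weights)

    def stim_loglik(k, candidate):
        z[k] = candidate
        return total_log_likelihood(z, kernel, weights, blocks_by_stim[k])

    retained = np.empty((n_sample, n, n_dim))
    kept = 0
    sweep = 0
    while kept < n_sample:
        order = rng.permutation(n)
        for k in order:
            if blocks_by_stim[k] is None:
                z[k] = prior.mean_for(k) + prior.chol @ rng.standard_normal(n_dim)
                continue
            old = z[k].copy()
            # current log-likelihood is recomputed because other stimuli
            # moved since this one was last visited
            new, _ = elliptical_slice_step(
                old,
                lambda candidate: stim_loglik(k, candidate),
                prior.mean_for(k),
                prior.chol,
                rng,
            )
            z[k] = new
        sweep += 1
        if sweep > burn_in and (sweep - burn_in) % thin == 0:
            retained[kept] = z
            kept += 1
    return PosteriorSamples(retained, burn_in=burn_in, thin=thin, seed=seed)
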