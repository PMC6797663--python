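"""Maximum-likelihood fitting, dimensionality search, and model comparison.

Fitting jointly optimizes the stimulus coordinates, the trainable kernel
parameters, and (for multi-group data) the attention-weight rows by
quasi-Newton descent on the negative mean log-likelihood, taking the best of
several random restarts.  Dimensionality is chosen by hold-out validation
loss: candidates are tried in ascending order until the loss stops
improving.  Convergence with growing data is assessed by correlating the
similarity matrices of embeddings fit on cumulative data partitions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from ._objective import ParameterPacker, compile_observations, make_objective
from .kernel import (
    KernelParams,
    random_params,
    similarity,
    uniform_weights,
    weighted_minkowski,
)
from .likelihood import PsychEmbedding
from .trials import Observations

logger = logging.getLogger(__name__)

# iid Normal scale for coordinate initialization at restarts
Z_INIT_SCALE = 0.17
DEFAULT_N_RESTART = 10
FIT_TOL = 1e-5
FIT_MAX_ITER = 5000
# validation-loss ties (within this) count as "no improvement"
DIM_SEARCH_TIE = 1e-6


@dataclass
class FitResult:
    """Outcome of :func:`fit`: best embedding and per-restart diagnostics."""

    embedding: PsychEmbedding
    loss: float  # negative mean log-likelihood of the best restart
    restart_losses: list[float] = field(default_factory=list)
    seed: int | None = None


def _loss(emb: PsychEmbedding, obs: Observations) -> float:
    from ._objective import total_log_likelihood

    blocks = compile_observations(obs)
    ll = total_log_likelihood(emb.z, emb.kernel, emb.weights, blocks)
    return -ll / max(obs.n_trial, 1)


def fit(
    obs: Observations,
    n_dim: int,
    kernel: str | KernelParams = "exponential",
    n_restart: int = DEFAULT_N_RESTART,
    seed: int | None = None,
    *,
    n_stimulus: int | None = None,
    init: PsychEmbedding | None = None,
    train_kernel: bool = True,
    max_iter: int = FIT_MAX_ITER,
    tol: float = FIT_TOL,
) -> FitResult:
    """Infer an embedding from observations by maximum likelihood.

    Parameters
    ----------
    obs : Observations
        Judged trials; the number of stimuli is inferred as max index + 1
        unless ``n_stimulus`` is given.
    n_dim : int
        Embedding dimensionality.
    kernel : str or KernelParams
        Kernel family name, or explicit parameters used as the first
        restart's initial value.  Further restarts draw random parameters
        of the same family (unless ``train_kernel`` is False), so a poor
        kernel optimum from a previous fit cannot trap every restart.
    n_restart : int
        Number of random initializations; the best final loss wins.
    seed : int, optional
        Seed for the restart initializations; the result is deterministic
        given (data, seed).
    init : PsychEmbedding, optional
        Warm start: used as the first restart's initialization.
    train_kernel : bool
        If False, kernel parameters are held at their given values.

    Notes
    -----
    With a single group the attention weights are fixed at one and not
    trained — the coordinates absorb any axis scaling.  With K > 1 groups a
    weight row per group is trained through a softmax bijection that keeps
    every row nonnegative and summing to D.
    """
    n = n_stimulus if n_stimulus is not None else obs.n_stimulus
    if n < 2:
        raise ValueError("need at least two stimuli")
    n_group = obs.n_group
    rng = np.random.default_rng(seed)
    blocks = compile_observations(obs)
    n_free = n * n_dim
    if obs.n_trial < n_free:
        warnings.warn(
            f"{obs.n_trial} trials may under-constrain {n_free} coordinates",
            stacklevel=2,
        )

    if isinstance(kernel, KernelParams):
        base_params = kernel
        family = kernel.family
    else:
        base_params = None
        family = kernel
    train_weights = n_group > 1

    best = None
    restart_losses: list[float] = []
    for r in range(n_restart):
        fresh = not (init is not None and r == 0)
        if not fresh:
            z0 = init.z.copy()
            params0 = init.kernel
            w0 = init.weights
        else:
            z0 = rng.normal(0.0, Z_INIT_SCALE, size=(n, n_dim))
            if base_params is not None and (r == 0 or not train_kernel):
                params0 = base_params
            else:
                params0 = random_params(family, rng,
                                        rho=2.0 if base_params is None
                                        else base_params.rho)
            w0 = uniform_weights(n_group, n_dim)
        if not train_kernel:
            params0 = params0.frozen()
        packer = ParameterPacker(n, n_dim, params0, n_group, train_weights)
        fixed_w = None if train_weights else uniform_weights(n_group, n_dim)
        objective = make_objective(blocks, packer, fixed_weights=fixed_w)
        x0 = packer.pack(z0, params0, w0)
        result = optimize.minimize(
            objective,
            x0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-8},
        )
        if not np.isfinite(result.fun):
            logger.warning("restart %d diverged (non-finite loss); discarded", r)
            continue
        restart_losses.append(float(result.fun))
        if best is None or result.fun < best[0]:
            z_fit, params_fit, w_fit = packer.unpack(result.x)
            if w_fit is None:
                w_fit = fixed_w
            best = (float(result.fun), z_fit - z_fit.mean(axis=0),
                    params_fit, w_fit)
    if best is None:
        raise RuntimeError("all restarts failed with non-finite loss")
    loss, z_fit, params_fit, w_fit = best
    if not train_kernel:
        # restore the caller's trainable flags: freezing was for this fit
        # only and must not stick to the returned kernel
        source = init.kernel if init is not None else base_params
        if source is not None:
            params_fit = params_fit.with_values(trainable=source.trainable)
    emb = PsychEmbedding(z_fit, params_fit, w_fit)
    return FitResult(emb, loss, restart_losses, seed)


def similarity_matrix(emb: PsychEmbedding, group_id: int = 0) -> np.ndarray:
    """Pairwise similarity matrix under one group's attention weights."""
    if not 0 <= group_id < emb.n_group:
        raise ValueError(f"group_id {group_id} out of range")
    w = emb.weights[group_id]
    d = weighted_minkowski(
        emb.z[:, None, :], emb.z[None, :, :], w=w, rho=emb.kernel.rho
    )
    return similarity(d, emb.kernel)


def matrix_correlation(s1: np.ndarray, s2: np.ndarray) -> float:
    """Pearson correlation of the strictly-upper-triangle entries.

    The diagonal (self-similarity) and the redundant lower triangle are
    excluded before correlating.
    """
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if s1.shape != s2.shape or s1.ndim != 2 or s1.shape[0] != s1.shape[1]:
        raise ValueError("similarity matrices must share a square shape")
    if s1.shape[0] < 3:
        raise ValueError("need at least 3 stimuli for a correlation")
    iu = np.triu_indices(s1.shape[0], k=1)
    a, b = s1[iu], s2[iu]
    if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        raise ValueError("zero variance in upper-triangle similarities")
    return float(stats.pearsonr(a, b)[0])


def _stratified_split(obs: Observations, holdout_frac: float,
                      rng: np.random.Generator):
    """Train/validation split stratified by trial configuration."""
    keys = np.stack(
        [obs.n_reference, obs.n_select, obs.is_ranked.astype(np.int64)], axis=1
    )
    val_rows = np.zeros(obs.n_trial, dtype=bool)
    for key in np.unique(keys, axis=0):
        idx = np.flatnonzero(np.all(keys == key, axis=1))
        n_val = max(1, int(round(holdout_frac * idx.size))) if idx.size > 1 else 0
        chosen = rng.choice(idx, size=n_val, replace=False)
        val_rows[chosen] = True
    if not val_rows.any() or val_rows.all():
        raise ValueError("too few trials for a train/validation split")
    return obs.subset(~val_rows), obs.subset(val_rows)


def dimension_search(
    obs: Observations,
    candidate_dims,
    kernel: str | KernelParams = "exponential",
    n_restart: int = 3,
    seed: int | None = None,
    holdout_frac: float = 0.1,
) -> int:
    """Choose an embedding dimensionality by hold-out validation loss.

    Candidates are fit in ascending order; the search stops at the first
    dimensionality whose validation loss fails to improve on the previous
    one (ties count as no improvement) and returns the dimensionality of
    the last observed improvement.
    """
    dims = sorted(int(d) for d in candidate_dims)
    if not dims:
        raise ValueError("no candidate dimensionalities")
    if len(dims) == 1:
        return dims[0]
    rng = np.random.default_rng(seed)
    train, val = _stratified_split(obs, holdout_frac, rng)
    n_stimulus = obs.n_stimulus
    best_dim = dims[0]
    prev_loss = np.inf
    for dim in dims:
        result = fit(
            train, dim, kernel, n_restart=n_restart,
            seed=int(rng.integers(2**31)), n_stimulus=n_stimulus,
        )
        val_loss = _loss(result.embedding, val)
        logger.info("dimension_search: D=%d validation loss %.5f", dim, val_loss)
        if val_loss < prev_loss - DIM_SEARCH_TIE:
            best_dim = dim
            prev_loss = val_loss
        else:
            break
    return best_dim


def assess_convergence(
    obs: Observations,
    n_dim: int,
    kernel: str | KernelParams = "exponential",
    n_partition: int = 10,
    n_shuffle: int = 3,
    seed: int | None = None,
    n_restart: int = 3,
    mode: str = "consecutive",
) -> np.ndarray:
    """Correlation curves showing how the embedding stabilizes with data.

    For each shuffle the observations are re-partitioned; embeddings are fit
    on 1, 2, ..., n_partition cumulative partitions.  ``mode='consecutive'``
    correlates each embedding's similarity matrix with the previous
    increment's; ``mode='final'`` correlates each with the full-data
    embedding.  Returns an (n_shuffle, n_partition - 1) array of Pearson r.
    """
    if n_partition < 2:
        raise ValueError("n_partition must be >= 2")
    if mode not in ("consecutive", "final"):
        raise ValueError("mode must be 'consecutive' or 'final'")
    rng = np.random.default_rng(seed)
    n_stimulus = obs.n_stimulus
    curves = np.empty((n_shuffle, n_partition - 1))
    for shuffle in range(n_shuffle):
        order = rng.permutation(obs.n_trial)
        bounds = np.linspace(0, obs.n_trial, n_partition + 1).astype(int)
        mats = []
        for p in range(1, n_partition + 1):
            part = obs.subset(order[: bounds[p]])
            result = fit(
                part, n_dim, kernel, n_restart=n_restart,
                seed=int(rng.integers(2**31)), n_stimulus=n_stimulus,
            )
            mats.append(similarity_matrix(result.embedding))
        if mode == "consecutive":
            curves[shuffle] = [
                matrix_correlation(mats[p - 1], mats[p])
                for p in range(1, n_partition)
            ]
        else:
            curves[shuffle] = [
                matrix_correlation(mats[p], mats[-1])
                for p in range(n_partition - 1)
            ]
    return curves


def compare_kernels(
    obs: Observations,
    n_dim: int,
    families=("exponential", "student_t", "inverse", "heavy_tailed"),
    n_fold: int = 4,
    n_restart: int = 2,
    seed: int | None = None,
) -> dict[str, np.ndarray]:
    """Cross-validated validation losses for several kernel families.

    Returns per-family arrays of per-fold validation (negative mean
    log-likelihood) losses, fold-stratified by trial configuration, suitable
    for paired comparisons between families.
    """
    rng = np.random.default_rng(seed)
    keys = np.stack(
        [obs.n_reference, obs.n_select, obs.is_ranked.astype(np.int64)], axis=1
    )
    fold_of = np.empty(obs.n_trial, dtype=int)
    for key in np.unique(keys, axis=0):
        idx = np.flatnonzero(np.all(keys == key, axis=1))
        idx = rng.permutation(idx)
        fold_of[idx] = np.arange(idx.size) % n_fold
    n_stimulus = obs.n_stimulus
    losses = {family: np.empty(n_fold) for family in families}
    for fold in range(n_fold):
        train = obs.subset(fold_of != fold)
        val = obs.subset(fold_of == fold)
        for family in families:
            result = fit(
                train, n_dim, family, n_restart=n_restart,
                seed=int(rng.integers(2**31)), n_stimulus=n_stimulus,
            )
            losses[family][fold] = _loss(result.embedding, val)
    return losses


def validation_loss(emb: PsychEmbedding, obs: Observations) -> float:
    """Negative mean log-likelihood of held-out observations."""
    return _loss(emb, obs)
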