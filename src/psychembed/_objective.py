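"""Vectorized log-likelihood and analytic gradients for fitting.

Trials are compiled into blocks of identical configuration so each block is
one batched numpy computation.  For an ordered selection the log probability
under sequential removal is

    log p_i = sum_j [ log s_j - log(total - sum_{l<j} s_l) ],

with the selected references occupying the first ``n_select`` columns.  The
gradient with respect to the per-reference similarities has closed form, and
is chained through the kernel and the weighted Minkowski distance to the
coordinates, the kernel parameters, and the attention-weight logits.
Positive kernel parameters are optimized through a shifted-softplus
bijection; attention-weight rows through a softmax scaled by D, so both
constraint sets hold at every optimizer step.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logsumexp

from .kernel import PARAM_LOWER, KernelParams, similarity_and_grads
from .trials import Observations

PROB_FLOOR = 2.2e-16
LOG_FLOOR = float(np.log(PROB_FLOOR))
_TINY = 1e-300


@dataclass
class TrialBlock:
    """All trials sharing one (n_reference, n_select, is_ranked) shape."""

    query: np.ndarray  # (t,)
    refs: np.ndarray  # (t, n_reference)
    group: np.ndarray  # (t,)
    n_select: int
    is_ranked: bool

    @property
    def n_trial(self) -> int:
        return self.query.shape[0]


def compile_observations(obs: Observations) -> list[TrialBlock]:
    """Group observation rows into homogeneous-configuration blocks."""
    n_ref = obs.n_reference
    group_id = getattr(obs, "group_id", None)
    if group_id is None:
        group_id = np.zeros(obs.n_trial, dtype=np.int64)
    blocks = []
    keys = np.stack([n_ref, obs.n_select, obs.is_ranked.astype(np.int64)], axis=1)
    if obs.n_trial == 0:
        return blocks
    for key in np.unique(keys, axis=0):
        mask = np.all(keys == key, axis=1)
        m, n_sel, ranked = int(key[0]), int(key[1]), bool(key[2])
        blocks.append(
            TrialBlock(
                query=obs.stimulus_set[mask, 0],
                refs=obs.stimulus_set[mask, 1 : 1 + m],
                group=group_id[mask],
                n_select=n_sel,
                is_ranked=ranked,
            )
        )
    return blocks


def _ranked_logp_and_grad(s: np.ndarray, n_sel: int, need_grad: bool):
    """Log probability of the first-``n_sel``-in-order outcome, and d/ds."""
    t, m = s.shape
    s_safe = np.maximum(s, _TINY)
    total = s_safe.sum(axis=1)
    cum = np.cumsum(s_safe, axis=1)
    removed = cum[:, :n_sel] - s_safe[:, :n_sel]
    denom = np.maximum(total[:, None] - removed, _TINY)
    logp = np.log(s_safe[:, :n_sel]).sum(axis=1) - np.log(denom).sum(axis=1)
    if not need_grad:
        return logp, None
    invden = 1.0 / denom
    cuminv = np.cumsum(invden, axis=1)
    idx = np.minimum(np.arange(m), n_sel - 1)
    g = -cuminv[:, idx]
    g[:, :n_sel] += 1.0 / s_safe[:, :n_sel]
    return logp, g


def _block_logp_and_grad(s: np.ndarray, block: TrialBlock, need_grad: bool):
    """Per-trial log probability of the recorded outcome and d logp / d s."""
    n_sel = block.n_select
    if block.is_ranked:
        logp, g = _ranked_logp_and_grad(s, n_sel, need_grad)
    else:
        perms = list(itertools.permutations(range(n_sel)))
        t, m = s.shape
        logps = np.empty((len(perms), t))
        grads = np.empty((len(perms), t, m)) if need_grad else None
        tail = np.arange(n_sel, m)
        for p_i, perm in enumerate(perms):
            order = np.concatenate([np.array(perm), tail])
            lp, gp = _ranked_logp_and_grad(s[:, order], n_sel, need_grad)
            logps[p_i] = lp
            if need_grad:
                back = np.empty(m, dtype=np.int64)
                back[order] = np.arange(m)
                grads[p_i] = gp[:, back]
        logp = logsumexp(logps, axis=0)
        if need_grad:
            omega = np.exp(logps - logp)  # (P, t)
            g = np.einsum("pt,ptm->tm", omega, grads)
        else:
            g = None
    # probability floor: floored trials contribute a constant, zero gradient
    floored = logp < LOG_FLOOR
    if floored.any():
        logp = np.where(floored, LOG_FLOOR, logp)
        if need_grad:
            g = np.where(floored[:, None], 0.0, g)
    return logp, g


def block_value_and_grads(z, params: KernelParams, weights, block: TrialBlock,
                          wrt_params=(), need_grad=True):
    """Sum of log probabilities of one block; gradients if requested.

    Returns ``(value, gz, gw, gtheta)`` where gradient terms are None when
    ``need_grad`` is False.
    """
    rho = params.rho
    n, n_dim = z.shape
    Zq = z[block.query]  # (t, D)
    Zr = z[block.refs]  # (t, m, D)
    W = weights[block.group]  # (t, D)
    diff = Zq[:, None, :] - Zr
    absd = np.abs(diff)
    powd = absd**rho
    inner = np.einsum("td,tmd->tm", W, powd)
    dist = inner ** (1.0 / rho)
    s, ds_dd, pgrads = similarity_and_grads(dist, params, wrt_params)
    logp, gs = _block_logp_and_grad(s, block, need_grad)
    value = float(logp.sum())
    if not need_grad:
        return value, None, None, None

    dL_dd = gs * ds_dd  # (t, m)
    pos = dist > 0.0
    dist_pow = np.where(pos, np.where(pos, dist, 1.0) ** (1.0 - rho), 0.0)
    c = dL_dd * dist_pow
    base = W[:, None, :] * absd ** (rho - 1.0) * np.sign(diff)  # (t, m, D)
    gq = np.einsum("tm,tmd->td", c, base)
    gr = -c[..., None] * base
    gz = np.zeros_like(z)
    np.add.at(gz, block.query, gq)
    np.add.at(gz, block.refs.reshape(-1), gr.reshape(-1, n_dim))

    gw = np.zeros_like(weights)
    gw_rows = np.einsum("tm,tmd->td", c, powd) / rho
    np.add.at(gw, block.group, gw_rows)

    gtheta = {name: float((gs * pg).sum()) for name, pg in pgrads.items()}
    return value, gz, gw, gtheta


def total_log_likelihood(z, params: KernelParams, weights,
                         blocks: list[TrialBlock]) -> float:
    """Summed (floored) log likelihood over compiled blocks."""
    weights = np.atleast_2d(weights)
    return sum(
        block_value_and_grads(z, params, weights, b, need_grad=False)[0]
        for b in blocks
    )


def _softplus(x):
    return np.logaddexp(0.0, x)


def _softplus_inv(y):
    y = np.asarray(y, dtype=float)
    small = y < 20.0
    return np.where(small, np.log(np.expm1(np.maximum(y, 1e-12))), y)


class ParameterPacker:
    """Maps (Z, kernel params, attention weights) to one flat free vector.

    Kernel parameters listed in ``params.trainable`` enter as
    softplus-inverse values shifted by their lower bound; attention weights
    (when trained) enter as per-row softmax logits scaled to sum to D.
    """

    def __init__(self, n_stimulus: int, n_dim: int, params: KernelParams,
                 n_group: int, train_weights: bool):
        self.n = n_stimulus
        self.d = n_dim
        self.template = params
        self.theta_names = tuple(params.trainable)
        self.k = n_group
        self.train_weights = bool(train_weights)
        self.n_z = self.n * self.d
        self.n_theta = len(self.theta_names)
        self.n_w = self.k * self.d if self.train_weights else 0
        self.size = self.n_z + self.n_theta + self.n_w

    def pack(self, z, params: KernelParams, weights) -> np.ndarray:
        x = np.empty(self.size)
        x[: self.n_z] = np.asarray(z, dtype=float).ravel()
        for i, name in enumerate(self.theta_names):
            lo = PARAM_LOWER[name]
            x[self.n_z + i] = _softplus_inv(getattr(params, name) - lo)
        if self.train_weights:
            w = np.maximum(np.atleast_2d(weights), 1e-12)
            logits = np.log(w)
            logits -= logits.mean(axis=1, keepdims=True)
            x[self.n_z + self.n_theta :] = logits.ravel()
        return x

    def unpack(self, x: np.ndarray):
        z = x[: self.n_z].reshape(self.n, self.d)
        values = {}
        for i, name in enumerate(self.theta_names):
            lo = PARAM_LOWER[name]
            # floor guards against softplus underflow for strictly
            # positive parameters
            values[name] = float(lo + max(_softplus(x[self.n_z + i]), 1e-10))
        params = self.template.with_values(**values) if values else self.template
        if self.train_weights:
            logits = x[self.n_z + self.n_theta :].reshape(self.k, self.d)
            e = np.exp(logits - logits.max(axis=1, keepdims=True))
            weights = self.d * e / e.sum(axis=1, keepdims=True)
        else:
            weights = None
        return z, params, weights

    def pack_grad(self, x, gz, gtheta: dict, gw) -> np.ndarray:
        g = np.empty(self.size)
        g[: self.n_z] = gz.ravel()
        for i, name in enumerate(self.theta_names):
            g[self.n_z + i] = gtheta.get(name, 0.0) * expit(x[self.n_z + i])
        if self.train_weights:
            logits = x[self.n_z + self.n_theta :].reshape(self.k, self.d)
            e = np.exp(logits - logits.max(axis=1, keepdims=True))
            sigma = e / e.sum(axis=1, keepdims=True)
            inner = (sigma * gw).sum(axis=1, keepdims=True)
            gv = self.d * sigma * (gw - inner)
            g[self.n_z + self.n_theta :] = gv.ravel()
        return g


def make_objective(blocks: list[TrialBlock], packer: ParameterPacker,
                   fixed_weights=None):
    """Negative mean log-likelihood and gradient as a function of x."""
    n_trial = sum(b.n_trial for b in blocks)
    scale = 1.0 / max(n_trial, 1)

    def objective(x):
        # line-search probes can momentarily blow up coordinates; the
        # resulting non-finite losses are handled by the optimizer and
        # the restart loop, so the intermediate overflows are expected
        with np.errstate(over="ignore", invalid="ignore"):
            return _evaluate(x)

    def _evaluate(x):
        z, params, weights = packer.unpack(x)
        if weights is None:
            weights = fixed_weights
        value = 0.0
        gz = np.zeros_like(z)
        gw = np.zeros_like(weights)
        gtheta = {name: 0.0 for name in packer.theta_names}
        for block in blocks:
            v, bz, bw, bt = block_value_and_grads(
                z, params, weights, block, wrt_params=packer.theta_names
            )
            value += v
            gz += bz
            gw += bw
            for name in packer.theta_names:
                gtheta[name] += bt[name]
        loss = -value * scale
        grad = packer.pack_grad(
            x, -gz * scale, {k: -v * scale for k, v in gtheta.items()},
            -gw * scale,
        )
        return loss, grad

    return objective
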