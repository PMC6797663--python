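"""Weighted Minkowski distance and parameterized similarity kernels.

Similarity between two stimuli is a decreasing function of the weighted
Minkowski distance between their embedding points,

    d(z_m, z_n) = ( sum_j w_j |z_mj - z_nj|^rho )^(1/rho),

where the nonnegative attention weights w sum to the dimensionality D, so
uniform weights recover the ordinary Minkowski distance.  Four kernel
families map distance to similarity: an exponential family covering the
Gaussian/Laplacian kernels of classic generalization theory, the Student's-t
kernel popular in machine learning, an inverse-distance kernel, and a
heavy-tailed generalization of Student's-t.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np

FAMILIES = ("exponential", "student_t", "inverse", "heavy_tailed")

# family -> ordered tuple of its free parameter names (rho handled separately)
FAMILY_PARAMS = {
    "exponential": ("beta", "tau", "gamma"),
    "student_t": ("alpha",),
    "inverse": ("mu", "tau"),
    "heavy_tailed": ("kappa", "tau", "alpha"),
}

MU_FLOOR = 1e-7
# lower bounds enforced by the softplus reparameterization during fitting
PARAM_LOWER = {
    "beta": 0.0,
    "tau": 0.0,
    "gamma": 0.0,
    "alpha": 0.0,
    "mu": MU_FLOOR,
    "kappa": 0.0,
}

# ranges for random restarts, recorded here so runs are reproducible
INIT_RANGES = {
    "beta": (1.0, 30.0),
    "tau": (1.0, 2.0),
    "gamma": (0.0, 0.001),
    "alpha": (1.0, 10.0),
    "mu": (1e-4, 1e-2),
    "kappa": (1.0, 11.0),
}


@dataclass(frozen=True)
class KernelParams:
    """Similarity-kernel family plus its parameter values.

    ``rho`` is the Minkowski distance order, fixed (not trained) by default
    at 2; the Student's-t kernel always uses the 2-norm.  ``trainable``
    lists the parameters adjusted during fitting.
    """

    family: str = "exponential"
    rho: float = 2.0
    beta: float = 10.0
    tau: float = 1.0
    gamma: float = 0.0
    alpha: float = 2.0
    mu: float = 1e-3
    kappa: float = 2.0
    trainable: tuple[str, ...] = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown kernel family {self.family!r}")
        if self.family == "student_t" and self.rho != 2.0:
            object.__setattr__(self, "rho", 2.0)
        if self.rho < 1.0:
            raise ValueError(f"rho must be >= 1, got {self.rho}")
        if self.trainable is None:
            object.__setattr__(self, "trainable", FAMILY_PARAMS[self.family])
        else:
            object.__setattr__(self, "trainable", tuple(self.trainable))
            bad = set(self.trainable) - set(FAMILY_PARAMS[self.family])
            if bad:
                raise ValueError(
                    f"trainable params {sorted(bad)} not part of {self.family}"
                )
        for name in FAMILY_PARAMS[self.family]:
            lo = PARAM_LOWER[name]
            value = getattr(self, name)
            strict = name in ("beta", "tau", "alpha")
            if value < lo or (strict and value <= 0.0):
                raise ValueError(f"{name}={value} violates lower bound {lo}")

    @property
    def free_params(self) -> tuple[str, ...]:
        return FAMILY_PARAMS[self.family]

    def with_values(self, **values) -> "KernelParams":
        return replace(self, **values)

    def frozen(self) -> "KernelParams":
        """A copy with no trainable parameters (all held fixed)."""
        return replace(self, trainable=())

    def to_dict(self) -> dict:
        out = {"family": self.family, "rho": self.rho,
               "trainable": list(self.trainable)}
        for name in self.free_params:
            out[name] = float(getattr(self, name))
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "KernelParams":
        data = dict(data)
        data["trainable"] = tuple(data.get("trainable", ()))
        return cls(**data)


def weighted_minkowski(z_m, z_n, w=None, rho: float = 2.0) -> np.ndarray:
    """Attention-weighted Minkowski distance between points.

    Broadcasts over leading axes; the last axis is the embedding dimension.
    With ``w=None`` uniform weights (all ones) are used.
    """
    z_m = np.asarray(z_m, dtype=float)
    z_n = np.asarray(z_n, dtype=float)
    if z_m.shape[-1] != z_n.shape[-1]:
        raise ValueError("dimension mismatch between z_m and z_n")
    if rho < 1.0:
        raise ValueError(f"rho must be >= 1, got {rho}")
    diff = np.abs(z_m - z_n)
    if w is None:
        w = np.ones(z_m.shape[-1])
    w = np.asarray(w, dtype=float)
    if (w < 0).any():
        raise ValueError("attention weights must be nonnegative")
    return np.sum(w * diff**rho, axis=-1) ** (1.0 / rho)


def sim_exponential(d, beta: float, tau: float, gamma: float = 0.0):
    """Exponential-family kernel: exp(-beta * d^tau) + gamma."""
    d = _check_distance(d)
    return np.exp(-beta * d**tau) + gamma


def sim_student_t(d, alpha: float):
    """Student's-t kernel: (1 + d^2/alpha)^(-(alpha+1)/2)."""
    d = _check_distance(d)
    return (1.0 + d**2 / alpha) ** (-(alpha + 1.0) / 2.0)


def sim_inverse(d, mu: float, tau: float):
    """Inverse-distance kernel: 1 / (mu + d^tau); mu keeps d=0 finite."""
    d = _check_distance(d)
    return 1.0 / (mu + d**tau)


def sim_heavy_tailed(d, kappa: float, tau: float, alpha: float):
    """Heavy-tailed kernel: (kappa + d^tau)^(-alpha)."""
    d = _check_distance(d)
    if kappa == 0.0 and np.any(d == 0.0):
        raise ValueError("heavy-tailed kernel undefined at d=0 when kappa=0")
    return (kappa + d**tau) ** (-alpha)


def _check_distance(d):
    d = np.asarray(d, dtype=float)
    if (d < 0).any():
        raise ValueError("distance must be nonnegative")
    return d


def similarity(d, params: KernelParams) -> np.ndarray:
    """Evaluate the kernel named by ``params.family`` at distances ``d``."""
    if params.family == "exponential":
        return sim_exponential(d, params.beta, params.tau, params.gamma)
    if params.family == "student_t":
        return sim_student_t(d, params.alpha)
    if params.family == "inverse":
        return sim_inverse(d, params.mu, params.tau)
    return sim_heavy_tailed(d, params.kappa, params.tau, params.alpha)


def similarity_and_grads(d, params: KernelParams, wrt: Iterable[str] = ()):
    """Kernel value, derivative in d, and derivatives in selected parameters.

    Returns ``(s, ds_dd, {name: ds_dname})``.  Used by the fitting machinery;
    derivatives at d=0 for terms involving log d are taken as 0 (the
    one-sided limit along the parameter direction).
    """
    d = np.asarray(d, dtype=float)
    wrt = tuple(wrt)
    grads = {}
    pos = d > 0.0
    safe_d = np.where(pos, d, 1.0)
    logd = np.where(pos, np.log(safe_d), 0.0)
    if params.family == "exponential":
        dt = d**params.tau
        core = np.exp(-params.beta * dt)
        s = core + params.gamma
        ds_dd = -params.beta * params.tau * safe_d ** (params.tau - 1.0) * core
        ds_dd = np.where(pos, ds_dd, 0.0)
        if "beta" in wrt:
            grads["beta"] = -dt * core
        if "tau" in wrt:
            grads["tau"] = -params.beta * dt * logd * core
        if "gamma" in wrt:
            grads["gamma"] = np.ones_like(d)
    elif params.family == "student_t":
        a = params.alpha
        u = 1.0 + d**2 / a
        s = u ** (-(a + 1.0) / 2.0)
        ds_dd = -(a + 1.0) * d / a * u ** (-(a + 3.0) / 2.0)
        if "alpha" in wrt:
            grads["alpha"] = s * (
                -0.5 * np.log(u) + (a + 1.0) * d**2 / (2.0 * a**2 * u)
            )
    elif params.family == "inverse":
        dt = d**params.tau
        s = 1.0 / (params.mu + dt)
        ds_dd = -params.tau * safe_d ** (params.tau - 1.0) * s**2
        ds_dd = np.where(pos, ds_dd, 0.0)
        if "mu" in wrt:
            grads["mu"] = -(s**2)
        if "tau" in wrt:
            grads["tau"] = -dt * logd * s**2
    else:  # heavy_tailed
        dt = d**params.tau
        g = params.kappa + dt
        s = g ** (-params.alpha)
        base = g ** (-params.alpha - 1.0)
        ds_dd = -params.alpha * params.tau * safe_d ** (params.tau - 1.0) * base
        ds_dd = np.where(pos, ds_dd, 0.0)
        if "kappa" in wrt:
            grads["kappa"] = -params.alpha * base
        if "tau" in wrt:
            grads["tau"] = -params.alpha * dt * logd * base
        if "alpha" in wrt:
            grads["alpha"] = -np.log(g) * s
    return s, ds_dd, grads


def random_params(family: str, rng: np.random.Generator,
                  rho: float = 2.0) -> KernelParams:
    """Draw kernel parameters uniformly from the documented restart ranges."""
    values = {}
    for name in FAMILY_PARAMS[family]:
        lo, hi = INIT_RANGES[name]
        values[name] = float(rng.uniform(lo, hi))
    return KernelParams(family=family, rho=rho, **values)


def validate_weights(weights: np.ndarray, n_dim: int) -> np.ndarray:
    """Check the attention-weight invariants: w >= 0, each row sums to D."""
    weights = np.atleast_2d(np.asarray(weights, dtype=float))
    if weights.shape[1] != n_dim:
        raise ValueError(
            f"weights have {weights.shape[1]} columns, expected {n_dim}"
        )
    if (weights < 0).any():
        raise ValueError("attention weights must be nonnegative")
    sums = weights.sum(axis=1)
    if not np.allclose(sums, n_dim, rtol=1e-6, atol=1e-6):
        raise ValueError(
            f"each attention-weight row must sum to the dimensionality "
            f"{n_dim}; got row sums {sums}"
        )
    return weights


def uniform_weights(n_group: int, n_dim: int) -> np.ndarray:
    return np.ones((n_group, n_dim))
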