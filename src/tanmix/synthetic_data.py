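"""Simulators for the synthetic study conditions.

Three latent-mixture scenarios and one class-conditional chain:

* ``sim_gmm_scenario`` — d-dimensional bimodal latent mixture
  pi(theta) = 0.5 N(mu1, 2I) + 0.5 N(mu2, I) with mu1 = (-3, ..., -3),
  mu2 = (3, ..., 3); observations x = theta + N(0, I).
* ``sim_gamm_scenario`` — latent theta_j ~ Beta(10, 5) i.i.d. per coordinate
  (support (0, 1)); observations x_j ~ Gamma(shape 10, rate theta_j).
* ``sim_trimodal`` — 1-D data density 1/3 N(-3, 0.5^2) + 1/3 N(0, 1) +
  1/3 N(3, 0.7^2): trimodal, long-tailed, heteroskedastic.  Here the
  estimand is the data density itself (no deconvolution).
* ``sim_tan_chain`` — binary class C ~ Bernoulli(1/2) and eight continuous
  attributes forming the fixed chain X1 -> X2 -> ... -> X8: X1 | C = c ~
  N(mu1(c), sigma1^2) and Xj | X_{j-1}, C = c ~ N(a_j(c) X_{j-1} + b_j(c),
  sigma_j^2).  Chain coefficients are drawn once from ``param_seed`` and
  fixed across trials; the defaults give within-class parent-child
  correlations strong enough that the chain is recoverable.

Every generator is a pure function of its seeds and sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import stats

from .observation_models import ObservationModel

__all__ = [
    "ScenarioSample",
    "ChainDataset",
    "sim_gmm_scenario",
    "sim_gamm_scenario",
    "sim_trimodal",
    "sim_tan_chain",
    "chain_adjacency",
]

GMM_MODES = (-3.0, 3.0)
GMM_COMPONENT_VARS = (2.0, 1.0)
GAMM_BETA = (10.0, 5.0)
TRIMODAL_MEANS = (-3.0, 0.0, 3.0)
TRIMODAL_SDS = (0.5, 1.0, 0.7)


@dataclass
class ScenarioSample:
    """Latent draws, observations, and the closed-form truth of a scenario."""

    scenario: str
    theta: np.ndarray  # (n, d) latent draws
    x: np.ndarray  # (n, d) observations
    observation_model: ObservationModel
    seed: int
    mixing_marginal_pdf: Callable[[np.ndarray], np.ndarray]
    mixing_sampler: Callable[[int, np.random.Generator], np.ndarray]
    observed_marginal_pdf: Callable[[np.ndarray], np.ndarray] | None = None
    mixing_joint_pdf: Callable[[np.ndarray], np.ndarray] | None = None

    @property
    def n(self) -> int:
        return self.x.shape[0]

    @property
    def dim(self) -> int:
        return self.x.shape[1]


def _gmm_marginal_pdf(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return 0.5 * stats.norm.pdf(x, GMM_MODES[0], np.sqrt(GMM_COMPONENT_VARS[0])) + \
        0.5 * stats.norm.pdf(x, GMM_MODES[1], np.sqrt(GMM_COMPONENT_VARS[1]))


def _gmm_observed_marginal_pdf(x: np.ndarray) -> np.ndarray:
    # observation adds unit-variance noise per coordinate
    x = np.asarray(x, dtype=float)
    return 0.5 * stats.norm.pdf(x, GMM_MODES[0], np.sqrt(GMM_COMPONENT_VARS[0] + 1)) + \
        0.5 * stats.norm.pdf(x, GMM_MODES[1], np.sqrt(GMM_COMPONENT_VARS[1] + 1))


def sim_gmm_scenario(n: int, d: int = 2, seed: int = 0) -> ScenarioSample:
    """Bimodal Gaussian latent mixture with unit-variance observation noise."""
    if n < 1 or d < 1:
        raise ValueError("n and d must be >= 1")
    rng = np.random.default_rng(seed)
    comp = rng.random(n) < 0.5  # exact fair-coin component choice
    mu = np.where(comp[:, None], GMM_MODES[0], GMM_MODES[1])
    sd = np.where(comp[:, None], np.sqrt(GMM_COMPONENT_VARS[0]),
                  np.sqrt(GMM_COMPONENT_VARS[1]))
    theta = mu + sd * rng.standard_normal((n, d))
    x = theta + rng.standard_normal((n, d))

    def mixing_sampler(m: int, r: np.random.Generator) -> np.ndarray:
        c = r.random(m) < 0.5
        mm = np.where(c[:, None], GMM_MODES[0], GMM_MODES[1])
        ss = np.where(c[:, None], np.sqrt(GMM_COMPONENT_VARS[0]),
                      np.sqrt(GMM_COMPONENT_VARS[1]))
        return mm + ss * r.standard_normal((m, d))

    def joint_pdf(T: np.ndarray) -> np.ndarray:
        T = np.atleast_2d(np.asarray(T, dtype=float))
        out = np.zeros(T.shape[0])
        for wk, mk, vk in zip((0.5, 0.5), GMM_MODES, GMM_COMPONENT_VARS):
            z2 = np.sum((T - mk) ** 2, axis=1) / vk
            out += wk * np.exp(-0.5 * z2) / (2 * np.pi * vk) ** (d / 2.0)
        return out

    return ScenarioSample(
        scenario="gmm", theta=theta, x=x,
        observation_model=ObservationModel("gaussian_location", dim=d, scale=1.0),
        seed=seed,
        mixing_marginal_pdf=_gmm_marginal_pdf,
        mixing_sampler=mixing_sampler,
        observed_marginal_pdf=_gmm_observed_marginal_pdf,
        mixing_joint_pdf=joint_pdf,
    )


def sim_gamm_scenario(n: int, d: int = 2, seed: int = 0) -> ScenarioSample:
    """Product-Beta(10, 5) latent rates with Gamma(10, theta_j) observations."""
    if n < 1 or d < 1:
        raise ValueError("n and d must be >= 1")
    a, b = GAMM_BETA
    rng = np.random.default_rng(seed)
    theta = rng.beta(a, b, size=(n, d))
    x = rng.gamma(shape=10.0, scale=1.0 / theta)

    def mixing_sampler(m: int, r: np.random.Generator) -> np.ndarray:
        return r.beta(a, b, size=(m, d))

    def joint_pdf(T: np.ndarray) -> np.ndarray:
        T = np.atleast_2d(np.asarray(T, dtype=float))
        return np.prod(stats.beta.pdf(T, a, b), axis=1)

    return ScenarioSample(
        scenario="gamm", theta=theta, x=x,
        observation_model=ObservationModel("gamma_rate", dim=d),
        seed=seed,
        mixing_marginal_pdf=lambda t: stats.beta.pdf(np.asarray(t, dtype=float), a, b),
        mixing_sampler=mixing_sampler,
        mixing_joint_pdf=joint_pdf,
    )


def trimodal_pdf(x: np.ndarray, weights=(1 / 3, 1 / 3, 1 / 3)) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    for wk, mk, sk in zip(weights, TRIMODAL_MEANS, TRIMODAL_SDS):
        out += wk * stats.norm.pdf(x, mk, sk)
    return out


def sim_trimodal(n: int, seed: int = 0,
                 weights=(1 / 3, 1 / 3, 1 / 3)) -> ScenarioSample:
    """Trimodal heteroskedastic 1-D mixture; the data density is the truth."""
    weights = np.asarray(weights, dtype=float)
    if weights.min() < 0 or not np.isclose(weights.sum(), 1.0):
        raise ValueError("weights must lie on the simplex")
    rng = np.random.default_rng(seed)
    comp = rng.choice(3, size=n, p=weights)
    means = np.asarray(TRIMODAL_MEANS)[comp]
    sds = np.asarray(TRIMODAL_SDS)[comp]
    x = (means + sds * rng.standard_normal(n))[:, None]

    def sampler(m: int, r: np.random.Generator) -> np.ndarray:
        c = r.choice(3, size=m, p=weights)
        return (np.asarray(TRIMODAL_MEANS)[c]
                + np.asarray(TRIMODAL_SDS)[c] * r.standard_normal(m))[:, None]

    pdf = lambda t: trimodal_pdf(t, tuple(weights))  # noqa: E731
    return ScenarioSample(
        scenario="trimodal", theta=x.copy(), x=x,
        observation_model=ObservationModel("gaussian_location", dim=1, scale=1.0),
        seed=seed,
        mixing_marginal_pdf=pdf,
        mixing_sampler=sampler,
        observed_marginal_pdf=pdf,
        mixing_joint_pdf=lambda T: pdf(np.atleast_2d(T)[:, 0]),
    )


# ---------------------------------------------------------------------------
# class-conditional linear-Gaussian chain


def chain_adjacency(d: int = 8) -> np.ndarray:
    a = np.zeros((d, d), dtype=int)
    for j in range(d - 1):
        a[j, j + 1] = a[j + 1, j] = 1
    return a


@dataclass
class ChainDataset:
    """Labelled chain sample with its generating parameters and true tree."""

    x: np.ndarray  # (n, 8)
    labels: np.ndarray  # (n,) in {0, 1}
    true_adjacency: np.ndarray
    params: dict = field(repr=False)
    seed: int = 0
    feature_names: tuple = tuple(f"X{j + 1}" for j in range(8))

    @property
    def n(self) -> int:
        return self.x.shape[0]


def sim_tan_chain(
    n: int,
    seed: int = 0,
    param_seed: int = 12345,
    strength: dict | None = None,
) -> ChainDataset:
    """Linear-Gaussian chain over 8 attributes with a binary class.

    Parameters are drawn once from ``param_seed`` and reused across trials:
    mu1(0) = -1, mu1(1) = +1, sigma1 = 1; for j = 2..8, |a_j(c)| uniform in
    [0.7, 1.3] with random sign, b_j(c) uniform in [-1, 1], sigma_j = 0.5.
    """
    if n < 16:
        raise ValueError("n must be >= 16")
    d = 8
    defaults = {"mu1": (-1.0, 1.0), "sigma1": 1.0,
                "a_range": (0.7, 1.3), "b_range": (-1.0, 1.0), "sigma_j": 0.5}
    if strength:
        defaults.update(strength)
    prng = np.random.default_rng(param_seed)
    a = np.empty((2, d))  # a[c, j]; column 0 unused
    b = np.empty((2, d))
    lo, hi = defaults["a_range"]
    blo, bhi = defaults["b_range"]
    for c in range(2):
        mag = prng.uniform(lo, hi, size=d)
        sign = np.where(prng.random(d) < 0.5, -1.0, 1.0)
        a[c] = mag * sign
        b[c] = prng.uniform(blo, bhi, size=d)
    params = {
        "mu1": defaults["mu1"], "sigma1": defaults["sigma1"],
        "a": a, "b": b, "sigma_j": defaults["sigma_j"],
        "param_seed": param_seed,
    }

    rng = np.random.default_rng(seed)
    labels = (rng.random(n) < 0.5).astype(int)
    X = np.empty((n, d))
    mu1 = np.asarray(defaults["mu1"])
    X[:, 0] = mu1[labels] + defaults["sigma1"] * rng.standard_normal(n)
    for j in range(1, d):
        X[:, j] = (a[labels, j] * X[:, j - 1] + b[labels, j]
                   + defaults["sigma_j"] * rng.standard_normal(n))
    return ChainDataset(x=X, labels=labels, true_adjacency=chain_adjacency(d),
                        params=params, seed=seed)
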