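"""Known observation families f(y | theta) for latent mixture models.

A latent mixture model draws theta_i ~ pi(theta) and then y_i ~ f(y | theta_i)
with f known.  Everything downstream (NPMLE, the generative bootstrap
estimator, the TAN density back-ends) only touches the observation model
through ``log_density`` / ``sample`` and the vectorised helpers here, so the
families are deliberately minimal:

* ``gaussian_location`` — y ~ N(theta, diag(scale^2)); theta carries locations
  only, the component scale is a model field.
* ``gaussian_location_diagonal`` — alias with per-dimension scales (the
  constructor stores scales per dimension either way).
* ``gamma_rate`` — y_j ~ Gamma(shape GAMMA_SHAPE, rate theta_j) independently
  per dimension; theta must be strictly positive componentwise.

All densities are computed in log space; mixtures over candidates are combined
with log-sum-exp by the callers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

GAUSSIAN_FAMILIES = ("gaussian_location", "gaussian_location_diagonal")
GAMMA_SHAPE = 10.0

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class ObservationModel:
    """A known conditional density f(y | theta) on R^d or (0, inf)^d."""

    family: str
    dim: int = 1
    scale: np.ndarray | float | None = None
    _scale_vec: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ValueError(f"dim must be >= 1, got {self.dim}")
        if self.family in GAUSSIAN_FAMILIES:
            s = 1.0 if self.scale is None else self.scale
            vec = np.broadcast_to(np.asarray(s, dtype=float), (self.dim,)).copy()
            if np.any(vec <= 0):
                raise ValueError("gaussian scale must be strictly positive")
        elif self.family == "gamma_rate":
            if self.scale is not None:
                raise ValueError("gamma_rate has a fixed shape; scale is not a field")
            vec = np.empty(0)
        else:
            raise ValueError(f"unknown observation family {self.family!r}")
        object.__setattr__(self, "_scale_vec", vec)

    # -- parameter / support validation ------------------------------------

    @property
    def positive_parameters(self) -> bool:
        return self.family == "gamma_rate"

    def validate_theta(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_1d(np.asarray(theta, dtype=float))
        if theta.shape[-1] != self.dim and theta.size == self.dim:
            theta = theta.reshape(self.dim)
        if theta.shape[-1] != self.dim:
            raise ValueError(
                f"theta has {theta.shape[-1]} components, model dim is {self.dim}"
            )
        if not np.all(np.isfinite(theta)):
            raise ValueError("theta contains non-finite components")
        if self.family == "gamma_rate":
            bad = np.where(theta <= 0)
            if bad[0].size:
                raise ValueError(
                    f"gamma_rate requires strictly positive theta; "
                    f"component {tuple(int(b[0]) for b in bad)} is not"
                )
        return theta

    def in_support(self, y: np.ndarray) -> np.ndarray:
        """Boolean mask over rows of ``y`` (n, d)."""
        y = np.atleast_2d(np.asarray(y, dtype=float))
        ok = np.all(np.isfinite(y), axis=1)
        if self.family == "gamma_rate":
            ok &= np.all(y > 0, axis=1)
        return ok

    def check_support(self, y: np.ndarray) -> np.ndarray:
        y = np.atleast_2d(np.asarray(y, dtype=float))
        ok = self.in_support(y)
        if not np.all(ok):
            row = int(np.flatnonzero(~ok)[0])
            raise ValueError(f"data row {row} lies outside the support of {self.family}")
        return y


# ---------------------------------------------------------------------------
# densities


def log_density(model: ObservationModel, y: np.ndarray, theta: np.ndarray) -> float:
    """log f(y | theta) at a single point y in R^d."""
    theta = model.validate_theta(theta)
    y = model.check_support(np.asarray(y, dtype=float).reshape(1, model.dim))
    return float(log_density_matrix(model, y, theta.reshape(model.dim, 1))[0, 0])


def log_density_matrix(
    model: ObservationModel, Y: np.ndarray, Theta: np.ndarray
) -> np.ndarray:
    """log f(y_i | theta^(j)) for all rows of Y (n, d) and columns of Theta (d, l).

    The workhorse of every estimator here; fully vectorised, no support
    re-checks (callers validate once).
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    Theta = np.asarray(Theta, dtype=float)
    if Theta.ndim == 1:
        Theta = Theta.reshape(model.dim, -1)
    if model.family in GAUSSIAN_FAMILIES:
        s = model._scale_vec  # (d,)
        # squared-distance expansion ||a - b||^2 = |a|^2 + |b|^2 - 2 a.b so
        # the (n, l) matrix comes from one GEMM instead of an (n, l, d) tensor
        U = Y / s
        V = (Theta.T / s)  # (l, d)
        sq = (
            np.sum(U * U, axis=1)[:, None]
            + np.sum(V * V, axis=1)[None, :]
            - 2.0 * (U @ V.T)
        )
        np.maximum(sq, 0.0, out=sq)
        const = -0.5 * model.dim * _LOG_2PI - float(np.sum(np.log(s)))
        return const - 0.5 * sq
    # gamma_rate: shape k fixed, theta is the rate; mean k / theta
    k = GAMMA_SHAPE
    logY = np.log(Y)  # caller guarantees positivity
    t1 = k * np.sum(np.log(Theta), axis=0)  # (l,)
    t2 = (k - 1.0) * np.sum(logY, axis=1)  # (n,)
    t3 = Y @ Theta  # (n, l)
    return t1[None, :] + t2[:, None] - t3 - model.dim * gammaln(k)


def grad_log_density_theta(
    model: ObservationModel, Y: np.ndarray, Theta: np.ndarray
) -> np.ndarray:
    """d log f(y_i | theta^(j)) / d theta, shape (n, d, l).

    Used by the generator's backward pass: gaussian gives (y - theta) / scale^2,
    gamma-rate gives k / theta - y.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    Theta = np.asarray(Theta, dtype=float)
    if model.family in GAUSSIAN_FAMILIES:
        s2 = model._scale_vec**2
        return (Y[:, :, None] - Theta[None, :, :]) / s2[None, :, None]
    return GAMMA_SHAPE / Theta[None, :, :] - Y[:, :, None]


# ---------------------------------------------------------------------------
# sampling


def sample(
    model: ObservationModel,
    theta: np.ndarray,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw n points from f(. | theta); returns an (n, d) array."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    theta = model.validate_theta(theta)
    if model.family in GAUSSIAN_FAMILIES:
        return theta[None, :] + model._scale_vec * rng.standard_normal((n, model.dim))
    return rng.gamma(shape=GAMMA_SHAPE, scale=1.0 / theta, size=(n, model.dim))
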