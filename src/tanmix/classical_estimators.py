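"""Classical comparison estimators: weighted-bootstrap NPMLE, KDE, GMM-EM.

The nonparametric MLE of a mixing distribution (Kiefer–Wolfowitz) is computed
by EM over the masses on a fixed support; the weighted-likelihood bootstrap
version refits it under scaled-Dirichlet weight draws and averages the
resulting discrete measures.  KDE is a product-Gaussian kernel estimator with
the normal-reference (Silverman) bandwidth rule; Gaussian-mixture EM is
delegated to scikit-learn.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from sklearn.mixture import GaussianMixture

from .fgbmle_core import sample_bootstrap_weights
from .observation_models import ObservationModel, log_density_matrix

__all__ = [
    "DiscreteMixingDistribution",
    "BootstrapEnsemble",
    "npmle_em",
    "bootstrap_npmle",
    "ProductKDE",
    "kde",
    "gmm_em",
]


@dataclass
class DiscreteMixingDistribution:
    """A discrete measure: s support points in R^d with simplex masses.

    The NPMLE of a mixing distribution is of this form with at most n support
    points carrying mass.
    """

    support: np.ndarray  # (s, d)
    mass: np.ndarray  # (s,)
    loglik_trace: list | None = None

    def __post_init__(self) -> None:
        self.support = np.atleast_2d(np.asarray(self.support, dtype=float))
        self.mass = np.asarray(self.mass, dtype=float)
        if self.support.shape[0] != self.mass.shape[0]:
            raise ValueError("support and mass lengths differ")
        if np.any(self.mass < -1e-12):
            raise ValueError("negative mass")
        total = self.mass.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"masses sum to {total}, expected 1")

    @property
    def dim(self) -> int:
        return self.support.shape[1]

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        idx = rng.choice(self.support.shape[0], size=n, p=self.mass / self.mass.sum())
        return self.support[idx]

    def smoothed_pdf(self, X: np.ndarray, bandwidth: float | None = None) -> np.ndarray:
        """Gaussian-kernel smoothing of the discrete measure, for ISE/MSE/KL.

        Default bandwidth: half the median nearest-neighbour spacing of the
        support (for grid supports this is half the grid spacing).
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if bandwidth is None:
            s = self.support
            if s.shape[0] > 1:
                order = np.argsort(s[:, 0])
                gaps = np.diff(s[order, 0])
                gaps = gaps[gaps > 0]
                bandwidth = 0.5 * float(np.median(gaps)) if gaps.size else 0.1
            else:
                bandwidth = 0.1
        d = self.dim
        z = (X[:, None, :] - self.support[None, :, :]) / bandwidth
        logk = -0.5 * np.sum(z * z, axis=2) - d * np.log(
            bandwidth * np.sqrt(2 * np.pi)
        )
        with np.errstate(divide="ignore"):
            logm = np.log(np.maximum(self.mass, 1e-300))
        return np.exp(logsumexp(logk + logm[None, :], axis=1))


@dataclass
class BootstrapEnsemble:
    """B weighted-bootstrap NPMLE fits and their averaged measure."""

    members: list

    @property
    def B(self) -> int:
        return len(self.members)

    def average(self) -> DiscreteMixingDistribution:
        """pi_bar = (1/B) sum_b pi_hat^(b); a single discrete measure."""
        if not self.members:
            raise ValueError("empty ensemble")
        first = self.members[0]
        same_support = all(
            m.support.shape == first.support.shape
            and np.array_equal(m.support, first.support)
            for m in self.members
        )
        if same_support:
            mass = np.mean([m.mass for m in self.members], axis=0)
            return DiscreteMixingDistribution(first.support, mass / mass.sum())
        support = np.vstack([m.support for m in self.members])
        mass = np.concatenate([m.mass for m in self.members]) / self.B
        return DiscreteMixingDistribution(support, mass / mass.sum())


def _resolve_support(data: np.ndarray, spec) -> np.ndarray:
    """Support rule: 1-D -> 200-point expanded grid; d >= 2 -> data points."""
    if isinstance(spec, np.ndarray):
        return np.atleast_2d(spec)
    if spec in (None, "auto"):
        spec = "grid" if data.shape[1] == 1 else "data"
    if spec == "data":
        return data.copy()
    if spec == "grid":
        if data.shape[1] != 1:
            raise ValueError("grid support rule is 1-D only")
        lo, hi = data.min(), data.max()
        pad = 0.1 * (hi - lo)
        return np.linspace(lo - pad, hi + pad, 200)[:, None]
    raise ValueError(f"unknown support spec {spec!r}")


def npmle_em(
    data: np.ndarray,
    obs: ObservationModel,
    weights: np.ndarray | None = None,
    support_spec="auto",
    max_iter: int = 500,
    tol: float = 1e-9,
) -> DiscreteMixingDistribution:
    """Weighted NPMLE of the mixing distribution by EM over fixed support.

    Maximises sum_i w_i log sum_k m_k f(y_i | s_k) in the masses m; the
    weighted log-likelihood is non-decreasing at every EM iteration (asserted
    by storing the trace).  Unit weights recover the plain NPMLE.
    """
    Y = obs.check_support(np.atleast_2d(np.asarray(data, dtype=float)))
    n = Y.shape[0]
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (n,):
        raise ValueError("weights length mismatch")
    support = _resolve_support(Y, support_spec)
    s = support.shape[0]
    if s < 1:
        raise ValueError("support resolves to zero points")
    logF = log_density_matrix(obs, Y, support.T)  # (n, s)
    row_max = logF.max(axis=1)
    if not np.all(np.isfinite(row_max)):
        row = int(np.flatnonzero(~np.isfinite(row_max))[0])
        raise FloatingPointError(
            f"data row {row} has zero likelihood under every support point"
        )
    # row-shifted linear-space likelihoods: exact, and the EM loop then needs
    # no per-iteration exp/log over the full (n, s) matrix
    F = np.exp(logF - row_max[:, None])
    mass = np.full(s, 1.0 / s)
    wsum = w.sum()
    trace = []
    prev = -np.inf
    for _ in range(max_iter):
        num = F * mass[None, :]
        norm = num.sum(axis=1)  # (n,) > 0 by construction
        ll = float(np.sum(w * (np.log(norm) + row_max)))
        trace.append(ll)
        mass = (w / norm) @ num / wsum
        mass = np.maximum(mass, 0.0)
        mass /= mass.sum()
        if ll - prev < tol * max(1.0, abs(ll)) and len(trace) > 1:
            break
        prev = ll
    return DiscreteMixingDistribution(support, mass, loglik_trace=trace)


def bootstrap_npmle(
    data: np.ndarray,
    obs: ObservationModel,
    B: int = 100,
    rng: np.random.Generator | None = None,
    support_spec="auto",
    max_iter: int = 500,
    tol: float = 1e-9,
) -> BootstrapEnsemble:
    """Weighted-likelihood bootstrap: B Dirichlet draws, one NPMLE each."""
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = rng or np.random.default_rng()
    Y = np.atleast_2d(np.asarray(data, dtype=float))
    support = _resolve_support(Y, support_spec)
    members = []
    for b in range(B):
        w = sample_bootstrap_weights(Y.shape[0], rng)
        try:
            members.append(
                npmle_em(Y, obs, weights=w, support_spec=support,
                         max_iter=max_iter, tol=tol)
            )
        except Exception as exc:  # annotate which member failed
            raise RuntimeError(f"bootstrap member {b} failed: {exc}") from exc
    return BootstrapEnsemble(members)


class ProductKDE:
    """Product-Gaussian kernel density estimate with per-dimension bandwidths.

    Bandwidth rules: ``silverman`` (normal reference 1.06 sigma_j n^(-1/5)),
    ``scott`` (sigma_j n^(-1/(d+4))), or a fixed positive number.
    """

    def __init__(self, data: np.ndarray, bandwidth_rule="silverman"):
        X = np.atleast_2d(np.asarray(data, dtype=float))
        if X.shape[0] < 2:
            raise ValueError("KDE needs at least 2 points")
        n, d = X.shape
        sd = X.std(axis=0, ddof=1)
        if np.any(sd <= 0):
            raise ValueError("degenerate data: zero variance in a dimension")
        if bandwidth_rule == "silverman":
            h = 1.06 * sd * n ** (-1.0 / 5.0)
        elif bandwidth_rule == "scott":
            h = sd * n ** (-1.0 / (d + 4.0))
        elif np.isscalar(bandwidth_rule):
            h = np.full(d, float(bandwidth_rule))
            if np.any(h <= 0):
                raise ValueError("fixed bandwidth must be positive")
        else:
            raise ValueError(f"unknown bandwidth rule {bandwidth_rule!r}")
        self.data = X
        self.bandwidth = h

    @property
    def dim(self) -> int:
        return self.data.shape[1]

    def logpdf(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        h = self.bandwidth
        # one GEMM via the squared-distance expansion (see log_density_matrix)
        U = X / h
        V = self.data / h
        sq = (
            np.sum(U * U, axis=1)[:, None]
            + np.sum(V * V, axis=1)[None, :]
            - 2.0 * (U @ V.T)
        )
        np.maximum(sq, 0.0, out=sq)
        logk = -0.5 * sq - np.sum(np.log(h * np.sqrt(2 * np.pi)))
        return logsumexp(logk, axis=1) - np.log(self.data.shape[0])

    def pdf(self, X: np.ndarray) -> np.ndarray:
        return np.exp(self.logpdf(X))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        idx = rng.integers(0, self.data.shape[0], size=n)
        return self.data[idx] + self.bandwidth * rng.standard_normal(
            (n, self.dim)
        )


def kde(data: np.ndarray, bandwidth_rule="silverman") -> ProductKDE:
    return ProductKDE(data, bandwidth_rule)


class GMMDensity:
    """Thin evaluable wrapper around a fitted scikit-learn Gaussian mixture."""

    def __init__(self, gm: GaussianMixture):
        self._gm = gm
        self.means_ = gm.means_
        self.covariances_ = gm.covariances_
        self.weights_ = gm.weights_

    @property
    def dim(self) -> int:
        return self.means_.shape[1]

    def logpdf(self, X: np.ndarray) -> np.ndarray:
        return self._gm.score_samples(np.atleast_2d(np.asarray(X, dtype=float)))

    def pdf(self, X: np.ndarray) -> np.ndarray:
        return np.exp(self.logpdf(X))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        # delegate component choice + draws to a reseeded sklearn sampler
        self._gm.random_state = int(rng.integers(0, 2**31 - 1))
        X, _ = self._gm.sample(n)
        return X


def gmm_em(
    data: np.ndarray,
    K: int,
    restarts: int = 3,
    tol: float = 1e-6,
    seed: int = 0,
    covariance_type: str = "full",
) -> GMMDensity:
    """Best-of-restarts EM fit of a K-component Gaussian mixture."""
    X = np.atleast_2d(np.asarray(data, dtype=float))
    if K < 1:
        raise ValueError("K must be >= 1")
    if X.shape[0] <= K:
        raise ValueError("need more points than components")
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    gm = GaussianMixture(
        n_components=K,
        covariance_type=covariance_type,
        tol=tol,
        reg_covar=1e-6,
        n_init=restarts,
        max_iter=300,
        random_state=seed,
    )
    with warnings.catch_warnings():
        # best-of-restarts at a tight tol on small class subsets routinely
        # trips the iteration cap without affecting the returned fit
        warnings.simplefilter("ignore", ConvergenceWarning)
        gm.fit(X)
    return GMMDensity(gm)
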