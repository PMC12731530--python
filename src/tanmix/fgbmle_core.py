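"""Fast generative bootstrap maximum-likelihood estimation of a mixing density.

The estimator replaces the classical "refit the NPMLE under every bootstrap
weight draw" loop with a single trained generator plus a mixture-weight
refinement:

* **Stage I** trains a fully connected generator ``G(w, z)`` that maps a
  weighted-likelihood-bootstrap weight vector ``w ~ n x Dirichlet(1_n)`` and
  uniform noise ``z`` to a candidate parameter matrix ``Theta in R^{d x l}``,
  each column a candidate mixture-component parameter.  The training signal is
  the bootstrap-weighted mixture log-likelihood of the data under the l
  candidates with the uniform prior ``tau0 = (1/l, ..., 1/l)``.
* **Stage II** freezes a Monte-Carlo ensemble of M generator draws and runs an
  exact EM (an MCEM whose expectation is fixed once) for the mixture weights
  ``tau`` over the candidates, so the fitted density is

      p_hat(y) = sum_j tau_j * (1/M) sum_m f(y | Theta^(m)[:, j]),

  a finite mixture of l * M observation-model components.

Everything is plain numpy: the generator is a small MLP with hand-written
backprop and an Adam update, Xavier-uniform initialisation and ReLU
activations.  Gaussian families are fitted on internally standardised data
(the transform is recorded and inverted on every output), which keeps the
network's initial output range aligned with the data; gamma-rate parameters go
through a softplus head to enforce positivity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logsumexp, softmax

from .observation_models import (
    GAUSSIAN_FAMILIES,
    ObservationModel,
    grad_log_density_theta,
    log_density_matrix,
)

__all__ = [
    "GeneratorConfig",
    "FGBMLEModel",
    "sample_bootstrap_weights",
    "stage1_loss",
    "train_stage1",
    "stage2_mcem",
    "fit_fgbmle",
]

_SOFTPLUS_FLOOR = 1e-4


def sample_bootstrap_weights(n: int, rng: np.random.Generator) -> np.ndarray:
    """Weighted-likelihood-bootstrap weights: n x Dirichlet(1, ..., 1).

    Entries are strictly positive and sum to n (a scaled flat Dirichlet), so a
    unit-weight vector is the no-perturbation special case.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    g = rng.gamma(shape=1.0, scale=1.0, size=n)
    g = np.maximum(g, 1e-300)
    return n * g / g.sum()


@dataclass(frozen=True)
class GeneratorConfig:
    """Hyperparameters of the Stage-I generator and its training loop.

    Defaults follow the reference simulation protocol: two hidden layers of
    600 ReLU units, l = 50 candidates, Adam at 1e-3 with Xavier-uniform
    initialisation, early stopping when the smoothed held-out NLL improves by
    less than ``early_stop_delta`` for ``early_stop_patience`` consecutive
    epochs.  ``noise_dim`` entries are Unif(0, 1).
    """

    hidden_layers: tuple[int, ...] = (600, 600)
    noise_dim: int = 1
    n_candidates: int = 50
    epochs: int = 500
    learning_rate: float = 1e-3
    batch_size: int = 128
    early_stop_delta: float = 1e-4
    early_stop_patience: int = 10
    ensemble_size: int = 100
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_candidates < 1:
            raise ValueError("n_candidates must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.ensemble_size < 1:
            raise ValueError("ensemble_size must be >= 1")


class _MLP:
    """Tiny fully connected network with ReLU hidden layers.

    Operates on single input vectors (the generator consumes one (w, z) pair
    per step).  Xavier-uniform init; backprop and Adam are written out by hand
    so the package has no deep-learning dependency.
    """

    def __init__(self, sizes: list[int], rng: np.random.Generator):
        self.sizes = list(sizes)
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            self.W.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))
        self._adam_m = [np.zeros_like(p) for p in self.W + self.b]
        self._adam_v = [np.zeros_like(p) for p in self.W + self.b]
        self._adam_t = 0

    def forward(self, x: np.ndarray, keep: bool = False):
        acts = [x]
        h = x
        last = len(self.W) - 1
        for k, (W, b) in enumerate(zip(self.W, self.b)):
            h = h @ W + b
            if k < last:
                h = np.maximum(h, 0.0)
            acts.append(h)
        if keep:
            self._acts = acts
        return h

    def backward(self, grad_out: np.ndarray) -> list[np.ndarray]:
        """Gradients for all parameters given dL/d(output); uses cached acts."""
        acts = self._acts
        gW = [np.empty(0)] * len(self.W)
        gb = [np.empty(0)] * len(self.b)
        g = grad_out
        for k in range(len(self.W) - 1, -1, -1):
            gW[k] = np.outer(acts[k], g)
            gb[k] = g.copy()
            if k > 0:
                g = (g @ self.W[k].T) * (acts[k] > 0)
        return gW + gb

    def adam_step(self, grads: list[np.ndarray], lr: float,
                  beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self._adam_t += 1
        t = self._adam_t
        params = self.W + self.b
        for p, g, m, v in zip(params, grads, self._adam_m, self._adam_v):
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g * g
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)

    def state(self) -> dict:
        return {"sizes": self.sizes,
                "W": [w.copy() for w in self.W],
                "b": [b.copy() for b in self.b]}


@dataclass
class FGBMLEModel:
    """Trained generator + frozen Monte-Carlo ensemble + mixture weights.

    ``ensemble`` holds M candidate matrices (M, d, l) in the *original*
    parameter space.  ``tau`` lives on the l-simplex.  After ``stage2_mcem``
    the model is an evaluable density over the observation space and an
    evaluable discrete mixing measure over the parameter space.
    """

    observation_model: ObservationModel
    config: GeneratorConfig
    n_train: int
    mlp: _MLP | None = None
    standardize_mean: np.ndarray | None = None
    standardize_scale: np.ndarray | None = None
    ensemble: np.ndarray | None = None  # (M, d, l)
    tau: np.ndarray | None = None
    fit_log: dict = field(default_factory=dict)
    _logL: np.ndarray | None = field(default=None, repr=False)

    # -- construction helpers ---------------------------------------------

    @classmethod
    def from_candidates(
        cls,
        obs: ObservationModel,
        candidates: np.ndarray,
        tau: np.ndarray | None = None,
    ) -> "FGBMLEModel":
        """Build a generator-free model from explicit candidate matrices.

        ``candidates`` is (d, l) for a single-member ensemble or (M, d, l).
        Useful for closed-form checks and as a lightweight mixture container.
        """
        candidates = np.asarray(candidates, dtype=float)
        if candidates.ndim == 2:
            candidates = candidates[None, :, :]
        M, d, l = candidates.shape
        if d != obs.dim:
            raise ValueError(f"candidate rows {d} != model dim {obs.dim}")
        cfg = GeneratorConfig(n_candidates=l, ensemble_size=M)
        tau = np.full(l, 1.0 / l) if tau is None else np.asarray(tau, dtype=float)
        return cls(observation_model=obs, config=cfg, n_train=0,
                   ensemble=candidates, tau=tau)

    # -- generator ---------------------------------------------------------

    def _head(self, raw: np.ndarray) -> np.ndarray:
        """Map raw network output (d, l) to valid parameters in original space."""
        if self.observation_model.family in GAUSSIAN_FAMILIES:
            theta = raw
            if self.standardize_mean is not None:
                theta = theta * self.standardize_scale[:, None] + self.standardize_mean[:, None]
            return theta
        # softplus keeps gamma rates strictly positive
        return np.logaddexp(0.0, raw) + _SOFTPLUS_FLOOR

    def generator_forward(self, w: np.ndarray, z: np.ndarray) -> np.ndarray:
        """Candidate matrix Theta = G(w, z), shape (d, l), original space."""
        if self.mlp is None:
            raise RuntimeError("model has no trained generator")
        w = np.asarray(w, dtype=float)
        if w.shape != (self.n_train,):
            raise ValueError(
                f"weight vector has length {w.size}; generator expects n={self.n_train}"
            )
        z = np.atleast_1d(np.asarray(z, dtype=float))
        x = np.concatenate([w, z])
        raw = self.mlp.forward(x).reshape(self.observation_model.dim,
                                          self.config.n_candidates)
        return self._head(raw)

    # -- ensemble / density -------------------------------------------------

    def _require_ensemble(self) -> np.ndarray:
        if self.ensemble is None:
            raise RuntimeError("no cached ensemble; run train_stage1 first")
        return self.ensemble

    def log_component_matrix(self, Y: np.ndarray) -> np.ndarray:
        """log of the Monte-Carlo component likelihoods, shape (n, l).

        Entry (i, j) is log (1/M) sum_m f(y_i | Theta^(m)[:, j]), the frozen
        Stage-II quantity L_ij, combined with log-sum-exp over the M members.
        """
        ens = self._require_ensemble()
        obs = self.observation_model
        Y = obs.check_support(Y)
        M = ens.shape[0]
        logs = np.stack(
            [log_density_matrix(obs, Y, ens[m]) for m in range(M)], axis=0
        )  # (M, n, l)
        return logsumexp(logs, axis=0) - np.log(M)

    def mc_component_likelihood(self, y: np.ndarray, j: int) -> float:
        """(1/M) sum_m f(y | Theta^(m)[:, j]); strictly positive."""
        l = self._require_ensemble().shape[2]
        if not 0 <= j < l:
            raise IndexError(f"candidate index {j} outside 0..{l - 1}")
        row = self.log_component_matrix(
            np.asarray(y, dtype=float).reshape(1, self.observation_model.dim)
        )
        return float(np.exp(row[0, j]))

    def log_density(self, Y: np.ndarray) -> np.ndarray:
        """log p_hat(y_i) for rows of Y under the fitted mixture."""
        if self.tau is None:
            raise RuntimeError("mixture weights not set; run stage2_mcem")
        logL = self.log_component_matrix(Y)
        with np.errstate(divide="ignore"):
            logtau = np.log(self.tau)
        return logsumexp(logL + logtau[None, :], axis=1)

    def density(self, Y: np.ndarray) -> np.ndarray:
        return np.exp(self.log_density(Y))

    def mixing_atoms(self) -> tuple[np.ndarray, np.ndarray]:
        """The fitted discrete mixing measure: (l*M, d) atoms, (l*M,) weights.

        Member m's column j carries weight tau_j / M; this is the estimate of
        the latent mixing density pi, used for the W1 comparisons.
        """
        ens = self._require_ensemble()
        M, d, l = ens.shape
        locs = np.swapaxes(ens, 1, 2).reshape(M * l, d)
        weights = np.tile(self.tau, M) / M
        return locs, weights

    def sample_mixing(self, n: int, rng: np.random.Generator) -> np.ndarray:
        locs, wts = self.mixing_atoms()
        idx = rng.choice(locs.shape[0], size=n, p=wts / wts.sum())
        return locs[idx]

    def sample_observed(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw from the fitted observation-space density p_hat."""
        from .observation_models import sample as obs_sample

        atoms = self.sample_mixing(n, rng)
        obs = self.observation_model
        if obs.family in GAUSSIAN_FAMILIES:
            return atoms + obs._scale_vec * rng.standard_normal(atoms.shape)
        out = np.empty_like(atoms)
        for i in range(n):  # gamma rates vary per atom
            out[i] = obs_sample(obs, atoms[i], 1, rng)[0]
        return out

    # -- serialization -------------------------------------------------------

    def save(self, manifest_path: str, tensor_path: str) -> None:
        """JSON manifest (config, tau, traces) + npz tensor file (weights)."""
        manifest = {
            "family": self.observation_model.family,
            "dim": self.observation_model.dim,
            "scale": None
            if self.observation_model.family == "gamma_rate"
            else self.observation_model._scale_vec.tolist(),
            "n_train": self.n_train,
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in vars(self.config).items()},
            "tau": None if self.tau is None else self.tau.tolist(),
            "fit_log": {k: (np.asarray(v).tolist() if not isinstance(v, dict) else v)
                        for k, v in self.fit_log.items()},
        }
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=1)
        arrays = {}
        if self.ensemble is not None:
            arrays["ensemble"] = self.ensemble
        if self.mlp is not None:
            st = self.mlp.state()
            arrays["sizes"] = np.asarray(st["sizes"])
            for k, w in enumerate(st["W"]):
                arrays[f"W{k}"] = w
            for k, b in enumerate(st["b"]):
                arrays[f"b{k}"] = b
        if self.standardize_mean is not None:
            arrays["standardize_mean"] = self.standardize_mean
            arrays["standardize_scale"] = self.standardize_scale
        np.savez(tensor_path, **arrays)


# ---------------------------------------------------------------------------
# Stage I


def stage1_loss(
    model: FGBMLEModel,
    data: np.ndarray,
    w: np.ndarray,
    z: np.ndarray,
    r: int,
) -> float:
    """Single-candidate bootstrap-weighted negative log-likelihood.

    The Stage-I integrand: - sum_i w_i log f(y_i | theta^(r)) with theta^(r)
    the r-th column of G(w, z) (1-based r).  For generator-free models built
    via :meth:`FGBMLEModel.from_candidates` the first ensemble member stands
    in for G(w, z).
    """
    obs = model.observation_model
    Y = obs.check_support(data)
    if model.mlp is not None:
        Theta = model.generator_forward(w, z)
    else:
        Theta = model._require_ensemble()[0]
    l = Theta.shape[1]
    if not 1 <= r <= l:
        raise IndexError(f"candidate index r={r} outside 1..{l}")
    col = Theta[:, r - 1][:, None]
    ll = log_density_matrix(obs, Y, col)[:, 0]
    return float(-np.sum(np.asarray(w, dtype=float) * ll))


def _mixture_nll(obs, Y, Theta, weights) -> float:
    """Bootstrap-weighted NLL of the uniform candidate mixture."""
    ll = log_density_matrix(obs, Y, Theta)  # (n, l)
    mix = logsumexp(ll, axis=1) - np.log(Theta.shape[1])
    return float(-np.sum(weights * mix))


def train_stage1(
    data: np.ndarray,
    obs: ObservationModel,
    config: GeneratorConfig,
) -> FGBMLEModel:
    """Stage-I generator training.

    Each epoch draws fresh bootstrap weights w and noise z, pushes (w, z)
    through the network to get the candidate matrix, and takes one Adam step
    on the bootstrap-weighted negative log-likelihood of the data under the
    uniform-weight candidate mixture (the candidate set realises the inner
    expectation of the generator objective; averaging the component
    likelihoods before the log is what makes distinct candidates settle on
    distinct parts of the latent distribution instead of collapsing onto the
    weighted MLE point).  A held-out split drives early stopping on the
    exponentially smoothed validation NLL.  After training an ensemble of M
    frozen (w, z) draws is evaluated and cached, and tau is initialised
    uniform.
    """
    Y = obs.check_support(np.atleast_2d(np.asarray(data, dtype=float)))
    if Y.shape[0] < 2:
        raise ValueError("need at least 2 data points")
    if Y.shape[1] != obs.dim:
        raise ValueError(f"data has {Y.shape[1]} columns, model dim is {obs.dim}")
    d, l = obs.dim, config.n_candidates

    root = np.random.SeedSequence(config.seed)
    s_split, s_init, s_w, s_z, s_ens = [np.random.default_rng(s)
                                        for s in root.spawn(5)]

    # held-out split for early stopping
    n_all = Y.shape[0]
    n_val = int(round(config.validation_fraction * n_all))
    n_val = min(max(n_val, 0), n_all - 2)
    perm = s_split.permutation(n_all)
    Y_val, Y_tr = Y[perm[:n_val]], Y[perm[n_val:]]
    n = Y_tr.shape[0]

    # internal standardisation for gaussian families
    if obs.family in GAUSSIAN_FAMILIES:
        mu = Y_tr.mean(axis=0)
        sd = Y_tr.std(axis=0)
        if np.any(sd <= 0):
            raise ValueError("degenerate data: zero variance in a dimension")
        Y_tr_i = (Y_tr - mu) / sd
        Y_val_i = (Y_val - mu) / sd if n_val else Y_val
        obs_i = ObservationModel(obs.family if obs.family != "gaussian_location"
                                 else "gaussian_location_diagonal",
                                 dim=d, scale=obs._scale_vec / sd)
    else:
        mu = sd = None
        Y_tr_i, Y_val_i, obs_i = Y_tr, Y_val, obs

    sizes = [n + config.noise_dim, *config.hidden_layers, d * l]
    mlp = _MLP(sizes, s_init)

    def head_internal(raw):
        # parameters in the *internal* (standardised) space
        if obs.family in GAUSSIAN_FAMILIES:
            return raw, None
        theta = np.logaddexp(0.0, raw) + _SOFTPLUS_FLOOR
        return theta, expit(raw)  # d theta / d raw

    loss_trace: list[float] = []
    val_trace: list[float] = []
    ema = None
    best_ema = np.inf
    stall = 0
    # patience starts counting only after a warmup; per-epoch improvements are
    # smaller than early_stop_delta long before the fit has converged
    warmup = max(50, config.epochs // 5)
    # an epoch is one nominal pass over the data: ceil(n / batch_size) steps,
    # each with fresh (w, z) draws and (for n <= 2000) the full-batch weighted
    # loss, which preserves the objective's expectation
    steps_per_epoch = max(1, int(np.ceil(n / config.batch_size)))
    full_batch = n <= 2000
    for epoch in range(config.epochs):
        epoch_loss = 0.0
        for _ in range(steps_per_epoch):
            w = sample_bootstrap_weights(n, s_w)
            z = s_z.uniform(size=config.noise_dim)
            x = np.concatenate([w, z])
            raw = mlp.forward(x, keep=True).reshape(d, l)
            theta, dtheta = head_internal(raw)

            if full_batch:
                Yb, wb = Y_tr_i, w
            else:
                idx = s_w.integers(0, n, size=config.batch_size)
                Yb = Y_tr_i[idx]
                wb = w[idx] * (config.batch_size / w[idx].sum())
            ll = log_density_matrix(obs_i, Yb, theta)  # (nb, l)
            mix = logsumexp(ll, axis=1) - np.log(l)
            loss = float(-np.sum(wb * mix))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite Stage-I loss at epoch {epoch} (loss={loss})"
                )
            epoch_loss += loss * (n / Yb.shape[0])

            # gradient wrt candidate columns: responsibility-weighted score
            gamma = softmax(ll, axis=1)  # (nb, l); tau0 uniform cancels
            A = wb[:, None] * gamma  # (nb, l)
            score = grad_log_density_theta(obs_i, Yb, theta)  # (nb, d, l)
            g_theta = -np.einsum("il,idl->dl", A, score)
            if dtheta is not None:
                g_theta = g_theta * dtheta
            grads = mlp.backward(g_theta.reshape(-1))
            mlp.adam_step(grads, config.learning_rate)
        loss_trace.append(epoch_loss / steps_per_epoch)

        # validation NLL (per point), EMA-smoothed for early stopping
        if n_val:
            vll = log_density_matrix(obs_i, Y_val_i, theta)
            vmix = logsumexp(vll, axis=1) - np.log(l)
            vnll = float(-np.mean(vmix))
        else:
            vnll = loss / n
        val_trace.append(vnll)
        ema = vnll if ema is None else 0.9 * ema + 0.1 * vnll
        if ema < best_ema - config.early_stop_delta:
            best_ema = ema
            stall = 0
        else:
            stall += 1
            if epoch >= warmup and stall >= config.early_stop_patience:
                break

    model = FGBMLEModel(
        observation_model=obs,
        config=config,
        n_train=n,
        mlp=mlp,
        standardize_mean=mu,
        standardize_scale=sd,
        tau=np.full(l, 1.0 / l),
        fit_log={"stage1_loss": loss_trace, "stage1_val_nll": val_trace,
                 "stopped_epoch": len(loss_trace)},
    )

    # frozen Monte-Carlo ensemble (original parameter space)
    M = config.ensemble_size
    ens = np.empty((M, d, l))
    for m in range(M):
        wm = sample_bootstrap_weights(n, s_ens)
        zm = s_ens.uniform(size=config.noise_dim)
        ens[m] = model.generator_forward(wm, zm)
    model.ensemble = ens
    return model


# ---------------------------------------------------------------------------
# Stage II


def stage2_mcem(
    model: FGBMLEModel,
    data: np.ndarray,
    tol: float = 1e-5,
    max_iter: int = 500,
) -> np.ndarray:
    """EM refinement of the mixture weights over the frozen ensemble.

    With L_ij = (1/M) sum_m f(y_i | Theta^(m)[:, j]) held fixed, the update

        tau_j <- (1/n) sum_i tau_j L_ij / sum_j' tau_j' L_ij'

    is an exact EM step for the finite mixture, so the negative log-likelihood
    is non-increasing at every iteration.  Stops when max_j |delta tau_j| <
    tol or at ``max_iter``.  Returns tau and stores the objective trace in
    ``model.fit_log``.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    logL = model.log_component_matrix(data)  # (n, l) frozen
    n, l = logL.shape
    finite_rows = np.isfinite(logsumexp(logL, axis=1))
    if not np.all(finite_rows):
        row = int(np.flatnonzero(~finite_rows)[0])
        raise FloatingPointError(
            f"all component likelihoods underflow to zero for data row {row}"
        )
    tau = np.full(l, 1.0 / l) if model.tau is None else model.tau.copy()
    obj_trace = []
    for _ in range(max_iter):
        with np.errstate(divide="ignore"):
            logtau = np.log(tau)
        lognum = logL + logtau[None, :]
        lognorm = logsumexp(lognum, axis=1)  # (n,)
        obj_trace.append(float(-np.sum(lognorm)))
        resp = np.exp(lognum - lognorm[:, None])  # (n, l)
        tau_new = resp.mean(axis=0)
        tau_new = np.maximum(tau_new, 0.0)
        tau_new /= tau_new.sum()
        delta = float(np.max(np.abs(tau_new - tau)))
        tau = tau_new
        if delta < tol:
            break
    with np.errstate(divide="ignore"):
        obj_trace.append(float(-np.sum(logsumexp(logL + np.log(tau)[None, :], axis=1))))
    model.tau = tau
    model.fit_log["stage2_objective"] = obj_trace
    model._logL = logL
    return tau


def fit_fgbmle(
    data: np.ndarray,
    obs: ObservationModel,
    config: GeneratorConfig | None = None,
    tol: float = 1e-5,
    max_iter: int = 500,
) -> FGBMLEModel:
    """Convenience composition: Stage-I training then Stage-II MCEM."""
    config = config or GeneratorConfig()
    model = train_stage1(data, obs, config)
    stage2_mcem(model, data, tol=tol, max_iter=max_iter)
    return model


def fit_fgbmle_density(
    data: np.ndarray,
    config: GeneratorConfig | None = None,
    component_scale: np.ndarray | None = None,
    tol: float = 1e-5,
) -> FGBMLEModel:
    """Fit the estimator as a plain density estimator of the observed data.

    Uses a Gaussian-location family whose per-axis component scale defaults to
    the normal-reference bandwidth 1.06 * sd * n^(-1/5): a learned-location
    Gaussian mixture, the configuration the TAN back-end uses when no
    observation model is given by the problem.
    """
    Y = np.atleast_2d(np.asarray(data, dtype=float))
    if component_scale is None:
        n = Y.shape[0]
        component_scale = np.maximum(
            1.06 * Y.std(axis=0, ddof=1) * n ** (-1.0 / 5.0), 1e-3
        )
    obs = ObservationModel(
        "gaussian_location_diagonal", dim=Y.shape[1], scale=component_scale
    )
    return fit_fgbmle(Y, obs, config, tol=tol)
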