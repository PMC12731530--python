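"""Tree-augmented naive Bayes for continuous attributes.

Structure learning follows the Chow–Liu recipe with class-conditional
densities supplied by a pluggable back-end (``fgbmle``, ``kde`` or ``gmm``):

1. fit class-conditional univariate densities p(y_i | c) and, per candidate
   edge, bivariate densities p(y_i, y_j | c);
2. estimate the conditional mutual information I(X_i; X_j | C) by Monte
   Carlo — sample from the fitted joint and average the log density ratio;
3. run Prim's algorithm for the maximum spanning tree on the CMI weights;
4. orient edges away from a root and classify by
   c_hat(y) = argmax_c p(c) prod_i p(y_i | y_pa(i), c).

All densities are fitted on globally standardised coordinates; the recorded
transform is inverted on evaluation, so log-densities are reported in the
original units.  The orientation root is irrelevant to the classifier: the
pairwise factorisation telescopes to a root-free form.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import classical_estimators as ce
from .fgbmle_core import FGBMLEModel, GeneratorConfig, fit_fgbmle
from .observation_models import ObservationModel

__all__ = [
    "LabeledDataset",
    "TANConfig",
    "CMIMatrix",
    "TANStructure",
    "TANClassifier",
    "load_csv",
    "fit_class_conditional",
    "estimate_cmi",
    "prim_max_spanning_tree",
    "build_tan",
    "build_nb",
    "cross_validate",
]

BACKENDS = ("fgbmle", "kde", "gmm")


@dataclass
class LabeledDataset:
    """Continuous attribute matrix plus a categorical class column."""

    x: np.ndarray  # (n, d)
    labels: np.ndarray  # (n,)
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.x = np.atleast_2d(np.asarray(self.x, dtype=float))
        self.labels = np.asarray(self.labels)
        if self.x.shape[0] != self.labels.shape[0]:
            raise ValueError("x and labels have different lengths")
        if not np.all(np.isfinite(self.x)):
            raise ValueError("x contains missing/non-finite values after loading")
        if len(self.feature_names) != self.x.shape[1]:
            raise ValueError("feature_names length mismatch")
        classes, counts = np.unique(self.labels, return_counts=True)
        if np.any(counts < 2):
            small = classes[counts < 2]
            raise ValueError(f"every class needs >= 2 rows; {small} violate this")
        self.classes_ = classes

    @property
    def n(self) -> int:
        return self.x.shape[0]

    @property
    def dim(self) -> int:
        return self.x.shape[1]


def load_csv(path, class_col: str) -> LabeledDataset:
    """Read a delimited table; impute missing feature values by column means."""
    df = pd.read_csv(path)
    if class_col not in df.columns:
        raise ValueError(f"class column {class_col!r} not found in {list(df.columns)}")
    labels = df[class_col].to_numpy()
    feats = df.drop(columns=[class_col])
    feats = feats.apply(pd.to_numeric, errors="coerce")
    feats = feats.fillna(feats.mean())
    return LabeledDataset(
        x=feats.to_numpy(dtype=float),
        labels=labels,
        feature_names=list(feats.columns),
    )


@dataclass(frozen=True)
class TANConfig:
    """Back-end hyperparameters for density fitting and CMI estimation.

    ``cmi_samples`` is the Monte-Carlo budget S per class and pair.  The
    generator settings used for the fgbmle back-end are smaller than the
    density-benchmark defaults because a TAN fit trains K*(2d - 1) separate
    one- and two-dimensional models.
    """

    gmm_components: int = 3
    gmm_restarts: int = 2
    bandwidth_rule: object = "silverman"
    cmi_samples: int = 5000
    fgbmle: GeneratorConfig = GeneratorConfig(
        hidden_layers=(128, 64),
        n_candidates=20,
        epochs=150,
        ensemble_size=30,
    )
    seed: int = 0


@dataclass
class CMIMatrix:
    """Clamped and raw Monte-Carlo CMI estimates for all attribute pairs."""

    values: np.ndarray  # max(raw, 0), symmetric, zero diagonal
    raw_values: np.ndarray
    mc_samples: int


@dataclass
class TANStructure:
    """An undirected attribute tree plus an orientation away from a root."""

    edges: list[tuple[int, int]]
    n_nodes: int
    root: int = 0
    parent: dict[int, int | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.edges = [tuple(sorted(e)) for e in self.edges]
        if len(self.edges) != self.n_nodes - 1:
            raise ValueError("a spanning tree on d nodes has d - 1 edges")
        if not self.parent:
            self.orient(self.root)

    def orient(self, root: int) -> None:
        """Set the parent map by BFS from ``root`` over the tree edges."""
        adj: dict[int, list[int]] = {v: [] for v in range(self.n_nodes)}
        for i, j in self.edges:
            adj[i].append(j)
            adj[j].append(i)
        parent: dict[int, int | None] = {root: None}
        frontier = [root]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in parent:
                        parent[v] = u
                        nxt.append(v)
            frontier = nxt
        if len(parent) != self.n_nodes:
            raise ValueError("edges do not form a connected tree")
        self.root = root
        self.parent = parent

    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.n_nodes, self.n_nodes), dtype=int)
        for i, j in self.edges:
            a[i, j] = a[j, i] = 1
        return a


# ---------------------------------------------------------------------------
# density back-ends


class StandardizedDensity:
    """Wrap a density fitted on z-scored coordinates; evaluate in originals."""

    def __init__(self, inner, mean: np.ndarray, scale: np.ndarray):
        self.inner = inner
        self.mean = np.asarray(mean, dtype=float)
        self.scale = np.asarray(scale, dtype=float)
        self._log_jac = float(np.sum(np.log(self.scale)))

    def logpdf(self, Y: np.ndarray) -> np.ndarray:
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        Z = (Y - self.mean) / self.scale
        return np.asarray(self.inner.logpdf(Z)) - self._log_jac

    def pdf(self, Y: np.ndarray) -> np.ndarray:
        return np.exp(self.logpdf(Y))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self.inner.sample(n, rng) * self.scale + self.mean


class FGBMLEDensity:
    """Evaluable/sampleable wrapper around a fitted generative-bootstrap model.

    The observation family is Gaussian-location with per-axis component scale
    set by the normal-reference bandwidth rule on the (standardised) class
    data, so the fitted object is a learned-location Gaussian mixture —
    directly comparable to a KDE whose kernel centres were estimated rather
    than pinned at the data.
    """

    def __init__(self, model: FGBMLEModel):
        self.model = model
        self._scale = model.observation_model._scale_vec

    def logpdf(self, Y: np.ndarray) -> np.ndarray:
        return self.model.log_density(Y)

    def pdf(self, Y: np.ndarray) -> np.ndarray:
        return np.exp(self.logpdf(Y))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        atoms = self.model.sample_mixing(n, rng)
        return atoms + self._scale * rng.standard_normal(atoms.shape)


def _silverman_scales(Z: np.ndarray) -> np.ndarray:
    n = Z.shape[0]
    sd = Z.std(axis=0, ddof=1)
    return np.maximum(1.06 * sd * n ** (-1.0 / 5.0), 1e-3)


def fit_class_conditional(
    data: LabeledDataset,
    feature_subset,
    c,
    backend: str = "gmm",
    config: TANConfig | None = None,
    seed: int | None = None,
):
    """Fit a 1- or 2-D class-conditional density on standardised coordinates.

    The global per-feature z-scoring transform is recorded and inverted on
    evaluation, so the returned object's ``logpdf``/``sample`` operate in the
    original units.
    """
    config = config or TANConfig()
    if backend not in BACKENDS:
        raise ValueError(f"backend must be one of {BACKENDS}")
    subset = [int(f) for f in np.atleast_1d(feature_subset)]
    if len(subset) not in (1, 2):
        raise ValueError("feature_subset must have 1 or 2 indices")
    mask = data.labels == c
    if mask.sum() < 5:
        raise ValueError(f"class {c!r} has {int(mask.sum())} rows; need >= 5")
    mean = data.x.mean(axis=0)[subset]
    scale = data.x.std(axis=0)[subset]
    if np.any(scale <= 0):
        raise ValueError("zero-variance feature in subset")
    Z = (data.x[np.ix_(mask, subset)] - mean) / scale
    seed = config.seed if seed is None else seed

    if backend == "kde":
        inner = ce.ProductKDE(Z, bandwidth_rule=config.bandwidth_rule)
    elif backend == "gmm":
        K = min(config.gmm_components, Z.shape[0] - 1)
        inner = ce.gmm_em(Z, K=K, restarts=config.gmm_restarts, seed=seed)
    else:  # fgbmle: learned-location Gaussian mixture
        obs = ObservationModel(
            "gaussian_location_diagonal",
            dim=Z.shape[1],
            scale=_silverman_scales(Z),
        )
        gcfg = replace(config.fgbmle, seed=seed)
        inner = FGBMLEDensity(fit_fgbmle(Z, obs, gcfg))
    return StandardizedDensity(inner, mean, scale)


# ---------------------------------------------------------------------------
# conditional mutual information


def estimate_cmi(
    marg_i: dict,
    marg_j: dict,
    joint_ij: dict,
    priors: dict,
    S: int = 5000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Monte-Carlo CMI: sum_c p(c) E_{joint} [log joint - log marg_i - log marg_j].

    ``marg_i``, ``marg_j``, ``joint_ij`` map class -> fitted density (the
    joint over the ordered pair (i, j)).  Non-finite log-ratios are dropped
    and counted; more than 1% drops triggers a warning.  Returns the raw
    estimate and its clamp at zero (the structure-learning edge weight).
    """
    if S < 100:
        raise ValueError("S must be >= 100")
    rng = rng or np.random.default_rng(0)
    raw = 0.0
    dropped = total = 0
    for c, p_c in priors.items():
        pts = np.atleast_2d(joint_ij[c].sample(S, rng))
        lr = (
            joint_ij[c].logpdf(pts)
            - marg_i[c].logpdf(pts[:, :1])
            - marg_j[c].logpdf(pts[:, 1:])
        )
        ok = np.isfinite(lr)
        dropped += int(S - ok.sum())
        total += S
        if not np.any(ok):
            raise FloatingPointError(f"all CMI samples non-finite for class {c!r}")
        raw += p_c * float(np.mean(lr[ok]))
    if dropped > 0.01 * total:
        import warnings

        warnings.warn(f"CMI Monte Carlo dropped {dropped}/{total} samples")
    return raw, max(raw, 0.0)


def prim_max_spanning_tree(weights: np.ndarray) -> list[tuple[int, int]]:
    """Maximum spanning tree by Prim's algorithm, started at vertex 0.

    Among equal-weight candidate edges the lexicographically smallest
    (min(i, j), max(i, j)) pair wins, which makes the output deterministic
    (all-equal weights yield the star centred at vertex 0).
    """
    W = np.asarray(weights, dtype=float)
    d = W.shape[0]
    if W.ndim != 2 or W.shape[1] != d or d < 2:
        raise ValueError("weights must be a square matrix with d >= 2")
    if not np.allclose(W, W.T):
        raise ValueError("weights must be symmetric")
    if not np.all(np.isfinite(W)):
        raise ValueError("weights must be finite")
    in_tree = {0}
    edges: list[tuple[int, int]] = []
    while len(in_tree) < d:
        best = None
        for u in sorted(in_tree):
            for v in range(d):
                if v in in_tree:
                    continue
                key = (W[u, v], -min(u, v), -max(u, v))
                if best is None or key > best[0]:
                    best = (key, (min(u, v), max(u, v)), v)
        edges.append(best[1])
        in_tree.add(best[2])
    return edges


# ---------------------------------------------------------------------------
# classifier


@dataclass
class TANClassifier:
    """Fitted tree-augmented (or naive, if structure is None) Bayes model."""

    structure: TANStructure | None
    classes: np.ndarray
    class_priors: np.ndarray
    marginal_models: dict  # (feature, class) -> density
    pair_models: dict  # (child, parent, class) -> density over (child, parent)
    backend: str
    cmi: CMIMatrix | None = None
    feature_names: list[str] | None = None

    @property
    def dim(self) -> int:
        return max(f for f, _ in self.marginal_models) + 1

    def log_joint(self, y: np.ndarray, c) -> float:
        """log p(c) + log p(y | c) under the tree factorisation."""
        return float(self.class_log_scores(np.atleast_2d(y))[0, self._cidx(c)])

    def _cidx(self, c) -> int:
        idx = np.flatnonzero(self.classes == c)
        if idx.size == 0:
            raise ValueError(f"unknown class {c!r}")
        return int(idx[0])

    def class_log_scores(self, X: np.ndarray) -> np.ndarray:
        """(n, K) matrix of log p(c) + log p(y | c)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n = X.shape[0]
        scores = np.empty((n, len(self.classes)))
        for k, c in enumerate(self.classes):
            total = np.full(n, np.log(self.class_priors[k]))
            if self.structure is None:
                for f in range(X.shape[1]):
                    total += self.marginal_models[(f, c)].logpdf(X[:, f : f + 1])
            else:
                root = self.structure.root
                total += self.marginal_models[(root, c)].logpdf(
                    X[:, root : root + 1]
                )
                for child, parent in self.structure.parent.items():
                    if parent is None:
                        continue
                    pair = self.pair_models[(child, parent, c)]
                    total += pair.logpdf(X[:, [child, parent]])
                    total -= self.marginal_models[(parent, c)].logpdf(
                        X[:, parent : parent + 1]
                    )
            scores[:, k] = total
        return scores

    def classify(self, y: np.ndarray):
        return self.predict_batch(np.atleast_2d(y))[0][0]

    def predict_batch(self, X: np.ndarray):
        """Labels and per-class log-scores; ties go to the lowest class index."""
        scores = self.class_log_scores(X)
        return self.classes[np.argmax(scores, axis=1)], scores

    def manifest(self) -> dict:
        """JSON-serialisable summary: structure, priors, backend, features."""
        return {
            "backend": self.backend,
            "classes": [str(c) for c in self.classes],
            "class_priors": [float(p) for p in self.class_priors],
            "feature_names": self.feature_names,
            "structure": None if self.structure is None else {
                "root": self.structure.root,
                "edges": [list(e) for e in self.structure.edges],
                "parent": {str(k): v for k, v in self.structure.parent.items()},
            },
        }

    def rerooted(self, root: int) -> "TANClassifier":
        """The same classifier with edges oriented away from another root.

        Reuses the fitted pairwise joints (swapping coordinates where the
        orientation flips); the factorisation telescopes, so decisions and
        log-joints are unchanged.
        """
        if self.structure is None:
            return self
        new_structure = TANStructure(
            edges=list(self.structure.edges),
            n_nodes=self.structure.n_nodes,
            root=root,
        )
        pair_models = {}
        for child, parent in new_structure.parent.items():
            if parent is None:
                continue
            for c in self.classes:
                if (child, parent, c) in self.pair_models:
                    pair_models[(child, parent, c)] = self.pair_models[(child, parent, c)]
                else:
                    pair_models[(child, parent, c)] = _SwappedDensity(
                        self.pair_models[(parent, child, c)]
                    )
        return TANClassifier(
            structure=new_structure,
            classes=self.classes,
            class_priors=self.class_priors,
            marginal_models=self.marginal_models,
            pair_models=pair_models,
            backend=self.backend,
            cmi=self.cmi,
            feature_names=self.feature_names,
        )


def _fit_all_densities(data, backend, config, seed_seq):
    classes = np.unique(data.labels)
    marg = {}
    for f in range(data.dim):
        for c in classes:
            s = int(seed_seq.spawn(1)[0].generate_state(1)[0] % (2**31))
            marg[(f, c)] = fit_class_conditional(data, [f], c, backend, config, seed=s)
    return classes, marg


def _pair_key_density(data, i, j, c, backend, config, seed):
    return fit_class_conditional(data, [i, j], c, backend, config, seed=seed)


def build_tan(
    data: LabeledDataset,
    backend: str = "gmm",
    config: TANConfig | None = None,
    seed: int | None = None,
) -> TANClassifier:
    """Learn a TAN classifier: densities -> CMI matrix -> Prim MST -> orient.

    The root for orientation is attribute 0 (provably irrelevant to the
    decisions).  Priors are empirical class frequencies.
    """
    config = config or TANConfig()
    if data.dim < 2:
        raise ValueError("TAN needs at least 2 attributes")
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    classes, marg = _fit_all_densities(data, backend, config, ss)
    priors = {
        c: float(np.mean(data.labels == c)) for c in classes
    }

    d = data.dim
    raw = np.zeros((d, d))
    joints_cache = {}
    cmi_rng = np.random.default_rng(ss.spawn(1)[0])
    for i in range(d):
        for j in range(i + 1, d):
            joint = {}
            for c in classes:
                s = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
                joint[c] = _pair_key_density(data, i, j, c, backend, config, s)
            joints_cache[(i, j)] = joint
            r, _ = estimate_cmi(
                {c: marg[(i, c)] for c in classes},
                {c: marg[(j, c)] for c in classes},
                joint,
                priors,
                S=config.cmi_samples,
                rng=cmi_rng,
            )
            raw[i, j] = raw[j, i] = r
    clamped = np.maximum(raw, 0.0)
    np.fill_diagonal(clamped, 0.0)
    cmi = CMIMatrix(values=clamped, raw_values=raw, mc_samples=config.cmi_samples)

    edges = prim_max_spanning_tree(clamped)
    structure = TANStructure(edges=edges, n_nodes=d, root=0)

    # pair models oriented as (child, parent); reuse the cached (i, j) joints
    pair_models = {}
    for child, parent in structure.parent.items():
        if parent is None:
            continue
        lo, hi = min(child, parent), max(child, parent)
        joint = joints_cache[(lo, hi)]
        for c in classes:
            if (lo, hi) == (child, parent):
                pair_models[(child, parent, c)] = joint[c]
            else:
                pair_models[(child, parent, c)] = _SwappedDensity(joint[c])

    return TANClassifier(
        structure=structure,
        classes=classes,
        class_priors=np.array([priors[c] for c in classes]),
        marginal_models=marg,
        pair_models=pair_models,
        backend=backend,
        cmi=cmi,
        feature_names=data.feature_names,
    )


class _SwappedDensity:
    """View of a bivariate density with its two coordinates exchanged."""

    def __init__(self, inner):
        self.inner = inner

    def logpdf(self, Y: np.ndarray) -> np.ndarray:
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        return self.inner.logpdf(Y[:, ::-1])

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self.inner.sample(n, rng)[:, ::-1]


def build_nb(
    data: LabeledDataset,
    backend: str = "gmm",
    config: TANConfig | None = None,
    seed: int | None = None,
) -> TANClassifier:
    """Naive-Bayes baseline: class-conditional independence, same back-ends."""
    config = config or TANConfig()
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    classes, marg = _fit_all_densities(data, backend, config, ss)
    priors = np.array([float(np.mean(data.labels == c)) for c in classes])
    return TANClassifier(
        structure=None,
        classes=classes,
        class_priors=priors,
        marginal_models=marg,
        pair_models={},
        backend=backend,
        feature_names=data.feature_names,
    )


# ---------------------------------------------------------------------------
# cross-validation


def _stratified_folds(labels: np.ndarray, folds: int, rng: np.random.Generator):
    """Round-robin per-class fold assignment (handles leave-one-out)."""
    assign = np.empty(labels.shape[0], dtype=int)
    offset = 0
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        for k, i in enumerate(idx):
            assign[i] = (k + offset) % folds
        offset += idx.size
    return assign


def cross_validate(
    data: LabeledDataset,
    backend: str = "gmm",
    folds: int = 10,
    seed: int = 0,
    config: TANConfig | None = None,
    model: str = "tan",
) -> dict:
    """Stratified k-fold CV; per-fold accuracy and held-out log-likelihood.

    The reported log-likelihood is the mean per-instance log p(c_true, y)
    on the held-out fold.  ``model`` selects "tan" or "nb".
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    rng = np.random.default_rng(seed)
    assign = _stratified_folds(data.labels, folds, rng)
    if callable(model):
        builder = model
    else:
        builder = build_tan if model == "tan" else build_nb
    accs, lls = [], []
    for k in range(folds):
        test = assign == k
        train = ~test
        if not np.any(test):
            continue
        tr_labels = data.labels[train]
        if np.unique(tr_labels).size < np.unique(data.labels).size:
            raise ValueError(f"fold {k}: a class is missing from the training split")
        tr = LabeledDataset(data.x[train], tr_labels, data.feature_names)
        clf = builder(tr, backend=backend, config=config, seed=seed + k)
        pred, scores = clf.predict_batch(data.x[test])
        accs.append(float(np.mean(pred == data.labels[test])))
        ll = [
            scores[row, clf._cidx(c)]
            for row, c in enumerate(data.labels[test])
        ]
        lls.append(float(np.mean(ll)))
    return {
        "fold_accuracy": accs,
        "fold_loglik": lls,
        "accuracy_mean": float(np.mean(accs)),
        "accuracy_std": float(np.std(accs)),
        "loglik_mean": float(np.mean(lls)),
    }
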