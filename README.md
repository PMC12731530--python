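# tanmix

Estimation of latent mixing densities by a fast generative bootstrap, and
tree-augmented naive Bayes (TAN) structure learning for continuous
attributes built on top of it.

## The problem

Many biostatistical models are latent mixtures: each observation is generated
as

```
theta_i ~ pi(theta),      y_i | theta_i ~ f(y | theta_i),
```

with a known observation family `f` (Gaussian-location or Gamma-rate here)
and an unknown mixing density `pi` — the estimation target (empirical-Bayes
deconvolution). The nonparametric MLE of `pi` (Kiefer–Wolfowitz) is discrete,
and quantifying its uncertainty classically means re-solving the optimisation
under every weighted-likelihood-bootstrap draw `w ~ n x Dirichlet(1_n)`.

`tanmix` implements a two-stage amortised alternative:

* **Stage I** trains a small fully connected generator `G(w, z)` (bootstrap
  weights plus uniform noise in, a d x l candidate parameter matrix
  `Theta = [theta^(1), ..., theta^(l)]` out) by stochastic gradient descent
  on the bootstrap-weighted mixture negative log-likelihood
  `-sum_i w_i log (1/l) sum_j f(y_i | theta^(j))`, with fresh `(w, z)` draws
  every step.
* **Stage II** freezes a Monte-Carlo ensemble of M generator draws and runs
  an exact EM for mixture weights `tau` on the simplex:
  `tau_j <- (1/n) sum_i tau_j L_ij / sum_j' tau_j' L_ij'` with
  `L_ij = (1/M) sum_m f(y_i | Theta^(m)[:, j])` held fixed.

The result is an evaluable density `p_hat(y) = sum_j tau_j L_j(y)` and a
discrete mixing estimate (the l x M candidate atoms weighted by `tau_j / M`).

The TAN layer turns class-conditional density estimates (generative, KDE or
Gaussian-mixture back-ends) into Monte-Carlo conditional mutual information
`I(X_i; X_j | C)`, builds the maximum spanning tree with Prim's algorithm,
orients it, and classifies by `argmax_c p(c) prod_i p(y_i | y_pa(i), c)`.

Comparison estimators (weighted-bootstrap NPMLE by EM over a fixed support,
product-Gaussian KDE, Gaussian-mixture EM), the evaluation metrics (W1, ISE,
MSE, KL, SHD, Wilcoxon signed-rank, bootstrap edge consistency) and the
synthetic-data generators for every benchmark are included.

## Worked example

```python
import numpy as np
from tanmix import sim_gmm_scenario, fit_fgbmle, GeneratorConfig, w1

s = sim_gmm_scenario(n=1000, d=2, seed=0)          # bimodal latent mixture
cfg = GeneratorConfig(epochs=200, n_candidates=50, seed=1)
model = fit_fgbmle(s.x, s.observation_model, cfg)  # Stage I + Stage II

locs, wts = model.mixing_atoms()                   # discrete mixing estimate
print(round(w1(s.mixing_sampler, (locs, wts), m=50_000), 3))
```

This prints `0.189`: the mean coordinate-wise 1-Wasserstein distance between
the estimated mixing measure and the true bimodal mixing density
`0.5 N((-3,-3), 2I) + 0.5 N((3,3), I)` — i.e. the estimate concentrates its
mass correctly around both latent modes despite the unit-variance observation
noise.

Structure learning from a shell:

```
tanmix simulate --scenario chain --n 2000 --seed 7 --out chain.csv
tanmix classify --data chain.csv --class-col class --backend gmm \
    --folds 10 --seed 0 --out cv.json
tanmix learn-structure --n 1000 --reps 5 --backend kde --seed 0 --out shd.csv
```

The last command prints `mean SHD 0.000 +/- 0.000`: with the default strong
chain coefficients the learned attribute tree matches the true 8-node chain
in every trial.

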