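# Methods

## Model

Observations follow a latent mixture: `theta_i ~ pi`, `y_i | theta_i ~
f(y | theta_i)` with `f` known. Two families are built in:

* `gaussian_location` / `gaussian_location_diagonal`: `y ~ N(theta,
  diag(scale^2))`. `theta` carries locations only; the component scale is a
  model field, so the generator output is unconstrained real.
* `gamma_rate`: `y_j ~ Gamma(shape 10, rate theta_j)` independently per
  dimension (mean `10 / theta_j`). The shape is fixed; `theta` must be
  strictly positive. The rate convention is a deliberate reading of the
  scenario definition `Gamma(10, theta_j)` with `theta_j ~ Beta(10, 5)`:
  rates in (0, 1) give well-spread positive observations, whereas a scale
  convention would concentrate all mass below ~10.

All densities are computed in log space and mixtures combined by
log-sum-exp; products over dimensions and mixtures over `l x M` components
underflow otherwise.

## Two-stage generative bootstrap estimator

**Stage I.** The generator is a fully connected ReLU network mapping the
concatenation of a weighted-likelihood-bootstrap draw `w ~ n x
Dirichlet(1_n)` (length n — the model is therefore bound to the training n)
and uniform noise `z` to a candidate matrix `Theta in R^{d x l}`. Training
minimises the bootstrap-weighted mixture negative log-likelihood

    L(G) = - E_{w,z} sum_i w_i log (1/l) sum_j f(y_i | theta^(j)),

i.e. the candidate set realises the inner expectation of the generator
objective with a uniform prior `tau0` over candidates. This "log outside the
candidate average" form matters: averaging `log f` over candidates instead
(equivalently, scoring one sampled candidate per step) has a maximiser that
places *every* column at the bootstrap-weighted MLE point for the strictly
concave-in-theta families used here, and can never produce a mode-separated
candidate cloud. With the mixture form the gradient on column j is the
responsibility-weighted score `sum_i w_i gamma_ij d log f(y_i |
theta_j)/d theta`, an EM-like signal that separates candidates onto distinct
parts of the latent distribution. A single-candidate bootstrap-weighted loss
(`stage1_loss`) is still exported as a per-draw diagnostic.

Numerics: one "epoch" is `ceil(n / batch_size)` Adam steps (lr 1e-3,
Xavier-uniform init), each with fresh `(w, z)`; for n <= 2000 every step uses
the full weighted batch, which keeps the objective's expectation intact;
beyond that a subsampled batch with rescaled weights is used. Gaussian
families are fitted on internally standardised data (per-dimension mean/sd;
the component scale is rescaled and candidates are mapped back on output) so
the network's initial output range matches the data — a pure conditioning
choice. Gamma rates pass through a softplus head with a 1e-4 floor. Early
stopping watches an exponentially smoothed held-out NLL (10% split, delta
1e-4, patience 10) and only arms after a warmup of max(50, T/5) epochs,
since per-epoch improvements are smaller than the delta long before
convergence. Backprop and Adam are written out in numpy; the network is
small enough (default two hidden layers of 600) that a deep-learning
framework would buy nothing.

**Stage II.** After training, M = 100 frozen `(w, z)` draws are pushed
through the generator and cached. With `L_ij = (1/M) sum_m f(y_i |
Theta^(m)[:, j])` fixed, the mixture-weight update

    tau_j <- (1/n) sum_i tau_j L_ij / sum_j' tau_j' L_ij'

is an exact EM step for a finite mixture, so the negative log-likelihood is
non-increasing at every iteration (asserted, not sampled). Freezing the
ensemble is a deliberate resolution of an ambiguity: re-drawing `(w, z)`
every iteration would make the procedure a noisy MCEM without a monotonicity
guarantee and the fitted density non-deterministic. The printed stopping
rule of the reference pseudocode (`while min_j |delta tau_j| >= tol`) never
terminates once any single coordinate converges; we stop when `max_j
|delta tau_j| < tol` (tol 1e-5, at most 500 iterations).

The fitted density is `p_hat(y) = sum_j tau_j L_j(y)`, a mixture of `l x M`
observation-model components with weights `tau_j / M`; the mixing estimate
is the discrete measure on the `l x M` candidate columns with those weights.

Seeding: one root seed is split (`numpy.random.SeedSequence`) into
independent streams for the data split, weights, noise, initialisation and
the frozen ensemble, making runs bit-reproducible.

## Comparison estimators

* **Weighted-bootstrap NPMLE**: EM over the masses on a fixed support
  (1-D: 200-point grid over the data range expanded 10% per side; d >= 2:
  the observed points, Lindsay-style). B independent Dirichlet draws are
  fitted and the discrete measures averaged. The EM works on a row-shifted
  linear-space likelihood matrix (exact; avoids per-iteration log-sum-exp).
  Note the converged NPMLE is *discrete*: it represents a wide mixing
  component by a few atom clusters straddling the mode rather than a smooth
  bump. For ISE/MSE/KL the discrete average is convolved with a Gaussian
  kernel of bandwidth half the support spacing; W1 is computed directly on
  the discrete measure.
* **KDE**: product-Gaussian kernels, per-dimension normal-reference
  bandwidth `1.06 sigma_j n^(-1/5)` (Silverman), Scott and fixed rules
  available. In the mixing-recovery tables the KDE is applied to the
  *observed* samples and compared against the mixing truth — no
  deconvolution — which is exactly why it trails the deconvolving methods.
* **GMM**: scikit-learn `GaussianMixture` (best of `restarts` inits,
  1e-6 covariance ridge) behind a thin evaluable wrapper.

## TAN structure learning and classification

Class-conditional densities for single features and feature pairs are fitted
per class on globally z-scored coordinates (transform recorded; log-densities
reported in original units). Back-ends: `kde`, `gmm`, and `fgbmle` — the
latter a learned-location Gaussian mixture whose per-axis component scale is
the normal-reference bandwidth of the class data, making it directly
comparable to a KDE with estimated kernel centres. The per-fit generator for
the TAN back-end is smaller than the deconvolution default (hidden layers
128-64, l = 20, 150 epochs, M = 30): a TAN fit trains `K (2d - 1)` one- and
two-dimensional models, and these problems are easier than the full
deconvolution benchmarks — but it cannot be shrunk much further, since the
conditional-mutual-information ranking between adjacent and second-neighbour
chain pairs is decided by subtle density differences.

CMI `I(X_i; X_j | C)` is estimated per class by sampling S = 5000 points
from the fitted joint and averaging `log joint - log marg_i - log marg_j`
(natural log; only the ranking matters for the tree). Raw values may be
slightly negative by Monte-Carlo noise; they are clamped at zero for edge
weights and retained raw in reports. Prim's algorithm grows the maximum
spanning tree from vertex 0, breaking weight ties toward the
lexicographically smallest pair, so the structure is deterministic. Edges
are oriented away from attribute 0; the classifier's pairwise factorisation
telescopes, so the orientation root provably never changes a decision
(asserted to 1e-9). Class priors are empirical frequencies; missing feature
values are mean-imputed at load time.

## Synthetic study conditions

* Bimodal Gaussian scenario: `pi = 0.5 N((-3,...), 2I) + 0.5 N((3,...), I)`,
  observation noise `N(0, I)`; component membership by fair coin.
* Gamma scenario: `theta_j ~ Beta(10, 5)` i.i.d., `x_j ~ Gamma(10, rate
  theta_j)`.
* Trimodal 1-D density `1/3 N(-3, 0.5^2) + 1/3 N(0, 1) + 1/3 N(3, 0.7^2)`
  (equal weights — the source leaves them unstated); here the estimand is
  the data density itself.
* Linear-Gaussian chain: binary class `C ~ Bernoulli(1/2)`, eight attributes
  with `X_1 | c ~ N(mu_1(c), 1)` (`mu_1 = -/+1`) and `X_j | X_{j-1}, c ~
  N(a_j(c) X_{j-1} + b_j(c), 0.25)`, `|a_j| in [0.7, 1.3]` with random sign
  and `b_j in [-1, 1]`, drawn once from a parameter seed and fixed across
  trials. The ranges are chosen so within-class parent-child correlations
  are strong (≳ 0.6) and near-zero SHD is achievable; they are
  config-exposed.

What the generators do *not* emulate: model misspecification (the observation
family is always exactly right), heavy-tailed or contaminated noise,
dependent latent draws, and discrete attributes. Passing benchmarks here
demonstrates correct estimation under the stated conditions, not robustness
on arbitrary real data.

## Evaluation conventions

W1 is the CDF-difference integral, exact in 1-D via weighted quantile
matching on 1e5 samples; for d >= 2 the *mean of coordinate-wise marginal
W1* is reported (the cheapest faithful extension of the 1-D definition —
reported absolute values in multi-dimensional tables depend on this
convention). Grid metrics use 512 points spanning the truth's 99.99% mass in
1-D and 128 x 128 in 2-D; KL is `KL(truth || estimate)` with the estimate
floored at 1e-12 (this direction penalises missing mass where the truth
lives). SHD counts undirected attribute-edge disagreements. The Wilcoxon
signed-rank test drops zero differences, average-ranks ties, and is exact
for <= 25 tie-free pairs (normal approximation with continuity correction
otherwise).

## Problem sizes

The default benchmark drivers use n = 1000 (d = 2) with 5–10 replicates,
B = 50 bootstrap resamples, 20 structure-recovery trials, and 200 training
epochs for the 2-D deconvolution fits; the test suite re-runs the same
protocols at 1–6 replicates. These are the package's chosen desk-scale
conditions; all counts are arguments.

## Known limitations

* The generator is bound to the training sample size n (its input includes
  the length-n weight vector); no amortisation across datasets.
* Stage-I optimisation is non-convex; different seeds move the mixing W1 of
  the Gamma scenario by a factor ~2 (the replicate average is the reported
  quantity).
* Exact Kiefer–Wolfowitz support optimisation (vertex-direction methods) is
  not implemented; the NPMLE support is fixed.
* Multi-dimensional W1 is the marginal mean, not an optimal-transport
  distance.
* Only continuous attributes are supported in the TAN layer.
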