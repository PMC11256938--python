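# Methods

## Generative model

A cell's measured expression is modeled as arising from two latent
quantities: a low-dimensional state vector `z ∈ R^d` that carries the
biology, and a positive scaling factor `t` that absorbs capture efficiency
and sequencing depth. The state has a Gaussian-mixture prior with identity
component covariances, `p(z) = Σ_c π_c N(z; μ_c, I)`; the mixture is the
heterogeneity model, and restricting covariances to the identity keeps the
component responsibilities available in closed form,
`q(c|z) ∝ π_c exp(−‖z−μ_c‖²/2)`. The log scaling factor has a Gaussian
prior whose mean and variance are the empirical per-batch moments of the
log library size (population variance, floored at 1e−4 so single-cell or
constant-depth batches remain usable).

Counts are zero-inflated negative binomial. Two decoder networks map
`(z, s)` — `s` the one-hot batch label — to the mean expression fractions
`ρ` (softmax head, so each cell's fractions sum to 1) and the dropout
probabilities `α` (sigmoid link); gene-wise inverse dispersions enter as
`θ_g = exp(free parameter)` to stay positive. The NB branch is the
Gamma–Poisson mixture with mean `t·ρ_ng` and shape `θ_g`; zero counts also
receive the inflation mass `α`. The log-pmf is evaluated through
`logaddexp` at zero so `θ` in the hundreds and `α` near the boundaries are
safe.

Conditioning both decoders (and the encoders) on `s` is what removes batch
effects: the decoder can explain batch-specific distortion through `s`, so
the latent state has no incentive to encode it.

## Variational inference and coordinate descent

Mean-field posteriors `q(z|x,s) = N(μ_z, diag σ_z²)` and
`q(log t|x,s) = N(μ_t, σ_t²)` are amortized by two encoder networks.
Training maximizes a Monte-Carlo estimator of the mixture-aware evidence
lower bound: per cell, the closed-form Gaussian KL for the scaling factor,
plus (averaged over L reparameterized draws) the ZINB log-likelihood, the
negative sampled log-density of `q(z|x,s)`, and the mixture terms
`−KL(q(c|z)‖π) + Σ_c q(c|z) log N(z; μ_c, I)`. By the closed form of
`q(c|z)` these mixture terms sum exactly to `log p(z)`; the implementation
exploits the identity and evaluates a log-sum-exp over components (the
Bayes-consistency property is tested).

Parameters split into two blocks. The **network block** (four MLPs plus
`log θ`) takes one Adam step per minibatch with the mixture frozen. The
**mixture block** `(π, μ)` is updated once per epoch by a single EM
iteration on the latent draws stored during that epoch's minibatch sweep,
with the networks frozen: responsibilities are recomputed from the stored
draws under the current `(π, μ)` (responsibilities computed mid-epoch under
drifting network weights are discarded), then means become
responsibility-weighted draw averages and weights the normalized
responsibility mass. One EM iteration per epoch cannot decrease the
mixture likelihood of the stored draws (tested).

Mixture initialization: for the first `warmup_epochs` (default 10) the
prior is a single standard Gaussian; then k-means with C centers on the
full-data posterior means seeds `μ_c`, with `π_c` the cluster fractions.
A component whose responsibility mass vanishes (< 1e−10 of the draws) is
re-seeded at the draw farthest from all current means. With
`n_components=1` the prior stays the fixed standard Gaussian and EM never
runs — exactly a scVI-style non-mixture VAE; this configuration is the
ablation baseline used in the evaluation.

Convergence: training stops when the relative change of the epoch-mean
bound estimator over a trailing 10-epoch window falls below
`convergence_tol` (default 1e−4), or at `max_epochs`.

## Networks and numerical choices

Each of the four networks is one hidden layer of 128 units (ReLU) with
batch normalization; the one-hot batch label is concatenated to every
layer input. Posterior scales use a softplus link with a 1e−4 floor.
Evaluation-mode batch normalization uses exponential running averages, so
encodings are deterministic and independent of minibatch composition.

The networks are trained in float64 by a small reverse-mode automatic
differentiation engine written on numpy (`scvic._autodiff`); the full
objective's gradients agree with central finite differences to ~1e−7
relative. Defaults follow the scVI convention set: `d = 10`, `L = 1`
Monte-Carlo sample, minibatch 128, up to 400 epochs, Adam at 1e−3.

Three initialization choices matter at small problem sizes, where an epoch
is only a handful of Adam steps:

- encoders see per-gene standardized `log1p` of library-normalized counts
  (cells scaled to a common total of 1e4). Depth is deliberately removed
  from the conditioning signal — it belongs to the scaling factor — and
  raw-count `log1p` inputs otherwise put sequencing depth on the first
  latent axis. The likelihood always sees raw counts.
- the softmax mean head starts at the global expression profile
  (log mean proportions) and `θ_g` at a moment-matched estimate, so early
  gradients work on between-cell structure instead of on the
  orders-of-magnitude differences between gene abundances.
- the latent-mean head is warm-started by least squares onto the leading
  PCA scores of the (batch-centered) normalized input — with the component
  scales preserved, not whitened — and the encoder's covariate weight
  columns start at zero so one-hot labels induce no artificial batch
  separation at initialization.
- for the first `decoder_warmup_epochs` (default 10) only the decoders and
  dispersions receive updates. Early in training the likelihood is nearly
  blind to `z` (the decoder has not yet learned to use it), so encoder
  gradients are dominated by the prior and entropy terms, which would
  scramble the warm-started encodings before reconstruction can anchor
  them. Freezing the encoders until the decoders catch up preserves the
  initialization; the objective itself is unchanged.

## Clustering

Built-in: `argmax_c q(c | μ_z)`, ties to the lowest component index.
Louvain: a symmetrized 15-nearest-neighbor graph on the encodings
(Euclidean), edges weighted by the Jaccard similarity of the endpoint
neighborhoods, modularity optimization with resolution 0.5 and a seeded
RNG. The resolution default was calibrated once on simulator latents:
plain modularity (resolution 1) splits tight ~170-cell groups into halves,
an artifact of modularity's characteristic community scale at a few
hundred cells; 0.5 recovers the generative groups across the scenario
grid. Both label sets are relabeled to consecutive integers in order of
first appearance.

## Synthetic data

The simulator emulates the splat generative pathway at the point needed to
evaluate clustering and batch correction: lognormal gene base means
(log-location −0.56, log-scale 1.73 — the log-moment match of the splat
gamma with shape 0.6 and rate 0.3); per-group differential-expression
factors `exp(±N(loc, scale))` on a random 10 % of genes (scale defaults to
0.2, the evaluation design's value; the log-location defaults to 0.5 so
that datasets of a few hundred genes — the package's default working size
— carry the same aggregate group separability that the original
2500-gene design has at splat's 0.1); lognormal library sizes (log-location
11, log-scale 0.2, splat defaults, ≈ 60 000 median counts); Gamma–Poisson
counts with shape 100 (biological CV ≈ 0.1); and experiment-wide logistic
dropout, `P(zeroed) = sigmoid(shape·(log mean − mid))` with `shape = −1`.
Batch scenarios multiply all gene means by per-batch lognormal factors
(log-location and scale 0.1) and split cells into batches whose sizes
follow a geometric sequence (ratio 0.7 in the three-batch design).

The `dropout_mid` axis indexes expected capture loss — the fraction of
would-be non-zero entries zeroed — linearly: −1.5 → 5 %, 0.5 → 25 %. The
logistic midpoint realizing the target is solved per dataset by bisection
on the expected rate, so realized rates match the design at every problem
size (tested to land at 5/15/25 % across sizes).

What the generator does **not** emulate: splat's outlier genes and
mean–variance BCV trend, doublets, paths/trajectories, per-batch dropout
differences, and any form of gene–gene correlation beyond group and batch
structure. Passing tests therefore demonstrate recovery of compact,
program-level group structure under dropout and multiplicative batch
effects — not performance on continuous differentiation or on data with
correlated technical artifacts.

## Evaluation

ARI and NMI (normalized by the larger partition entropy) quantify
agreement with the simulated ground truth. Batch mixing is scored by the
KNN-region KL divergence: repeatedly sample 50 query cells, take each
query's 50 nearest latent-space neighbors (the query excluded), and
average `Σ_b q_b log(q_b/p_b)` between regional and global batch
proportions over regions and 100 iterations; zero regional proportions
contribute nothing (0·log 0 = 0). Lower is better-mixed; the score is
invariant to rigid motions of the latent space.

## Problem sizes

The package's test and benchmark runs use scaled-down designs chosen to
exercise the full pipeline on a single CPU: unit fixtures of 200–300
cells, an end-to-end recovery scenario of 500 cells × 300 genes at 15 %
capture loss and 100 epochs, and a reduced balanced study grid (3/5/7
groups × 5/15/25 % capture loss × 3 seeds, 500 × 300, 200 epochs) with the
non-mixture ablation fit on every dataset. The original full-size design
(2500 × 2500, 25 grid cells, 10 seeds) is available behind
`scvic reproduce-sim --full`.

## Known limitations

- The identity-covariance mixture prior and the built-in argmax rule
  assume roughly isotropic latent clusters; at high dropout the latent
  geometry elongates and graph-based Louvain labels become more reliable
  than the built-in ones (visible in the study output).
- EM on one noisy draw per cell per epoch (L = 1) makes mixture means
  slightly jittery; raising `mc_samples` smooths them at linear cost.
- The simulator's group programs are axis-aligned fold changes; real cell
  types also differ in co-expression structure the model never sees.
- Checkpoints store network weights and mixture/library parameters, not
  optimizer state; resuming training restarts Adam moments.
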