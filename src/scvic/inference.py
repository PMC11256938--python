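"""Coordinate-descent inference.

Training alternates two blocks:

* **network block** — encoder/decoder weights and the gene-wise
  log-dispersions are updated by Adam on a reparameterized Monte-Carlo
  estimator of the mixture-aware variational lower bound, with the mixture
  parameters held fixed;
* **mixture block** — after each epoch's minibatch sweep, the mixture
  weights and means are updated by one EM iteration on the latent draws
  accumulated during that epoch, with the networks held fixed.  The E-step
  responsibilities are recomputed from the stored draws under the current
  mixture parameters (the draws collected under drifting network weights
  are reused, their responsibilities are not).

With a single mixture component the prior stays the fixed standard
Gaussian and EM is skipped entirely, which recovers the scVI-style
non-mixture model; that configuration doubles as the ablation baseline.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln
from sklearn.cluster import KMeans

from ._autodiff import Adam, Tensor, logsumexp
from .config import TrainingConfig
from .core import (
    LOG_2PI,
    CountDataset,
    DecoderOutput,
    GMMPrior,
    LatentSamples,
    LibraryPrior,
    VariationalPosterior,
    compute_library_prior,
    responsibilities,
)
from .networks import CovariateMLP, Parameter, positive_scale

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# model state
# ---------------------------------------------------------------------------


@dataclass
class ModelState:
    enc_z: CovariateMLP
    enc_t: CovariateMLP
    dec_rho: CovariateMLP
    dec_alpha: CovariateMLP
    log_theta: Parameter
    gmm: GMMPrior
    lib_prior: LibraryPrior
    config: TrainingConfig
    gene_mean: np.ndarray
    gene_std: np.ndarray
    batch_categories: np.ndarray
    rng: np.random.Generator
    optimizer: Adam | None = None
    epoch: int = 0
    elbo_trace: list = field(default_factory=list)
    em_events: list = field(default_factory=list)
    gmm_seeded: bool = False

    def set_training(self, training: bool) -> None:
        for net in (self.enc_z, self.enc_t, self.dec_rho, self.dec_alpha):
            net.set_training(training)

    @property
    def _bn_buffers(self):
        out = []
        for ni, net in enumerate((self.enc_z, self.enc_t, self.dec_rho, self.dec_alpha)):
            for li, norm in enumerate(net.norms):
                out.append((f"bn_{ni}_{li}", norm))
        return out

    @property
    def network_params(self) -> list[Parameter]:
        return (
            self.enc_z.params
            + self.enc_t.params
            + self.dec_rho.params
            + self.dec_alpha.params
            + [self.log_theta]
        )

    # -- conditioning helpers ---------------------------------------------

    def _norm_input(self, counts: np.ndarray) -> np.ndarray:
        """Library-normalized log1p counts, standardized per gene.

        Cells are scaled to a common total of 10^4 before log1p so the
        conditioning signal reflects composition, not sequencing depth
        (depth enters the model through the scaling factor instead); the
        raw counts are what the likelihood sees.
        """
        totals = np.maximum(counts.sum(axis=1, keepdims=True), 1)
        xl = np.log1p(counts / totals * 1e4)
        return (xl - self.gene_mean) / self.gene_std

    def _onehot(self, batch_labels: np.ndarray) -> np.ndarray:
        out = np.zeros((len(batch_labels), len(self.batch_categories)))
        for i, lab in enumerate(batch_labels):
            idx = np.where(self.batch_categories == lab)[0]
            if len(idx) == 0:
                raise KeyError(f"unseen batch label {lab!r}")
            out[i, idx[0]] = 1.0
        return out

    def snapshot(self) -> dict:
        return {
            "params": [p.data.copy() for p in self.network_params],
            "bn": [
                (norm.running_mean.copy(), norm.running_var.copy())
                for _, norm in self._bn_buffers
            ],
            "gmm_pi": self.gmm.pi.copy(),
            "gmm_mu": self.gmm.mu.copy(),
            "opt": None
            if self.optimizer is None
            else {
                "t": self.optimizer.t,
                "m": [m.copy() for m in self.optimizer.m],
                "v": [v.copy() for v in self.optimizer.v],
            },
        }

    def restore(self, snap: dict) -> None:
        for p, data in zip(self.network_params, snap["params"]):
            p.data = data.copy()
        for (_, norm), (rm, rv) in zip(self._bn_buffers, snap["bn"]):
            norm.running_mean = rm.copy()
            norm.running_var = rv.copy()
        self.gmm = GMMPrior(snap["gmm_pi"].copy(), snap["gmm_mu"].copy())
        if snap["opt"] is not None and self.optimizer is not None:
            self.optimizer.load_state_dict(
                {
                    "t": snap["opt"]["t"],
                    "m": [m.copy() for m in snap["opt"]["m"]],
                    "v": [v.copy() for v in snap["opt"]["v"]],
                }
            )

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        arrays = {f"param_{i}": p.data for i, p in enumerate(self.network_params)}
        for name, norm in self._bn_buffers:
            arrays[f"{name}_mean"] = norm.running_mean
            arrays[f"{name}_var"] = norm.running_var
        arrays["gmm_pi"] = self.gmm.pi
        arrays["gmm_mu"] = self.gmm.mu
        arrays["lib_mu_bar"] = self.lib_prior.mu_bar
        arrays["lib_sigma_bar_sq"] = self.lib_prior.sigma_bar_sq
        arrays["gene_mean"] = self.gene_mean
        arrays["gene_std"] = self.gene_std
        arrays["batch_categories"] = self.batch_categories.astype(str)
        arrays["elbo_trace"] = np.asarray(self.elbo_trace, dtype=np.float64)
        arrays["epoch"] = np.array([self.epoch])
        arrays["gmm_seeded"] = np.array([int(self.gmm_seeded)])
        arrays["config_json"] = np.array([json.dumps(self.config.to_dict())])
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "ModelState":
        with np.load(path, allow_pickle=False) as f:
            config = TrainingConfig.from_dict(json.loads(str(f["config_json"][0])))
            gene_mean = f["gene_mean"]
            gene_std = f["gene_std"]
            batch_categories = f["batch_categories"]
            state = initialize_state_from_shapes(
                n_genes=len(gene_mean),
                n_batches=len(batch_categories),
                config=config,
            )
            state.gene_mean = gene_mean
            state.gene_std = gene_std
            state.batch_categories = batch_categories
            state.lib_prior = LibraryPrior(
                f["lib_mu_bar"], f["lib_sigma_bar_sq"], batch_categories
            )
            state.gmm = GMMPrior(f["gmm_pi"], f["gmm_mu"])
            state.elbo_trace = list(f["elbo_trace"])
            state.epoch = int(f["epoch"][0])
            state.gmm_seeded = bool(f["gmm_seeded"][0])
            for i, p in enumerate(state.network_params):
                p.data = f[f"param_{i}"]
            for name, norm in state._bn_buffers:
                norm.running_mean = f[f"{name}_mean"]
                norm.running_var = f[f"{name}_var"]
        return state


def initialize_state_from_shapes(
    n_genes: int, n_batches: int, config: TrainingConfig
) -> ModelState:
    rng = np.random.default_rng(config.seed)
    d = config.latent_dim
    hidden = config.hidden_sizes
    enc_z = CovariateMLP(rng, n_genes, n_batches, hidden, (d, d))
    enc_t = CovariateMLP(rng, n_genes, n_batches, hidden, (1, 1))
    dec_rho = CovariateMLP(rng, d, n_batches, hidden, (n_genes,))
    dec_alpha = CovariateMLP(rng, d, n_batches, hidden, (n_genes,))
    log_theta = Parameter(np.zeros(n_genes))  # theta_g = exp(.) initialized at 1
    gmm = GMMPrior(np.ones(1), np.zeros((1, d)))
    lib = LibraryPrior(
        np.zeros(n_batches),
        np.ones(n_batches),
        np.array([f"batch{i}" for i in range(n_batches)]),
    )
    state = ModelState(
        enc_z=enc_z,
        enc_t=enc_t,
        dec_rho=dec_rho,
        dec_alpha=dec_alpha,
        log_theta=log_theta,
        gmm=gmm,
        lib_prior=lib,
        config=config,
        gene_mean=np.zeros(n_genes),
        gene_std=np.ones(n_genes),
        batch_categories=lib.batch_categories,
        rng=rng,
    )
    state.optimizer = Adam(state.network_params, lr=config.learning_rate)
    return state


def initialize_state(dataset: CountDataset, config: TrainingConfig) -> ModelState:
    state = initialize_state_from_shapes(dataset.n_genes, dataset.n_batches, config)
    state.batch_categories = dataset.batch_categories
    state.lib_prior = compute_library_prior(dataset, var_floor=config.lib_var_floor)
    totals = np.maximum(dataset.counts.sum(axis=1, keepdims=True), 1)
    xlog = np.log1p(dataset.counts / totals * 1e4)
    state.gene_mean = xlog.mean(axis=0)
    state.gene_std = np.maximum(xlog.std(axis=0), 1e-3)
    # start the scaling-factor posterior near the observed library scale
    state.enc_t.heads[0].b.data[:] = np.log(dataset.library_sizes()).mean()
    # start the softmax mean head at the global expression profile so the
    # early gradient budget goes to between-cell structure, not to the
    # orders-of-magnitude differences between gene abundances
    lib = dataset.library_sizes().astype(np.float64)
    prop = (dataset.counts / lib[:, None]).mean(axis=0)
    state.dec_rho.heads[0].b.data[:] = np.log(np.maximum(prop, 1e-12))
    # moment-matched gene dispersions from library-scaled counts:
    # var = mu + mu^2 / theta  =>  theta = mu^2 / (var - mu)
    scaled = dataset.counts * (lib.mean() / lib)[:, None]
    mu_g = scaled.mean(axis=0)
    excess = np.maximum(scaled.var(axis=0) - mu_g, 1e-8)
    theta0 = np.clip(mu_g**2 / excess, 1e-2, 1e3)
    state.log_theta.data[:] = np.log(theta0)
    # encoders start batch-neutral; decoders keep random covariate weights
    # (they must learn the batch factors)
    state.enc_z.zero_covariate_weights(dataset.n_batches)
    state.enc_t.zero_covariate_weights(dataset.n_batches)
    _warm_start_encoder(state, dataset)
    return state


def _warm_start_encoder(state: ModelState, dataset: CountDataset) -> None:
    """Align the latent-mean head with the top principal components.

    The head weights are set by least squares from the initial hidden
    features to the leading PCA scores of the normalized input, so the
    latent space starts out informative instead of spending most of the
    step budget escaping an arbitrary initialization.  Purely an
    initialization: the objective and training loop are unchanged.
    """
    from sklearn.decomposition import PCA

    d = state.config.latent_dim
    xin = state._norm_input(dataset.counts)
    cov = state._onehot(dataset.batch)
    # seed every BN buffer with exact full-data statistics so evaluation-mode
    # features at initialization equal the features the fit below sees
    from ._autodiff import concat as _concat

    for net in (state.enc_z, state.enc_t, state.dec_rho, state.dec_alpha):
        net.set_training(True)
    ht = Tensor(xin)
    covt = Tensor(cov)
    for layer, norm in zip(state.enc_z.trunk, state.enc_z.norms):
        pre = layer(_concat([ht, covt], axis=-1))
        norm.running_mean = pre.data.mean(axis=0)
        norm.running_var = pre.data.var(axis=0)
        ht = norm(pre).relu()
    feats = np.concatenate([ht.data, cov], axis=1)
    n_comp = min(d, dataset.n_cells - 1, dataset.n_genes)
    # batch-center the PCA target so the warm start aims at biological
    # structure, not at the batch axis
    xc = xin.copy()
    for b in range(dataset.n_batches):
        sel = dataset.batch_codes == b
        xc[sel] -= xc[sel].mean(axis=0)
    scores = PCA(n_components=n_comp, random_state=int(state.config.seed % (2**31))
                 ).fit_transform(xc)
    # preserve the relative component scales; normalize only the overall
    # size so the latent starts prior-sized
    scores = scores / max(scores[:, 0].std(), 1e-8)
    target = np.zeros((dataset.n_cells, d))
    target[:, :n_comp] = scores
    feats_aug = np.concatenate([feats, np.ones((dataset.n_cells, 1))], axis=1)
    coef, *_ = np.linalg.lstsq(feats_aug, target, rcond=None)
    head = state.enc_z.heads[0]
    head.W.data[:] = coef[:-1]
    head.b.data[:] = coef[-1]


# ---------------------------------------------------------------------------
# differentiable objective
# ---------------------------------------------------------------------------


def _zinb_loglik_graph(x, t, rho, alogit, theta):
    """Tape version of the ZINB log-pmf, summed over genes -> (n,) Tensor."""
    mu = t * rho
    log_theta = theta.log()
    log_theta_mu = (theta + mu).log()
    nb_zero = theta * (log_theta - log_theta_mu)  # log NB(0; mu, theta)
    sp_alogit = alogit.softplus()
    # stable logaddexp(a, b) = a + softplus(b - a)
    case_zero = alogit + (nb_zero - alogit).softplus() - sp_alogit
    lgam_const = -gammaln(x + 1.0)
    case_pos = (
        -sp_alogit
        + (theta + x).lgamma()
        - theta.lgamma()
        + lgam_const
        + nb_zero
        + x * (mu.log() - log_theta_mu)
    )
    mask0 = (x == 0).astype(np.float64)
    ll = mask0 * case_zero + (1.0 - mask0) * case_pos
    return ll.sum(axis=1)


def _forward_graph(state: ModelState, x, s_onehot, batch_codes, eps_z, eps_t):
    """Build the estimator of the variational bound for one minibatch.

    Returns ``(estimator, z_data)`` where ``estimator`` is the scalar tape
    node (sum over cells of the per-cell bound contribution) and ``z_data``
    the raw latent draws with shape (L, n, d).
    """
    cfg = state.config
    n = x.shape[0]
    n_l = eps_z.shape[0]
    xin = Tensor(state._norm_input(x))
    cov = Tensor(s_onehot)

    mu_z, raw_sz = state.enc_z(xin, cov)
    sigma_z = positive_scale(raw_sz, cfg.sigma_floor)
    mu_t, raw_st = state.enc_t(xin, cov)
    sigma_t = positive_scale(raw_st, cfg.sigma_floor)

    # closed-form KL for the log scaling factor against its batch prior
    m_bar = state.lib_prior.mu_bar[batch_codes][:, None]
    v_bar = state.lib_prior.sigma_bar_sq[batch_codes][:, None]
    kl_t = (
        0.5 * np.log(v_bar)
        - sigma_t.log()
        + (sigma_t.square() + (mu_t - m_bar).square()) * (0.5 / v_bar)
        - 0.5
    ).sum(axis=1)

    pi = state.gmm.pi
    mu_c = state.gmm.mu
    d = mu_c.shape[1]
    m2 = (mu_c**2).sum(axis=1)  # (C,)

    x_counts = x.astype(np.float64)
    theta = state.log_theta.exp()

    per_cell = -kl_t
    z_data = np.empty((n_l, n, d))
    for draw in range(n_l):
        z = mu_z + sigma_z * eps_z[draw]
        t = (mu_t + sigma_t * eps_t[draw][:, None]).exp()  # (n, 1)
        rho = state.dec_rho(z, cov)[0].softmax(axis=-1)
        alogit = state.dec_alpha(z, cov)[0]
        ll = _zinb_loglik_graph(x_counts, t, rho, alogit, theta)

        # -E log q(z|x): the quadratic term is constant under reparameterization
        log_q_z = (-0.5 * LOG_2PI - sigma_z.log()).sum(axis=1) + Tensor(
            -0.5 * (eps_z[draw] ** 2).sum(axis=1)
        )

        # mixture terms: -KL(q(c|z)||p(c)) + sum_c q(c|z) log p(z|c)
        # which collapses exactly to log p(z) = logsumexp_c [log pi_c + log N(z; mu_c, I)]
        z2 = z.square().sum(axis=1, keepdims=True)  # (n, 1)
        cross = z @ mu_c.T  # (n, C)
        sq = z2 - 2.0 * cross + m2
        log_w = np.log(pi)[None, :] + (-0.5 * d * LOG_2PI) + (-0.5) * sq
        mix = logsumexp(log_w, axis=-1)

        per_cell = per_cell + (ll - log_q_z + mix) * (1.0 / n_l)
        z_data[draw] = z.data

    return per_cell.sum(), z_data


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def encode(state: ModelState, minibatch: CountDataset) -> VariationalPosterior:
    """Variational posterior parameters for each cell in the minibatch."""
    state.set_training(False)
    xin = Tensor(state._norm_input(minibatch.counts))
    cov = Tensor(state._onehot(minibatch.batch))
    mu_z, raw_sz = state.enc_z(xin, cov)
    mu_t, raw_st = state.enc_t(xin, cov)
    floor = state.config.sigma_floor
    return VariationalPosterior(
        mu_z=mu_z.data,
        sigma_z=positive_scale(raw_sz, floor).data,
        mu_t=mu_t.data[:, 0],
        sigma_t=positive_scale(raw_st, floor).data[:, 0],
    )


def decode(state: ModelState, z: np.ndarray, batch_labels: np.ndarray) -> DecoderOutput:
    """ZINB parameters decoded from latent points (deterministic)."""
    state.set_training(False)
    cov = Tensor(state._onehot(batch_labels))
    zt = Tensor(np.atleast_2d(z))
    rho = state.dec_rho(zt, cov)[0].softmax(axis=-1)
    alpha = state.dec_alpha(zt, cov)[0].sigmoid()
    eps = 1e-12
    return DecoderOutput(
        rho=rho.data,
        alpha=np.clip(alpha.data, eps, 1 - eps),
        theta=np.exp(state.log_theta.data),
    )


def reparameterized_sample(
    posterior: VariationalPosterior, n_samples: int, rng
) -> LatentSamples:
    """Draw ``z = mu + sigma * eps`` and ``t = exp(mu_t + sigma_t * eps')``."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n, d = posterior.mu_z.shape
    eps_z = rng.standard_normal((n_samples, n, d))
    eps_t = rng.standard_normal((n_samples, n))
    z = posterior.mu_z[None] + posterior.sigma_z[None] * eps_z
    t = np.exp(posterior.mu_t[None] + posterior.sigma_t[None] * eps_t)
    return LatentSamples(z_draws=z, t_draws=t)


def gradient_step(minibatch: CountDataset, state: ModelState):
    """One Adam update of the network block; mixture block untouched.

    Returns ``(estimator_value, z_draws)`` where the estimator is the
    minibatch sum of per-cell bound contributions and ``z_draws`` has shape
    (L, n, d) for the epoch's EM accumulation.
    """
    cfg = state.config
    x = minibatch.counts
    s_onehot = state._onehot(minibatch.batch)
    batch_codes = np.array(
        [int(np.where(state.batch_categories == b)[0][0]) for b in minibatch.batch]
    )
    n = x.shape[0]
    state.set_training(True)
    eps_z = state.rng.standard_normal((cfg.mc_samples, n, cfg.latent_dim))
    eps_t = state.rng.standard_normal((cfg.mc_samples, n))

    estimator, z_data = _forward_graph(state, x, s_onehot, batch_codes, eps_z, eps_t)
    loss = estimator * (-1.0 / n)  # maximize per-cell mean of the bound
    state.optimizer.zero_grad()
    loss.backward()
    for p in state.network_params:
        if p.grad is not None and not np.all(np.isfinite(p.grad)):
            raise FloatingPointError("non-finite gradient in network block")
    if state.epoch < cfg.decoder_warmup_epochs:
        # let the decoders learn to use z before the encoders move: early
        # on the likelihood is nearly z-blind and the prior/entropy pull
        # would scramble the warm-started encodings
        for p in state.enc_z.params + state.enc_t.params:
            p.grad = None
    state.optimizer.step()
    return float(estimator.data), z_data


def em_update(
    z_samples: np.ndarray, prior: GMMPrior, min_mass: float = 1e-10
) -> GMMPrior:
    """One EM iteration on accumulated latent draws.

    E-step: responsibilities of each draw under the current mixture.
    M-step: means become responsibility-weighted draw averages, weights the
    normalized responsibility mass.  A component whose normalized mass
    falls below ``min_mass`` is re-seeded at the draw farthest from all
    current means, with weights redistributed proportionally.
    """
    z = np.atleast_2d(np.asarray(z_samples, dtype=np.float64))
    if z.ndim == 3:  # (L, N, d) -> flatten draws
        z = z.reshape(-1, z.shape[-1])
    m = z.shape[0]
    resp = responsibilities(z, prior).q_c_z  # (M, C)
    mass = resp.sum(axis=0)  # (C,)
    new_pi = mass / m
    empty = new_pi < min_mass
    new_mu = prior.mu.copy()
    ok = ~empty
    new_mu[ok] = (resp[:, ok].T @ z) / mass[ok][:, None]
    if np.any(empty):
        # farthest draw from all current means re-seeds each empty component
        for c in np.where(empty)[0]:
            dists = np.linalg.norm(z[:, None, :] - new_mu[None], axis=-1).min(axis=1)
            far = int(np.argmax(dists))
            new_mu[c] = z[far]
            logger.warning("re-seeded empty mixture component %d at draw %d", c, far)
        new_pi[empty] = 1.0 / len(new_pi)
        new_pi = new_pi / new_pi.sum()
    return GMMPrior(new_pi, new_mu)


def gmm_objective(z_samples: np.ndarray, prior: GMMPrior) -> float:
    """Mixture log-likelihood of the stored draws (the EM target)."""
    from .core import gmm_log_density

    z = np.atleast_2d(np.asarray(z_samples, dtype=np.float64))
    if z.ndim == 3:
        z = z.reshape(-1, z.shape[-1])
    return float(np.sum(gmm_log_density(z, prior)))


def fit(dataset: CountDataset, config: TrainingConfig) -> ModelState:
    """Full coordinate-descent training loop.

    Each epoch sweeps shuffled minibatches with Adam updates of the network
    block, then (once the mixture is active) performs one EM iteration on
    the latent draws stored during the sweep.  The mixture is seeded after
    a warm-up window by k-means on the full-data posterior means.  Training
    stops at ``max_epochs`` or when the relative change of the epoch-mean
    estimator over a trailing window falls below ``convergence_tol``.
    """
    state = initialize_state(dataset, config)
    n = dataset.n_cells
    c = config.n_components
    if c > n:
        raise ValueError("more mixture components than cells")

    last_good = state.snapshot()
    for epoch in range(config.max_epochs):
        order = state.rng.permutation(n)
        epoch_sum = 0.0
        z_epoch = np.empty((config.mc_samples, n, config.latent_dim))
        for start in range(0, n, config.minibatch_size):
            idx = order[start : start + config.minibatch_size]
            mb = dataset.subset(idx)
            try:
                value, z_data = gradient_step(mb, state)
            except FloatingPointError:
                logger.error(
                    "divergence at epoch %d; restoring last good state", epoch
                )
                state.restore(last_good)
                return state
            epoch_sum += value
            z_epoch[:, idx, :] = z_data
        epoch_mean = epoch_sum / n
        if not np.isfinite(epoch_mean):
            logger.error("divergence at epoch %d; restoring last good state", epoch)
            state.restore(last_good)
            return state
        state.elbo_trace.append(epoch_mean)
        state.epoch = epoch + 1
        last_good = state.snapshot()

        if c > 1:
            if not state.gmm_seeded and epoch + 1 >= config.warmup_epochs:
                mu_full = encode(state, dataset).mu_z
                km = KMeans(
                    n_clusters=c,
                    n_init=10,
                    random_state=int(config.seed % (2**31)),
                ).fit(mu_full)
                counts = np.bincount(km.labels_, minlength=c).astype(np.float64)
                pi = np.maximum(counts, 1.0)
                state.gmm = GMMPrior(pi / pi.sum(), km.cluster_centers_)
                state.gmm_seeded = True
                state.em_events.append({"epoch": epoch + 1, "event": "kmeans_seed"})
            elif state.gmm_seeded:
                state.gmm = em_update(z_epoch, state.gmm)

        # convergence: relative change of the epoch-mean estimator
        w = config.convergence_window
        trace = state.elbo_trace
        if len(trace) > w and (c == 1 or state.gmm_seeded):
            prev, cur = trace[-1 - w], trace[-1]
            if abs(cur - prev) / (abs(prev) + 1e-12) < config.convergence_tol:
                logger.info("converged at epoch %d", epoch + 1)
                break
        if (epoch + 1) % 25 == 0:
            ent = float(-(state.gmm.pi * np.log(state.gmm.pi)).sum())
            logger.info(
                "epoch %d  bound/cell %.3f  pi-entropy %.3f", epoch + 1, epoch_mean, ent
            )
    return state
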