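"""Probabilistic building blocks of the generative model.

The observation model for a count ``x_ng`` is zero-inflated negative
binomial (ZINB): with probability ``alpha`` the entry is a technical zero
(dropout), otherwise it is a Gamma-Poisson (negative binomial) draw with
mean ``mu = t_n * rho_ng`` and gene-wise inverse dispersion ``theta_g``.
The latent cell state ``z`` carries a Gaussian-mixture prior with identity
component covariances, ``p(z) = sum_c pi_c N(z; mu_c, I)``; the
log-scaling-factor ``log t`` carries a per-batch Gaussian prior whose
moments are the empirical mean/variance of the log library size.

Everything here is deterministic numpy/scipy; the differentiable training
path mirrors these formulas on the autodiff tape (see ``inference``) and is
tested for agreement with them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import special as sp

from .data import CountDataset

logger = logging.getLogger(__name__)

LOG_2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GMMPrior:
    """Mixture weights ``pi`` (C,) and means ``mu`` (C, d); identity covariances."""

    pi: np.ndarray
    mu: np.ndarray

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=np.float64)
        self.mu = np.atleast_2d(np.asarray(self.mu, dtype=np.float64))
        if self.pi.ndim != 1 or len(self.pi) != self.mu.shape[0]:
            raise ValueError("pi and mu must agree on the number of components")
        if np.any(self.pi <= 0):
            raise ValueError("all mixture weights must be strictly positive")
        if abs(self.pi.sum() - 1.0) > 1e-8:
            raise ValueError(f"mixture weights sum to {self.pi.sum()}, not 1")

    @property
    def n_components(self) -> int:
        return len(self.pi)

    @property
    def dim(self) -> int:
        return self.mu.shape[1]


@dataclass
class LibraryPrior:
    """Per-batch Gaussian prior on the log scaling factor."""

    mu_bar: np.ndarray
    sigma_bar_sq: np.ndarray
    batch_categories: np.ndarray

    def __post_init__(self):
        self.mu_bar = np.asarray(self.mu_bar, dtype=np.float64)
        self.sigma_bar_sq = np.asarray(self.sigma_bar_sq, dtype=np.float64)
        if np.any(self.sigma_bar_sq <= 0):
            raise ValueError("sigma_bar_sq must be strictly positive")

    def index_of(self, batch_label) -> int:
        idx = np.where(self.batch_categories == batch_label)[0]
        if len(idx) == 0:
            raise KeyError(f"unknown batch label {batch_label!r}")
        return int(idx[0])


@dataclass
class VariationalPosterior:
    """Mean-field Gaussian posteriors: z per-dimension, log t scalar."""

    mu_z: np.ndarray  # (N, d)
    sigma_z: np.ndarray  # (N, d), > 0
    mu_t: np.ndarray  # (N,)
    sigma_t: np.ndarray  # (N,), > 0

    def __post_init__(self):
        if np.any(self.sigma_z <= 0) or np.any(self.sigma_t <= 0):
            raise ValueError("posterior scales must be strictly positive")

    def slice(self, idx) -> "VariationalPosterior":
        return VariationalPosterior(
            self.mu_z[idx], self.sigma_z[idx], self.mu_t[idx], self.sigma_t[idx]
        )


@dataclass
class DecoderOutput:
    """Per-cell-per-gene ZINB parameters.

    ``rho`` rows are mean expression fractions (sum to 1), ``alpha`` dropout
    probabilities in (0, 1), ``theta`` gene-wise inverse dispersions.
    """

    rho: np.ndarray  # (N, G)
    alpha: np.ndarray  # (N, G)
    theta: np.ndarray  # (G,)

    def __post_init__(self):
        if np.any(np.abs(self.rho.sum(axis=-1) - 1.0) > 1e-6):
            raise ValueError("each rho row must sum to 1")
        if np.any(self.alpha <= 0) or np.any(self.alpha >= 1):
            raise ValueError("alpha must lie strictly in (0, 1)")
        if np.any(self.theta <= 0):
            raise ValueError("theta must be strictly positive")


@dataclass
class Responsibilities:
    """Posterior component memberships q(c|z); rows on the simplex."""

    q_c_z: np.ndarray

    def __post_init__(self):
        q = np.atleast_2d(np.asarray(self.q_c_z, dtype=np.float64))
        if np.any(q < -1e-12) or np.any(q > 1 + 1e-12):
            raise ValueError("responsibilities must lie in [0, 1]")
        if np.any(np.abs(q.sum(axis=-1) - 1.0) > 1e-8):
            raise ValueError("responsibility rows must sum to 1")
        self.q_c_z = q

    def hard_labels(self) -> np.ndarray:
        # argmax breaks ties toward the lowest component index
        return np.argmax(self.q_c_z, axis=-1)


@dataclass
class LatentSamples:
    """Reparameterized draws: z (L, N, d), t (L, N) strictly positive."""

    z_draws: np.ndarray
    t_draws: np.ndarray

    def __post_init__(self):
        if np.any(self.t_draws <= 0):
            raise ValueError("scaling-factor draws must be strictly positive")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def compute_library_prior(
    dataset: CountDataset, var_floor: float = 1e-4
) -> LibraryPrior:
    """Empirical per-batch mean and population variance of log library size.

    Raises if any cell has zero total count (its log library size is
    undefined).  Degenerate batches (single cell, or identical totals) get
    their variance floored at ``var_floor``.
    """
    totals = dataset.library_sizes()
    if np.any(totals <= 0):
        bad = np.where(totals <= 0)[0][0]
        raise ValueError(
            f"cell {dataset.cell_names[bad]!r} (index {bad}) has zero total count"
        )
    log_lib = np.log(totals.astype(np.float64))
    n_b = dataset.n_batches
    mu_bar = np.zeros(n_b)
    var_bar = np.zeros(n_b)
    for b in range(n_b):
        vals = log_lib[dataset.batch_codes == b]
        mu_bar[b] = vals.mean()
        var_bar[b] = max(vals.var(), var_floor)  # population (1/N) variance
    return LibraryPrior(mu_bar, var_bar, dataset.batch_categories)


def nb_log_pmf(x, mu, theta):
    """Negative binomial log-pmf, mean/inverse-dispersion parameterization.

    ``NB(x; mu, theta)`` is the Gamma-Poisson mixture: rate drawn from
    Gamma(shape=theta, mean=mu), then Poisson.  Success probability
    ``theta/(theta+mu)``.
    """
    x = np.asarray(x, dtype=np.float64)
    mu = np.asarray(mu, dtype=np.float64)
    theta = np.asarray(theta, dtype=np.float64)
    log_theta_mu = np.log(theta + mu)
    return (
        sp.gammaln(x + theta)
        - sp.gammaln(theta)
        - sp.gammaln(x + 1.0)
        + theta * (np.log(theta) - log_theta_mu)
        + x * (np.log(mu) - log_theta_mu) * (x > 0)
    )


def zinb_log_pmf(x, mu, theta, alpha):
    """Zero-inflated negative binomial log-pmf.

    ``log[alpha * 1{x=0} + (1 - alpha) * NB(x; mu, theta)]``, stable at
    ``x = 0`` and for large ``theta``.  ``alpha = 1`` with ``x > 0`` yields
    ``-inf`` (the event has probability zero), not an exception.
    """
    x = np.asarray(x, dtype=np.float64)
    if np.any(x < 0) or not np.allclose(x, np.round(x)):
        raise ValueError("x must contain non-negative integers")
    mu = np.asarray(mu, dtype=np.float64)
    theta = np.asarray(theta, dtype=np.float64)
    alpha = np.asarray(alpha, dtype=np.float64)
    if np.any(mu <= 0) or np.any(theta <= 0):
        raise ValueError("mu and theta must be strictly positive")
    if np.any(alpha < 0) or np.any(alpha > 1):
        raise ValueError("alpha must lie in [0, 1]")

    nb = nb_log_pmf(x, mu, theta)
    with np.errstate(divide="ignore"):
        log_alpha = np.log(alpha)
        log_1m_alpha = np.log1p(-alpha)
    # x > 0: only the NB branch survives
    out = log_1m_alpha + nb
    # x = 0: logaddexp of the point mass and the NB zero mass
    zero_case = np.logaddexp(log_alpha, log_1m_alpha + nb)
    out = np.where(x == 0, zero_case, out)
    return out


def gmm_log_density(z, prior: GMMPrior):
    """``log p(z) = logsumexp_c [log pi_c + log N(z; mu_c, I)]``."""
    z = np.atleast_2d(np.asarray(z, dtype=np.float64))
    if z.shape[-1] != prior.dim:
        raise ValueError(
            f"z has dimension {z.shape[-1]}, prior has dimension {prior.dim}"
        )
    sq = ((z[:, None, :] - prior.mu[None, :, :]) ** 2).sum(axis=-1)  # (N, C)
    log_norm = np.log(prior.pi)[None, :] - 0.5 * prior.dim * LOG_2PI - 0.5 * sq
    out = sp.logsumexp(log_norm, axis=-1)
    return out if out.shape != (1,) else float(out[0])


def responsibilities(z, prior: GMMPrior) -> Responsibilities:
    """Posterior memberships ``q(c|z)`` under the identity-covariance mixture.

    Computed as a log-space softmax of ``log pi_c - ||z - mu_c||^2 / 2``
    (the Gaussian normalizing constant is shared and cancels).
    """
    z = np.atleast_2d(np.asarray(z, dtype=np.float64))
    if z.shape[-1] != prior.dim:
        raise ValueError(
            f"z has dimension {z.shape[-1]}, prior has dimension {prior.dim}"
        )
    sq = ((z[:, None, :] - prior.mu[None, :, :]) ** 2).sum(axis=-1)
    logits = np.log(prior.pi)[None, :] - 0.5 * sq
    logits -= logits.max(axis=-1, keepdims=True)
    q = np.exp(logits)
    q /= q.sum(axis=-1, keepdims=True)
    return Responsibilities(q)


def kl_library(mu_t, sigma_t, prior: LibraryPrior, batch) -> float:
    """KL between the cell's Gaussian log-t posterior and its batch prior.

    Closed form for univariate Gaussians:
    ``log(s_bar/s) + (s^2 + (m - m_bar)^2) / (2 s_bar^2) - 1/2``.
    """
    if np.any(np.asarray(sigma_t) <= 0):
        raise ValueError("sigma_t must be strictly positive")
    b = prior.index_of(batch)
    m_bar = prior.mu_bar[b]
    v_bar = prior.sigma_bar_sq[b]
    sigma_t = np.asarray(sigma_t, dtype=np.float64)
    mu_t = np.asarray(mu_t, dtype=np.float64)
    out = (
        0.5 * np.log(v_bar)
        - np.log(sigma_t)
        + (sigma_t**2 + (mu_t - m_bar) ** 2) / (2.0 * v_bar)
        - 0.5
    )
    return float(out) if out.ndim == 0 else out


def kl_categorical(q, pi) -> float:
    """``sum_c q_c log(q_c / pi_c)`` with the ``0 log 0 = 0`` convention.

    Returns ``+inf`` (and logs a warning) if q places mass where pi has none.
    """
    q = np.asarray(q, dtype=np.float64)
    pi = np.asarray(pi, dtype=np.float64)
    if abs(q.sum() - 1.0) > 1e-8 or abs(pi.sum() - 1.0) > 1e-8:
        raise ValueError("q and pi must lie on the probability simplex")
    support = q > 0
    if np.any(support & (pi == 0)):
        logger.warning("q places mass outside the support of pi; KL is +inf")
        return float("inf")
    return float(np.sum(q[support] * (np.log(q[support]) - np.log(pi[support]))))


def log_gaussian_identity_cov(z, mu):
    """``log N(z; mu, I)`` for each z row against each mu row -> (N, C)."""
    z = np.atleast_2d(z)
    mu = np.atleast_2d(mu)
    d = z.shape[-1]
    sq = ((z[:, None, :] - mu[None, :, :]) ** 2).sum(axis=-1)
    return -0.5 * d * LOG_2PI - 0.5 * sq


def elbo_lprime(
    minibatch: CountDataset,
    posterior: VariationalPosterior,
    decoder_out: DecoderOutput,
    prior: GMMPrior,
    lib_prior: LibraryPrior,
    samples: LatentSamples,
) -> float:
    """Monte-Carlo estimator of the mixture-aware variational lower bound.

    Per cell: ``-KL(q(t)||p(t))`` plus the average over the L draws of
    ``[ZINB log-lik - log q(z|x) - KL(q(c|z)||p(c)) + sum_c q(c|z) log p(z|c)]``.
    Returns the sum over the minibatch.  Raises on non-finite terms, naming
    the offending cell.  ``decoder_out`` may be a single DecoderOutput
    (shared across draws) or one per Monte-Carlo draw.
    """
    x = minibatch.counts
    n, g = x.shape
    l_draws = samples.z_draws.shape[0]
    if isinstance(decoder_out, DecoderOutput):
        decoder_out_per_draw = [decoder_out] * l_draws
    else:
        decoder_out_per_draw = list(decoder_out)
        if len(decoder_out_per_draw) != l_draws:
            raise ValueError("need one DecoderOutput per Monte-Carlo draw")

    kl_t = np.empty(n)
    for i in range(n):
        kl_t[i] = kl_library(
            posterior.mu_t[i], posterior.sigma_t[i], lib_prior, minibatch.batch[i]
        )

    per_cell = -kl_t
    for draw in range(l_draws):
        dec = decoder_out_per_draw[draw]
        z = samples.z_draws[draw]  # (n, d)
        t = samples.t_draws[draw]  # (n,)
        mu = t[:, None] * dec.rho
        ll = zinb_log_pmf(x, mu, dec.theta[None, :], dec.alpha).sum(axis=1)
        log_q_z = (
            -0.5 * LOG_2PI
            - np.log(posterior.sigma_z)
            - 0.5 * ((z - posterior.mu_z) / posterior.sigma_z) ** 2
        ).sum(axis=1)
        resp = responsibilities(z, prior).q_c_z  # (n, C)
        log_pz_c = log_gaussian_identity_cov(z, prior.mu)  # (n, C)
        kl_c = np.array([kl_categorical(resp[i], prior.pi) for i in range(n)])
        cross = (resp * log_pz_c).sum(axis=1)
        per_cell = per_cell + (ll - log_q_z - kl_c + cross) / l_draws

    if not np.all(np.isfinite(per_cell)):
        bad = int(np.where(~np.isfinite(per_cell))[0][0])
        raise FloatingPointError(
            f"non-finite bound contribution for cell index {bad}"
        )
    return float(per_cell.sum())
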