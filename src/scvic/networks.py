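"""The four multilayer perceptrons of the model.

Two probabilistic encoders map a cell's (normalized log1p) expression plus
its one-hot batch label to Gaussian posterior parameters for the latent
state ``z`` and the log scaling factor ``log t``.  Two decoders map a
latent draw plus the batch label back to ZINB parameters: ``rho`` (softmax
head, rows sum to 1) and the dropout logit for ``alpha`` (sigmoid link).

Batch one-hots are concatenated to the input of every layer, so the
conditional structure survives depth.  Scale heads use a softplus link with
a small floor to keep posterior scales strictly positive.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Parameter, Tensor, concat


class BatchNorm:
    """Batch normalization with learnable scale/shift.

    Training mode normalizes by minibatch statistics (differentiable
    through mean and variance); evaluation mode uses exponential running
    averages so encodings are deterministic and independent of minibatch
    composition.
    """

    def __init__(self, n_features: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(n_features))
        self.beta = Parameter(np.zeros(n_features))
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.momentum = momentum
        self.eps = eps
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=0, keepdims=True)
            xc = x - mu
            var = xc.square().mean(axis=0, keepdims=True)
            y = xc * ((var + self.eps) ** -0.5)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mu.data[0]
            self.running_var = m * self.running_var + (1 - m) * var.data[0]
        else:
            y = (x - self.running_mean) * (
                1.0 / np.sqrt(self.running_var + self.eps)
            )
        return y * self.gamma + self.beta

    @property
    def params(self):
        return [self.gamma, self.beta]


class Dense:
    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int, scale=None):
        if scale is None:
            scale = np.sqrt(2.0 / n_in)  # He init for relu trunks
        self.W = Parameter(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    @property
    def params(self):
        return [self.W, self.b]


class CovariateMLP:
    """Relu trunk + linear heads; covariates re-injected at every layer."""

    def __init__(
        self,
        rng: np.random.Generator,
        n_in: int,
        n_cov: int,
        hidden: tuple[int, ...],
        head_sizes: tuple[int, ...],
    ):
        self.trunk: list[Dense] = []
        self.norms: list[BatchNorm] = []
        cur = n_in
        for h in hidden:
            self.trunk.append(Dense(rng, cur + n_cov, h))
            self.norms.append(BatchNorm(h))
            cur = h
        head_scale = 1.0 / np.sqrt(cur + n_cov)
        self.heads = [
            Dense(rng, cur + n_cov, h_out, scale=head_scale) for h_out in head_sizes
        ]

    def __call__(self, x: Tensor, cov: Tensor) -> list[Tensor]:
        h = x
        for layer, norm in zip(self.trunk, self.norms):
            h = norm(layer(concat([h, cov], axis=-1))).relu()
        return [head(concat([h, cov], axis=-1)) for head in self.heads]

    def set_training(self, training: bool) -> None:
        for norm in self.norms:
            norm.training = training

    def zero_covariate_weights(self, n_cov: int) -> None:
        """Start covariate-blind: zero the trailing covariate rows of every
        weight matrix so one-hot labels induce no offsets at initialization
        (they are re-learned only if the objective rewards them)."""
        if n_cov == 0:
            return
        for layer in self.trunk + self.heads:
            layer.W.data[-n_cov:, :] = 0.0

    @property
    def params(self):
        out = []
        for layer, norm in zip(self.trunk, self.norms):
            out.extend(layer.params)
            out.extend(norm.params)
        for head in self.heads:
            out.extend(head.params)
        return out


def positive_scale(raw: Tensor, floor: float) -> Tensor:
    """Softplus link with an additive floor; output strictly positive."""
    return raw.softplus() + floor
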