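"""Training hyper-parameters.

Defaults follow the scVI-style convention set: 10-dimensional latent space,
one Monte-Carlo sample per cell, minibatches of 128, up to 400 epochs with
Adam at learning rate 1e-3.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass
class TrainingConfig:
    n_components: int = 1
    latent_dim: int = 10
    mc_samples: int = 1
    minibatch_size: int = 128
    max_epochs: int = 400
    learning_rate: float = 1e-3
    seed: int = 0
    convergence_tol: float = 1e-4
    convergence_window: int = 10
    hidden_sizes: tuple[int, ...] = (128,)
    warmup_epochs: int = 10
    decoder_warmup_epochs: int = 10
    sigma_floor: float = 1e-4
    lib_var_floor: float = 1e-4

    def __post_init__(self):
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.mc_samples < 1:
            raise ValueError("mc_samples must be >= 1")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hidden_sizes"] = list(self.hidden_sizes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainingConfig":
        d = dict(d)
        if "hidden_sizes" in d:
            d["hidden_sizes"] = tuple(d["hidden_sizes"])
        return cls(**d)
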