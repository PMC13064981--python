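"""Shared training configuration."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

from .exceptions import ConfigurationError

__all__ = ["TrainConfig", "DROPOUT_GRID"]

DROPOUT_GRID = (0.0, 0.1, 0.2)


@dataclass
class TrainConfig:
    """Hyperparameters of the search and retraining phases.

    Defaults follow the reference setting: a two-layer backbone with
    256-dimensional hidden representations, Adam at learning rate 1e-4,
    mini-batches of 128, and 20 epochs each for architecture search and
    retraining. The architecture parameters get their own Adam step size
    (1e-3); the Gumbel–Softmax temperature ``tau`` is fixed at 1.0.
    """

    hidden_dim: int = 256
    n_layers: int = 2
    learning_rate: float = 1e-4
    arch_learning_rate: float = 1e-3
    batch_size: int = 128
    train_epochs: int = 20
    search_epochs: int = 20
    tau: float = 1.0
    dropout: float = 0.0
    message_direction: str = "symmetric"
    message_edges: str = "all"
    standardize: bool = True
    device: str = "cpu"
    seed: int = 0
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if min(self.hidden_dim, self.n_layers, self.batch_size) <= 0:
            raise ConfigurationError("hidden_dim, n_layers, batch_size must be positive")
        if min(self.train_epochs, self.search_epochs) <= 0:
            raise ConfigurationError("epoch counts must be positive")
        if self.learning_rate <= 0 or self.arch_learning_rate <= 0:
            raise ConfigurationError("learning rates must be positive")
        if self.tau <= 0:
            raise ConfigurationError("tau must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigurationError("dropout must be in [0, 1)")
        if self.message_edges not in ("train", "all"):
            raise ConfigurationError("message_edges must be 'train' or 'all'")
        if self.device != "cpu":
            raise ConfigurationError("only CPU execution is supported")

    def to_dict(self) -> dict:
        return asdict(self)
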