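"""Scikit-learn style estimators for TF→target link prediction.

`MessagePassingLinkPredictor` trains a fixed-architecture message-passing
network; `AutoGRNLinkPredictor` first searches the architecture with the
stochastic differentiable scheme and then retrains the derived architecture
from scratch. Both follow the sklearn contract: hyperparameters in
``__init__``, data in ``fit(X, y, ...)`` where ``X`` is an ``(m, 2)`` array
of (TF index, gene index) pairs into the prior graph passed as a fit
keyword, fitted attributes with a trailing underscore, and
``predict_proba``/``predict`` for scoring.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .config import TrainConfig
from .exceptions import ConfigurationError
from .graph_data import PriorGraph
from .model import ArchitectureChoice, SearchSpace, arrays_from_graph, model_forward
from .search import derive_architecture, run_search, run_training

__all__ = ["MessagePassingLinkPredictor", "AutoGRNLinkPredictor"]


def _check_pairs(X) -> np.ndarray:
    X = np.asarray(X, dtype=int)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ConfigurationError("X must be an (m, 2) array of node-index pairs")
    return X


class _LinkPredictorBase(BaseEstimator, ClassifierMixin):
    def _config(self, seed_offset: int = 0) -> TrainConfig:
        return TrainConfig(
            hidden_dim=self.hidden_dim,
            n_layers=self.n_layers,
            learning_rate=self.learning_rate,
            arch_learning_rate=getattr(self, "arch_learning_rate", 1e-3),
            batch_size=self.batch_size,
            train_epochs=getattr(self, "train_epochs", 20),
            search_epochs=getattr(self, "search_epochs", 20),
            tau=getattr(self, "tau", 1.0),
            dropout=self.dropout,
            message_direction=self.message_direction,
            message_edges=self.message_edges,
            standardize=self.standardize,
            seed=self.random_state + seed_offset,
        )

    def _arrays(self, graph: PriorGraph, X: np.ndarray, y: np.ndarray) -> dict:
        if graph is None:
            raise ConfigurationError("fit requires the prior graph (graph=...)")
        message = X[np.asarray(y) == 1] if self.message_edges == "train" else None
        return arrays_from_graph(
            graph,
            message_edges=message,
            direction=self.message_direction,
            standardize=self.standardize,
        )

    def predict_proba(self, X) -> np.ndarray:
        p = self.decision_scores(X)
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.decision_scores(X) >= 0.5).astype(int)


class MessagePassingLinkPredictor(_LinkPredictorBase):
    """Fixed-architecture message-passing link classifier.

    Parameters mirror the reference training setup (hidden width 256, two
    layers, Adam at 1e-4, mini-batches of 128, 20 epochs). The
    message-passing adjacency is built from the positive pairs seen in
    ``fit`` (``message_edges="train"``) or from every prior edge
    (``"all"``); expression profiles are z-scored per gene by default.
    """

    def __init__(
        self,
        architecture: ArchitectureChoice | None = None,
        hidden_dim: int = 256,
        n_layers: int = 2,
        learning_rate: float = 1e-4,
        batch_size: int = 128,
        train_epochs: int = 20,
        dropout: float = 0.0,
        message_direction: str = "symmetric",
        message_edges: str = "all",
        standardize: bool = True,
        random_state: int = 0,
    ):
        self.architecture = architecture
        self.hidden_dim = hidden_dim
        self.n_layers = n_layers
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.train_epochs = train_epochs
        self.dropout = dropout
        self.message_direction = message_direction
        self.message_edges = message_edges
        self.standardize = standardize
        self.random_state = random_state

    def fit(self, X, y, graph: PriorGraph = None, X_val=None, y_val=None):
        X = _check_pairs(X)
        y = np.asarray(y, dtype=int)
        choice = self.architecture or ArchitectureChoice(
            agg=("sum",) * self.n_layers,
            combine=("sum",) * self.n_layers,
            activation=("relu",) * self.n_layers,
            connect=("stack",) * self.n_layers,
            layer_agg="skip",
            pool="concat",
        )
        self.arrays_ = self._arrays(graph, X, y)
        X_val = _check_pairs(X_val) if X_val is not None else np.zeros((0, 2), dtype=int)
        y_val = np.asarray(y_val, dtype=int) if y_val is not None else np.zeros(0, dtype=int)
        cfg = self._config()
        self.params_, self.history_, self.best_epoch_ = run_training(
            self.arrays_, X, y, X_val, y_val, choice, cfg
        )
        self.architecture_ = choice
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = 2
        return self

    def decision_scores(self, X) -> np.ndarray:
        X = _check_pairs(X)
        return np.asarray(
            model_forward(self.params_, self.arrays_, X, self.architecture_)
        )


class AutoGRNLinkPredictor(_LinkPredictorBase):
    """Architecture-searched message-passing link classifier.

    ``fit`` runs the stochastic differentiable architecture search on the
    training/validation pairs (weights against training loss, architecture
    logits against validation loss, straight-through Gumbel–Softmax draws),
    derives the argmax architecture, then retrains it from scratch and keeps
    the best-validation-AUROC checkpoint.

    ``no_inter=True`` freezes the inter-layer slots (stack connections,
    last-layer aggregation), leaving only the intra-layer search space;
    ``fixed_pool`` freezes the endpoint readout to one operator.
    """

    def __init__(
        self,
        search_space: SearchSpace | None = None,
        hidden_dim: int = 256,
        n_layers: int = 2,
        learning_rate: float = 1e-4,
        arch_learning_rate: float = 1e-3,
        batch_size: int = 128,
        train_epochs: int = 20,
        search_epochs: int = 20,
        tau: float = 1.0,
        dropout: float = 0.0,
        message_direction: str = "symmetric",
        message_edges: str = "all",
        standardize: bool = True,
        no_inter: bool = False,
        fixed_pool: str | None = None,
        reinit_after_search: bool = True,
        random_state: int = 0,
    ):
        self.search_space = search_space
        self.hidden_dim = hidden_dim
        self.n_layers = n_layers
        self.learning_rate = learning_rate
        self.arch_learning_rate = arch_learning_rate
        self.batch_size = batch_size
        self.train_epochs = train_epochs
        self.search_epochs = search_epochs
        self.tau = tau
        self.dropout = dropout
        self.message_direction = message_direction
        self.message_edges = message_edges
        self.standardize = standardize
        self.no_inter = no_inter
        self.fixed_pool = fixed_pool
        self.reinit_after_search = reinit_after_search
        self.random_state = random_state

    def _effective_space(self) -> SearchSpace:
        space = self.search_space or SearchSpace()
        if self.no_inter:
            space = space.collapse(layer_connect="stack", layer_agg="skip")
        if self.fixed_pool is not None:
            space = space.collapse(pool=self.fixed_pool)
        return space

    def fit(self, X, y, graph: PriorGraph = None, X_val=None, y_val=None):
        X = _check_pairs(X)
        y = np.asarray(y, dtype=int)
        if X_val is None or y_val is None:
            raise ConfigurationError(
                "architecture search needs a validation set (X_val, y_val)"
            )
        X_val = _check_pairs(X_val)
        y_val = np.asarray(y_val, dtype=int)
        space = self._effective_space()
        self.arrays_ = self._arrays(graph, X, y)
        cfg = self._config()

        self.arch_params_, self.search_history_, supernet_weights = run_search(
            self.arrays_, X, y, X_val, y_val, space, cfg
        )
        self.architecture_ = derive_architecture(self.arch_params_, space, self.n_layers)
        self.architecture_report_ = self.architecture_.to_report()

        retrain_cfg = self._config(seed_offset=1)
        warm = None if self.reinit_after_search else supernet_weights
        self.params_, self.train_history_, self.best_epoch_ = run_training(
            self.arrays_, X, y, X_val, y_val, self.architecture_, retrain_cfg,
            warm_start=warm,
        )
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = 2
        return self

    def decision_scores(self, X) -> np.ndarray:
        X = _check_pairs(X)
        return np.asarray(
            model_forward(self.params_, self.arrays_, X, self.architecture_)
        )
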