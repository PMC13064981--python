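"""Stochastic differentiable architecture search.

Every architectural slot (per-layer aggregation, combination, activation and
inter-layer connection; global cross-layer aggregation and pooling) carries a
categorical distribution parameterised by free logits ``log beta``. Each
forward pass draws an approximately one-hot sample per slot via the
Gumbel–Softmax reparameterisation at temperature ``tau`` and runs in discrete
mode: the hard argmax candidate is the one that is numerically active, while
gradients flow through the soft relaxation (straight-through estimator).

The search phase alternates, per epoch, (a) Adam steps on the model weights
against the training cross-entropy with a fresh draw per slot per mini-batch
and (b) Adam steps on the architecture logits against the validation
cross-entropy (bilevel split). The final architecture is the per-slot argmax
of beta; the retraining phase then re-initialises all weights and trains the
fixed architecture, checkpointing the epoch with the best validation AUROC.
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import autograd.numpy as anp
import numpy as np
import pandas as pd
from autograd import value_and_grad
from autograd.misc import flatten
from autograd.tracer import getval

from .config import TrainConfig
from .exceptions import ConfigurationError, NumericError
from .metrics import PROB_EPS, auroc
from .model import (
    ArchitectureChoice,
    SearchSpace,
    _activate,
    _aggregate,
    arrays_from_graph,
    init_model_params,
    init_node_features,
    inter_layer_connect,
    layer_aggregate,
    model_forward,
    scorer_input_width,
    score_link,
)

__all__ = [
    "ArchParams",
    "GumbelDraw",
    "gumbel_softmax_sample",
    "mixed_operation",
    "search_phase",
    "derive_architecture",
    "retrain_phase",
    "run_search",
    "run_training",
    "write_trajectory",
    "save_model",
    "load_model",
]


@dataclass
class ArchParams:
    """Per-slot categorical architecture parameters.

    ``logits[slot]`` are free reals; ``beta = exp(logits)`` so positivity
    holds without constraints. Slots collapsed to a single candidate carry
    no logits and are never updated.
    """

    logits: dict[str, np.ndarray]
    tau: float = 1.0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ConfigurationError("tau must be positive")
        self.logits = {k: np.asarray(v, dtype=float) for k, v in self.logits.items()}

    def beta(self) -> dict[str, np.ndarray]:
        return {k: np.exp(v) for k, v in self.logits.items()}


@dataclass
class GumbelDraw:
    """One approximately one-hot sample for a slot."""

    theta: np.ndarray
    hard_index: int

    def __post_init__(self) -> None:
        theta_val = np.asarray(getval(self.theta), dtype=float)
        if abs(theta_val.sum() - 1.0) > 1e-9:
            raise ConfigurationError("theta must sum to 1")
        if int(np.argmax(theta_val)) != self.hard_index:
            raise ConfigurationError("hard_index must be argmax(theta)")


def _open_uniform(rng: np.random.Generator, size: int) -> np.ndarray:
    """Uniform(0,1) samples guaranteed strictly inside the open interval."""
    u = rng.uniform(size=size)
    while ((u <= 0.0) | (u >= 1.0)).any():  # pragma: no cover - measure zero
        bad = (u <= 0.0) | (u >= 1.0)
        u[bad] = rng.uniform(size=int(bad.sum()))
    return u


def _theta_from(logits, u, tau):
    """Softmax((log beta + Gumbel noise) / tau); works on traced logits."""
    g = (logits - anp.log(-anp.log(u))) / tau
    g = g - anp.max(getval(g))
    e = anp.exp(g)
    return e / anp.sum(e)


def gumbel_softmax_sample(
    arch: ArchParams, slot: str, rng: np.random.Generator
) -> GumbelDraw:
    """Draw one Gumbel–Softmax sample for a slot.

    The hard argmax follows the Gumbel-max property, so
    ``P(hard_index = o) = beta_o / sum(beta)``; as ``tau → 0`` theta itself
    becomes one-hot.
    """
    logits = arch.logits.get(slot)
    if logits is None or len(logits) == 1:
        return GumbelDraw(theta=np.ones(1), hard_index=0)
    u = _open_uniform(rng, len(logits))
    theta = _theta_from(logits, u, arch.tau)
    return GumbelDraw(theta=theta, hard_index=int(np.argmax(theta)))


def _straight_through(draw: GumbelDraw):
    """Selection weights: hard one-hot forward, soft-theta gradient."""
    theta = draw.theta
    k = len(getval(theta))
    hard = np.zeros(k)
    hard[draw.hard_index] = 1.0
    return hard + (theta - getval(theta))


def mixed_operation(inputs, candidates, draw: GumbelDraw):
    """Discrete-mode mixed operation over candidate operators.

    ``output = sum_o I_o * candidate_o(inputs)`` with ``I`` the one-hot of
    the drawn hard index, so exactly one candidate is numerically active;
    gradients reach the architecture logits through the soft relaxation.
    """
    args = inputs if isinstance(inputs, tuple) else (inputs,)
    st = _straight_through(draw)
    out = None
    for weight, cand in zip(st, candidates):
        try:
            term = weight * cand(*args)
        except Exception as exc:
            raise type(exc)(f"candidate {cand!r} failed in mixed operation: {exc}") from exc
        out = term if out is None else out + term
    return out


# ---------------------------------------------------------------------------
# supernet forward
# ---------------------------------------------------------------------------


def _mix(st, outs):
    out = st[0] * outs[0]
    for w, o in zip(st[1:], outs[1:]):
        out = out + w * o
    return out


def _one_hot_st(k: int, index: int) -> np.ndarray:
    v = np.zeros(k)
    v[index] = 1.0
    return v


def supernet_forward(
    weights: dict,
    st: dict,
    arrays: dict,
    pairs: np.ndarray,
    space: SearchSpace,
    n_layers: int,
    dropout_masks=None,
):
    """Forward pass of the weight-sharing supernet.

    ``st[slot]`` is a straight-through selection vector. Candidates whose
    natural output is wider than ``d`` (concatenations) are projected back
    to ``d`` by dedicated learned matrices so all candidates of a slot share
    one output contract; the scorer input is therefore always ``d``.
    """
    pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
    H = init_node_features(arrays["X"], weights["proj"])
    intermediates = []
    h = H
    for l in range(n_layers):
        lp = weights["layers"][l]
        S = anp.dot(h, lp["W_self"])
        M = anp.dot(h, lp["W_nb"])
        T = _mix(st[f"agg_{l}"], [_aggregate(M, arrays, a) for a in space.intra_agg])
        combined = []
        for c in space.intra_combine:
            if c == "sum":
                combined.append(S + T)
            elif c == "concat":
                combined.append(anp.dot(anp.concatenate([S, T], axis=1), lp["W_comb"]))
            else:
                raise ConfigurationError(f"unknown combine {c!r}")
        C = _mix(st[f"combine_{l}"], combined)
        act = _mix(
            st[f"act_{l}"], [_activate(C, a, lp["prelu"]) for a in space.intra_activation]
        )
        if dropout_masks is not None:
            act = act * dropout_masks[l]
        conn = _mix(
            st[f"connect_{l}"],
            [inter_layer_connect(h, act, m, lp["W_cnt"]) for m in space.layer_connect],
        )
        h = conn
        intermediates.append(h)

    lagg_outs = []
    for m in space.layer_agg:
        if m == "concat":
            lagg_outs.append(
                anp.dot(layer_aggregate(intermediates, "concat"), weights["agg_proj"])
            )
        else:
            lagg_outs.append(layer_aggregate(intermediates, m))
    hL = _mix(st["layer_agg"], lagg_outs)

    if len(pairs) == 0:
        return anp.zeros(0)
    hu, hv = hL[pairs[:, 0]], hL[pairs[:, 1]]
    pool_outs = []
    for m in space.pool:
        if m == "concat":
            pool_outs.append(
                anp.dot(anp.concatenate([hu, hv], axis=-1), weights["pool_proj"])
            )
        elif m == "sum":
            pool_outs.append(hu + hv)
        elif m == "max":
            pool_outs.append(anp.maximum(hu, hv))
        elif m == "zero":
            pool_outs.append(hu * 0.0)
        else:
            raise ConfigurationError(f"unknown pooling {m!r}")
    E = _mix(st["pool"], pool_outs)
    return score_link(E, weights["scorer"])


def _bce(probs, labels):
    p = anp.clip(probs, PROB_EPS, 1.0 - PROB_EPS)
    y = labels
    return -anp.mean(y * anp.log(p) + (1.0 - y) * anp.log(1.0 - p))


class Adam:
    """Flat-vector Adam."""

    def __init__(self, lr: float, b1: float = 0.9, b2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.t = 0
        self.m = self.v = None

    def step(self, x: np.ndarray, g: np.ndarray) -> np.ndarray:
        if self.m is None:
            self.m = np.zeros_like(x)
            self.v = np.zeros_like(x)
        self.t += 1
        self.m = self.b1 * self.m + (1 - self.b1) * g
        self.v = self.b2 * self.v + (1 - self.b2) * g**2
        mhat = self.m / (1 - self.b1**self.t)
        vhat = self.v / (1 - self.b2**self.t)
        return x - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def _dropout_masks(rng, n_nodes, d, n_layers, rate):
    if rate <= 0:
        return None
    return [
        (rng.random((n_nodes, d)) >= rate) / (1.0 - rate) for _ in range(n_layers)
    ]


def _fixed_st(space: SearchSpace, choice: ArchitectureChoice, n_layers: int) -> dict:
    st = {}
    for l in range(n_layers):
        st[f"agg_{l}"] = _one_hot_st(len(space.intra_agg), space.intra_agg.index(choice.agg[l]))
        st[f"combine_{l}"] = _one_hot_st(
            len(space.intra_combine), space.intra_combine.index(choice.combine[l])
        )
        st[f"act_{l}"] = _one_hot_st(
            len(space.intra_activation), space.intra_activation.index(choice.activation[l])
        )
        st[f"connect_{l}"] = _one_hot_st(
            len(space.layer_connect), space.layer_connect.index(choice.connect[l])
        )
    st["layer_agg"] = _one_hot_st(len(space.layer_agg), space.layer_agg.index(choice.layer_agg))
    st["pool"] = _one_hot_st(len(space.pool), space.pool.index(choice.pool))
    return st


def derive_architecture(
    arch: ArchParams, space: SearchSpace, n_layers: int = 2
) -> ArchitectureChoice:
    """Per-slot argmax of beta; exact ties resolve to the lowest index."""
    slots = space.slots(n_layers)

    def pick(name: str, candidates: tuple[str, ...]) -> str:
        logits = arch.logits.get(name)
        if logits is None or len(candidates) == 1:
            return candidates[0]
        best = float(np.max(logits))
        if int((logits == best).sum()) > 1:
            warnings.warn(f"exact tie in slot {name}; taking the lowest index")
        return candidates[int(np.argmax(logits))]

    return ArchitectureChoice(
        agg=tuple(pick(f"agg_{l}", slots[f"agg_{l}"]) for l in range(n_layers)),
        combine=tuple(pick(f"combine_{l}", slots[f"combine_{l}"]) for l in range(n_layers)),
        activation=tuple(pick(f"act_{l}", slots[f"act_{l}"]) for l in range(n_layers)),
        connect=tuple(pick(f"connect_{l}", slots[f"connect_{l}"]) for l in range(n_layers)),
        layer_agg=pick("layer_agg", slots["layer_agg"]),
        pool=pick("pool", slots["pool"]),
    )


# ---------------------------------------------------------------------------
# search phase
# ---------------------------------------------------------------------------


def run_search(
    arrays: dict,
    train_pairs: np.ndarray,
    train_labels: np.ndarray,
    valid_pairs: np.ndarray,
    valid_labels: np.ndarray,
    space: SearchSpace,
    cfg: TrainConfig,
) -> tuple[ArchParams, list[dict], dict]:
    """Joint weight/architecture optimisation on prebuilt graph tensors.

    Returns the learned :class:`ArchParams`, a per-epoch trajectory
    (train loss, validation AUROC, current argmax architecture) and the
    supernet weights.
    """
    rng = np.random.default_rng(cfg.seed)
    d, L = cfg.hidden_dim, cfg.n_layers
    n_nodes, n_feat = arrays["X"].shape

    slot_candidates = space.slots(L)
    searchable = {k: v for k, v in slot_candidates.items() if len(v) > 1}
    logits = {k: np.zeros(len(v)) for k, v in searchable.items()}

    weights = init_model_params(rng, n_feat, d, L, scorer_in=d)
    flat_w, unflat_w = flatten(weights)
    flat_a, unflat_a = flatten(logits)
    adam_w = Adam(cfg.learning_rate)
    adam_a = Adam(cfg.arch_learning_rate)

    train_labels = np.asarray(train_labels, dtype=float)
    valid_labels = np.asarray(valid_labels, dtype=float)

    def sampled_st(logit_tree, u_by_slot):
        st = {}
        for name, candidates in slot_candidates.items():
            if name in searchable:
                theta = _theta_from(logit_tree[name], u_by_slot[name], cfg.tau)
                hard = int(np.argmax(getval(theta)))
                st[name] = _straight_through(GumbelDraw(theta=theta, hard_index=hard))
            else:
                st[name] = np.ones(1)
        return st

    def draw_noise():
        return {name: _open_uniform(rng, len(c)) for name, c in searchable.items()}

    trajectory: list[dict] = []
    for epoch in range(cfg.search_epochs):
        losses = []
        for idx in _batches(len(train_pairs), cfg.batch_size, rng):
            noise = draw_noise()
            masks = _dropout_masks(rng, n_nodes, d, L, cfg.dropout)

            def loss_w(fw):
                w = unflat_w(fw)
                st = sampled_st(logits, noise)
                probs = supernet_forward(w, st, arrays, train_pairs[idx], space, L, masks)
                return _bce(probs, train_labels[idx])

            val, g = value_and_grad(loss_w)(flat_w)
            if not np.isfinite(val):
                raise NumericError(
                    f"non-finite search loss at epoch {epoch}; "
                    f"|w|_max={np.abs(flat_w).max():.3g}"
                )
            flat_w = adam_w.step(flat_w, g)
            losses.append(float(val))

        if searchable:
            weights_now = unflat_w(flat_w)
            for idx in _batches(len(valid_pairs), cfg.batch_size, rng):
                noise = draw_noise()

                def loss_a(fa):
                    st = sampled_st(unflat_a(fa), noise)
                    probs = supernet_forward(
                        weights_now, st, arrays, valid_pairs[idx], space, L
                    )
                    return _bce(probs, valid_labels[idx])

                val, g = value_and_grad(loss_a)(flat_a)
                if not np.isfinite(val):
                    raise NumericError(f"non-finite architecture loss at epoch {epoch}")
                flat_a = adam_a.step(flat_a, g)
            logits = unflat_a(flat_a)

        arch_now = derive_architecture(ArchParams(logits=logits, tau=cfg.tau), space, L)
        st_eval = _fixed_st(space, arch_now, L)
        v_probs = supernet_forward(
            unflat_w(flat_w), st_eval, arrays, valid_pairs, space, L
        )
        v_auroc = _safe_auroc(v_probs, valid_labels)
        trajectory.append(
            {
                "epoch": epoch,
                "phase": "search",
                "train_loss": float(np.mean(losses)),
                "valid_auroc": v_auroc,
                "architecture": arch_now.to_report(),
            }
        )

    arch_params = ArchParams(logits={k: v.copy() for k, v in logits.items()}, tau=cfg.tau)
    return arch_params, trajectory, unflat_w(flat_w)


def _safe_auroc(probs, labels) -> float | None:
    labels = np.asarray(labels)
    if len(labels) == 0 or len(np.unique(labels)) < 2:
        return None
    return auroc(np.asarray(getval(probs)), labels)


# ---------------------------------------------------------------------------
# retraining phase
# ---------------------------------------------------------------------------


def run_training(
    arrays: dict,
    train_pairs: np.ndarray,
    train_labels: np.ndarray,
    valid_pairs: np.ndarray,
    valid_labels: np.ndarray,
    choice: ArchitectureChoice,
    cfg: TrainConfig,
    warm_start: dict | None = None,
) -> tuple[dict, list[dict], int]:
    """Train a fixed architecture from freshly initialised weights.

    Adam on the mean binary cross-entropy, mini-batches of
    ``cfg.batch_size``, ``cfg.train_epochs`` epochs; the returned parameters
    are the checkpoint of the epoch with the best validation AUROC (the last
    epoch if validation AUROC is undefined). ``warm_start`` (a parameter
    pytree, e.g. supernet weights) seeds the projection and layer matrices
    instead of re-initialising them; the scorer is always re-initialised
    because its input width depends on the chosen architecture.
    """
    rng = np.random.default_rng(cfg.seed)
    d, L = cfg.hidden_dim, choice.n_layers
    n_nodes, n_feat = arrays["X"].shape
    params = init_model_params(rng, n_feat, d, L, scorer_in=scorer_input_width(choice, d))
    if warm_start is not None:
        params["proj"] = copy.deepcopy(warm_start["proj"])
        params["layers"] = copy.deepcopy(warm_start["layers"])
    flat, unflat = flatten(params)
    adam = Adam(cfg.learning_rate)
    train_labels = np.asarray(train_labels, dtype=float)
    valid_labels = np.asarray(valid_labels, dtype=float)

    best_flat, best_auroc, best_epoch = flat.copy(), -np.inf, -1
    trajectory: list[dict] = []
    for epoch in range(cfg.train_epochs):
        losses = []
        for idx in _batches(len(train_pairs), cfg.batch_size, rng):
            masks = _dropout_masks(rng, n_nodes, d, L, cfg.dropout)

            def loss_fn(f):
                probs = model_forward(
                    unflat(f), arrays, train_pairs[idx], choice, dropout_masks=masks
                )
                return _bce(probs, train_labels[idx])

            val, g = value_and_grad(loss_fn)(flat)
            if not np.isfinite(val):
                raise NumericError(
                    f"non-finite training loss at epoch {epoch}; "
                    f"|w|_max={np.abs(flat).max():.3g}"
                )
            flat = adam.step(flat, g)
            losses.append(float(val))

        v_probs = model_forward(unflat(flat), arrays, valid_pairs, choice)
        v_auroc = _safe_auroc(v_probs, valid_labels)
        if v_auroc is not None and v_auroc > best_auroc:
            best_flat, best_auroc, best_epoch = flat.copy(), v_auroc, epoch
        trajectory.append(
            {
                "epoch": epoch,
                "phase": "retrain",
                "train_loss": float(np.mean(losses)),
                "valid_auroc": v_auroc,
                "architecture": choice.to_report(),
            }
        )
    if best_epoch < 0:
        best_flat, best_epoch = flat, cfg.train_epochs - 1
    return unflat(best_flat), trajectory, best_epoch


# ---------------------------------------------------------------------------
# spec-level wrappers over PriorGraph / EdgeSplit
# ---------------------------------------------------------------------------


def _split_arrays(graph, split, cfg: TrainConfig):
    message = split.train.positives if cfg.message_edges == "train" else None
    arrays = arrays_from_graph(
        graph,
        message_edges=message,
        direction=cfg.message_direction,
        standardize=cfg.standardize,
    )
    return arrays


def search_phase(graph, split, space: SearchSpace | None = None, cfg: TrainConfig | None = None):
    """Architecture search on a prior graph and labeled split."""
    space = space or SearchSpace()
    cfg = cfg or TrainConfig()
    arrays = _split_arrays(graph, split, cfg)
    arch, trajectory, _ = run_search(
        arrays,
        split.train.pairs,
        split.train.labels,
        split.valid.pairs,
        split.valid.labels,
        space,
        cfg,
    )
    return arch, trajectory


def retrain_phase(graph, split, choice: ArchitectureChoice, cfg: TrainConfig | None = None):
    """Retrain the derived architecture from scratch; returns (model, trajectory)."""
    cfg = cfg or TrainConfig()
    arrays = _split_arrays(graph, split, cfg)
    params, trajectory, best_epoch = run_training(
        arrays,
        split.train.pairs,
        split.train.labels,
        split.valid.pairs,
        split.valid.labels,
        choice,
        cfg,
    )
    model = {"params": params, "arrays": arrays, "choice": choice, "best_epoch": best_epoch}
    return model, trajectory


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def write_trajectory(trajectory: list[dict], path) -> Path:
    """Write a trajectory log as CSV (epoch, phase, train_loss, valid_auroc,
    architecture_json)."""
    rows = [
        {
            "epoch": r["epoch"],
            "phase": r["phase"],
            "train_loss": r["train_loss"],
            "valid_auroc": r["valid_auroc"],
            "architecture_json": json.dumps(r["architecture"], sort_keys=True),
        }
        for r in trajectory
    ]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def _tree_to_jsonable(tree):
    if isinstance(tree, dict):
        return {k: _tree_to_jsonable(v) for k, v in tree.items()}
    if isinstance(tree, (list, tuple)):
        return [_tree_to_jsonable(v) for v in tree]
    return np.asarray(tree).tolist()


def save_model(path, params: dict, choice: ArchitectureChoice, cfg: TrainConfig) -> Path:
    """JSON model checkpoint: parameters, architecture and configuration."""
    payload = {
        "params": _tree_to_jsonable(params),
        "architecture": {
            "agg": list(choice.agg),
            "combine": list(choice.combine),
            "activation": list(choice.activation),
            "connect": list(choice.connect),
            "layer_agg": choice.layer_agg,
            "pool": choice.pool,
        },
        "config": cfg.to_dict(),
    }
    path = Path(path)
    path.write_text(json.dumps(payload))
    return path


def _tree_to_arrays(tree):
    if isinstance(tree, dict):
        return {k: _tree_to_arrays(v) for k, v in tree.items()}
    if isinstance(tree, list) and tree and isinstance(tree[0], dict):
        return [_tree_to_arrays(v) for v in tree]
    return np.asarray(tree)


def load_model(path) -> tuple[dict, ArchitectureChoice, dict]:
    payload = json.loads(Path(path).read_text())
    arch = payload["architecture"]
    choice = ArchitectureChoice(
        agg=tuple(arch["agg"]),
        combine=tuple(arch["combine"]),
        activation=tuple(arch["activation"]),
        connect=tuple(arch["connect"]),
        layer_agg=arch["layer_agg"],
        pool=arch["pool"],
    )
    return _tree_to_arrays(payload["params"]), choice, payload["config"]
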