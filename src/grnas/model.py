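"""Searchable message-passing network for TF→target link scoring.

The network is a two-layer (by default) message-passing GNN over the prior
regulatory graph. Each node starts from a learned linear projection of its
expression profile. Within a layer, neighbor states are transformed by a
neighbor-specific weight matrix and aggregated (mean/sum/max), combined with
the self-transformed state (sum, or concatenation projected back to width
``d``), and passed through ReLU or PReLU. Across layers, the layer input and
the intra-layer output are connected by stacking, skip-summation or
skip-concatenation (with a learned projection), and the retained per-layer
outputs are aggregated (skip = last layer, concatenation, or elementwise
max) into final node embeddings. A link embedding for an ordered (TF, gene)
pair is read out from the two endpoint embeddings (sum/max/concatenation,
source first, so concatenation is direction-aware) and scored by a two-layer
MLP with a sigmoid output.

Everything here is a pure function of an explicit parameter pytree and is
written with :mod:`autograd.numpy`, so the same code serves evaluation and
gradient-based training.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import product

import autograd.numpy as anp
import numpy as np
from autograd.extend import defvjp, primitive
from autograd.tracer import getval

from .exceptions import ConfigurationError, ContractError, NumericError
from .graph_data import PriorGraph

__all__ = [
    "SearchSpace",
    "ArchitectureChoice",
    "DEFAULT_HIDDEN_DIM",
    "graph_arrays",
    "init_model_params",
    "init_node_features",
    "intra_layer_forward",
    "inter_layer_connect",
    "layer_aggregate",
    "endpoint_pool",
    "score_link",
    "model_forward",
    "arrays_from_graph",
    "scorer_input_width",
]

DEFAULT_HIDDEN_DIM = 256
_NEG_BIG = -1e30


@dataclass(frozen=True)
class SearchSpace:
    """Candidate operator sets, one slot per architectural decision.

    Per-layer slots: neighbor aggregation, combination, activation and
    inter-layer connection; global slots: cross-layer aggregation and the
    endpoint pooling readout. Ablations collapse a slot to a single
    candidate via :meth:`collapse`.
    """

    intra_agg: tuple[str, ...] = ("mean", "sum", "max")
    intra_combine: tuple[str, ...] = ("sum", "concat")
    intra_activation: tuple[str, ...] = ("relu", "prelu")
    layer_connect: tuple[str, ...] = ("stack", "skip_sum", "skip_concat")
    layer_agg: tuple[str, ...] = ("skip", "concat", "max")
    pool: tuple[str, ...] = ("sum", "max", "concat")

    def __post_init__(self) -> None:
        for name in (
            "intra_agg",
            "intra_combine",
            "intra_activation",
            "layer_connect",
            "layer_agg",
            "pool",
        ):
            if not getattr(self, name):
                raise ConfigurationError(f"search-space slot {name} is empty")

    def collapse(self, **kwargs) -> "SearchSpace":
        """Return a copy with the given slots fixed to single candidates."""
        fixed = {k: (v,) if isinstance(v, str) else tuple(v) for k, v in kwargs.items()}
        return replace(self, **fixed)

    def slots(self, n_layers: int) -> dict[str, tuple[str, ...]]:
        """Flatten to named slots: per-layer intra/connect plus global ones."""
        out: dict[str, tuple[str, ...]] = {}
        for l in range(n_layers):
            out[f"agg_{l}"] = self.intra_agg
            out[f"combine_{l}"] = self.intra_combine
            out[f"act_{l}"] = self.intra_activation
            out[f"connect_{l}"] = self.layer_connect
        out["layer_agg"] = self.layer_agg
        out["pool"] = self.pool
        return out

    def architectures(self, n_layers: int):
        """Iterate every architecture with choices shared across layers."""
        for agg, com, act, conn, lagg, pool in product(
            self.intra_agg,
            self.intra_combine,
            self.intra_activation,
            self.layer_connect,
            self.layer_agg,
            self.pool,
        ):
            yield ArchitectureChoice(
                agg=(agg,) * n_layers,
                combine=(com,) * n_layers,
                activation=(act,) * n_layers,
                connect=(conn,) * n_layers,
                layer_agg=lagg,
                pool=pool,
            )


@dataclass(frozen=True)
class ArchitectureChoice:
    """One selected operator per slot (per layer where applicable)."""

    agg: tuple[str, ...] = ("sum", "sum")
    combine: tuple[str, ...] = ("sum", "sum")
    activation: tuple[str, ...] = ("relu", "relu")
    connect: tuple[str, ...] = ("stack", "stack")
    layer_agg: str = "skip"
    pool: str = "concat"

    @property
    def n_layers(self) -> int:
        return len(self.agg)

    def validate(self, space: SearchSpace) -> None:
        for l in range(self.n_layers):
            checks = (
                (self.agg[l], space.intra_agg),
                (self.combine[l], space.intra_combine),
                (self.activation[l], space.intra_activation),
                (self.connect[l], space.layer_connect),
            )
            for value, candidates in checks:
                if value not in candidates:
                    raise ConfigurationError(f"{value!r} not in slot {candidates}")
        if self.layer_agg not in space.layer_agg:
            raise ConfigurationError(f"{self.layer_agg!r} not a layer_agg candidate")
        if self.pool not in space.pool:
            raise ConfigurationError(f"{self.pool!r} not a pool candidate")

    def to_report(self) -> dict:
        """Architecture report with one entry per layer where applicable."""
        cap = lambda s: s.capitalize()  # noqa: E731
        return {
            "Agg": [cap(a) for a in self.agg],
            "Combine": [cap(c) for c in self.combine],
            "Activation": [cap(a) for a in self.activation],
            "LayerConnect": [cap(c) for c in self.connect],
            "LayerAgg": cap(self.layer_agg),
            "Pool": cap(self.pool),
        }


def scorer_input_width(choice: ArchitectureChoice, d: int) -> int:
    width = d * (choice.n_layers if choice.layer_agg == "concat" else 1)
    return 2 * width if choice.pool == "concat" else width


# ---------------------------------------------------------------------------
# graph tensors and parameter initialisation
# ---------------------------------------------------------------------------


def graph_arrays(
    features: np.ndarray,
    edges: np.ndarray,
    n_nodes: int,
    direction: str = "symmetric",
    standardize: bool = True,
) -> dict:
    """Dense tensors for message passing.

    ``A[v, u] = 1`` means node u sends messages to node v. ``direction``
    controls how a directed (tf, target) edge maps onto message flow:
    ``directed`` (tf → target), ``reversed`` (target → tf) or ``symmetric``
    (both; the default — cold-start targets must be reachable from their
    regulators and vice versa). With ``standardize`` each gene's expression
    profile is z-scored across cells, so embedding inner products start out
    proportional to expression correlations.
    """
    edges = np.asarray(edges, dtype=int).reshape(-1, 2)
    A = np.zeros((n_nodes, n_nodes))
    if direction in ("directed", "symmetric"):
        A[edges[:, 1], edges[:, 0]] = 1.0
    if direction in ("reversed", "symmetric"):
        A[edges[:, 0], edges[:, 1]] = 1.0
    if direction not in ("directed", "reversed", "symmetric"):
        raise ConfigurationError(f"unknown message direction {direction!r}")
    np.fill_diagonal(A, 0.0)
    X = np.asarray(features, dtype=float)
    if standardize:
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        X = (X - mu) / np.where(sd > 0, sd, 1.0)
    deg = A.sum(axis=1)
    # edge-segment structure for fast neighbor-max (messages sorted by target)
    tgt_all, src_all = np.nonzero(A)
    if len(src_all):
        ptr = np.flatnonzero(np.r_[True, tgt_all[1:] != tgt_all[:-1]])
        nbmax = {
            "src": src_all,
            "ptr": ptr,
            "tgt_nodes": tgt_all[ptr],
            "tgt_edge": tgt_all,
            "seg_edge": np.searchsorted(ptr, np.arange(len(src_all)), side="right") - 1,
        }
    else:
        nbmax = {
            "src": src_all,
            "ptr": np.zeros(0, dtype=int),
            "tgt_nodes": np.zeros(0, dtype=int),
            "tgt_edge": tgt_all,
            "seg_edge": np.zeros(0, dtype=int),
        }
    return {"A": A, "mask": A > 0, "deg": deg, "X": X, "nbmax": nbmax}


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / (fan_in + fan_out)), size=(fan_in, fan_out))


def init_model_params(
    rng: np.random.Generator,
    n_features: int,
    d: int,
    n_layers: int,
    scorer_in: int,
) -> dict:
    """Initialise the full parameter pytree.

    Every layer carries all operator-specific matrices (combination and
    skip-concatenation projections, PReLU slope) regardless of the chosen
    architecture; unused ones simply receive zero gradient. The scorer's
    output layer starts at zero so initial predictions sit at the base rate
    and early ranking reflects only learned signal.
    """
    if d <= 0:
        raise ConfigurationError("hidden size d must be positive")
    layers = []
    for _ in range(n_layers):
        layers.append(
            {
                "W_self": _glorot(rng, d, d),
                "W_nb": _glorot(rng, d, d),
                "W_comb": _glorot(rng, 2 * d, d),
                "W_cnt": _glorot(rng, 2 * d, d),
                "prelu": np.array(0.25),
            }
        )
    return {
        "proj": {"W": _glorot(rng, n_features, d), "b": np.zeros(d)},
        "layers": layers,
        "agg_proj": _glorot(rng, n_layers * d, d),
        "pool_proj": _glorot(rng, 2 * d, d),
        "scorer": {
            "W1": _glorot(rng, scorer_in, d),
            "b1": np.zeros(d),
            "W2": np.zeros((d, 1)),
            "b2": np.zeros(1),
        },
    }


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------


def init_node_features(features, proj_params):
    """h^0: learned linear projection of each gene's expression profile."""
    return anp.dot(features, proj_params["W"]) + proj_params["b"]


def _neighbor_max(M, mask, deg):
    # materialize the broadcast explicitly; nodes without neighbors get 0
    n = mask.shape[0]
    stacked = M[None, :, :] + anp.zeros((n, 1, 1))
    masked = anp.where(mask[:, :, None], stacked, _NEG_BIG)
    mx = anp.max(masked, axis=1)
    return anp.where((deg > 0)[:, None], mx, 0.0)


@primitive
def _segment_neighbor_max(M, src, ptr, tgt_nodes, tgt_edge, seg_edge, n_nodes):
    """Per-target elementwise max of ``M[src]`` over edge segments.

    Edges are pre-sorted by target; ``ptr`` holds segment starts for
    ``np.maximum.reduceat``. Targets without neighbors stay at 0.
    """
    out = np.zeros((n_nodes, M.shape[1]))
    if len(src):
        out[tgt_nodes] = np.maximum.reduceat(M[src], ptr, axis=0)
    return out


def _segment_neighbor_max_vjp(ans, M, src, ptr, tgt_nodes, tgt_edge, seg_edge, n_nodes):
    def vjp(g):
        dM = np.zeros_like(M)
        if len(src):
            vals = M[src]
            ties = (vals == ans[tgt_edge]).astype(float)
            cnt = np.add.reduceat(ties, ptr, axis=0)
            # split gradient equally among tying neighbors (np.max convention)
            contrib = ties * g[tgt_edge] / cnt[seg_edge]
            np.add.at(dM, src, contrib)
        return dM

    return vjp


defvjp(_segment_neighbor_max, _segment_neighbor_max_vjp)


def _aggregate(M, arrays, mode):
    if mode == "sum":
        return anp.dot(arrays["A"], M)
    if mode == "mean":
        denom = anp.maximum(arrays["deg"], 1.0)[:, None]
        return anp.dot(arrays["A"], M) / denom
    if mode == "max":
        nb = arrays.get("nbmax")
        if nb is not None:
            return _segment_neighbor_max(
                M,
                nb["src"],
                nb["ptr"],
                nb["tgt_nodes"],
                nb["tgt_edge"],
                nb["seg_edge"],
                arrays["A"].shape[0],
            )
        return _neighbor_max(M, arrays["mask"], arrays["deg"])
    if mode == "zero":  # constant-output control operator (search diagnostics)
        return anp.zeros_like(M)
    raise ConfigurationError(f"unknown aggregation {mode!r}")


def _activate(C, mode, prelu_slope):
    if mode == "relu":
        return anp.maximum(C, 0.0)
    if mode == "prelu":
        return anp.maximum(C, 0.0) + prelu_slope * anp.minimum(C, 0.0)
    raise ConfigurationError(f"unknown activation {mode!r}")


def intra_layer_forward(
    H,
    arrays,
    layer_params,
    agg: str,
    combine: str,
    activation: str,
    dropout_mask=None,
    layer_index: int | None = None,
):
    """One round of intra-layer message passing.

    ``T_v = Agg({W_nb h_u : u in N(v)})`` (zero vector for isolated nodes),
    combined with ``W_self h_v`` by summation or concatenation-then-
    projection, then activated. ``dropout_mask`` (already scaled by
    1/(1-rate)) is applied to the output in training mode.
    """
    S = anp.dot(H, layer_params["W_self"])
    M = anp.dot(H, layer_params["W_nb"])
    T = _aggregate(M, arrays, agg)
    if combine == "sum":
        C = S + T
    elif combine == "concat":
        C = anp.dot(anp.concatenate([S, T], axis=1), layer_params["W_comb"])
    else:
        raise ConfigurationError(f"unknown combine {combine!r}")
    out = _activate(C, activation, layer_params["prelu"])
    if dropout_mask is not None:
        out = out * dropout_mask
    if not np.isfinite(getval(out)).all():
        where = f" in layer {layer_index}" if layer_index is not None else ""
        raise NumericError(f"non-finite embedding{where}")
    return out


def inter_layer_connect(h_prev, h_inter, mode: str, w_cnt=None):
    """Connect a layer's input with its intra-layer output."""
    if getval(h_prev).shape[0] != getval(h_inter).shape[0]:
        raise ContractError("h_prev and h_inter node counts differ")
    if mode == "stack":
        return h_inter
    if mode == "skip_sum":
        if getval(h_prev).shape != getval(h_inter).shape:
            raise ContractError("skip_sum needs matching shapes")
        return h_prev + h_inter
    if mode == "skip_concat":
        if w_cnt is None:
            raise ContractError("skip_concat requires the W_cnt projection")
        return anp.dot(anp.concatenate([h_prev, h_inter], axis=1), w_cnt)
    raise ConfigurationError(f"unknown layer connection {mode!r}")


def layer_aggregate(intermediates, mode: str):
    """Aggregate retained per-layer outputs into final node embeddings."""
    if not intermediates:
        raise ContractError("layer_aggregate needs at least one intermediate")
    if mode == "skip":
        return intermediates[-1]
    if mode == "concat":
        return anp.concatenate(list(intermediates), axis=1)
    if mode == "max":
        out = intermediates[0]
        for h in intermediates[1:]:
            out = anp.maximum(out, h)
        return out
    raise ConfigurationError(f"unknown layer aggregation {mode!r}")


def endpoint_pool(h_u, h_v, mode: str):
    """Link embedding from the two endpoint embeddings (source first)."""
    if getval(h_u).shape[-1] != getval(h_v).shape[-1]:
        raise ContractError("endpoint widths differ")
    if mode == "sum":
        return h_u + h_v
    if mode == "max":
        return anp.maximum(h_u, h_v)
    if mode == "concat":
        return anp.concatenate([h_u, h_v], axis=-1)
    if mode == "zero":  # constant-output control operator (search diagnostics)
        return h_u * 0.0
    raise ConfigurationError(f"unknown pooling {mode!r}")


def score_link(embedding, scorer_params):
    """Two-layer MLP (hidden width d, ReLU) -> sigmoid probability."""
    if getval(embedding).shape[-1] != scorer_params["W1"].shape[0]:
        raise ContractError(
            f"link embedding width {getval(embedding).shape[-1]} does not "
            f"match scorer input {scorer_params['W1'].shape[0]}"
        )
    hidden = anp.maximum(
        anp.dot(embedding, scorer_params["W1"]) + scorer_params["b1"], 0.0
    )
    logit = anp.dot(hidden, scorer_params["W2"]) + scorer_params["b2"]
    logit = anp.reshape(logit, (-1,))
    if not np.isfinite(getval(logit)).all():
        raise NumericError("non-finite logit in link scorer")
    return 1.0 / (1.0 + anp.exp(-logit))


def model_forward(
    params: dict,
    arrays: dict,
    pairs: np.ndarray,
    choice: ArchitectureChoice,
    dropout_masks=None,
):
    """Full forward pass: one probability per ordered (TF, gene) pair.

    ``dropout_masks`` (one per layer, pre-scaled) enables training mode;
    omit them for deterministic evaluation.
    """
    pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
    H = init_node_features(arrays["X"], params["proj"])
    intermediates = []
    h = H
    for l in range(choice.n_layers):
        lp = params["layers"][l]
        mask = dropout_masks[l] if dropout_masks is not None else None
        h_inter = intra_layer_forward(
            h,
            arrays,
            lp,
            choice.agg[l],
            choice.combine[l],
            choice.activation[l],
            dropout_mask=mask,
            layer_index=l,
        )
        h = inter_layer_connect(h, h_inter, choice.connect[l], lp["W_cnt"])
        intermediates.append(h)
    hL = layer_aggregate(intermediates, choice.layer_agg)
    if len(pairs) == 0:
        return anp.zeros(0)
    E = endpoint_pool(hL[pairs[:, 0]], hL[pairs[:, 1]], choice.pool)
    return score_link(E, params["scorer"])


def arrays_from_graph(
    graph: PriorGraph,
    message_edges: np.ndarray | None = None,
    direction: str = "symmetric",
    standardize: bool = True,
) -> dict:
    """Build dense message-passing tensors from a :class:`PriorGraph`.

    ``message_edges`` restricts the adjacency (e.g. to training positives,
    avoiding test-edge leakage); ``None`` uses all prior edges.
    """
    edges = graph.pos_edges if message_edges is None else message_edges
    return graph_arrays(
        graph.features, edges, graph.n_nodes, direction=direction, standardize=standardize
    )
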