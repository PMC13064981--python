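"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written as per-node / per-pair Python loops
over the dense adjacency so it shares no code path with the vectorised
implementation it checks.
"""

from __future__ import annotations

import numpy as np


def relu(x):
    return np.maximum(x, 0.0)


def prelu(x, a):
    return np.where(x > 0, x, a * x)


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def intra_oracle(H, A, lp, agg, combine, activation):
    """Per-node intra-layer message passing on a dense adjacency."""
    n, d = H.shape
    out = np.zeros((n, lp["W_self"].shape[1]))
    for v in range(n):
        msgs = [H[u] @ lp["W_nb"] for u in range(n) if A[v, u] > 0]
        if not msgs:
            T = np.zeros(lp["W_nb"].shape[1])
        elif agg == "sum":
            T = np.sum(msgs, axis=0)
        elif agg == "mean":
            T = np.mean(msgs, axis=0)
        elif agg == "max":
            T = np.max(msgs, axis=0)
        else:
            raise ValueError(agg)
        S = H[v] @ lp["W_self"]
        if combine == "sum":
            C = S + T
        elif combine == "concat":
            C = np.concatenate([S, T]) @ lp["W_comb"]
        else:
            raise ValueError(combine)
        out[v] = relu(C) if activation == "relu" else prelu(C, lp["prelu"])
    return out


def forward_oracle(params, X, A, pairs, choice):
    """Full model forward pass, one node / one pair at a time."""
    H = np.array([X[i] @ params["proj"]["W"] + params["proj"]["b"] for i in range(len(X))])
    intermediates = []
    h = H
    for l in range(choice.n_layers):
        lp = params["layers"][l]
        inter = intra_oracle(h, A, lp, choice.agg[l], choice.combine[l], choice.activation[l])
        mode = choice.connect[l]
        if mode == "stack":
            h_new = inter
        elif mode == "skip_sum":
            h_new = h + inter
        elif mode == "skip_concat":
            h_new = np.array(
                [np.concatenate([h[v], inter[v]]) @ lp["W_cnt"] for v in range(len(h))]
            )
        else:
            raise ValueError(mode)
        intermediates.append(h_new)
        h = h_new
    if choice.layer_agg == "skip":
        hL = intermediates[-1]
    elif choice.layer_agg == "concat":
        hL = np.concatenate(intermediates, axis=1)
    elif choice.layer_agg == "max":
        hL = np.maximum.reduce(intermediates)
    else:
        raise ValueError(choice.layer_agg)

    probs = []
    sc = params["scorer"]
    for s, t in pairs:
        hu, hv = hL[s], hL[t]
        if choice.pool == "sum":
            e = hu + hv
        elif choice.pool == "max":
            e = np.maximum(hu, hv)
        elif choice.pool == "concat":
            e = np.concatenate([hu, hv])
        else:
            raise ValueError(choice.pool)
        logit = relu(e @ sc["W1"] + sc["b1"]) @ sc["W2"] + sc["b2"]
        probs.append(sigmoid(float(np.ravel(logit)[0])))
    return np.array(probs)


def auroc_oracle(scores, labels):
    """Exhaustive positive-negative pair counting with half credit for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def auprc_oracle(scores, labels):
    """Stepwise average precision over distinct thresholds, descending."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    thresholds = sorted(set(scores), reverse=True)
    ap, prev_recall = 0.0, 0.0
    tp = fp = 0
    for t in thresholds:
        at_t = scores == t
        tp += int((labels[at_t] == 1).sum())
        fp += int((labels[at_t] == 0).sum())
        recall = tp / n_pos
        precision = tp / (tp + fp)
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def bce_oracle(scores, labels, eps=1e-7):
    total = 0.0
    for p, y in zip(scores, labels):
        p = min(max(p, eps), 1 - eps)
        total += -(y * np.log(p) + (1 - y) * np.log(1 - p))
    return total / len(scores)


def random_architecture(rng, space, n_layers=2):
    """Uniform draw of one architecture from a search space."""
    pick = lambda c: c[rng.integers(len(c))]  # noqa: E731
    from grnas.model import ArchitectureChoice

    return ArchitectureChoice(
        agg=tuple(pick(space.intra_agg) for _ in range(n_layers)),
        combine=tuple(pick(space.intra_combine) for _ in range(n_layers)),
        activation=tuple(pick(space.intra_activation) for _ in range(n_layers)),
        connect=tuple(pick(space.layer_connect) for _ in range(n_layers)),
        layer_agg=pick(space.layer_agg),
        pool=pick(space.pool),
    )


def random_graph_instance(rng, n_max=20, n_feat=6):
    """Random directed graph + features for forward-oracle comparisons."""
    n = int(rng.integers(4, n_max + 1))
    n_edges = int(rng.integers(1, max(2, n * 2)))
    edges = rng.integers(0, n, size=(n_edges, 2))
    edges = edges[edges[:, 0] != edges[:, 1]]
    if len(edges) == 0:
        edges = np.array([[0, 1]])
    edges = np.unique(edges, axis=0)
    X = rng.standard_normal((n, n_feat))
    return n, edges, X
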