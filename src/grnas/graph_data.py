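"""Prior-graph assembly, edge-disjoint splits and negative sampling.

Supervision units are ordered TF→target pairs. Positives are the prior-graph
edges, partitioned 80/10/10 into edge-disjoint train/validation/test sets
either at random or with the cold-start "hard" scheme where the partition is
over target genes, so validation/test edges point at genes that have no
training edge. Negatives are unlabeled TF→gene pairs sampled without
replacement from the complement of the positive set at a configurable
positive:negative ratio, disjointly across the three splits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ContractError, DatasetError
from .io_preprocess import GenePanel

__all__ = [
    "PriorGraph",
    "SplitPart",
    "EdgeSplit",
    "build_prior_graph",
    "split_edges",
    "sample_negatives",
    "write_split_manifest",
    "read_split_manifest",
]

SPLIT_RATIOS = (0.8, 0.1, 0.1)


@dataclass
class PriorGraph:
    """Directed TF→target prior graph over the feature panel.

    ``features[i]`` is gene i's expression profile (length = number of
    cells); ``pos_edges`` is an ``(m, 2)`` integer array of
    (tf_index, gene_index) pairs.
    """

    panel: GenePanel
    features: np.ndarray
    pos_edges: np.ndarray
    n_dropped_edges: int = 0

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.pos_edges = np.asarray(self.pos_edges, dtype=int).reshape(-1, 2)
        n = len(self.panel)
        if self.features.shape[0] != n:
            raise ContractError("feature row count must equal panel size")
        if self.pos_edges.size:
            if self.pos_edges.min() < 0 or self.pos_edges.max() >= n:
                raise ContractError("edge index out of range")
            if not self.panel.tf_flags[self.pos_edges[:, 0]].all():
                raise ContractError("every edge source must be a TF")
            as_set = {tuple(e) for e in self.pos_edges}
            if len(as_set) != len(self.pos_edges):
                raise ContractError("duplicate edges in prior graph")

    @property
    def n_nodes(self) -> int:
        return len(self.panel)

    @property
    def tf_indices(self) -> np.ndarray:
        return np.flatnonzero(self.panel.tf_flags)


@dataclass
class SplitPart:
    """Pairs and labels of one split."""

    pairs: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        self.labels = np.asarray(self.labels, dtype=int).reshape(-1)
        if len(self.pairs) != len(self.labels):
            raise ContractError("pairs and labels length mismatch")

    @property
    def positives(self) -> np.ndarray:
        return self.pairs[self.labels == 1]

    @property
    def negatives(self) -> np.ndarray:
        return self.pairs[self.labels == 0]

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class EdgeSplit:
    """Edge-disjoint train/valid/test supervision sets."""

    train: SplitPart
    valid: SplitPart
    test: SplitPart
    mode: str = "random"
    seed: int = 0
    neg_ratio: int | None = None

    def parts(self) -> dict[str, SplitPart]:
        return {"train": self.train, "valid": self.valid, "test": self.test}

    def validate(self, graph: PriorGraph) -> None:
        """Machine-check every split invariant; raise ContractError on failure."""
        all_pos = {tuple(e) for e in graph.pos_edges}
        pos_sets, neg_sets = [], []
        for name, part in self.parts().items():
            for s, t in part.pairs:
                if s == t:
                    raise ContractError(f"{name}: self-loop pair ({s},{t})")
                if not graph.panel.tf_flags[s]:
                    raise ContractError(f"{name}: pair source {s} is not a TF")
            pos_sets.append({tuple(e) for e in part.positives})
            neg_sets.append({tuple(e) for e in part.negatives})
        for i in range(3):
            for j in range(i + 1, 3):
                if pos_sets[i] & pos_sets[j]:
                    raise ContractError("positive pairs shared across splits")
                if neg_sets[i] & neg_sets[j]:
                    raise ContractError("negative pairs shared across splits")
        if set().union(*pos_sets) != all_pos:
            raise ContractError("split positives do not partition pos_edges")
        for name, negs in zip(("train", "valid", "test"), neg_sets):
            if negs & all_pos:
                raise ContractError(f"{name} negatives overlap positives")


def build_prior_graph(
    panel: GenePanel, x: pd.DataFrame, edges: list[tuple[str, str]]
) -> PriorGraph:
    """Assemble the prior graph, attaching expression rows as node features.

    Keeps only edges whose endpoints both belong to the panel and whose
    source is flagged as a TF; the dropped-edge count is recorded on the
    result.
    """
    missing = [g for g in panel.genes if g not in x.index]
    if missing:
        raise DatasetError(f"panel genes absent from expression matrix: {missing[:5]}")
    index = {g: i for i, g in enumerate(panel.genes)}
    kept, dropped = [], 0
    seen: set[tuple[int, int]] = set()
    for src, tgt in edges:
        si, ti = index.get(src), index.get(tgt)
        if si is None or ti is None or not panel.tf_flags[si] or si == ti:
            dropped += 1
            continue
        if (si, ti) in seen:
            dropped += 1
            continue
        seen.add((si, ti))
        kept.append((si, ti))
    if not kept:
        raise DatasetError(
            f"no usable edge: all {len(edges)} prior edges were dropped "
            "(endpoint outside panel or non-TF source)"
        )
    features = x.loc[panel.genes].to_numpy(dtype=float)
    return PriorGraph(
        panel=panel,
        features=features,
        pos_edges=np.array(kept),
        n_dropped_edges=dropped,
    )


def _slice_counts(n: int) -> tuple[int, int, int]:
    n_valid = int(np.floor(SPLIT_RATIOS[1] * n))
    n_test = int(np.floor(SPLIT_RATIOS[2] * n))
    return n - n_valid - n_test, n_valid, n_test


def split_edges(graph: PriorGraph, mode: str = "random", seed: int = 0) -> EdgeSplit:
    """Partition the positive edges 80/10/10.

    ``mode="random"`` shuffles edges and slices contiguously (floor counts
    for valid/test, remainder to train). ``mode="hard"`` partitions the
    distinct *target genes* 80/10/10 and assigns each edge to its target's
    split, so validation/test edges involve target genes with no training
    edge (cold start). If a hard split leaves a part empty it is retried
    with derived seeds up to 20 times.
    """
    edges = graph.pos_edges
    if len(edges) < 10:
        raise DatasetError(f"need at least 10 positive edges, have {len(edges)}")

    if mode == "random":
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(edges))
        n_train, n_valid, n_test = _slice_counts(len(edges))
        groups = (
            edges[perm[:n_train]],
            edges[perm[n_train : n_train + n_valid]],
            edges[perm[n_train + n_valid :]],
        )
    elif mode == "hard":
        groups = None
        for attempt in range(20):
            rng = np.random.default_rng([seed, attempt])
            targets = np.array(sorted(set(edges[:, 1])))
            perm = rng.permutation(len(targets))
            n_train, n_valid, n_test = _slice_counts(len(targets))
            part_of = {}
            for k, idx in enumerate(perm):
                part_of[targets[idx]] = (
                    0 if k < n_train else (1 if k < n_train + n_valid else 2)
                )
            cand = [[], [], []]
            for e in edges:
                cand[part_of[e[1]]].append(e)
            if all(len(c) > 0 for c in cand):
                groups = tuple(np.array(c) for c in cand)
                break
        if groups is None:
            raise DatasetError(
                "hard split produced an empty part in 20 seeded attempts"
            )
    else:
        raise ConfigurationError(f"unknown split mode {mode!r}")

    parts = [SplitPart(g, np.ones(len(g), dtype=int)) for g in groups]
    split = EdgeSplit(*parts, mode=mode, seed=seed)
    split.validate(graph)
    return split


def sample_negatives(
    graph: PriorGraph, split: EdgeSplit, neg_ratio: int, seed: int = 0
) -> EdgeSplit:
    """Attach sampled negatives at ``neg_ratio`` negatives per positive.

    The negative universe is every ordered (TF, gene) pair that is not a
    self-loop and not a positive edge of the graph. Pairs are drawn without
    replacement and assigned disjointly across train/valid/test; if the
    universe cannot cover the demand, it is allocated proportionally with a
    warning.
    """
    if neg_ratio < 1:
        raise ConfigurationError("neg_ratio must be >= 1")
    pos = {tuple(e) for e in graph.pos_edges}
    tf_idx = graph.tf_indices
    universe = [
        (int(t), int(v))
        for t in tf_idx
        for v in range(graph.n_nodes)
        if v != t and (t, v) not in pos
    ]
    if not universe:
        raise DatasetError("negative universe is empty")

    demands = [neg_ratio * len(part.positives) for part in split.parts().values()]
    total = sum(demands)
    if total > len(universe):
        warnings.warn(
            f"negative universe ({len(universe)}) smaller than demand "
            f"({total}); taking all, allocated proportionally"
        )
        scale = len(universe) / total
        demands = [int(np.floor(d * scale)) for d in demands]
        leftover = len(universe) - sum(demands)
        for i in range(leftover):
            demands[i % 3] += 1

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(universe))
    cursor = 0
    new_parts = {}
    for (name, part), demand in zip(split.parts().items(), demands):
        take = order[cursor : cursor + demand]
        cursor += demand
        negs = np.array([universe[i] for i in take], dtype=int).reshape(-1, 2)
        pairs = np.vstack([part.positives, negs])
        labels = np.concatenate(
            [np.ones(len(part.positives), dtype=int), np.zeros(len(negs), dtype=int)]
        )
        new_parts[name] = SplitPart(pairs, labels)

    out = EdgeSplit(
        train=new_parts["train"],
        valid=new_parts["valid"],
        test=new_parts["test"],
        mode=split.mode,
        seed=split.seed,
        neg_ratio=neg_ratio,
    )
    out.validate(graph)
    return out


def write_split_manifest(split: EdgeSplit, graph: PriorGraph, path) -> Path:
    """Write a (source, target, label, split) CSV manifest with gene names."""
    rows = []
    for name, part in split.parts().items():
        for (s, t), y in zip(part.pairs, part.labels):
            rows.append((graph.panel.genes[s], graph.panel.genes[t], int(y), name))
    path = Path(path)
    pd.DataFrame(rows, columns=["source", "target", "label", "split"]).to_csv(
        path, index=False
    )
    return path


def read_split_manifest(path, graph: PriorGraph) -> EdgeSplit:
    """Read a manifest written by :func:`write_split_manifest`."""
    df = pd.read_csv(path, dtype={"source": str, "target": str})
    index = {g: i for i, g in enumerate(graph.panel.genes)}
    parts = {}
    for name in ("train", "valid", "test"):
        sub = df[df["split"] == name]
        pairs = np.array(
            [(index[s], index[t]) for s, t in zip(sub["source"], sub["target"])],
            dtype=int,
        ).reshape(-1, 2)
        parts[name] = SplitPart(pairs, sub["label"].to_numpy(dtype=int))
    return EdgeSplit(**parts)
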