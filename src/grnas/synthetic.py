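"""Planted regulatory networks with matching synthetic expression matrices.

The generator plants a directed acyclic TF→target network and propagates
expression through it as a linear structural-equation model with a softplus
link, additive Gaussian measurement noise and Bernoulli dropout
(zero-inflation) — the minimal mechanism that yields a nonnegative,
zero-inflated genes × cells matrix in which targets carry a learnable
statistical signature of their planted regulators. Output files use the same
BEELINE dialects the readers in :mod:`grnas.io_preprocess` expect, so every
downstream module is exercisable without external downloads. It is a test
fixture, not a biological claim: there is no UMI count model, no feedback
cycle and no cell-state trajectory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError

__all__ = [
    "SimulationConfig",
    "PlantedGRN",
    "generate_planted_grn",
    "simulate_expression",
    "write_fixture_bundle",
    "load_bundle",
    "simulate_bundle",
]


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults are the reference benchmark conditions used throughout the test
    suite: 30 TFs regulating 300 targets across 500 cells with a mean TF
    out-degree of 8, unit-magnitude signed edge weights, measurement noise
    of 0.1 and 30% dropout.
    """

    n_tfs: int = 30
    n_targets: int = 300
    n_cells: int = 500
    mean_out_degree: float = 8.0
    weight_scale: float = 1.0
    noise_sd: float = 0.1
    dropout_prob: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tfs < 1 or self.n_targets < 0 or self.n_cells < 1:
            raise ConfigurationError("n_tfs, n_targets, n_cells must be positive")
        if self.mean_out_degree <= 0:
            raise ConfigurationError("mean_out_degree must be positive")
        if self.weight_scale <= 0:
            raise ConfigurationError("weight_scale must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")
        if not 0.0 <= self.dropout_prob < 1.0:
            raise ConfigurationError("dropout_prob must be in [0, 1)")


@dataclass
class PlantedGRN:
    """A planted acyclic TF→target network with signed edge weights."""

    tf_ids: list[str]
    gene_ids: list[str]
    edges: list[tuple[str, str]]
    edge_weights: np.ndarray
    topological_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.edge_weights = np.asarray(self.edge_weights, dtype=float)
        tfs = set(self.tf_ids)
        if any(src not in tfs for src, _ in self.edges):
            raise ConfigurationError("edge sources must be TFs")
        if len(set(self.edges)) != len(self.edges):
            raise ConfigurationError("duplicate edges in planted network")
        if len(self.edge_weights) != len(self.edges):
            raise ConfigurationError("edge_weights length must match edges")
        if len(self.edge_weights) and (
            ~np.isfinite(self.edge_weights) | (self.edge_weights == 0)
        ).any():
            raise ConfigurationError("edge weights must be finite and nonzero")
        if not self.topological_order:
            self.topological_order = list(self.tf_ids) + list(self.gene_ids)

    @property
    def all_genes(self) -> list[str]:
        return list(self.tf_ids) + list(self.gene_ids)


def _softplus(x: np.ndarray) -> np.ndarray:
    # overflow-safe log(1 + e^x)
    return np.logaddexp(0.0, x)


def generate_planted_grn(cfg: SimulationConfig) -> PlantedGRN:
    """Sample a planted acyclic network.

    TF out-degrees are drawn from a log-normal distribution (heavy-tailed,
    sigma 0.6) with mean ``mean_out_degree``; each TF's targets are sampled
    uniformly without replacement among nodes strictly later in the
    topological order (other TFs included), which enforces acyclicity by
    construction. Weights are ``±weight_scale`` with random sign.
    """
    rng = np.random.default_rng(cfg.seed)
    tf_ids = [f"TF{i + 1:03d}" for i in range(cfg.n_tfs)]
    gene_ids = [f"G{i + 1:04d}" for i in range(cfg.n_targets)]

    order = list(tf_ids)
    rng.shuffle(order)
    tail = list(gene_ids)
    rng.shuffle(tail)
    order += tail

    sigma = 0.6
    mu = np.log(cfg.mean_out_degree) - sigma**2 / 2.0
    position = {g: i for i, g in enumerate(order)}

    edges: list[tuple[str, str]] = []
    weights: list[float] = []
    n_capped = 0
    for tf in tf_ids:
        downstream = order[position[tf] + 1 :]
        k = int(max(1, round(rng.lognormal(mu, sigma))))
        if k > len(downstream):
            k = len(downstream)
            n_capped += 1
        if k == 0:
            continue
        targets = rng.choice(len(downstream), size=k, replace=False)
        for t in targets:
            edges.append((tf, downstream[t]))
            weights.append(cfg.weight_scale * rng.choice([-1.0, 1.0]))
    if n_capped:
        warnings.warn(
            f"capped out-degree of {n_capped} TF(s) at the number of "
            "available downstream nodes"
        )
    return PlantedGRN(
        tf_ids=tf_ids,
        gene_ids=gene_ids,
        edges=edges,
        edge_weights=np.array(weights),
        topological_order=order,
    )


def simulate_expression(grn: PlantedGRN, cfg: SimulationConfig) -> pd.DataFrame:
    """Propagate expression through the planted network.

    Root nodes (no parents) draw log-normal activity per cell; every other
    node is ``softplus(sum_parents w * parent)`` plus Gaussian noise,
    truncated at zero. Dropout then zeroes each entry independently with
    probability ``dropout_prob``. Rows follow ``grn.all_genes`` order,
    columns are cells.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    parents: dict[str, list[tuple[str, float]]] = {}
    for (src, tgt), w in zip(grn.edges, grn.edge_weights):
        parents.setdefault(tgt, []).append((src, float(w)))

    values: dict[str, np.ndarray] = {}
    for node in grn.topological_order:
        if node not in parents:
            values[node] = rng.lognormal(mean=0.0, sigma=1.0, size=cfg.n_cells)
        else:
            total = np.zeros(cfg.n_cells)
            for src, w in parents[node]:
                total = total + w * values[src]
            v = _softplus(total)
            if cfg.noise_sd > 0:
                v = v + rng.normal(0.0, cfg.noise_sd, size=cfg.n_cells)
            values[node] = np.maximum(v, 0.0)

    genes = grn.all_genes
    mat = np.stack([values[g] for g in genes])
    if cfg.dropout_prob > 0:
        keep = rng.random(mat.shape) >= cfg.dropout_prob
        mat = mat * keep
    cells = [f"C{i + 1:04d}" for i in range(cfg.n_cells)]
    return pd.DataFrame(mat, index=genes, columns=cells)


def write_fixture_bundle(grn: PlantedGRN, x: pd.DataFrame, directory) -> dict[str, Path]:
    """Write ExpressionData.csv, refNetwork.csv and tf_list.txt.

    The three files use the dialects read by :mod:`grnas.io_preprocess`;
    reading them back reproduces the inputs.
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create fixture directory {directory}: {exc}") from exc

    expr_path = directory / "ExpressionData.csv"
    net_path = directory / "refNetwork.csv"
    tf_path = directory / "tf_list.txt"

    x.to_csv(expr_path, float_format="%.10g")
    pd.DataFrame(grn.edges, columns=["Gene1", "Gene2"]).to_csv(net_path, index=False)
    tf_path.write_text("".join(f"{t}\n" for t in grn.tf_ids))
    return {"expression": expr_path, "network": net_path, "tf_list": tf_path}


def load_bundle(directory):
    """Read a fixture bundle back as ``(expression, edges, tfs)``."""
    from .io_preprocess import read_edge_list_csv, read_expression_csv, read_tf_list

    directory = Path(directory)
    return (
        read_expression_csv(directory / "ExpressionData.csv"),
        read_edge_list_csv(directory / "refNetwork.csv"),
        read_tf_list(directory / "tf_list.txt"),
    )


def simulate_bundle(cfg: SimulationConfig) -> tuple[PlantedGRN, pd.DataFrame]:
    """Convenience: planted network plus its simulated expression matrix."""
    grn = generate_planted_grn(cfg)
    return grn, simulate_expression(grn, cfg)
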