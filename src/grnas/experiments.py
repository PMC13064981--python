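"""End-to-end pipelines: single runs, the imbalance sweep and ablations.

A run takes a dataset bundle (expression matrix, prior edge list, TF
catalogue), assembles the prior graph, draws an edge-disjoint split with
sampled negatives, fits :class:`~grnas.estimators.AutoGRNLinkPredictor`
(search + retrain) and reports test-split AUROC/AUPRC together with the
selected architecture. The imbalance sweep repeats the run over a list of
positive:negative ratios while keeping the positive split fixed; ablations
freeze parts of the search space.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import DROPOUT_GRID, TrainConfig
from .estimators import AutoGRNLinkPredictor
from .exceptions import ConfigurationError
from .graph_data import (
    EdgeSplit,
    PriorGraph,
    build_prior_graph,
    sample_negatives,
    split_edges,
)
from .io_preprocess import (
    GenePanel,
    PreprocessConfig,
    build_feature_panel,
    filter_genes,
    normalize_log,
    select_hvg,
)
from .metrics import MetricsReport, auprc, auroc

__all__ = [
    "DEFAULT_IMBALANCE_RATIOS",
    "prepare_graph",
    "run_pipeline",
    "imbalance_experiment",
    "ablation_run",
    "operator_recovery_experiment",
    "scaled_epochs",
    "select_dropout",
]

DEFAULT_IMBALANCE_RATIOS = (1, 5, 10, 20, 50, 100, 200, 400)

_VARIANTS = {
    "full": {},
    "no_inter": {"no_inter": True},
    "fixed_pool": {"fixed_pool": "max"},
}

# Optimiser step budgets the experiment harness holds roughly constant
# across dataset sizes (see scaled_epochs).
TARGET_TRAIN_STEPS = 1000
TARGET_SEARCH_STEPS = 300
MAX_TRAIN_EPOCHS = 1000
MAX_SEARCH_EPOCHS = 300


def scaled_epochs(n_train_pairs: int, cfg: TrainConfig) -> tuple[int, int]:
    """Epoch counts giving a size-independent optimiser step budget.

    The stock epoch counts assume datasets large enough that one epoch
    contains dozens of mini-batches. On small supervision sets (e.g. a 1:1
    split of a few hundred pairs) the same epoch count yields only a handful
    of weight updates, so the harness raises the epoch count to keep roughly
    ``TARGET_TRAIN_STEPS`` retraining updates and ``TARGET_SEARCH_STEPS``
    search-phase weight updates, never dropping below the configured
    defaults and capped to keep runs bounded.
    """
    nb = max(1, int(np.ceil(n_train_pairs / cfg.batch_size)))
    train = int(min(MAX_TRAIN_EPOCHS, max(cfg.train_epochs, round(TARGET_TRAIN_STEPS / nb))))
    search = int(min(MAX_SEARCH_EPOCHS, max(cfg.search_epochs, round(TARGET_SEARCH_STEPS / nb))))
    return train, search


def prepare_graph(
    expression: pd.DataFrame,
    edges: list[tuple[str, str]],
    tfs: set[str],
    preprocess: PreprocessConfig | None = None,
    full_panel: bool = True,
) -> PriorGraph:
    """Normalise expression and assemble the prior graph.

    With ``full_panel`` (the default for synthetic bundles, whose gene
    universe is already curated) the panel is every gene in the matrix,
    TF-flagged from the catalogue, after library-size normalisation and log
    transform only. Otherwise the full preprocessing chain runs: gene
    filtering, normalisation, HVG selection and TF-aware panel construction.
    """
    cfg = preprocess or PreprocessConfig()
    if full_panel:
        x = normalize_log(expression, cfg)
        genes = [str(g) for g in x.index]
        flags = np.array([g in tfs for g in genes])
        panel = GenePanel(
            genes=genes,
            tf_flags=flags,
            provenance=["hvg_tf" if f else "hvg_nontf" for f in flags],
        )
    else:
        x = normalize_log(filter_genes(expression, cfg), cfg)
        hvg = select_hvg(x, cfg)
        panel = build_feature_panel(hvg, tfs, cfg)
    return build_prior_graph(panel, x, edges)


def _fit_and_evaluate(
    graph: PriorGraph,
    split: EdgeSplit,
    cfg: TrainConfig,
    variant: str,
    scale_epochs: bool = True,
) -> MetricsReport:
    if variant not in _VARIANTS:
        raise ConfigurationError(
            f"unknown variant {variant!r}; expected one of {sorted(_VARIANTS)}"
        )
    train_epochs, search_epochs = cfg.train_epochs, cfg.search_epochs
    if scale_epochs:
        train_epochs, search_epochs = scaled_epochs(len(split.train), cfg)
    est = AutoGRNLinkPredictor(
        hidden_dim=cfg.hidden_dim,
        n_layers=cfg.n_layers,
        learning_rate=cfg.learning_rate,
        arch_learning_rate=cfg.arch_learning_rate,
        batch_size=cfg.batch_size,
        train_epochs=train_epochs,
        search_epochs=search_epochs,
        tau=cfg.tau,
        dropout=cfg.dropout,
        message_direction=cfg.message_direction,
        message_edges=cfg.message_edges,
        standardize=cfg.standardize,
        random_state=cfg.seed,
        **_VARIANTS[variant],
    )
    est.fit(
        split.train.pairs,
        split.train.labels,
        graph=graph,
        X_val=split.valid.pairs,
        y_val=split.valid.labels,
    )
    scores = est.decision_scores(split.test.pairs)
    y_test = split.test.labels
    return MetricsReport(
        auroc=auroc(scores, y_test),
        auprc=auprc(scores, y_test),
        n_pos=int((y_test == 1).sum()),
        n_neg=int((y_test == 0).sum()),
        neg_ratio=split.neg_ratio,
        split_mode=split.mode,
        seed=cfg.seed,
        variant=variant,
        architecture=est.architecture_report_,
        extras={
            "best_epoch": est.best_epoch_,
            "search_history": est.search_history_,
            "train_history": est.train_history_,
        },
    )


def run_pipeline(
    expression: pd.DataFrame,
    edges: list[tuple[str, str]],
    tfs: set[str],
    cfg: TrainConfig | None = None,
    neg_ratio: int = 1,
    split_mode: str = "random",
    variant: str = "full",
    preprocess: PreprocessConfig | None = None,
    full_panel: bool = True,
    graph: PriorGraph | None = None,
    scale_epochs: bool = True,
) -> MetricsReport:
    """One full run: preprocess → split → search → retrain → evaluate."""
    cfg = cfg or TrainConfig()
    if graph is None:
        graph = prepare_graph(expression, edges, tfs, preprocess, full_panel)
    split = split_edges(graph, mode=split_mode, seed=cfg.seed)
    split = sample_negatives(graph, split, neg_ratio=neg_ratio, seed=cfg.seed)
    return _fit_and_evaluate(graph, split, cfg, variant, scale_epochs=scale_epochs)


def imbalance_experiment(
    expression: pd.DataFrame,
    edges: list[tuple[str, str]],
    tfs: set[str],
    ratios=DEFAULT_IMBALANCE_RATIOS,
    cfg: TrainConfig | None = None,
    split_mode: str = "random",
    preprocess: PreprocessConfig | None = None,
    full_panel: bool = True,
    scale_epochs: bool = True,
) -> tuple[pd.DataFrame, list[MetricsReport]]:
    """Search + retrain + evaluate at each positive:negative ratio.

    The positive split is drawn once and reused; negatives are resampled
    per ratio with a ratio-derived seed. Returns a tidy table
    (ratio, auroc, auprc, n_pos, n_neg) and the per-ratio reports.
    """
    if any(r < 1 for r in ratios):
        raise ConfigurationError("ratios must be >= 1")
    cfg = cfg or TrainConfig()
    graph = prepare_graph(expression, edges, tfs, preprocess, full_panel)
    base_split = split_edges(graph, mode=split_mode, seed=cfg.seed)
    reports = []
    for k, ratio in enumerate(ratios):
        split = sample_negatives(
            graph, base_split, neg_ratio=int(ratio), seed=cfg.seed + 7919 * (k + 1)
        )
        reports.append(_fit_and_evaluate(graph, split, cfg, "full", scale_epochs=scale_epochs))
    table = pd.DataFrame(
        {
            "ratio": list(ratios),
            "auroc": [r.auroc for r in reports],
            "auprc": [r.auprc for r in reports],
            "n_pos": [r.n_pos for r in reports],
            "n_neg": [r.n_neg for r in reports],
        }
    )
    return table, reports


def ablation_run(
    expression: pd.DataFrame,
    edges: list[tuple[str, str]],
    tfs: set[str],
    variant: str,
    cfg: TrainConfig | None = None,
    neg_ratio: int = 1,
    split_mode: str = "random",
    preprocess: PreprocessConfig | None = None,
    full_panel: bool = True,
    scale_epochs: bool = True,
) -> MetricsReport:
    """Run the pipeline with a frozen-slot variant.

    ``no_inter`` removes the inter-layer search space (stack connections,
    last-layer aggregation); ``fixed_pool`` replaces the searchable readout
    with a fixed pooling operator.
    """
    return run_pipeline(
        expression,
        edges,
        tfs,
        cfg=cfg,
        neg_ratio=neg_ratio,
        split_mode=split_mode,
        variant=variant,
        preprocess=preprocess,
        full_panel=full_panel,
        scale_epochs=scale_epochs,
    )


def operator_recovery_experiment(
    n_seeds: int = 10,
    sim_seed_base: int = 200,
    hidden_dim: int = 64,
    slot: str = "pool",
    sim_cfg_kwargs: dict | None = None,
) -> tuple[int, list[str]]:
    """Can the search tell an informative operator from a constant one?

    For each seed a planted bundle is simulated and the search runs with
    every slot collapsed except ``slot``, whose candidates are the true
    mechanism (``sum``) and a constant-zero saboteur. Returns the number of
    seeds in which the argmax architecture selects the informative operator,
    plus the per-seed selections.
    """
    from .model import SearchSpace
    from .search import _split_arrays, derive_architecture, run_search
    from .synthetic import SimulationConfig, simulate_bundle

    kw = dict(
        intra_agg=("sum",),
        intra_combine=("sum",),
        intra_activation=("relu",),
        layer_connect=("stack",),
        layer_agg=("skip",),
        pool=("sum",),
    )
    if slot == "pool":
        kw["pool"] = ("sum", "zero")
    elif slot == "intra_agg":
        kw["intra_agg"] = ("sum", "zero")
    else:
        raise ConfigurationError(f"unsupported saboteur slot {slot!r}")
    space = SearchSpace(**kw)

    selections = []
    for i in range(n_seeds):
        grn, x = simulate_bundle(
            SimulationConfig(seed=sim_seed_base + i, **(sim_cfg_kwargs or {}))
        )
        graph = prepare_graph(x, list(grn.edges), set(grn.tf_ids))
        split = sample_negatives(graph, split_edges(graph, seed=i), neg_ratio=1, seed=i)
        cfg = TrainConfig(hidden_dim=hidden_dim, seed=i)
        _, cfg.search_epochs = scaled_epochs(len(split.train), cfg)
        arrays = _split_arrays(graph, split, cfg)
        arch, _, _ = run_search(
            arrays,
            split.train.pairs,
            split.train.labels,
            split.valid.pairs,
            split.valid.labels,
            space,
            cfg,
        )
        choice = derive_architecture(arch, space, cfg.n_layers)
        selections.append(choice.pool if slot == "pool" else choice.agg[0])
    wins = sum(s != "zero" for s in selections)
    return wins, selections


def select_dropout(
    expression: pd.DataFrame,
    edges: list[tuple[str, str]],
    tfs: set[str],
    grid=DROPOUT_GRID,
    cfg: TrainConfig | None = None,
    **kwargs,
) -> tuple[float, list[MetricsReport]]:
    """Pick the dropout rate with the best final validation AUROC."""
    cfg = cfg or TrainConfig()
    reports, best_rate, best_val = [], grid[0], -np.inf
    for rate in grid:
        run_cfg = TrainConfig(**{**cfg.to_dict(), "dropout": rate})
        report = run_pipeline(expression, edges, tfs, cfg=run_cfg, **kwargs)
        val = report.extras["train_history"][report.extras["best_epoch"]]["valid_auroc"]
        reports.append(report)
        if val is not None and val > best_val:
            best_rate, best_val = rate, val
    return best_rate, reports
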