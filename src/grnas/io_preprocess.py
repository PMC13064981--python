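"""Reading BEELINE-dialect files and scRNA-seq preprocessing.

The expression container is a pandas ``DataFrame`` with genes as rows (index)
and cells as columns, i.e. the on-disk ``ExpressionData.csv`` layout used by
the BEELINE benchmark. Preprocessing follows the usual single-cell recipe:
cell-fraction gene filtering, library-size (CPM-style) normalisation with a
``log1p`` transform, and highly-variable-gene (HVG) selection by a
mean–dispersion trend (robust per-bin z-scores) with Bonferroni-thresholded two-sided normal p-values.
The feature panel combines the highly variable transcription factors with the
top-``n`` non-TF HVGs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    ConfigurationError,
    FormatError,
    PreprocessingError,
    StatisticalError,
)

__all__ = [
    "PreprocessConfig",
    "GenePanel",
    "read_expression_csv",
    "read_edge_list_csv",
    "read_tf_list",
    "validate_expression",
    "filter_genes",
    "normalize_log",
    "select_hvg",
    "build_feature_panel",
]


@dataclass
class PreprocessConfig:
    """Parameters of the preprocessing pipeline.

    Attributes
    ----------
    min_gene_cell_fraction:
        Keep a gene only if it is non-zero in at least this fraction of
        cells. The literal benchmark value is 0.9, which is very strict for
        sparse data, hence configurable.
    normalization_scale:
        Per-cell library size after normalisation (counts-per-X; 1e6 = CPM).
        ``None`` (the default) targets the median library size of the
        dataset, which keeps values near their native scale so the
        subsequent ``log1p`` does not flatten magnitude information.
    hvg_alpha:
        Family-wise significance level for HVG selection; Bonferroni-divided
        by the number of tested genes.
    top_n_nontf:
        Number of highest-ranked non-TF HVGs added to the panel.
    n_bins:
        Number of mean-expression quantile bins for the dispersion trend.
    case_insensitive:
        Case-fold gene symbols when matching against the TF catalogue.
    """

    min_gene_cell_fraction: float = 0.9
    normalization_scale: float | None = None
    hvg_alpha: float = 0.01
    top_n_nontf: int = 500
    n_bins: int = 20
    case_insensitive: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_gene_cell_fraction <= 1.0:
            raise ConfigurationError("min_gene_cell_fraction must be in [0, 1]")
        if self.normalization_scale is not None and self.normalization_scale <= 0:
            raise ConfigurationError("normalization_scale must be positive")
        if not 0.0 < self.hvg_alpha < 1.0:
            raise ConfigurationError("hvg_alpha must be in (0, 1)")
        if self.top_n_nontf < 1:
            raise ConfigurationError("top_n_nontf must be a positive integer")


@dataclass
class GenePanel:
    """Ordered gene panel with TF annotation.

    ``provenance`` tags each gene as ``hvg_tf`` (highly variable TF),
    ``hvg_nontf`` (highly variable non-TF) or ``curated_tf`` (TF included
    from the curated catalogue without passing HVG selection).
    """

    genes: list[str]
    tf_flags: np.ndarray
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.tf_flags = np.asarray(self.tf_flags, dtype=bool)
        if len(set(self.genes)) != len(self.genes):
            raise ConfigurationError("panel genes must be unique")
        if self.tf_flags.shape != (len(self.genes),):
            raise ConfigurationError("tf_flags length must match genes")

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def tf_genes(self) -> list[str]:
        return [g for g, f in zip(self.genes, self.tf_flags) if f]


def validate_expression(x: pd.DataFrame) -> pd.DataFrame:
    """Check the expression-matrix invariants and return ``x`` unchanged."""
    if x.shape[0] == 0 or x.shape[1] == 0:
        raise FormatError("expression matrix is empty")
    if x.index.duplicated().any():
        dupes = x.index[x.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate gene names: {dupes[:5]}")
    if x.columns.duplicated().any():
        raise FormatError("duplicate cell identifiers")
    values = x.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise FormatError("expression values must be numeric")
    if not np.isfinite(values).all():
        raise FormatError("expression values must be finite")
    if (values < 0).any():
        raise FormatError("expression values must be non-negative")
    return x


def read_expression_csv(path) -> pd.DataFrame:
    """Read a genes × cells expression CSV (gene-name index, cell-ID header)."""
    try:
        x = pd.read_csv(path, index_col=0)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"cannot parse expression CSV {path!s}: {exc}") from exc
    x.index = x.index.astype(str)
    x.columns = x.columns.astype(str)
    try:
        x = x.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric expression value in {path!s}") from exc
    return validate_expression(x)


def read_edge_list_csv(path) -> list[tuple[str, str]]:
    """Read a two-column (regulator, target) edge list CSV.

    Duplicate edges and self-loops are dropped with a warning; file order is
    otherwise preserved.
    """
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 2:
        raise FormatError(
            f"edge list {path!s} needs two columns (regulator, target), "
            f"found {df.shape[1]}"
        )
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    n_dup = n_self = 0
    for src, tgt in df.iloc[:, :2].itertuples(index=False):
        edge = (str(src), str(tgt))
        if edge[0] == edge[1]:
            n_self += 1
            continue
        if edge in seen:
            n_dup += 1
            continue
        seen.add(edge)
        pairs.append(edge)
    if n_dup:
        warnings.warn(f"dropped {n_dup} duplicate edge(s) from {path!s}")
    if n_self:
        warnings.warn(f"dropped {n_self} self-loop(s) from {path!s}")
    return pairs


def read_tf_list(path) -> set[str]:
    """Read a TF catalogue (one symbol per line, blanks skipped, deduplicated)."""
    with open(path) as fh:
        names = {line.strip() for line in fh if line.strip()}
    if not names:
        raise ConfigurationError(f"TF list {path!s} is empty")
    return names


def filter_genes(x: pd.DataFrame, cfg: PreprocessConfig) -> pd.DataFrame:
    """Keep genes whose non-zero cell fraction is >= ``min_gene_cell_fraction``."""
    validate_expression(x)
    frac = (x.to_numpy() > 0).mean(axis=1)
    keep = frac >= cfg.min_gene_cell_fraction
    if not keep.any():
        raise PreprocessingError(
            f"gene filter removed all {x.shape[0]} genes "
            f"(threshold {cfg.min_gene_cell_fraction})"
        )
    return x.loc[keep]


def normalize_log(x: pd.DataFrame, cfg: PreprocessConfig) -> pd.DataFrame:
    """Scale each cell to a common total, then log1p.

    The target total is ``normalization_scale``, or the median library size
    when it is ``None``.
    """
    validate_expression(x)
    colsums = x.to_numpy().sum(axis=0)
    zero = np.flatnonzero(colsums == 0)
    if zero.size:
        raise PreprocessingError(
            f"cell(s) with zero total counts: {list(x.columns[zero[:5]])}"
        )
    target = cfg.normalization_scale
    if target is None:
        target = float(np.median(colsums))
    scaled = x.to_numpy() * (target / colsums)
    return pd.DataFrame(np.log1p(scaled), index=x.index, columns=x.columns)


def select_hvg(
    x: pd.DataFrame, cfg: PreprocessConfig, all_genes: bool = False
) -> pd.DataFrame:
    """Rank significantly highly variable genes.

    For each gene the dispersion (variance / mean of the log-normalised
    profile) is z-scored against genes of similar mean expression (quantile
    bins — the mean–dispersion trend), giving a two-sided normal p-value.
    Genes significant after Bonferroni correction at ``hvg_alpha`` are
    returned ranked by the z statistic, descending. The result frame is
    indexed by gene with columns ``mean``, ``dispersion``, ``z``, ``pvalue``;
    ``all_genes=True`` returns the full ranked table without the
    significance cut.
    """
    validate_expression(x)
    if x.shape[1] < 3:
        raise StatisticalError("HVG selection needs at least 3 cells")
    values = x.to_numpy()
    mean = values.mean(axis=1)
    var = values.var(axis=1, ddof=1)
    disp = var / (mean + 1e-12)

    n_bins = max(1, min(cfg.n_bins, len(np.unique(mean))))
    try:
        bins = pd.qcut(mean, q=n_bins, labels=False, duplicates="drop")
    except ValueError:
        bins = np.zeros(len(mean), dtype=int)
    bins = np.asarray(bins, dtype=float)
    bins[np.isnan(bins)] = -1

    def _center_scale(v: np.ndarray) -> tuple[float, float]:
        # robust location/scale so a gene does not inflate its own reference
        med = float(np.median(v))
        scale = 1.4826 * float(np.median(np.abs(v - med)))
        if scale == 0.0:
            scale = float(v.std(ddof=1)) if len(v) > 1 else 0.0
        return med, scale

    g_center, g_scale = _center_scale(disp)
    z = np.zeros_like(disp)
    for b in np.unique(bins):
        members = bins == b
        if members.sum() > 2:
            center, scale = _center_scale(disp[members])
        else:
            center, scale = g_center, g_scale
        if scale == 0.0:
            center, scale = g_center, g_scale
        if scale > 0.0:
            z[members] = (disp[members] - center) / scale
    pvalue = 2.0 * stats.norm.sf(np.abs(z))

    table = pd.DataFrame(
        {"mean": mean, "dispersion": disp, "z": z, "pvalue": pvalue},
        index=x.index,
    )
    table = table.sort_values("z", ascending=False, kind="stable")
    if all_genes:
        return table
    threshold = cfg.hvg_alpha / x.shape[0]
    return table[table["pvalue"] <= threshold]


def _hvg_gene_list(hvg) -> list[str]:
    if isinstance(hvg, pd.DataFrame):
        return [str(g) for g in hvg.index]
    return [str(g) for g in hvg]


def build_feature_panel(hvg, tfs: set[str], cfg: PreprocessConfig) -> GenePanel:
    """Combine highly variable TFs with the top-``n`` non-TF HVGs.

    ``hvg`` is a ranked gene list (or the frame from :func:`select_hvg`);
    panel order is TFs first (rank order) then non-TFs (rank order).
    """
    ranked = _hvg_gene_list(hvg)
    if cfg.case_insensitive:
        tf_keys = {t.casefold() for t in tfs}
        is_tf = lambda g: g.casefold() in tf_keys  # noqa: E731
    else:
        is_tf = lambda g: g in tfs  # noqa: E731

    tf_genes = [g for g in ranked if is_tf(g)]
    nontf_genes = [g for g in ranked if not is_tf(g)]
    if not tf_genes:
        warnings.warn("no curated TF among the highly variable genes")
    if cfg.top_n_nontf > len(nontf_genes):
        warnings.warn(
            f"requested {cfg.top_n_nontf} non-TF genes but only "
            f"{len(nontf_genes)} available; taking all"
        )
    kept_nontf = nontf_genes[: cfg.top_n_nontf]

    genes = tf_genes + kept_nontf
    flags = np.array([True] * len(tf_genes) + [False] * len(kept_nontf))
    provenance = ["hvg_tf"] * len(tf_genes) + ["hvg_nontf"] * len(kept_nontf)
    return GenePanel(genes=genes, tf_flags=flags, provenance=provenance)
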