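"""File input/output and run orchestration for the command-line surface.

Counts are read from TSV/CSV (samples in rows, taxa in columns, transposable),
trees from Newick, outcome and covariates from TSV keyed by sample ID.
Samples are aligned by ID across files (intersection join, with warnings on
drops) — never by row order.  Taxa are restricted to those present in both
the count table and the tree.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .kernels import OTUTable
from .model import POST
from .score import DEFAULT_C_GRID
from .tree import read_newick

__all__ = ["RunConfig", "load_inputs", "run_post", "write_results"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one association-test run."""

    counts: Path
    tree: Path
    outcome: Path
    output: Path
    covariates: Path | None = None
    family: str = "continuous"
    outcome_column: str | None = None
    pseudo: float | None = None
    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    alpha: float = 0.05
    min_abundance: float | None = None  # mean relative abundance threshold
    min_prevalence: float | None = None  # fraction of samples with nonzero count
    transpose_counts: bool = False
    sep: str = "\t"
    proportions: bool = False
    precision: str = "short"  # "short" (6 sig digits) | "full"
    per_c: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.c_grid = tuple(sorted(set(float(c) for c in self.c_grid)))
        if len(self.c_grid) == 0 or self.c_grid[0] < 0:
            raise ValueError("c grid must be non-empty with min >= 0")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")


def _filter_taxa(df: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """Mean-relative-abundance and prevalence filters (off by default)."""
    keep = pd.Series(True, index=df.columns)
    rel = df.div(df.sum(axis=1).replace(0, np.nan), axis=0)
    if config.min_abundance is not None:
        keep &= rel.mean(axis=0) >= config.min_abundance
    if config.min_prevalence is not None:
        keep &= (df > 0).mean(axis=0) >= config.min_prevalence
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("abundance/prevalence filters removed %d taxa", dropped)
    return df.loc[:, keep]


def load_inputs(config: RunConfig):
    """Read and align all inputs.

    Returns ``(table, dist_tree, y, X)`` where ``X`` includes the intercept
    column.  Sample IDs are intersected across counts/outcome/covariates;
    taxa are intersected with the tree tips (warning on drops).
    """
    counts = pd.read_csv(config.counts, sep=config.sep, index_col=0)
    if config.transpose_counts:
        counts = counts.T
    counts.index = counts.index.astype(str)
    counts.columns = counts.columns.astype(str)
    counts = _filter_taxa(counts, config)

    out_df = pd.read_csv(config.outcome, sep=config.sep, index_col=0)
    out_df.index = out_df.index.astype(str)
    col = config.outcome_column or out_df.columns[0]
    outcome = out_df[col].astype(float)

    cov = None
    if config.covariates is not None:
        cov = pd.read_csv(config.covariates, sep=config.sep, index_col=0)
        cov.index = cov.index.astype(str)

    common = counts.index.intersection(outcome.index)
    if cov is not None:
        common = common.intersection(cov.index)
    n_drop = len(counts.index) - len(common)
    if n_drop:
        logger.warning("dropping %d samples absent from outcome/covariates", n_drop)
    if len(common) == 0:
        raise ValueError("no samples shared across counts, outcome and covariates")
    counts = counts.loc[common]
    y = outcome.loc[common].to_numpy()

    tree = read_newick(str(config.tree), is_path=True)
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon}
    keep = [t for t in counts.columns if t in tips]
    missing = [t for t in counts.columns if t not in tips]
    if missing:
        logger.warning(
            "dropping %d taxa absent from the tree (e.g. %s)",
            len(missing),
            missing[:5],
        )
    if not keep:
        raise ValueError("no taxa shared between count table and tree")
    counts = counts[keep]

    if config.family == "binary" and not np.all(np.isin(np.unique(y), [0.0, 1.0])):
        raise ValueError("family=binary requires a 0/1 outcome")

    table = OTUTable.from_dataframe(
        counts, mode="proportions" if config.proportions else "counts"
    )
    X = np.column_stack([np.ones(table.n)] + ([cov.loc[common].to_numpy(dtype=float)] if cov is not None else []))
    return table, tree, y, X


def write_results(df: pd.DataFrame, path: Path, precision: str = "short") -> None:
    """Write the results table as TSV (6 significant digits unless full)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if precision == "short":
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    else:
        df.to_csv(path, sep="\t", index=False)


def run_post(config: RunConfig) -> pd.DataFrame:
    """Execute the full pipeline described by ``config`` and write results.

    A JSON run manifest (configuration, versions, seed) is written next to
    the results file for reproducibility.
    """
    import postkm

    table, tree, y, X = load_inputs(config)
    # intercept is already in X; POST prepends one, so strip it here
    covars = X[:, 1:] if X.shape[1] > 1 else None
    model = POST(
        table,
        tree,
        y,
        covars,
        family=config.family,
        c_grid=config.c_grid,
        pseudo=config.pseudo,
        alpha=config.alpha,
    )
    res = model.fit()
    df = res.summary(include_per_c=config.per_c)
    write_results(df, config.output, precision=config.precision)
    manifest = {
        "package": "postkm",
        "version": getattr(postkm, "__version__", "unknown"),
        "python": platform.python_version(),
        "numpy": np.__version__,
        "family": config.family,
        "c_grid": list(config.c_grid),
        "alpha": config.alpha,
        "pseudo": config.pseudo,
        "seed": config.seed,
        "n_samples": table.n,
        "n_taxa": table.M,
        "single_otu_test": list(config.c_grid) == [0.0],
    }
    Path(config.output).with_suffix(".manifest.json").write_text(
        json.dumps(manifest, indent=2)
    )
    return df
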