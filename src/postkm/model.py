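"""Model/results objects for the phylogeny-guided OTU association test.

``POST`` bundles the inputs (count table, tree, outcome, covariates) and
configuration (decay grid, pseudo-count, FDR level); ``fit()`` runs the
per-OTU kernel score tests and returns a ``POSTResults`` carrying raw and
FDR-adjusted p-values, the data-selected decay value per taxon, and a
summary table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .kernels import OTUTable
from .multtest import tsbh_adjust
from .score import DEFAULT_C_GRID, TestResult, post_test
from .tree import PhyloDistance, cophenetic_distances

__all__ = ["POST", "POSTResults"]


class POST:
    """Phylogeny-guided OTU-specific association test.

    Parameters
    ----------
    table : OTUTable
        Samples x taxa abundances (counts or proportions).
    tree : dendropy.Tree or PhyloDistance
        Phylogeny over (at least) the table's taxa, or a precomputed
        patristic distance matrix.
    y : array-like
        Outcome vector, aligned with the table's samples.
    X : array-like, optional
        Covariate matrix *without* intercept; an intercept column is
        prepended.  ``None`` means intercept-only.
    family : {"continuous", "binary"}
    c_grid : sequence of float
        Decay-parameter grid; default ``(0, 0.01, ..., 0.05)``.
    pseudo : float, optional
        Pseudo-count before the CLR transform (default 0.5 for counts,
        1e-6 for proportions).
    alpha : float
        Target FDR level for the two-stage BH adjustment.

    Examples
    --------
    >>> model = POST(table, tree, y, family="binary")
    >>> res = model.fit()
    >>> res.summary().head()
    """

    def __init__(
        self,
        table: OTUTable,
        tree,
        y,
        X=None,
        *,
        family: str = "continuous",
        c_grid=DEFAULT_C_GRID,
        pseudo: float | None = None,
        alpha: float = 0.05,
        s_convention: str = "all-entries",
    ):
        self.table = table
        self.y = np.asarray(y, dtype=float).ravel()
        if X is None:
            self.X = np.ones((table.n, 1))
        else:
            X = np.atleast_2d(np.asarray(X, dtype=float))
            if X.shape[0] != table.n:
                raise ValueError("covariate rows do not match number of samples")
            self.X = np.column_stack([np.ones(table.n), X])
        self.family = family
        self.c_grid = [float(c) for c in c_grid]
        self.pseudo = pseudo
        self.alpha = alpha
        if isinstance(tree, PhyloDistance):
            self.dist = tree
        else:
            self.dist = cophenetic_distances(
                tree, list(table.taxa), s_convention=s_convention
            )

    @classmethod
    def from_dataframes(
        cls,
        counts: pd.DataFrame,
        tree,
        outcome: pd.Series,
        covariates: pd.DataFrame | None = None,
        **kwargs,
    ) -> "POST":
        """Build from pandas objects, aligning samples by index."""
        common = counts.index.intersection(outcome.index)
        if covariates is not None:
            common = common.intersection(covariates.index)
        if len(common) == 0:
            raise ValueError("no samples shared between counts and outcome")
        counts = counts.loc[common]
        table = OTUTable.from_dataframe(counts, mode=kwargs.pop("mode", "counts"))
        X = covariates.loc[common].to_numpy(dtype=float) if covariates is not None else None
        return cls(table, tree, outcome.loc[common].to_numpy(dtype=float), X, **kwargs)

    def fit(self) -> "POSTResults":
        results = post_test(
            self.table,
            self.dist,
            self.y,
            self.X,
            family=self.family,
            c_grid=self.c_grid,
            pseudo=self.pseudo,
        )
        pvals = np.array([r.p_combined for r in results])
        adj = tsbh_adjust(pvals, alpha=self.alpha)
        for r, a in zip(results, adj.adjusted):
            r.p_adjusted = float(a)
        return POSTResults(self, results, adj.m0_hat)


class POSTResults:
    """Fitted per-OTU test results.

    Attributes
    ----------
    results : list of TestResult
        Per-taxon records (grid p-values, combined p, selected decay).
    pvalues, pvalues_adjusted : ndarray
    best_c : ndarray
    m0_hat : int
        Stage-1 estimate of the number of null taxa used by TSBH.
    """

    def __init__(self, model: POST, results: list[TestResult], m0_hat: int):
        self.model = model
        self.results = results
        self.m0_hat = m0_hat
        self.taxa = [r.taxon for r in results]
        self.pvalues = np.array([r.p_combined for r in results])
        self.pvalues_adjusted = np.array(
            [np.nan if r.p_adjusted is None else r.p_adjusted for r in results]
        )
        self.best_c = np.array([r.best_c for r in results])

    def summary(self, *, include_per_c: bool = False) -> pd.DataFrame:
        """Per-taxon table sorted by adjusted then raw p-value."""
        df = pd.DataFrame(
            {
                "taxon": self.taxa,
                "p_raw": self.pvalues,
                "best_c": self.best_c,
                "p_adjusted": self.pvalues_adjusted,
            }
        )
        if include_per_c:
            for j, c in enumerate(self.model.c_grid):
                df[f"p_c{c:g}"] = [
                    r.per_c[j][2] if len(r.per_c) > j else np.nan for r in self.results
                ]
        return df.sort_values(
            ["p_adjusted", "p_raw"], kind="stable", na_position="last"
        ).reset_index(drop=True)

    def significant(self, alpha: float | None = None) -> list[str]:
        """Taxa with FDR-adjusted p below the target level."""
        level = self.model.alpha if alpha is None else alpha
        return [t for t, a in zip(self.taxa, self.pvalues_adjusted) if a < level]

    def plot_pvalues(self, ax=None):
        """-log10 raw p-values in taxon order, with the FDR threshold."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        ax.scatter(
            np.arange(len(self.taxa)), -np.log10(self.pvalues), s=8, color="#2b6cb0"
        )
        sig = self.pvalues_adjusted < self.model.alpha
        if sig.any():
            thr = np.max(self.pvalues[sig])
            ax.axhline(-np.log10(thr), ls="--", color="#c53030", lw=0.8)
        ax.set_xlabel("taxon index (tree order)")
        ax.set_ylabel(r"$-\log_{10} p$")
        return ax

    def plot_qq(self, ax=None):
        """Q-Q plot of raw p-values against Uniform(0,1)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        p = np.sort(self.pvalues[np.isfinite(self.pvalues)])
        exp = (np.arange(1, p.size + 1) - 0.5) / p.size
        ax.plot(-np.log10(exp), -np.log10(p), ".", ms=4)
        lim = max(-np.log10(exp[0]), -np.log10(p[0] if p[0] > 0 else 1e-16))
        ax.plot([0, lim], [0, lim], "k--", lw=0.8)
        ax.set_xlabel(r"expected $-\log_{10} p$")
        ax.set_ylabel(r"observed $-\log_{10} p$")
        return ax
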