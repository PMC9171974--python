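"""Compositional transforms and OTU-specific local kernels.

Microbiome abundances are compositional: only relative information is
meaningful.  The centered log-ratio (CLR) transform maps each sample's
abundance vector to ``log(z / geometric_mean(z))`` after pseudo-count
addition; Euclidean distance on CLR rows is the Aitchison distance.  For a
focal taxon ``m`` the *local* Aitchison distance down-weights remote taxa by
phylogenetic correlation weights ``r_lm``:

    A^m_ij = sqrt( sum_l r_lm * (z*_il - z*_jl)^2 ),

a weighted Euclidean metric.  Gower double centering of the squared distance
matrix yields the positive semidefinite similarity kernel
``K = -1/2 C A^2 C`` with ``C = I - 11'/n``, which is exactly the centered
Gram matrix of the weight-scaled CLR coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .tree import CorrelationVector, PhyloDistance, phylo_correlation

__all__ = [
    "OTUTable",
    "CLRMatrix",
    "LocalDistance",
    "LocalKernel",
    "clr_transform",
    "local_aitchison",
    "gower_center",
    "build_local_kernels",
    "local_kernel_factor",
]

logger = logging.getLogger(__name__)

DEFAULT_PSEUDO_COUNT = 0.5
DEFAULT_PSEUDO_PROPORTION = 1e-6


@dataclass
class OTUTable:
    """Samples x taxa abundance matrix (counts or proportions).

    Fold-change-perturbed count tables are real-valued; any non-negative
    matrix is accepted.
    """

    samples: list[str]
    taxa: list[str]
    Z: np.ndarray
    mode: str = "counts"  # "counts" | "proportions"

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        n, M = len(self.samples), len(self.taxa)
        if self.Z.shape != (n, M):
            raise ValueError(f"abundance matrix shape {self.Z.shape} != ({n}, {M})")
        if not np.all(np.isfinite(self.Z)):
            raise ValueError("non-finite abundance values")
        if np.any(self.Z < 0):
            raise ValueError("negative abundance values")
        if self.mode not in ("counts", "proportions"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "proportions" and np.any(self.Z.sum(axis=1) > 1.0 + 1e-6):
            raise ValueError("proportions-mode rows must sum to <= 1")

    @property
    def n(self) -> int:
        return len(self.samples)

    @property
    def M(self) -> int:
        return len(self.taxa)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, mode: str = "counts") -> "OTUTable":
        """Build from a samples-in-rows, taxa-in-columns DataFrame."""
        return cls(
            samples=[str(s) for s in df.index],
            taxa=[str(t) for t in df.columns],
            Z=df.to_numpy(dtype=float),
            mode=mode,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.Z, index=self.samples, columns=self.taxa)

    @classmethod
    def read_tsv(
        cls,
        path: str | Path,
        *,
        sep: str = "\t",
        transpose: bool = False,
        mode: str = "counts",
    ) -> "OTUTable":
        """Read a TSV/CSV table: first column sample IDs, header taxon IDs.

        ``transpose=True`` accepts the taxa-in-rows dialect.
        """
        df = pd.read_csv(path, sep=sep, index_col=0)
        if transpose:
            df = df.T
        return cls.from_dataframe(df, mode=mode)

    def restrict_taxa(self, taxa: list[str]) -> "OTUTable":
        idx = [self.taxa.index(t) for t in taxa]
        return OTUTable(self.samples, list(taxa), self.Z[:, idx], self.mode)


@dataclass
class CLRMatrix:
    """Centered log-ratio transformed abundances; rows sum to zero."""

    samples: list[str]
    taxa: list[str]
    Zstar: np.ndarray


@dataclass
class LocalDistance:
    """Local Aitchison distance matrix for a focal taxon at decay ``c``."""

    focal: str
    c: float
    A: np.ndarray


@dataclass
class LocalKernel:
    """Gower-centered similarity kernel for a focal taxon at decay ``c``."""

    focal: str
    c: float
    K: np.ndarray


def clr_transform(table: OTUTable, pseudo: float | None = None) -> CLRMatrix:
    """Centered log-ratio transform with pseudo-count addition.

    A pseudo-count (default 0.5 for counts, 1e-6 for proportions) is added
    before taking logs so zeros are defined; CLR is invariant to row scaling
    so proportions are not renormalized afterwards.  All-zero samples become
    constant rows and transform to the zero CLR row (logged as a warning).
    """
    if pseudo is None:
        pseudo = DEFAULT_PSEUDO_COUNT if table.mode == "counts" else DEFAULT_PSEUDO_PROPORTION
    if pseudo <= 0:
        raise ValueError("pseudo-count must be positive")
    if table.n == 0 or table.M == 0:
        raise ValueError("empty abundance table")
    zero_rows = np.where(table.Z.sum(axis=1) == 0)[0]
    if zero_rows.size:
        logger.warning("%d all-zero sample(s); CLR rows will be zero", zero_rows.size)
    logz = np.log(table.Z + pseudo)
    Zstar = logz - logz.mean(axis=1, keepdims=True)
    return CLRMatrix(samples=table.samples, taxa=table.taxa, Zstar=Zstar)


def local_aitchison(clr: CLRMatrix, weights: CorrelationVector) -> LocalDistance:
    """Weighted Euclidean (local Aitchison) distances between samples.

    With the indicator weight vector this is ``|z*_im - z*_jm|``; with
    all-ones weights it is the full Aitchison distance.
    """
    r = np.asarray(weights.r, dtype=float)
    if r.shape[0] != clr.Zstar.shape[1]:
        raise ValueError(
            f"weight length {r.shape[0]} != number of taxa {clr.Zstar.shape[1]}"
        )
    active = np.flatnonzero(r > 0)
    Y = clr.Zstar[:, active] * np.sqrt(r[active])
    sq = np.sum(Y**2, axis=1)
    A2 = sq[:, None] + sq[None, :] - 2.0 * (Y @ Y.T)
    np.maximum(A2, 0.0, out=A2)
    np.fill_diagonal(A2, 0.0)
    A = np.sqrt(A2)
    A = 0.5 * (A + A.T)
    return LocalDistance(focal=weights.focal, c=weights.c, A=A)


def gower_center(dist: LocalDistance) -> LocalKernel:
    """Gower double centering: ``K = -1/2 C (A o A) C``, ``C = I - 11'/n``.

    Row and column sums of K are zero; for a Euclidean distance matrix K is
    the centered Gram matrix of the underlying coordinates (hence PSD).
    """
    A = np.asarray(dist.A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(A, A.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    A2 = A**2
    row_mean = A2.mean(axis=1, keepdims=True)
    grand = A2.mean()
    K = -0.5 * (A2 - row_mean - row_mean.T + grand)
    K = 0.5 * (K + K.T)
    return LocalKernel(focal=dist.focal, c=dist.c, K=K)


def local_kernel_factor(
    clr: CLRMatrix, weights: CorrelationVector
) -> np.ndarray:
    """Centered, weight-scaled CLR coordinates ``Yc`` with ``K = Yc @ Yc.T``.

    The local Aitchison distance is Euclidean in the coordinates
    ``Y = Zstar * sqrt(r)`` (taxa with zero weight dropped), so the Gower
    kernel equals the column-centered Gram matrix ``Yc Yc'``.  Returning the
    n x m_active factor instead of the n x n kernel lets downstream
    eigencomputations work on the small side.
    """
    r = np.asarray(weights.r, dtype=float)
    if r.shape[0] != clr.Zstar.shape[1]:
        raise ValueError("weight length mismatch")
    active = np.flatnonzero(r > 0)
    Y = clr.Zstar[:, active] * np.sqrt(r[active])
    return Y - Y.mean(axis=0, keepdims=True)


def build_local_kernels(
    table: OTUTable,
    dist: PhyloDistance,
    focal: str,
    c_grid: list[float],
    *,
    pseudo: float | None = None,
) -> list[LocalKernel]:
    """One Gower-centered local kernel per decay value, in grid order.

    Kernels are recomputed only when the weight vector changes between
    consecutive grid values.
    """
    if focal not in table.taxa:
        raise KeyError(f"focal taxon {focal!r} not in abundance table")
    if list(table.taxa) != list(dist.taxa):
        raise ValueError("table taxa and distance-matrix taxa must match in order")
    clr = clr_transform(table, pseudo=pseudo)
    kernels: list[LocalKernel] = []
    prev_r: np.ndarray | None = None
    prev_K: np.ndarray | None = None
    for c in c_grid:
        w = phylo_correlation(dist, focal, c)
        if prev_r is not None and np.array_equal(w.r, prev_r):
            K = prev_K
        else:
            Yc = local_kernel_factor(clr, w)
            K = Yc @ Yc.T
            prev_r, prev_K = w.r, K
        kernels.append(LocalKernel(focal=focal, c=float(c), K=K))
    return kernels
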