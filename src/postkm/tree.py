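"""Phylogenetic distances and decay-parameterized OTU correlation weights.

A phylogenetic tree relates the tested taxa; the patristic (cophenetic)
distance ``d_lm`` between two tips is the sum of branch lengths along the
unique tip-to-tip path.  Distances are converted to correlation weights with
a Gaussian decay

    r_lm = exp(-d_lm**2 / (c * s)),

where ``s`` is the standard deviation of the pairwise distances and ``c`` a
non-negative decay parameter measured in units of distance SD.  ``c = 0``
gives the focal-taxon indicator (no information borrowing); large ``c``
approaches all-ones weights (community-level pooling).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "PhyloDistance",
    "CorrelationVector",
    "read_newick",
    "cophenetic_distances",
    "phylo_correlation",
    "correlation_matrix",
]

#: weights below this are truncated to exactly zero (sparse neighborhoods)
WEIGHT_TOL = 1e-12


@dataclass
class PhyloDistance:
    """Pairwise patristic distances among an ordered set of taxa.

    Attributes
    ----------
    taxa : list of str
        Taxon labels in matrix order.
    D : ndarray, shape (M, M)
        Symmetric patristic distance matrix with zero diagonal.
    s : float
        Standard deviation of the distances, the scale on which the decay
        parameter ``c`` is measured.  See ``s_convention``.
    s_convention : {"all-entries", "upper-triangle"}
        Whether ``s`` is the sample SD over all M*M matrix entries
        (including the zero diagonal; each unordered pair counted twice) or
        over the strict upper triangle only.
    """

    taxa: list[str]
    D: np.ndarray
    s: float = field(init=False)
    s_convention: str = "all-entries"

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        M = len(self.taxa)
        if self.D.shape != (M, M):
            raise ValueError(f"distance matrix shape {self.D.shape} != ({M}, {M})")
        if not np.allclose(self.D, self.D.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(self.D < 0):
            raise ValueError("negative patristic distance")
        self.s = _distance_sd(self.D, self.s_convention)

    def index(self, taxon: str) -> int:
        try:
            return self.taxa.index(taxon)
        except ValueError:
            raise KeyError(f"taxon {taxon!r} not in distance matrix") from None

    def restrict(self, taxa: list[str]) -> "PhyloDistance":
        """Subset/reorder to the given taxa (``s`` recomputed on the subset)."""
        missing = [t for t in taxa if t not in self.taxa]
        if missing:
            raise KeyError(f"taxa absent from distance matrix: {missing}")
        idx = [self.taxa.index(t) for t in taxa]
        return PhyloDistance(
            taxa=list(taxa), D=self.D[np.ix_(idx, idx)], s_convention=self.s_convention
        )


@dataclass
class CorrelationVector:
    """Decay weights ``r_lm`` of every taxon toward a focal taxon ``m``."""

    focal: str
    c: float
    taxa: list[str]
    r: np.ndarray


def _distance_sd(D: np.ndarray, convention: str) -> float:
    if convention == "all-entries":
        return float(np.std(D, ddof=1))
    if convention == "upper-triangle":
        iu = np.triu_indices(D.shape[0], k=1)
        return float(np.std(D[iu], ddof=1))
    raise ValueError(f"unknown s convention {convention!r}")


def read_newick(source: str, *, is_path: bool | None = None) -> dendropy.Tree:
    """Read a rooted or unrooted Newick tree with branch lengths.

    Parameters
    ----------
    source : str
        Path to a Newick file, or a Newick string (auto-detected by the
        presence of parentheses unless ``is_path`` is given).
    """
    if is_path is None:
        is_path = "(" not in source
    kwargs = {"path": source} if is_path else {"data": source}
    tree = dendropy.Tree.get(schema="newick", preserve_underscores=True, **kwargs)
    return tree


def cophenetic_distances(
    tree: dendropy.Tree,
    taxa: list[str] | None = None,
    *,
    s_convention: str = "all-entries",
) -> PhyloDistance:
    """Pairwise tip-to-tip path-length distances for the requested taxa.

    Parameters
    ----------
    tree : dendropy.Tree
        Tree with branch lengths; missing lengths are treated as zero.
    taxa : list of str, optional
        Ordered subset of tip labels.  Defaults to all tips in tree order.

    Raises
    ------
    KeyError
        If a requested taxon is not a tip of the tree.
    ValueError
        If fewer than two taxa are requested (degenerate tree).
    """
    tip_map = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter() if leaf.taxon}
    if taxa is None:
        taxa = [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon]
    missing = [t for t in taxa if t not in tip_map]
    if missing:
        raise KeyError(f"taxa absent from tree: {missing}")
    M = len(taxa)
    if M < 2:
        raise ValueError("need at least two taxa for a distance matrix")
    pdm = tree.phylogenetic_distance_matrix()
    D = np.zeros((M, M))
    tax_objs = [tip_map[t].taxon for t in taxa]
    for i in range(M):
        for j in range(i + 1, M):
            D[i, j] = D[j, i] = pdm.patristic_distance(tax_objs[i], tax_objs[j])
    return PhyloDistance(taxa=list(taxa), D=D, s_convention=s_convention)


def phylo_correlation(
    dist: PhyloDistance, focal: str, c: float, *, truncate: float = WEIGHT_TOL
) -> CorrelationVector:
    """Gaussian-decay correlation weights of all taxa toward ``focal``.

    ``r_lm = exp(-d_lm^2 / (c*s))`` for ``c > 0``; ``c = 0`` returns the
    indicator vector at the focal taxon.  Weights below ``truncate`` are set
    to exactly zero.
    """
    if c < 0:
        raise ValueError("decay parameter c must be non-negative")
    m = dist.index(focal)
    M = len(dist.taxa)
    if c == 0:
        r = np.zeros(M)
        r[m] = 1.0
        return CorrelationVector(focal=focal, c=0.0, taxa=dist.taxa, r=r)
    if dist.s <= 0:
        raise ValueError("degenerate tree: distance SD is not positive")
    d = dist.D[m]
    r = np.exp(-(d**2) / (c * dist.s))
    r[r < truncate] = 0.0
    r[m] = 1.0
    return CorrelationVector(focal=focal, c=float(c), taxa=dist.taxa, r=r)


def correlation_matrix(
    dist: PhyloDistance, c: float, *, truncate: float = WEIGHT_TOL
) -> np.ndarray:
    """All-focal weight matrix R with ``R[l, m] = r_lm`` at a single ``c``."""
    M = len(dist.taxa)
    if c < 0:
        raise ValueError("decay parameter c must be non-negative")
    if c == 0:
        return np.eye(M)
    if dist.s <= 0:
        raise ValueError("degenerate tree: distance SD is not positive")
    R = np.exp(-(dist.D**2) / (c * dist.s))
    R[R < truncate] = 0.0
    np.fill_diagonal(R, 1.0)
    return R
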