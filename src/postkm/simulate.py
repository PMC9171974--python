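"""Dirichlet-multinomial simulation study for the OTU-specific kernel test.

Counts are modelled as Dirichlet-multinomial (DM): per-subject proportions
are Dirichlet with mean ``pi`` and over-dispersion ``theta`` (concentration
``alpha = pi * (1 - theta) / theta``), sequencing depth is negative binomial
(mean 10,000, size 25), and counts are multinomial given both.  Outcome
models:

* design A — case/control fold change: case counts are multiplied by
  ``exp(beta_m)`` with ``beta_m ~ N(+/-nu, 1)`` for causal taxa;
* design B — linear predictor
  ``eta_i = 0.5 w (scale(x1) + scale(x2)) + sum_m beta_m scale(z_im)`` with
  ``beta_m ~ N(+/-nu, nu/5)`` (variance), continuous ``y ~ N(eta, 1)`` or
  binary ``y ~ Bernoulli(expit(eta))``; ``x2`` is correlated with the causal
  taxa through its mean.

Causal taxa are placed as "hubs" of phylogenetically adjacent tips: the
taxa are partitioned into 20 clusters by k-medoids (PAM-style) on the
cophenetic distance, and hubs are drawn from the 8 most abundant clusters
(scenarios 1-4) or uniformly at random (scenario 5).

The module doubles as the repository's synthetic-fixture source: a bundled
log-normal DM parameter set and a two-level coalescent tree generator stand
in for real 16S reference data, which this package does not ship.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.special import expit, gammaln, polygamma, psi

from .kernels import OTUTable
from .multtest import tsbh_adjust
from .tree import PhyloDistance, cophenetic_distances, read_newick

__all__ = [
    "DMParams",
    "ScenarioSpec",
    "SimReplicate",
    "MetricSummary",
    "fit_dirichlet_multinomial",
    "dm_loglik",
    "dm_standard_errors",
    "generate_counts",
    "select_causal",
    "simulate_A",
    "simulate_B",
    "evaluate_selection",
    "cmax_calibration",
    "synthetic_params",
    "synthetic_tree",
]

logger = logging.getLogger(__name__)

DEPTH_MEAN = 10_000.0
DEPTH_SIZE = 25.0


def _scale(v: np.ndarray) -> np.ndarray:
    """Standardize to mean 0, SD 1 (sample SD, as in R's ``scale``)."""
    v = np.asarray(v, dtype=float)
    sd = np.std(v, ddof=1)
    if sd == 0:
        raise ValueError("cannot scale a constant vector")
    return (v - v.mean()) / sd


@dataclass
class DMParams:
    """Dirichlet-multinomial mean proportions and over-dispersion."""

    pi: np.ndarray
    theta: float

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        if np.any(self.pi <= 0):
            raise ValueError("mean proportions must be positive")
        if abs(self.pi.sum() - 1.0) > 1e-8:
            raise ValueError("mean proportions must sum to 1")
        if not (0.0 <= self.theta < 1.0):
            raise ValueError("over-dispersion theta must be in [0, 1)")

    @property
    def M(self) -> int:
        return self.pi.size

    @property
    def alpha(self) -> np.ndarray:
        """Dirichlet concentration vector ``pi * (1 - theta) / theta``."""
        if self.theta == 0:
            raise ValueError("theta = 0 is the multinomial limit (no Dirichlet)")
        return self.pi * (1.0 - self.theta) / self.theta


@dataclass
class ScenarioSpec:
    """Causal-taxon placement and effect-sign pattern for one scenario."""

    scenario: int
    nu: float
    causal_set: np.ndarray  # taxon indices
    hub_assignment: np.ndarray  # hub id per causal taxon (-1 for scenario 5)
    signs: np.ndarray  # +1 / -1 per causal taxon
    hub_size_range: tuple[int, int] | None

    @property
    def n_causal(self) -> int:
        return self.causal_set.size

    def causal_flags(self, M: int) -> np.ndarray:
        flags = np.zeros(M, dtype=bool)
        flags[self.causal_set] = True
        return flags


@dataclass
class SimReplicate:
    """One simulated dataset: abundances, outcome, covariates, truth."""

    Z: OTUTable
    y: np.ndarray
    X: np.ndarray | None
    beta: np.ndarray
    causal_flags: np.ndarray
    seed: int


@dataclass
class MetricSummary:
    """Selection-performance summary across replicates."""

    tpr: float
    fpr: float
    pseudo_f: float
    roc: np.ndarray  # (n_thresholds, 2) columns (mean FPR, mean TPR)
    auc: float


# ---------------------------------------------------------------------------
# Dirichlet-multinomial fitting


def dm_loglik(alpha: np.ndarray, counts: np.ndarray) -> float:
    """Dirichlet-multinomial log-likelihood (up to the multinomial constant)."""
    alpha = np.asarray(alpha, dtype=float)
    a0 = alpha.sum()
    N = counts.sum(axis=1)
    ll = np.sum(gammaln(a0) - gammaln(N + a0))
    ll += np.sum(gammaln(counts + alpha) - gammaln(alpha))
    return float(ll)


def fit_dirichlet_multinomial(
    counts: OTUTable | np.ndarray,
    *,
    max_iter: int = 2000,
    tol: float = 1e-10,
) -> DMParams:
    """Maximum-likelihood DM parameters by Minka's fixed-point iteration.

    The fixed point ``alpha_l <- alpha_l * num_l / den`` with
    ``num_l = sum_i [psi(x_il + alpha_l) - psi(alpha_l)]`` and
    ``den = sum_i [psi(N_i + a0) - psi(a0)]`` increases the likelihood
    monotonically.  Returns ``pi = alpha / a0`` and ``theta = 1/(1 + a0)``.
    """
    X = counts.Z if isinstance(counts, OTUTable) else np.asarray(counts, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D count matrix with at least two samples")
    if np.any(X < 0) or np.any(np.abs(X - np.round(X)) > 1e-9):
        raise ValueError("counts must be non-negative integers")
    n, M = X.shape
    N = X.sum(axis=1)
    props = X / N[:, None]
    pbar = props.mean(axis=0)
    pbar = np.maximum(pbar, 1e-12)
    pbar /= pbar.sum()
    # moment initialization of the total concentration
    v = props.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        theta0 = np.nanmedian(v / (pbar * (1.0 - pbar)))
    theta0 = float(np.clip(theta0 if np.isfinite(theta0) else 0.05, 1e-4, 0.9))
    alpha = pbar * (1.0 - theta0) / theta0
    ll_prev = dm_loglik(alpha, X)
    for it in range(max_iter):
        a0 = alpha.sum()
        num = psi(X + alpha).sum(axis=0) - n * psi(alpha)
        den = np.sum(psi(N + a0)) - n * psi(a0)
        if den <= 0:
            raise RuntimeError("DM fixed-point iteration hit a degenerate denominator")
        alpha_new = alpha * num / den
        alpha_new = np.maximum(alpha_new, 1e-12)
        ll = dm_loglik(alpha_new, X)
        rel = np.max(np.abs(alpha_new - alpha)) / max(alpha.max(), 1.0)
        theta_step = abs(1.0 / (1.0 + alpha_new.sum()) - 1.0 / (1.0 + alpha.sum()))
        alpha = alpha_new
        if rel < tol or theta_step < 1e-12 or abs(ll - ll_prev) < tol * max(abs(ll), 1.0):
            break
        ll_prev = ll
    else:
        # near the multinomial boundary (theta -> 0) the concentration grows
        # without an interior optimum; accept the boundary estimate
        if 1.0 / (1.0 + alpha.sum()) > 1e-4:
            raise RuntimeError(
                f"DM MLE did not converge after {max_iter} iterations "
                f"(last relative step {rel:.2e})"
            )
    a0 = alpha.sum()
    return DMParams(pi=alpha / a0, theta=1.0 / (1.0 + a0))


def dm_standard_errors(
    counts: OTUTable | np.ndarray, params: DMParams
) -> tuple[np.ndarray, float]:
    """Delta-method SEs of ``(pi, theta)`` from the observed information.

    The DM Hessian in concentration space is diagonal plus a rank-one
    common term, so the covariance inverts in closed form via
    Sherman-Morrison.
    """
    X = counts.Z if isinstance(counts, OTUTable) else np.asarray(counts, dtype=float)
    N = X.sum(axis=1)
    alpha = params.alpha
    a0 = alpha.sum()
    # H = c * 11' + diag(b); -H = diag(-b) - c 11'
    c = X.shape[0] * polygamma(1, a0) - np.sum(polygamma(1, N + a0))
    b = polygamma(1, X + alpha).sum(axis=0) - X.shape[0] * polygamma(1, alpha)
    d = -b  # positive
    if np.any(d <= 0):
        raise RuntimeError("observed information is not positive definite")
    u = 1.0 / d
    s = u.sum()
    k = c / (1.0 - c * s)
    # Cov = diag(u) + k u u'
    var_a0 = s + k * s * s
    se_theta = np.sqrt(var_a0) / (1.0 + a0) ** 2
    cov_diag = u + k * u * u
    cov_row1 = u + k * u * s  # (Cov 1)_l
    var_pi = (
        cov_diag / a0**2
        - 2.0 * alpha * cov_row1 / a0**3
        + alpha**2 * var_a0 / a0**4
    )
    return np.sqrt(np.maximum(var_pi, 0.0)), float(se_theta)


# ---------------------------------------------------------------------------
# generators


def generate_counts(
    params: DMParams,
    n: int,
    *,
    depth_mean: float = DEPTH_MEAN,
    depth_size: float = DEPTH_SIZE,
    seed: int | np.random.Generator = 0,
) -> OTUTable:
    """Simulate an n x M DM count table with negative-binomial depths.

    Per subject: proportions ~ Dirichlet(alpha), depth ~ NegBin(mean
    ``depth_mean``, size ``depth_size``), counts ~ Multinomial.
    ``theta = 0`` degenerates to plain multinomial sampling at ``pi``.
    """
    if n < 1:
        raise ValueError("need at least one sample")
    rng = np.random.default_rng(seed)
    if params.theta > 0:
        P = rng.dirichlet(params.alpha, size=n)
    else:
        P = np.tile(params.pi, (n, 1))
    nb_p = depth_size / (depth_size + depth_mean)
    depths = rng.negative_binomial(depth_size, nb_p, size=n)
    depths = np.maximum(depths, 1)
    Z = np.empty((n, params.M), dtype=float)
    for i in range(n):
        Z[i] = rng.multinomial(depths[i], P[i])
    samples = [f"S{i+1}" for i in range(n)]
    taxa = [f"OTU{m+1}" for m in range(params.M)]
    return OTUTable(samples=samples, taxa=taxa, Z=Z, mode="counts")


def _k_medoids(D: np.ndarray, k: int, rng: np.random.Generator, n_iter: int = 100):
    """PAM-style k-medoids by alternating assignment and medoid update."""
    M = D.shape[0]
    medoids = rng.choice(M, size=k, replace=False)
    labels = np.argmin(D[:, medoids], axis=1)
    for _ in range(n_iter):
        new_medoids = medoids.copy()
        for j in range(k):
            members = np.flatnonzero(labels == j)
            if members.size == 0:
                continue
            within = D[np.ix_(members, members)].sum(axis=1)
            new_medoids[j] = members[np.argmin(within)]
        new_labels = np.argmin(D[:, new_medoids], axis=1)
        if np.array_equal(new_medoids, medoids) and np.array_equal(new_labels, labels):
            break
        medoids, labels = new_medoids, new_labels
    return labels, medoids


def select_causal(
    tree: "dendropy.Tree | PhyloDistance",
    params: DMParams,
    scenario: int,
    nu: float,
    *,
    n_clusters: int = 20,
    n_hubs: int = 8,
    seed: int | np.random.Generator = 0,
) -> ScenarioSpec:
    """Choose causal taxa and effect signs for one of the five scenarios.

    Taxa are partitioned into ``n_clusters`` k-medoids clusters on the
    cophenetic distance; clusters are ranked by summed mean proportion and
    hubs are drawn from the top ``n_hubs``.  A hub is the block of tips
    nearest its cluster medoid.  Hub sizes: 7-10 (scenarios 1-3), 2-3
    (scenario 4); scenario 5 samples the same total number of causal taxa
    uniformly over all taxa.  Signs: 1 = all positive; 2 and 4 = half the
    hubs positive, half negative; 3 and 5 = a random half of causal taxa
    negative.
    """
    rng = np.random.default_rng(seed)
    dist = tree if isinstance(tree, PhyloDistance) else cophenetic_distances(tree)
    M = len(dist.taxa)
    if M < n_clusters:
        raise ValueError(f"need at least {n_clusters} taxa, got {M}")
    if params.M != M:
        raise ValueError("DM parameters and tree cover different numbers of taxa")
    if scenario not in (1, 2, 3, 4, 5):
        raise ValueError("scenario must be 1-5")
    labels, medoids = _k_medoids(dist.D, n_clusters, rng)
    cluster_mass = np.array(
        [params.pi[labels == j].sum() for j in range(n_clusters)]
    )
    top = np.argsort(cluster_mass)[::-1][:n_hubs]
    size_range = (7, 10) if scenario in (1, 2, 3) else (2, 3) if scenario == 4 else None

    if scenario == 5:
        sizes = rng.integers(7, 11, size=n_hubs)  # match scenarios 1-3 count
        n_causal = min(int(sizes.sum()), M)
        causal = rng.choice(M, size=n_causal, replace=False)
        hub_ids = np.full(n_causal, -1)
    else:
        causal_list, hub_list = [], []
        for h, j in enumerate(top):
            members = np.flatnonzero(labels == j)
            size = int(rng.integers(size_range[0], size_range[1] + 1))
            size = min(size, members.size)
            nearest = members[np.argsort(dist.D[medoids[j], members])][:size]
            causal_list.append(nearest)
            hub_list.append(np.full(size, h))
        causal = np.concatenate(causal_list)
        hub_ids = np.concatenate(hub_list)

    n_causal = causal.size
    signs = np.ones(n_causal)
    if scenario in (2, 4):
        neg_hubs = rng.permutation(n_hubs)[: n_hubs // 2]
        signs[np.isin(hub_ids, neg_hubs)] = -1.0
    elif scenario in (3, 5):
        neg = rng.permutation(n_causal)[: n_causal // 2]
        signs[neg] = -1.0
    return ScenarioSpec(
        scenario=scenario,
        nu=float(nu),
        causal_set=causal,
        hub_assignment=hub_ids,
        signs=signs,
        hub_size_range=size_range,
    )


def simulate_A(
    Z: OTUTable, spec: ScenarioSpec, *, seed: int | np.random.Generator = 0
) -> SimReplicate:
    """Case/control fold-change outcome model (design A).

    The first half of the samples are cases (y = 1); their counts are
    multiplied taxon-wise by ``exp(beta_m)`` with ``beta_m ~ N(sign * nu, 1)``
    for causal taxa and 0 otherwise.  Control rows are untouched.  The
    perturbed table is real-valued by construction.
    """
    if Z.n % 2 != 0:
        raise ValueError("design A needs an even number of samples")
    rng = np.random.default_rng(seed)
    M = Z.M
    beta = np.zeros(M)
    if spec.n_causal:
        beta[spec.causal_set] = rng.normal(spec.signs * spec.nu, 1.0)
    n_case = Z.n // 2
    y = np.concatenate([np.ones(n_case), np.zeros(Z.n - n_case)])
    Znew = Z.Z.copy()
    Znew[:n_case] *= np.exp(beta)[None, :]
    table = OTUTable(Z.samples, Z.taxa, Znew, mode=Z.mode)
    seed_val = seed if isinstance(seed, int) else -1
    return SimReplicate(
        Z=table, y=y, X=None, beta=beta, causal_flags=spec.causal_flags(M), seed=seed_val
    )


def simulate_B(
    Z: OTUTable,
    spec: ScenarioSpec,
    family: str,
    omega: int,
    *,
    seed: int | np.random.Generator = 0,
) -> SimReplicate:
    """Linear-predictor outcome model with covariates (design B).

    ``eta = 0.5 w (scale(x1) + scale(x2)) + sum beta_m scale(z_m)`` with
    ``x1 ~ Bernoulli(0.5)``, ``x2 ~ N(delta, 1)``,
    ``delta = scale(sum_causal z)``; causal ``beta_m ~ N(sign*nu, nu/5)``
    (second argument a variance).  ``y ~ N(eta, 1)`` or
    ``Bernoulli(expit(eta))``.
    """
    if family not in ("continuous", "binary"):
        raise ValueError("family must be 'continuous' or 'binary'")
    if omega not in (0, 1):
        raise ValueError("omega must be 0 or 1")
    if spec.n_causal and spec.nu <= 0:
        raise ValueError("effect magnitude nu must be positive with causal taxa")
    rng = np.random.default_rng(seed)
    n, M = Z.n, Z.M
    beta = np.zeros(M)
    if spec.n_causal:
        beta[spec.causal_set] = rng.normal(
            spec.signs * spec.nu, np.sqrt(spec.nu / 5.0)
        )
    x1 = rng.binomial(1, 0.5, size=n).astype(float)
    delta = _scale(Z.Z[:, spec.causal_set].sum(axis=1)) if spec.n_causal else np.zeros(n)
    x2 = rng.normal(delta, 1.0)
    eta = np.zeros(n)
    if omega:
        eta += 0.5 * (_scale(x1) + _scale(x2))
    for m in spec.causal_set:
        eta += beta[m] * _scale(Z.Z[:, m])
    if family == "continuous":
        y = rng.normal(eta, 1.0)
    else:
        y = rng.binomial(1, expit(eta)).astype(float)
    seed_val = seed if isinstance(seed, int) else -1
    return SimReplicate(
        Z=Z,
        y=y,
        X=np.column_stack([x1, x2]),
        beta=beta,
        causal_flags=spec.causal_flags(M),
        seed=seed_val,
    )


# ---------------------------------------------------------------------------
# metrics


def _pseudo_f(tpr: float, fpr: float) -> float:
    a, b = tpr, 1.0 - fpr
    return 0.0 if a + b == 0 else 2.0 * a * b / (a + b)


def evaluate_selection(
    pvals_per_replicate,
    causal_flags: np.ndarray,
    alpha: float = 0.05,
) -> MetricSummary:
    """Selection metrics across replicates.

    TPR/FPR/pseudo-F use the fixed rule "selected if p < alpha" per
    replicate, then average.  The ROC averages FPR and TPR across
    replicates at a common ladder of TSBH-adjusted p-value thresholds
    (the pooled distinct adjusted values, with (0,0) and (1,1) anchors);
    AUC is the trapezoid area under the averaged curve.
    """
    causal_flags = np.asarray(causal_flags, dtype=bool)
    if not causal_flags.any():
        logger.warning("no causal taxa: TPR undefined")
        return MetricSummary(np.nan, np.nan, np.nan, np.empty((0, 2)), np.nan)
    pvals = [np.asarray(p, dtype=float) for p in pvals_per_replicate]
    n_causal = int(causal_flags.sum())
    n_null = int((~causal_flags).sum())

    tprs, fprs, fs = [], [], []
    adj_all = []
    for p in pvals:
        sel = p < alpha
        tpr = sel[causal_flags].sum() / n_causal
        fpr = sel[~causal_flags].sum() / n_null
        tprs.append(tpr)
        fprs.append(fpr)
        fs.append(_pseudo_f(tpr, fpr))
        adj_all.append(tsbh_adjust(p, alpha=alpha).adjusted)

    thresholds = np.unique(np.concatenate([np.concatenate(adj_all), [0.0, 1.0]]))
    roc_tpr = np.zeros(thresholds.size)
    roc_fpr = np.zeros(thresholds.size)
    for adj in adj_all:
        causal_sorted = np.sort(adj[causal_flags])
        null_sorted = np.sort(adj[~causal_flags])
        roc_tpr += np.searchsorted(causal_sorted, thresholds, side="right") / n_causal
        roc_fpr += np.searchsorted(null_sorted, thresholds, side="right") / n_null
    roc_tpr /= len(pvals)
    roc_fpr /= len(pvals)
    order = np.argsort(roc_fpr, kind="stable")
    fpr_curve = np.concatenate([[0.0], roc_fpr[order], [1.0]])
    tpr_curve = np.concatenate([[0.0], roc_tpr[order], [1.0]])
    auc = float(np.trapezoid(tpr_curve, fpr_curve))
    roc = np.column_stack([roc_fpr[order], roc_tpr[order]])
    return MetricSummary(
        tpr=float(np.mean(tprs)),
        fpr=float(np.mean(fprs)),
        pseudo_f=float(np.mean(fs)),
        roc=roc,
        auc=auc,
    )


def cmax_calibration(
    run_replicate,
    cmax_grid,
    *,
    n_reps: int = 100,
    grid_step: float = 0.01,
    alpha: float = 0.05,
    seed: int = 0,
):
    """Mean pseudo-F as a function of the decay-grid upper bound.

    ``run_replicate(c_grid, rep_seed) -> (pvals, causal_flags)`` runs one
    simulated dataset through the test at the given grid.  For each
    ``c_max`` the grid is ``{0, grid_step, ..., c_max}``; replicate seeds
    are chained from ``seed`` so trajectories are reproducible and paired
    across ``c_max`` values.  Returns a pandas DataFrame with columns
    ``c_max``, ``pseudo_f``, ``tpr``, ``fpr``.
    """
    import pandas as pd

    rows = []
    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_reps)]
    for cmax in cmax_grid:
        grid = [0.0]
        k = 1
        while grid_step * k <= cmax + 1e-12:
            grid.append(round(grid_step * k, 10))
            k += 1
        pvals, flags = [], None
        for rs in rep_seeds:
            p, f = run_replicate(grid, rs)
            pvals.append(p)
            flags = f
        summ = evaluate_selection(pvals, flags, alpha=alpha)
        rows.append(
            {"c_max": cmax, "pseudo_f": summ.pseudo_f, "tpr": summ.tpr, "fpr": summ.fpr}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# synthetic reference fixtures (no real 16S data is bundled)


def synthetic_params(
    M: int = 400, theta: float = 0.02, *, sigma: float = 1.5, seed: int = 20240400
) -> DMParams:
    """Synthetic DM parameters with log-normally skewed mean proportions.

    Stand-in for parameters fitted to a real upper-respiratory 16S count
    table, which this package does not bundle; log-normal taxon masses with
    ``sigma = 1.5`` give the heavy-tailed rank-abundance profile typical of
    amplicon surveys, and ``theta = 0.02`` a realistic over-dispersion.
    """
    rng = np.random.default_rng(seed)
    mass = rng.lognormal(mean=0.0, sigma=sigma, size=M)
    return DMParams(pi=mass / mass.sum(), theta=theta)


def _coalescent_newick(labels: list[str], rng: np.random.Generator, scale: float) -> str:
    """Random binary coalescent subtree over ``labels``; returns Newick (no ';')."""
    nodes = [(lab, 0.0) for lab in labels]  # (newick, height)
    k = len(nodes)
    height = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        height += rng.exponential(scale * 2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        (nwk_j, h_j) = nodes.pop(j)
        (nwk_i, h_i) = nodes.pop(i)
        merged = f"({nwk_i}:{height - h_i:.10f},{nwk_j}:{height - h_j:.10f})"
        nodes.append((merged, height))
    return nodes[0][0]


def synthetic_tree(
    M: int = 400,
    *,
    n_clusters: int = 20,
    within_scale: float = 0.3,
    between_scale: float = 1.0,
    normalize_sd: bool = True,
    seed: int = 20240400,
) -> dendropy.Tree:
    """Two-level random coalescent tree emulating a clustered 16S OTU tree.

    OTUs formed at <=3% dissimilarity cluster tightly within species/genus
    clades separated by long internal branches, so a single-level coalescent
    is too uniform.  Here ``n_clusters`` cluster stems follow a coalescent
    with scale ``between_scale`` and each cluster's tips follow a shallow
    coalescent with scale ``within_scale``.  The 0.3:1 scale ratio makes the
    Gaussian decay weights at the default grid upper bound fall from ~0.9
    for nearest neighbors to ~0 across a clade, so the decay grid spans
    single-OTU through small-neighborhood tests (the geometry a clustered
    16S tree shows at these decay values).  Taxa are labelled ``OTU1..M``
    in tip order.  With ``normalize_sd`` branch lengths are rescaled so the
    SD of cophenetic distances is 1, putting the decay parameter directly
    on the distance-SD scale.
    """
    if M < n_clusters:
        raise ValueError("need at least one tip per cluster")
    rng = np.random.default_rng(seed)
    # spread tips over clusters as evenly as randomness allows (min 1 each)
    sizes = np.full(n_clusters, 1)
    extra = rng.multinomial(M - n_clusters, np.full(n_clusters, 1.0 / n_clusters))
    sizes = sizes + extra
    labels = iter([f"OTU{m+1}" for m in range(M)])
    subtrees = []
    for sz in sizes:
        labs = [next(labels) for _ in range(sz)]
        if sz == 1:
            subtrees.append(labs[0])
        else:
            subtrees.append(_coalescent_newick(labs, rng, within_scale))
    backbone = _coalescent_newick(subtrees, rng, between_scale)
    tree = read_newick(backbone + ";", is_path=False)
    if normalize_sd:
        dist = cophenetic_distances(tree)
        if dist.s > 0:
            for edge in tree.preorder_edge_iter():
                if edge.length is not None:
                    edge.length = edge.length / dist.s
    return tree
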