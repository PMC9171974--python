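# Methods

`postkm` implements a phylogeny-guided OTU-specific association test (POST)
for microbiome studies: a per-taxon kernel machine score test whose kernel
adaptively borrows information from phylogenetically neighboring taxa, with
p-values aggregated over a decay-parameter grid by the Cauchy combination
and adjusted for multiplicity by the two-stage Benjamini–Hochberg (TSBH)
procedure. This note records the model, its assumptions, the numerical
choices, and what the bundled synthetic world does and does not establish.

## Model and test

For subjects $i = 1,\dots,n$ with outcome $y_i$ (continuous or binary),
covariates $x_i \in \mathbb{R}^p$ (intercept included) and abundances
$z_i \in \mathbb{R}^M$ over $M$ taxa, the effect of a focal taxon $m$ is
modelled through kernel machine regression

$$ g(\mu) = X\gamma + h^m(Z), $$

where $h^m$ lives in the RKHS of a taxon-specific kernel $K^m$ and $g$ is
the identity (continuous) or logit (binary) link. Viewing $h^m$ as a random
effect with covariance $\tau K^m$, the null $h^m = 0$ is the
variance-component hypothesis $\tau = 0$, tested with the score statistic

$$ T^{m,c} = \frac{1}{2\hat\phi}\,(y-\hat\mu_0)^\top K^m\,(y-\hat\mu_0), $$

with $\hat\mu_0 = g^{-1}(X\hat\gamma)$ from the covariate-only null fit and
$\hat\phi$ the null dispersion ($\mathrm{RSS}/(n-p)$ for continuous, 1 for
binary). Under the null, $T^{m,c}$ follows a weighted mixture of 1-df
chi-squares given by the eigenvalues of the projected kernel.

### The local kernel

The kernel encodes both composition and phylogeny:

1. **Phylogenetic weights.** Patristic distances $d_{\ell m}$ (tip-to-tip
   branch-length sums) are converted to correlation weights
   $r_{\ell m} = \exp\{-d_{\ell m}^2 / (c\,s)\}$, with $s$ the standard
   deviation of the pairwise distances and $c \ge 0$ a decay parameter in
   units of distance SD. $c = 0$ gives the focal-taxon indicator (a strict
   single-OTU test, "SO"); $c \to \infty$ gives all-ones weights (a
   community-level test). Weights below $10^{-12}$ are truncated to zero.
2. **Local Aitchison distance.** Counts (plus pseudo-count 0.5; proportions
   plus $10^{-6}$) are CLR transformed,
   $z^*_{i\ell} = \log(z_{i\ell}/G(z_i))$, and the weighted Euclidean
   distance $A^m_{ij} = \sqrt{\sum_\ell r_{\ell m}(z^*_{i\ell}-z^*_{j\ell})^2}$
   is formed.
3. **Gower centering.** $K^m = -\tfrac12 C (A^m \circ A^m) C$ with
   $C = I - \mathbf{1}\mathbf{1}^\top/n$. Because the local Aitchison
   distance is Euclidean in the weight-scaled CLR coordinates
   $Y = Z^* \operatorname{diag}(\sqrt{r})$, this equals the centered Gram
   matrix $Y_c Y_c^\top$ — the implementation works with the $n \times
   m_{\text{active}}$ factor $Y_c$ throughout, never materializing more
   than one $n\times n$ kernel at a time.

### Small-sample p-values

Microbiome sample sizes are moderate, so the plain asymptotic mixture is
replaced by small-sample constructions:

* **Continuous.** An exact finite-sample pivot: with
  $P_0 = I - X(X^\top X)^{-1}X^\top$,
  $\Pr(T \ge t) = \Pr\!\big(u^\top [P_0 K P_0 - \tfrac{2t}{n-p} P_0] u \ge 0\big)$
  for standard-normal $u$; the scale of the errors cancels, so the p-value
  is exact under Gaussian errors at any $n$. The eigenvalues are obtained
  from the projected factor Gram matrix plus the known multiplicity of
  $-2t/(n-p)$.
* **Binary.** Eigenvalues of $\tilde P^{1/2}(K/2)\tilde P^{1/2}$ with
  $\tilde P = D - DX(X^\top D X)^{-1}X^\top D$, $D = \operatorname{diag}
  (\hat\mu_0(1-\hat\mu_0))$, combined with a permutation-moment
  small-sample calibration: the exact mean and variance of the quadratic
  form under random permutation of the null residuals have closed forms for
  a doubly centered kernel (validated against brute-force permutation
  sampling), and the observed statistic is affinely recentred/rescaled from
  the permutation scale to the asymptotic-mixture scale before the tail is
  evaluated. Below the permutation mean a mean-ratio scaling is used
  instead — the mixture support is $[0,\infty)$ and heavily skewed for the
  few-eigenvalue kernels of sparse taxa, where a linear shift can exit the
  support and pin the p-value at 1. Against a 20,000-permutation oracle the
  calibrated p-values track the permutation p-values to ~0.005 in the tail
  region (worst mid-distribution deviation ~0.03 on sparse taxa); the
  unadjusted mixture is conservative by ~0.015 in the tail.

### Weighted chi-square tails

`postkm.qfdist` evaluates $\Pr(\sum_k \lambda_k \chi^2_1 \ge x)$ by:

* **Characteristic-function inversion** (Imhof's real-integral form of the
  Davies approach): panel-wise Gauss–Legendre with oscillation-aware panel
  sizing, an analytic truncation bound, a first-order integration-by-parts
  boundary term for the truncated tail, exact compression of repeated
  eigenvalues, and mean-compensated dropping of negligible eigenvalues
  (dropped-suffix SD below $10^{-8}$ of the mixture SD). Worst-case
  absolute error ~$3\times10^{-9}$ against fine-grained quadrature and
  exact-series oracles.
* **Ruben's mixture series** for small all-positive eigenvalue sets (the
  binary path), exact to series tolerance and used whenever its convergence
  estimate allows.
* **Fallbacks:** Lugannani–Rice saddlepoint (also used for far tails,
  approximate $p < 10^{-6}$, where relative rather than absolute accuracy
  matters), then Liu–Tang–Zhang four-moment matching.

### Decay-grid aggregation

The optimal $c$ is unknown, so the test is run on the grid
$c \in \{0, 0.01, \dots, 0.05\}$ (configurable; upper bound $c_{\max} =
0.05$) and combined with the Cauchy combination:
$T^m = \sum_j \tan\{(0.5-p_{m,c_j})\pi\}$,
$p_m = \tfrac12 - \arctan(T^m/J)/\pi$. Inputs are clamped to
$[10^{-15}, 1-10^{-15}]$ before the tangent transform. The combination is
valid under arbitrary dependence and behaves like a minimum-p rule; the
reported `best_c` is the grid argmin of $p_{m,c}$ (ties broken toward the
smaller $c$, i.e. the least borrowing).

### Multiplicity

TSBH at target level $\alpha$ (default 0.05): stage 1 runs BH at
$\alpha/(1+\alpha)$ and estimates the null count $\hat m_0 = m - R_1$
(floored at 1); stage 2 is the BH step-up with $\hat m_0$ in place of $m$.
With no stage-1 rejections this is exactly BH; otherwise it is uniformly
less conservative.

## Simulation engine

Counts follow a Dirichlet-multinomial: mean proportions $\pi$,
over-dispersion $\theta$ (concentration $\alpha = \pi(1-\theta)/\theta$),
sequencing depth negative binomial with mean 10,000 and size 25, counts
multinomial given both. DM parameters are estimated from real count tables
by Minka's fixed-point maximum likelihood (with a boundary guard for
$\theta \to 0$); delta-method standard errors come from the closed-form
(diagonal plus rank-one) observed information.

Causal taxa form "hubs" of phylogenetically adjacent tips: taxa are
partitioned into 20 clusters by a seeded k-medoids (PAM-style) on the
cophenetic distance; hubs of 7–10 taxa (scenarios 1–3) or 2–3 (scenario 4)
are drawn from the 8 most abundant clusters as the tips nearest each
cluster medoid; scenario 5 samples the same number of causal taxa uniformly
at random. Effect-sign patterns: all positive (1); sign per hub, half
negative (2 and 4); a random half of causal taxa negative (3 and 5).

Outcomes:

* **Design A** (case/control fold change): 50 cases, 50 controls; case
  counts multiplied by $e^{\beta_m}$, $\beta_m \sim N(\pm\nu, 1)$ for
  causal taxa ($|\nu| = 1$ small, 2 large); fold-changed tables stay
  real-valued (the CLR pseudo-count handles non-integers).
* **Design B** (linear predictor):
  $\eta_i = 0.5\,\omega(\mathrm{scale}(x_{1i}) + \mathrm{scale}(x_{2i})) +
  \sum_m \beta_m\,\mathrm{scale}(z_{im})$ with $x_1 \sim$ Bernoulli(0.5),
  $x_2 \sim N(\delta_i, 1)$, $\delta = \mathrm{scale}(\sum_{\text{causal}}
  z)$; causal $\beta_m \sim N(\pm\nu, \nu/5)$ with the second argument read
  as a **variance** (the stated $(\nu, \text{var})$ pairs 0.2→0.04 and
  0.5→0.1 are consistent only with this reading); $y \sim N(\eta,1)$ or
  Bernoulli$(\mathrm{logit}^{-1}\eta)$. `scale` is mean 0 / sample SD 1.
  $\beta$ is redrawn per replicate with chained seeds.

Selection metrics: an OTU is "selected" if $p < 0.05$; TPR, FPR and the
pseudo-F score (harmonic mean of TPR and $1-$FPR) are computed per
replicate and averaged. ROC/AUC: TSBH-adjusted p-values are thresholded on
the pooled ladder of distinct adjusted values, FPR/TPR averaged across
replicates per threshold, the curve anchored at (0,0) and (1,1), and AUC
taken by trapezoid. `cmax_calibration` traces mean pseudo-F over grid
upper bounds with paired replicate seeds.

## The synthetic world

No real 16S reference data are bundled; offline fixtures use:

* **Mean proportions:** log-normal taxon masses ($\sigma = 1.5$),
  normalized; $\theta = 0.02$. This gives a heavy-tailed rank-abundance
  profile typical of amplicon surveys, though less extreme than real
  upper-respiratory data.
* **Tree:** a two-level random coalescent — 20 cluster stems (scale 1)
  each carrying a shallow within-cluster coalescent (scale 0.3), branch
  lengths normalized so the cophenetic-distance SD is 1. At the default
  grid upper bound this makes decay weights fall from ~0.9 for nearest
  neighbors to ~0 across a clade (median ~6 neighbors with $r > 0.1$),
  the geometry a clustered OTU tree shows at these decay values.

What a green test does establish: exactness of the continuous null,
permutation-level calibration of the binary null, the algebraic kernel
identities, and the qualitative power ordering (borrowing helps on hub
structure, is neutral-to-harmful under random placement). What it does not:
agreement with results computed on real 16S data — the synthetic abundance
profile is less skewed than real data, which makes *all* tests somewhat
more powerful here (the single-OTU baseline especially), so absolute AUC
values differ from those obtainable on the real reference dataset even at
matched sizes. The acceptance suite therefore checks orderings and
calibration, not absolute AUC values.

Two scale-down artifacts are worth knowing about. First, fold-change
designs shift every sample's CLR geometric mean, so *all* taxa acquire a
small case/control signal; the artifact scales with the causal fraction and
is much larger at M=100 with ~50% causal taxa than in the M=400 study
design (~16%). Power fixtures therefore use M≥200 and the random-placement
fixture the full M=400. Second, p-values of taxa in the same clade share
most of their kernel and are strongly dependent; uniformity checks that
compare against an i.i.d. reference thin the pool to one taxon per cluster.

## Numerical choices and degenerate inputs

* Eigenvalues below $10^{-10}$ of the largest magnitude are discarded
  (centering noise).
* Kernels with no signal direction (all eigenvalues at numerical zero,
  e.g. a constant CLR column) return $p = 1$ with a warning.
* All-zero samples become constant CLR rows (zero after centering), with a
  logged warning.
* Perfect separation and IRLS non-convergence in the binary null fit raise
  with diagnostics; rank-deficient designs are rejected.
* Per-taxon failures inside a run are logged and reported as NaN; TSBH
  carries NaNs through without affecting the other taxa.
* The distance-SD convention: sample SD over all $M^2$ matrix entries
  (including the zero diagonal), matching the literal index set of the
  definition; an upper-triangle-only option is exposed
  (`s_convention="upper-triangle"`). Patristic distances are
  root-placement invariant, so rooted and unrooted trees are both accepted.
* Proportions-mode pseudo-addition does not renormalize rows (CLR is
  invariant to row scaling).
* Scenario 5 caps the causal count at $M$ for small worlds.

## Known limitations

* The binary small-sample adjustment matches the first two permutation /
  Bernoulli moments but not skewness; residual tail error is ~0.005 at
  $n = 100$.
* The exact continuous construction assumes Gaussian errors; heavy-tailed
  outcomes inherit only asymptotic validity.
* UniFrac-family base distances, tree inference, and hierarchical FDR
  variants are out of scope; the kernel is always local Aitchison.
* Very long decay grids multiply compute linearly; kernels are built
  lazily, but runtime is dominated by one small eigendecomposition and one
  tail evaluation per (taxon, c).
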