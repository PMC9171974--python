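# postkm — phylogeny-guided OTU-specific association testing

`postkm` tests each taxon (OTU/ASV) in a microbiome count table for
association with a continuous or binary outcome, while **adaptively
borrowing information from its phylogenetic neighbors**. It is aimed at
microbiome association studies (e.g. vaginal microbiome vs bacterial
vaginosis, respiratory microbiome case/control designs) where single-taxon
tests are underpowered on sparse counts and community-level kernel tests
cannot say *which* taxon is associated.

## The method

For focal taxon $m$, a kernel machine regression
$g(\mu) = X\gamma + h^m(Z)$ is fitted with $h^m$ in the RKHS of a local
kernel built in three steps:

1. patristic distances $d_{\ell m}$ from the tree become decay weights
   $r_{\ell m} = \exp\{-d_{\ell m}^2/(c\,s)\}$ ($s$ = SD of distances,
   $c$ = decay parameter; $c=0$ is a strict single-OTU test);
2. the **local Aitchison distance**
   $A^m_{ij} = \sqrt{\sum_\ell r_{\ell m}(z^*_{i\ell} - z^*_{j\ell})^2}$
   on CLR-transformed abundances;
3. Gower double centering, $K^m = -\tfrac12 C (A^m)^2 C$.

Association is the variance-component score test
$T^{m,c} = (y-\hat\mu_0)^\top K^m (y-\hat\mu_0) / (2\hat\phi)$, whose null
is a weighted chi-square mixture; small-sample p-values use an exact
finite-sample pivot (continuous) or a permutation-moment calibration
(binary), evaluated by characteristic-function inversion. P-values over the decay
grid $c \in \{0, 0.01, \dots, 0.05\}$ are merged with the **Cauchy
combination** and FDR-adjusted with **two-stage Benjamini–Hochberg**.

The package also ships the full Dirichlet-multinomial simulation engine
used to validate the test (fold-change and linear-predictor outcome
designs, causal-hub placement on the tree, type-I error / pseudo-F / AUC
metrics) — see `docs/methods.md` for the model details.

## Worked example

```python
import numpy as np
from postkm import POST
from postkm.simulate import (
    generate_counts, select_causal, simulate_A, synthetic_params, synthetic_tree,
)
from postkm.tree import cophenetic_distances

# a synthetic world: 200 taxa on a clustered tree, Dirichlet-multinomial counts
M = 200
tree = synthetic_tree(M=M, seed=3)
dist = cophenetic_distances(tree, [f"OTU{m+1}" for m in range(M)])
params = synthetic_params(M=M, seed=3)

# hub-structured causal taxa, case/control fold-change outcome
spec = select_causal(dist, params, scenario=2, nu=2.0, seed=11)
base = generate_counts(params, n=100, seed=5)
rep = simulate_A(base, spec, seed=6)

res = POST(rep.Z, dist, rep.y, family="binary").fit()
print(res.summary().head())
```

Running exactly this prints

```
    taxon         p_raw  best_c    p_adjusted
0   OTU81  1.000000e-15    0.00  3.463896e-14
1  OTU143  1.000000e-15    0.00  3.463896e-14
2  OTU141  1.276756e-15    0.01  3.463896e-14
3  OTU146  1.332268e-15    0.01  3.463896e-14
4  OTU147  1.332268e-15    0.01  3.463896e-14
```

(all 20 top-ranked taxa in this replicate are truly causal).

`p_raw` is the Cauchy-combined p-value over the decay grid, `best_c` the
grid value with the smallest per-decay p-value (how far the test chose to
borrow: 0 = the taxon alone, 0.05 = a small clade neighborhood), and
`p_adjusted` the TSBH FDR-adjusted p-value; `res.significant()` lists taxa
with `p_adjusted < 0.05`. On this replicate the causal hub members
dominate the top of the table.

A command-line interface mirrors the library:

```bash
post run --counts counts.tsv --tree tree.nwk --outcome outcome.tsv \
         --covariates covars.tsv --family binary --out results.tsv
post simulate --design A --scenario 2 --nu 2 --n 100 --m 200 --reps 10 \
         --seed 1 --out simdir/
post calibrate-cmax --scenario 2 --nu 2 --reps 50 --out cmax.tsv
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's core pipeline from scratch: it builds the
synthetic world, places hub-structured causal taxa, simulates case/control
fold-change replicates, runs the phylogeny-guided test and its single-OTU
special case, applies TSBH, and prints the selection metrics (TPR, FPR,
pseudo-F, AUC) for both, writing its JSON manifest to `--out`. With
`--seed 1` the run reports the phylogeny-guided test well ahead of the
single-OTU baseline on hub-structured effects.
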