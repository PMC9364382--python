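# chromclust

Probabilistic clustering of genomic loci characterised by **multiple
chromatin-feature coverage profiles** — binned read counts of histone
modifications, polymerase occupancy, nucleosome or accessibility signals at
enhancers, promoters or peak sets.  Sets of regulatory elements are
biologically heterogeneous: an aggregate plot over all loci superimposes
several distinct chromatin signatures, and anchor positions and strand
orientations are uncertain.  `chromclust` addresses all three problems at
once with a product Dirichlet-multinomial mixture model with latent shift
and flip states.

## Model

For locus *i* and chromatin feature *m*, counts over *L* bins follow a
Dirichlet-multinomial (Pólya) compound distribution — a multinomial whose
probability vector is Dirichlet-distributed, capturing the overdispersion of
sequencing counts.  Features are independent given the mixture component:

    p(X | α, π) = Π_i Σ_k π_k ξ_is ζ_if Π_m DM(x_i^(m) | window(α_k^(m), s, f))

with component concentrations α, weights π, and latent discrete shift
(s ∈ 1..S) and flip (f ∈ {1,2}) states with priors ξ, ζ that align each
locus to its cluster's profile.  Component vectors are shift-extended to
length L + S − 1 and carry a regularised Gamma prior — elementwise
Gamma(η, ν) plus a Gamma(η_h, ν_h) on the roughness Σ_j (α_j − α_{j−1})² —
favouring profiles that vary smoothly along the genome.  Inference is MAP-EM
(BFGS on log α in the M-step); the number of clusters is chosen by AIC/BIC.
See `docs/methods.md` for the full treatment.

## Worked example

```python
import numpy as np
from chromclust import (ShiftFlipConfig, corrupt_shift_flip,
                        default_alpha_fixtures, evaluate_fit, fit,
                        simulate_dmm)

# two clusters, two features, 50 bins of 40 bp, coverage 100
alpha = default_alpha_fixtures(50, 2)
ds, truth = simulate_dmm(alpha, [0.5, 0.5], [100, 100], 300,
                         seed=1, bin_size=40)
# displace by Skellam shifts within +-400 bp and flip half the strands
ds, truth = corrupt_shift_flip(ds, truth, max_shift_bp=400, bin_size=40, seed=2)

cfg = ShiftFlipConfig(shift_enabled=True, flip_enabled=True, max_shift_bp=400,
                      bin_size=40, shift_prior_kind="pyramid")
res = fit(ds, K=2, config=cfg, seed=3, max_iter=200)
rep = evaluate_fit(ds, truth, res)
print(f"converged={res.converged} after {res.n_iterations} iterations")
print(f"AUC={rep.clustering_auc:.3f} shift_error={rep.shift_error_bp:.1f}bp "
      f"flip_error={rep.flip_error:.3f}")
```

Output:

```
converged=True after 121 iterations
AUC=1.000 shift_error=26.0bp flip_error=0.010
```

The clustering AUC of 1.0 means the posterior cluster memberships separate
the two simulated clusters perfectly; the mean shift error of ~26 bp (under
one bin at 40 bp resolution) and flip error of ~1% say the latent
alignment states were recovered almost exactly, after correcting for the
inherent label-switching and flip-inversion unidentifiability.

The same pipeline is available from the shell:

```sh
chromclust simulate --n 300 --m 2 --l 50 --shift-sd-bp 400 --outdir sim/
chromclust fit --feature h3k4me1=sim/feature1.tsv --feature polii=sim/feature2.tsv \
    --k 2 --shift --flip --max-shift-bp 400 --bin-size 40 \
    --shift-prior pyramid --seed 3 --outdir out/
chromclust select --feature h3k4me1=sim/feature1.tsv --k-min 1 --k-max 3 \
    --outdir sel/
```

`fit` writes an assignments table (locus, cluster, posterior, shift in bp,
flip), the model parameters as JSON, re-aligned count matrices and
per-cluster aggregate profiles.  Inputs are plain tab-delimited count
matrices (one per feature; optional BED file for locus names).

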