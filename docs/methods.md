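# Methods

## Model

A genomic locus *i* is described by *M* chromatin-feature coverage profiles
x_i^(m) — vectors of read counts over *L* consecutive bins of width *B* bp
(window *W* = *L·B*).  Each mixture component *k* models a profile with a
Dirichlet-multinomial (Pólya) compound distribution: p ~ Dirichlet(α_k^(m)),
counts ~ Multinomial(n_i^(m), p) with the total n fixed by the observed
coverage.  Features are conditionally independent given the component, so the
component likelihood is the product over *m* of Dirichlet-multinomial masses,
and the marginal likelihood of the data is

    p(X | α, π) = Π_i Σ_k π_k Π_m DM(x_i^(m) | α_k^(m)).

The DM mass includes the multinomial coefficient (a proper pmf): the
coefficient is constant per locus, so responsibilities are unchanged, but
log-likelihoods — and hence AIC/BIC — are well defined and comparable across
models.

The compound construction captures the overdispersion of sequencing counts
that a plain multinomial or Poisson model misses; the concentration scale
Σ_j α_kj^(m) controls how far per-locus profiles scatter around the cluster
mean α/Σα.

### Prior and regularisation

Concentrations carry a regularised Gamma prior (shape-rate throughout):
every element α_kj^(m) ~ Gamma(η, ν) independently, and the roughness
statistic h_k^(m) = Σ_{j≥2} (α_kj − α_{k,j−1})² of each component-feature
vector carries its own Gamma(η_h, ν_h) density, which rewards profiles that
vary smoothly across neighbouring bins.  Defaults: η = 1.1, ν = 0.1 (prior
mean 11 per element, weakly informative), and a mean-1, variance-0.1 Gamma on
h, i.e. η_h = ν_h = 10.  The joint prior is known only up to a normalising
constant; since the constant does not depend on α at fixed hyperparameters,
the unnormalised log posterior is used consistently for optimisation.
Setting η_h = ν_h = None disables the smoothness term entirely (the
"unregularised" ablation).  The smoothness term is evaluated on the full
shift-extended vector, since that is the parameter being estimated.

### Shift and flip alignment

Anchor positions of regulatory elements are uncertain and profiles can be
strand-ambiguous, so each locus additionally carries a latent shift state
s ∈ 1..S and flip state f ∈ {1, 2}.  With maximum shift ±max_shift_bp and
bin size B, S = 2·(max_shift_bp/B) + 1; component vectors are extended to
L_ext = L + S − 1 and state (s, f) selects the L-length window
α_ext[s−1 : s−1+L], reversed when f = 2.  Per-locus priors ξ (shift) and ζ
(flip) are row-stochastic; the shift prior is either uniform or a pyramid
(triangular) prior peaked at the no-shift state, appropriate when loci are
anchored at ChIP-seq summits.

Sign convention (the package fixes one and uses it everywhere): under the
window slicing above, data generated from window s appears translated right
by (s0 − s) bins relative to the central window s0 = (S+1)/2.  A hard
assignment therefore reports shift_bp = (s0 − s̃)·B — the data's rightward
displacement — and re-alignment reverses flipped profiles and translates by
−shift_bp/B bins, which exactly inverts the simulator's corruption except at
zero-filled edge bins.

## Inference

MAP estimates are obtained by generalized EM on the N × K × S × 2 latent
tensor:

* **E-step.** E[z_iksf] ∝ π_k ξ_is ζ_if Π_m DM(x_i^(m) | window(α_k^(m), s, f)),
  normalised per locus via log-sum-exp.
* **M-step.** π from responsibility means (closed form).  α is updated in
  λ = log α space with BFGS, one (k, m) block at a time — the expected
  complete-data log posterior separates across blocks.  The analytic
  gradient combines digamma terms of the DM mass, the Gamma prior terms, the
  roughness-chain term and the change-of-variables Jacobian Σλ; it is
  verified against central finite differences in the tests.  A block update
  is accepted only if it does not decrease its objective; otherwise the
  previous α is kept (with a warning), preserving generalized-EM
  monotonicity.  Because the optimisation target lives in λ space, the
  monotone quantity — traced per iteration and used for convergence — is the
  observed-data log posterior in the λ parameterisation, i.e. including the
  change-of-variables Jacobian Σ log α; the α-space posterior (without the
  Jacobian) has a slightly different maximiser and need not be monotone.

Because counts are small integers, the per-block objective is condensed once
per M-step into weighted histograms of count values at each extended
position (plus per-shift-state total-count weights), making each BFGS
evaluation O(L_ext · max_count) special-function calls regardless of N and
S.  An equality test against the direct loop over loci, states and features
guards this condensation.

**Initialisation.** Cluster memberships come from k-means on the row-wise
concatenation of per-feature bin proportions, softened by a softmax of
negative squared distances with temperature equal to the mean
nearest-centroid squared distance (memberships stay non-degenerate without a
separate fuzzifier parameter).  Shift/flip responsibilities are spread by ξ
and ζ; α is then initialised by a full BFGS maximisation of the lower bound
from membership-weighted mean profiles (edge-padded to L_ext).

**Numerical choices.** λ is clipped to ±29 before exponentiation; the
roughness h is floored at 1e-12 inside the optimizer so its log-density
stays finite when a block is numerically constant (the exact prior still
reports −∞ at h = 0).  Convergence: relative lower-bound change < 1e-6,
max_iter 200 by default.  All argmax operations break ties to the lowest
index.  Restart r of a multi-start fit uses seed + r; the best final lower
bound wins.  Degenerate loci (zero prior mass everywhere) receive uniform
responsibilities over supported states with a warning.

## Model selection

AIC = 2p − 2·logL and BIC = p·ln N − 2·logL with logL the maximized
marginal log-likelihood (shift/flip/cluster states summed out, prior
excluded, so regularisation strength does not distort the comparison) and
p = K·M·L_ext + (K − 1): the optimized quantities only, counting the
shift-extended length; fixed state priors and hyperparameters are not free
parameters.  Ties select the smaller K.  The convention is recorded in the
output metadata.

## Evaluation and identifiability

Cluster labels are aligned by the agreement-maximising permutation
(exhaustive, K ≤ 6).  Clustering accuracy for two true clusters is the AUC
of one cluster's marginal posterior, corrected for label switching by
max(AUC, 1 − AUC).  Flip labels within a cluster can be inverted without
changing the likelihood, so flip error takes the smaller mismatch proportion
of the two inversions per inferred cluster (hence ≤ 0.5); whether the
correction should be per cluster or global is not externally fixed — per
cluster is implemented.  A flipped frame mirrors the shift axis, so shift
error (mean |true − inferred| displacement in bp) negates the true
displacements of clusters whose flip frame was inverted.

## Synthetic data

`simulate_dmm` draws from the model itself at fixed per-feature coverages
(10–100 in the experiments), so row sums equal the coverage and zero rows
cannot occur.  The default two-cluster fixtures are smooth Gaussian-bump
concentration profiles: a central valley flanked by two *unequal* peaks
(asymmetric nucleosome-free region) and an off-centre single peak.  Both are
strand-asymmetric, as real chromatin profiles are — a perfectly symmetric
profile would make flip states fundamentally unidentifiable.  The absolute
concentration scale (Σα ≈ 55 over 50 bins) gives clearly super-multinomial
dispersion at coverage 100.

`corrupt_shift_flip` displaces profiles by mean-zero Skellam draws (equal
Poisson rates μ = σ²/2 with σ = max_shift_bins/2.576, putting ~99% of draws
inside the support; out-of-range draws are redrawn) in whole bins, and
reverses with probability 1/2.  The exact Skellam variance of the original
protocol is not published; this default is a documented stand-in honouring
the stated support.  Zero-fill at the edges means corruption followed by
true-state re-alignment restores the data except at edge bins — the tests
check interior bins exactly.

`simulate_gaussian_lowcov` emulates a low-coverage benchmark: per-cluster
Gaussian-shaped expected profiles scaled by a coverage factor f ∈ {0.5, 1},
per-bin Poisson counts, and rejection of all-zero profiles until the
requested number of non-zero profiles per cluster is collected (at these
rates most raw draws are empty).  The default expected total is 1 read per
profile at f = 1.  The precise functional form of the original generator is
unpublished; this reimplementation matches its qualitative structure.

`sample_from_prior` performs ancestral sampling for prior predictive
checks, drawing α from the independent Gamma(η, ν) part only — the
smoothness factor would require sampling from an unnormalised joint and is
deliberately ignored here.

What the simulations do *not* emulate: mapping artefacts, control-track
subtraction residuals, locus-to-locus coverage variation within a feature,
and spatial correlation beyond what the Dirichlet draw induces.  Passing
recovery tests therefore demonstrate correctness of the inference machinery
under the model's own assumptions, not robustness to real-data violations
of them.

## Problem sizes in the test-suite experiments

The recovery, alignment, selection and regularisation experiments run at
N = 400 (coverage 100, K = 2, M = 2, L = 50), N = 300 with S = 21 shift
states and flips, N = 1000 for the K sweep at coverages 100 and 10, and
N = 150 at coverage 10 for the paired regularised-vs-unregularised
comparison, each over 10 seeds.  The low-coverage comparison uses the
smallest N because with ample data both variants saturate near-perfect
accuracy and the comparison carries no information; at N = 150 estimation
error is material and the smoothness prior's effect is visible.

## Known limitations

* Flip states of symmetric profiles are unidentifiable in principle; the
  metrics correct for global inversions but cannot rescue per-locus flips of
  near-symmetric clusters.
* The M-step is a local maximiser; multi-start (`n_restarts`) is the only
  defence against poor initialisation.
* The histogram condensation assumes counts are modest integers; inputs with
  extremely large counts fall back on the same math but with a large count
  table (memory grows linearly in the maximum count).
* AIC/BIC count shift-extended parameters (K·M·L_ext), which heavily
  penalises shift-enabled models at small N; whether to count L or L_ext is
  a convention, stated in the output metadata.
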