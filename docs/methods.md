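# Methods

## Model

The longitudinal abundance tensor χ (subjects n = 1..N, taxa l = 1..L,
visits k = 1..K) is decomposed into at most C_max rank-one modules,

    χ_nlk ~ Normal( Σ_c H_nc ω_cl s_cl T_kc ,  λ_nk⁻¹ ),

with priors

    H_nc ~ N(0, 1)                      subject activities
    ω_cl ~ N(0, β_c⁻¹)                  slab loadings
    s_cl ~ Bernoulli(p_cl)              inclusion indicators
    p_cl ~ Beta(inclusion_a, inclusion_b)
    β_c  ~ Gamma(slab_shape, slab_rate)
    λ_nk ~ Gamma(noise_shape, noise_rate)

and, in the visit-correlated model, a first-order Markov prior on each visit
trajectory,

    T_1c ~ N(0, Λ_c⁻¹),  T_kc ~ N(T_{k−1,c}, Λ_c⁻¹),  Λ_c ~ Gamma(a, b).

The visit-uncorrelated variant replaces the chain by i.i.d. T_kc ~ N(0, Λ_c⁻¹)
— at K = 1 the two coincide exactly. The matrix-2d variant flattens the
tensor to an (N·K) × L matrix, drops the visit mode, and treats every sample
as an independent row; it quantifies what is lost by ignoring both the
sample–subject map and the repeated-measure correlation.

The spike-and-slab construction M_cl = ω_cl·s_cl gives exact zeros: a module
is the set of taxa with posterior inclusion probability PIP_cl = E_q[s_cl]
strictly above 0.5, modules with no member are inactive, and the effective
module count is learned (automatic complexity control under the C_max cap).

## Inference

Mean-field variational Bayes under the factorization
q(H)·q(ω)·q(s)·q(p)·q(T)·q(λ)·q(Λ)·q(β). All priors are conjugate, so every
update is closed-form and the ELBO is non-decreasing across sweeps — this is
asserted in the tests at a relative tolerance of 1e-6, and a non-finite ELBO
raises immediately.

Two within-block structures are kept exact rather than factorized further:

- **q(ω·l) is a joint C-dimensional Gaussian per taxon.** Taxa are
  conditionally independent given H and T, so this is still exact coordinate
  ascent for the factorization above. It matters: with per-entry updates,
  modules competing for the same taxon cannot explain each other away, and
  planted-membership recovery plateaus around F1 ≈ 0.85 regardless of
  iteration count. The joint solve per taxon costs L inversions of a C×C
  matrix per sweep.
- **q(T·c) is a joint K-dimensional Gaussian per module** with tridiagonal
  precision E[Λ_c]·Q + diag(likelihood terms), where Q is the random-walk
  quadratic form; the chain prior is therefore handled without approximation.

Sufficient statistics are maintained as C×C moment matrices, making one sweep
O(NLKC + (N+K+L)C²). Observation masks must be constant along the taxon axis
(samples are observed or missing as a whole — true of every sampling design);
fully missing (subject, visit) cells contribute to no likelihood moment and
their λ_nk stays at its prior.

### Initialization and warm-up

Factor means are drawn N(0, 1) under the user's seed; posterior variances
start at 1e-2 and all Gamma/Beta posteriors at their priors. Two departures
from the obvious defaults are deliberate, and both address the same failure
mode — the empty model (all loadings zero, noise precision absorbing all
variance) is a stable fixed point of the coordinate ascent:

- Initial posterior variances of 1 would dominate the second moments during
  the first sweeps, shrinking every mean to ≈ 0 before any structure is
  found; 1e-2 lets the random means drive the early iterations.
- The first `n_warmup` sweeps (default 20) update only H, ω, T and λ while
  s (at 0.5), p, Λ and β stay at initialization. Skipping coordinate updates
  preserves ELBO monotonicity; the effect is an ALS-like dense fitting phase
  that locks onto the CP structure before sparsity starts pruning. Without
  it, module death during the precision transient is common.

### Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `n_modules_max` | 300 | cap C_max on the module count; the prior empties unused components, so generous values are safe (slower). Desk-scale analyses use ~2× the expected count. |
| `inclusion_a`, `inclusion_b` | 1, 7 | Beta prior on p_cl; expected inclusion 1/8, matching typical module density (10–15 members out of ~100 profiled species). A flat Beta(1,1) exerts no sparsity pressure (its log-odds contribution is 0 at PIP 0.5) and admits a halo of weak false-positive members. |
| `noise_*`, `temporal_*`, `slab_*` | 1e-3, 1e-3 | broad Gamma priors (mean 1, variance 1000) on λ, Λ, β. |
| `n_warmup`, `max_iter`, `tol` | 20, 500, 1e-6 | dense warm-up sweeps; sparse-phase cap; relative-ELBO stopping rule. |
| `pip_threshold` | 0.5 | membership call; strictly greater-than (a PIP of exactly 0.5 is not a member). |

### Fixed-loadings projection

An external cohort profiled for (a subset of) the same taxa is projected by
clamping q(M) to the discovery posterior means (columns restricted to shared
taxa), running the visit-uncorrelated variant for H′ and T′, and initializing
both at the per-module means of the discovery factors. Because M is fixed,
the likelihood constrains only the product H′_c·T′_c; the scale gauge is
fixed after inference by rescaling each T′_c to the discovery T_c's RMS (H′_c
absorbing the inverse), so projected activities are commensurate with
discovery activities — the assumption under which a classifier trained on
discovery H transfers to H′. A residual caveat remains: if the external
cohort's true temporal trend for a module is sign-opposed to the discovery
trend, H′_c recovers the activity up to sign (the synthetic validation
generator therefore carries the discovery trajectories over; fresh
trajectories are available behind a flag with this caveat documented).

## Downstream statistics

- **Association**: per-module two-sided Wilcoxon rank-sum tests (exact when
  both groups have ≤ 25 subjects and no ties; normal approximation with tie
  correction otherwise) or Kruskal–Wallis for > 2 groups, on the subject
  activities H; Benjamini–Hochberg adjustment across modules; the
  significance call is FDR ≤ 0.25.
- **Variance partitioning**: single-factor PERMANOVA with the Gower-centred
  pseudo-F, R² = SS_between/SS_total, p from free label permutation
  (999 by default, seeded; exhaustive enumeration available for small n).
  Distances: Bray–Curtis between taxonomic profiles, Euclidean between
  module-activity vectors. Sample-level clinical factors are collapsed per
  subject to their overall state ("Yes" if recorded in any sample week).
- **Co-occurrence**: Dice index on presence (abundance > 0) and absolute
  Spearman correlation, either per subject (averaged over subjects) or across
  all samples (flattened). Spearman is undefined for constant series; such
  pairs are dropped from averages, not imputed. Module cohesion (mean over
  member pairs) is compared with size-matched random groups built from taxa
  pairs that co-occur in no module — a group matched to a module of size m is
  C(m, 2) sampled eligible pairs; sampling taxa cliques instead is infeasible
  (the eligible-pair graph of a realistic module set contains no cliques of
  module size). One-sided Wilcoxon rank-sum compares module vs null scores.
- **Functional similarity**: cosine similarity of two members' pathway
  contribution vectors within a sample (HUMAnN-style stratified input),
  averaged over samples where both contribute, then over member pairs; the
  metric is pluggable.
- **Classification**: module activities are quantile normalized (columns
  mapped to the mean order-statistic distribution; the fitted reference is
  applied to held-out data by rank interpolation), modules are ranked by
  Wilcoxon p-value, and a random forest (2000 trees by default) is scored by
  stratified 10-fold cross-validation — AUROC/AUPR on pooled out-of-fold
  scores, operating point by Youden's index (ties resolve to the lower
  cutoff). Multi-run model selection picks the restart with the best mean
  AUROC over the top-k curve, breaking ties within 0.01 by lowest
  reconstruction RMSE.

## Synthetic data

The generator mirrors the inference model: H ~ N(0, 1); each planted module
loads on 5–15 of 80 taxa (sampled uniformly, overlaps allowed) with positive
activities Uniform(0.5, 1.5); T columns are Gaussian random walks
(unit-variance start, step precision 4) normalized to unit RMS; Gaussian
noise is added at a target SNR (noise SD = realized signal SD / √SNR,
default 10); negative cells are then clipped to zero, with optional closure
to per-sample proportions. Defaults: N = 60, L = 80, K = 10, C = 6.
Case/control cohorts shift the affected modules' H columns by a chosen effect
size (default 2 SD); validation cohorts reuse the discovery M and T with
fresh subjects and noise.

Three generator choices deserve explanation:

- **Positive member activities.** With random-signed activities, clipping at
  zero makes opposite-signed members of the same module anti-co-occur,
  contradicting the qualitative behaviour the generator exists to emulate
  (intramodule co-occurrence enrichment). The fitted model remains
  sign-unconstrained.
- **Unit-RMS trajectories.** An unnormalized random walk's magnitude is
  essentially arbitrary, so per-module signal strength under a single nominal
  SNR varied by a factor of ~400 and several "planted" modules were
  undetectable by construction; normalization makes the nominal SNR apply to
  every module. Normalization preserves the walk's shape, hence its
  autocorrelation structure.
- **Clipping as default, not in the noiseless world.** Real abundances are
  nonnegative, so the default generator clips; but a clipped tensor is no
  longer an exact CP product, so exact-recovery checks use the unclipped
  model-space tensor (the inference likelihood is an unconstrained Gaussian).

What a green test does *not* establish: the generator is Gaussian-by-design
around a low-rank signal — it has no compositional closure coupling between
taxa (unless enabled), no zero-inflation beyond clipping, no phylogenetic
correlation, and no realistic ecological dynamics. Green recovery tests show
the inference works on data from (a clipped neighbourhood of) its own model
class, not that real stool profiles are that kind of data.

## Behaviour worth knowing about

- **Recovery vs noise is non-monotone on the easy side.** On the clipped
  generator, mean membership F1 at SNR 30 is *lower* than at SNR 10 or 3
  (≈ 0.87 vs 0.93 / 0.94 over 5 seeds): with little noise the likelihood is
  sharp enough that the model must fit the clipping distortion — cross-module
  interaction terms of clip(Σ_c ...) — which pollutes memberships, whereas
  moderate noise masks those artifacts (on unclipped data the same grid is
  flat at ≈ 0.96–0.98). Degradation with noise appears where the premise
  actually binds, from SNR 10 down through 1 to 0.1 (≈ 0.93 / 0.90 / 0.72);
  the acceptance check uses that grid.
- **Dense artifact components.** On clipped data the fit often spends one
  component on a dense, high-membership "baseline" module absorbing
  nonnegativity structure. It is a real feature of the fit on such data;
  size-matched nulls and Hungarian-matched recovery scoring are robust to it.
- **Variant comparisons need a non-saturated regime.** At the recovery SNR
  of 10 both temporal variants classify at AUROC ≈ 0.94 and the comparison is
  a tie at ceiling; the visit-correlated advantage (the method's point) shows
  at SNR 2, where its AUROC-vs-top-k curve dominates the uncorrelated
  variant's pointwise.
- **Compute scaling in the test-suite.** Acceptance-style simulations run
  with 300-tree forests (not 2000), C_max = 12 and 250–300 sweep caps to fit
  a single-CPU budget; these affect variance, not the comparisons being made.

## Known limitations

- Single-run VB finds local optima; the multi-run protocol (`--runs`, best
  AUROC then lowest RMSE) is the supported mitigation, as in the original
  workflow.
- Per-module sign indeterminacy is inherent to CP; downstream analyses use
  ranks, |Spearman| or classifiers, all sign-robust, but raw activities are
  only comparable within a fit (and across cohorts only via the projection
  gauge above).
- The model fits observed relative abundances as unconstrained Gaussian; it
  does not model compositionality, zero-inflation, or sequencing depth.
- The 2D variant's subject factors are per-sample; subject-level summaries
  must be aggregated by the caller.
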