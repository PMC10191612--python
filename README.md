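# microtensor

Microbial module discovery from longitudinal microbiome data by sparse
Bayesian tensor factorization.

## The problem

Longitudinal gut-microbiome studies profile the same subjects repeatedly,
producing species-level relative-abundance tables whose structure is naturally
a third-order tensor: subjects × taxa × visits. Conventional analyses test
taxa one at a time and ignore both the grouping of ecologically related taxa
and the correlation between repeated measures of a subject. `microtensor`
factorizes the abundance tensor into **microbial modules** — groups of taxa
that share a latent abundance pattern — together with each module's activity
per subject and its trajectory over visits, and provides the downstream
statistics used to characterize modules: association with clinical factors,
intramodule co-occurrence, subject classification, and projection of the
modules onto external cohorts. It is aimed at microbiome researchers with
longitudinal case/control cohorts (the motivating application is inflammatory
bowel disease).

## The model

The abundance tensor χ ∈ R^{N×L×K} (N subjects, L taxa, K visits) is modeled
as a sparse CP decomposition with at most C_max components ("modules"):

    χ_nlk ~ N( Σ_c H_nc · M_cl · T_kc ,  λ_nk⁻¹ )

- **H** (N×C): module activities per subject, H_nc ~ N(0, 1).
- **M** (C×L): taxon loadings under a spike-and-slab prior, reparameterized
  as M_cl = ω_cl·s_cl with ω_cl ~ N(0, β_c⁻¹), s_cl ~ Bernoulli(p_cl),
  p_cl ~ Beta(a, b). The point mass at zero induces exact sparsity: each
  module loads on a small taxon subset, and unused components empty out, so
  the effective number of modules C ≤ C_max is learned from the data.
- **T** (K×C): visit trajectories. The *visit-correlated* model places a
  first-order random-walk prior T_kc ~ N(T_{k−1,c}, Λ_c⁻¹) that encodes the
  smooth change of gut communities between neighboring visits; a
  *visit-uncorrelated* variant (i.i.d. prior) and a *matrix-2d* variant
  (samples × taxa, no visit mode) are included for comparison.
- **λ, Λ, β**: per-sample noise precisions, per-module temporal precisions
  and slab precisions, all with broad Gamma priors.

Inference is conjugate mean-field variational Bayes (all updates closed-form;
the ELBO is non-decreasing by construction). A taxon is a **member** of module
c when its posterior inclusion probability PIP_cl = E[s_cl] exceeds 0.5.
Missing visits are masked out of the likelihood, so incomplete designs and
external cohorts are handled directly; an external tensor is projected onto
fitted modules by clamping M and re-estimating H′ and T′.

## Worked example

```python
import numpy as np
from microtensor import (
    BayesianTensorFactorization, simulate_case_control, call_modules,
    associate_modules, membership_recovery,
)

# a labeled synthetic cohort: 60 subjects x 80 taxa x 10 visits, 6 planted
# modules, the first shifted by 2 SD between cases and controls
tensor, labels, truth = simulate_case_control(
    N_case=30, N_control=30, affected_modules=(0,), effect_size=2.0, seed=0)

fit = BayesianTensorFactorization(
    n_modules_max=12, max_iter=300, random_state=0).fit(tensor)
modules = call_modules(fit)                      # PIP > 0.5 membership
f1, jaccard, _ = membership_recovery(truth.S, modules)
assoc = associate_modules(
    fit.subject_factors_[:, fit.active_modules_], labels,
    module_ids=fit.active_modules_, fdr_cut=0.25)

print(f"{fit.n_modules_} modules, RMSE {fit.rmse_:.3f}, recovery F1 {f1:.2f}")
print("disease-associated modules:", list(assoc.module_ids[assoc.significant]))
```

This prints

```
8 modules, RMSE 0.259, recovery F1 0.88
disease-associated modules: [5]
```

meaning: the spike-and-slab prior kept 8 of 12 allowed modules, the
reconstruction error is about a quarter of the data scale (the data are
noisy by design, SNR 10 before clipping), the called memberships match the
planted ones at F1 ≈ 0.9, and the Wilcoxon rank-sum test with
Benjamini–Hochberg control flags exactly one fitted module — the one that
matches the planted case/control module — at FDR ≤ 0.25.

The same workflow is available from the shell:

```bash
microtensor simulate --seed 0 --out sim/
microtensor fit --tensor sim/ --cmax 12 --out fit/
microtensor modules --tensor sim/ --fit fit/ --out mods/
microtensor associate --tensor sim/ --fit fit/ --out assoc/
microtensor classify --tensor sim/ --fit fit/ --out clf/
```

Real profiles enter through `read_profiles` (MetaPhlAn-style TSV) and
`read_metadata`, with the standard cohort filters (taxon prevalence ≥ 10%,
subjects with ≥ 10 samples, 10 visits selected at roughly equal intervals).

## Acceptance script

`scripts/acceptance.py` runs the complete discovery-to-validation workflow
from scratch: it simulates a labeled cohort, fits the visit-correlated model,
calls modules and scores them against the planted truth, tests module–disease
associations, compares intramodule co-occurrence with size-matched
random-group nulls, cross-validates a random-forest classifier on the module
activities, and projects a held-out cohort through the fixed taxon loadings.

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Progress and summary figures are printed to stderr; the JSON result object is
written to the `--out` path.
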