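# nestfidelity

Hierarchical Bayesian models of fine-scale **nest-site fidelity** and
**nest survival** for long-term capture-mark-reencounter data on nesting
birds, with a native MCMC engine, convergence diagnostics, posterior
predictive checks, and a calibrated synthetic-data generator.

The package is aimed at avian ecologists testing the *win-stay
lose-switch* hypothesis — that birds return to a nest site after a
successful breeding attempt and disperse after a failure — and asking
whether that strategy is adaptive, i.e. whether dispersing farther after
failure improves subsequent nest survival. It was built around the
emperor goose (*Anser canagicus*) study system on the Yukon–Kuskokwim
Delta (245 marked females, 2000–2017, major floods in 2010 and 2013),
but the models apply to any dataset of consecutive-year nest encounters
with coordinates, fates, and visit histories.

## The models

**Nest-site fidelity.** Dispersal distance d (meters between an
individual's nests in consecutive years) is modelled on the log scale
with a heavy-tailed location-scale Student-t whose residual scale σ_k
and degrees of freedom κ_k depend on previous nest fate k:

    log d_ij ~ t(g_ij, σ_k², κ_k)
    g_ij  = α_j + β_f f_{i,j−1} + β_f×w f_{i,j−1} w_{j−1} + ϵ_ind,i
    α_j   = μ + η_s s_j + η_w w_{j−1} + ϵ_yr,j

with previous fate f (0 success / 1 fail), flood indicator w, spring
timing index s, and normal individual and year random effects. Unknown
previous fates are latent Bernoulli variables whose prior failure
probability is `1 − ∏ φ_a` over the daily survival probabilities from
the age at last check through the 28-day exposure period, with
informative beta priors on the φ's — a built-in missing-data model
rather than censoring.

**Nest survival.** Visit histories become exposure intervals of length
l days with survived/failed outcomes, `y ~ Bernoulli(φ^l)`, and daily
survival φ is logit-linear in dispersal distance, previous fate, and
their interaction, with a random year intercept around the grand mean δ
and individual random effects. 28-day nest survival is derived as φ²⁸.
A positive dispersal-by-fate interaction γ_d×f is the adaptive-fidelity
signal: birds that failed and moved farther survive better.

Inference: adaptive Metropolis-within-Gibbs with noncentered random
effects, split-chain Gelman–Rubin R̂, posterior medians, 95% highest
posterior density intervals, sign probabilities ρ, and Bayesian
p-values from posterior predictive replicates. See `docs/methods.md`
for the full account.

## Worked example

Simulate one study-scale dataset (the calibrated default scenario) and
fit the fidelity model with the fast preset:

```python
import nestfidelity as nf
from nestfidelity.data_model import build_exposure_intervals
from nestfidelity.inference import MCMCConfig, fit_fidelity

cfg = nf.default_scenario(seed=0)           # 245 birds, 2000–2017
pairs = nf.simulate_fidelity_data(cfg)      # ~600 consecutive-year pairs
prior = nf.DailySurvivalPrior.neutral(cfg.years)
post = fit_fidelity(pairs, prior, MCMCConfig.fast(seed=1))
print(post.summary().round(3))
```

```
             median  hpdi_lo  hpdi_hi    rho   rhat      ess
parameter
mu            4.773    4.639    4.914  1.000  1.004   627.8
beta_f        0.443    0.169    0.701  1.000  1.002   710.8
beta_fxw     -0.499   -1.238    0.199  0.921  1.002   863.2
eta_w         0.265   -0.009    0.564  0.966  1.004   732.8
eta_s         0.004   -0.024    0.031  0.610  1.002  1281.8
sigma_ind     0.663    0.553    0.771  1.000  1.001   754.3
sigma_yr      0.059    0.000    0.176  1.000  1.001   762.6
sigma_0       0.783    0.670    0.890  1.000  1.001   594.4
sigma_1       0.552    0.286    0.798  1.000  1.003   508.8
log_kappa_0   1.255    0.876    1.610  1.000  1.001   720.4
log_kappa_1   0.898    0.164    1.682  0.993  1.004   726.2
```

The previous-fate coefficient β_f = 0.443 (95% HPDI 0.169–0.701,
ρ ≈ 1.0) recovers the generating value 0.506: previously failed birds
disperse about e^0.44 ≈ 1.6 times farther. Marginalized expected
dispersal distances follow from the posterior:

```python
import numpy as np
from nestfidelity.fidelity import expected_dispersal
med0, _ = expected_dispersal(post, f=0, w=0, rng=np.random.default_rng(0))
med1, _ = expected_dispersal(post, f=1, w=0, rng=np.random.default_rng(0))
print(round(med0, 1), round(med1, 1))   # 118.6 184.9 (meters)
```

i.e. ~119 m for previously successful birds vs ~185 m after a failure,
against generating values 125.5 m and 207.7 m. The survival side works
the same way through `fit_survival`; with the same simulated truth it
recovers mean daily nest survival `logit⁻¹(δ) ≈ 0.992–0.995` and a
positive dispersal-by-fate interaction.

A shell workflow is also available:

```bash
nestfidelity simulate --seed 0 --out simdata
nestfidelity fit-fidelity --data simdata --preset fast --out fit_f
nestfidelity fit-survival --data simdata --preset fast --out fit_s
nestfidelity run-all --seed 0 --out report   # end-to-end incl. PPC tables
```

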