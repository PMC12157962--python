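# npidce

Discrete choice experiments (DCEs) for pandemic-policy preference studies:
design blocked stated-preference surveys over nonpharmaceutical
interventions (NPIs), simulate respondent panels, estimate mixed-logit and
latent-class mixed-logit models by maximum simulated likelihood, and report
willingness to pay (WTP).

The package is aimed at health-preference researchers and modellers who
want a transparent, fully scripted version of the analysis pipeline behind
NPI preference surveys: which restrictions (mask mandates, dining limits,
quarantine rules, booster mandates) a population would accept when a new
variant emerges, how much money those preferences are worth, and which
demographic groups cluster into pro- and anti-restriction segments.

## The models

Respondent *i*'s utility for alternative *j* is

```
U_ij = beta_i' x_j + eps_ij        eps_ij ~ i.i.d. type-1 extreme value
beta_i = beta + eta_i              eta_i  ~ N(0, diag(sigma^2))
```

where `x_j` holds dummy codes for each non-reference attribute level
(reference = least stringent level), a one-time fee in SGD, and a left-
position constant (ASC). The mixed logit (MXL) estimates the population
means `beta` and heterogeneity SDs `sigma` by maximum simulated likelihood
over scrambled-Halton draws. The mixed-mixed multinomial logit (MMML) adds
latent classes: class-specific `beta_c, sigma_c` with membership
probabilities `P(c|z_i) ∝ exp(gamma_c' z_i)` driven by respondent
covariates; the class count is chosen by BIC. WTP for level k is
`beta_k / |beta_fee|`.

See `docs/methods.md` for the design-construction criterion, estimation
details, and validation-study sizes.

## Worked example

Generate the canonical design (20 blocks × 7 binary tasks over the
seven-attribute NPI space), simulate 1500 respondents from known taste
parameters, and fit the mixed logit:

```python
import numpy as np
import npidce as dce

space = dce.AttributeSpace.canonical()
design = dce.generate_design(space, dce.DesignDims.for_space(space), seed=1)
print(dce.sample_size_requirements(design.dims))
# SampleSize(orme_n=143, block_rule_n=400, recommended_n=400)

truth = np.array([-0.08, 0.54, 0.59, -0.89, -0.33, 0.19,
                  -0.05, -0.07, -0.37, 0.10, 0.03, -0.02])   # means, fee last
sigma = np.zeros(12); sigma[[1, 2, 3, 8, 10]] = 0.8          # heterogeneity

profiles = dce.simulate_profiles(1500, seed=2)
data = dce.simulate_choices(
    design, profiles,
    dce.SimulationConfig(classes=(dce.TasteClass(truth, sigma),)), seed=3)
fit = dce.fit_mxl(data, R=300, seed=4)
print(fit.summary_frame().round(3))
```

which prints (abridged)

```
log-likelihood -6269.2, converged=True
                             term  coefficient    se  ci_low  ci_high  p_value
                         asc_left       -0.099 0.028  -0.154   -0.043    0.001
           masks:mandatory_public        0.486 0.050   0.389    0.583    0.000
               dining:not_allowed       -0.903 0.059  -1.019   -0.787    0.000
   quarantine:government_facility       -0.446 0.047  -0.538   -0.354    0.000
                              fee       -0.020 0.001  -0.022   -0.019    0.000
        sd:masks:mandatory_public        0.947 0.071   0.809    1.086    0.000
```

The fitted means sit on the simulated truth to within sampling error — a
small negative left-position bias, support for mask mandates, opposition to
a dining ban and to government-facility quarantine, and a fee coefficient
of −0.02 per SGD. Significant `sd:` rows flag the attributes with real
individual-level heterogeneity. Converting to money,

```python
print(dce.compute_wtp(fit).round(2))
```

```
                          term    wtp  wtp_rounded  ci_low  ci_high        direction
        masks:mandatory_public  23.78           24   18.81    28.75 pay_to_implement
            dining:not_allowed -44.16          -44  -50.29   -38.03     pay_to_avoid
quarantine:government_facility -21.80          -22  -26.50   -17.09     pay_to_avoid
```

i.e. this synthetic population would pay ~24 SGD to have public mask
mandates implemented and ~44 SGD to avoid a ban on dining in.

For latent classes: `dce.select_k(data, k_range=(1, 2, 3), ...)` returns
the BIC-best class count; `dce.fit_mmml(data, K=2, ...)` reports
class-specific coefficient tables, class shares, per-respondent posterior
probabilities, and membership odds ratios (`dce.membership_odds_ratios`).

The same pipeline is scriptable from the shell:

```
npidce run --config config.yaml --seed 1 --out results/
npidce design --blocks 20 --tasks 7 --seed 1 --out design_out/
```

`npidce run` writes design CSVs, the simulated (or ingested) long-format
dataset, MXL and MMML summary tables, the BIC table, WTP and preference
grids, and a `manifest.json` with every sub-seed — rerunning the same
config is bit-identical.

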