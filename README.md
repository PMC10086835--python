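# ostreg — ordinal state-trait regression for intensive longitudinal data

Experience-sampling and other intensive longitudinal studies measure mental
states repeatedly for each participant, almost always on ordinal scales
("how stressed are you right now?", 0–6).  Multilevel models can split the
association between two such variables into a **between-person (trait)**
component — do typically-stressed people think less pleasant thoughts? — and
a **within-person (state)** component — are *moments* of higher-than-usual
stress accompanied by less pleasant thoughts?  The standard linear
mixed-model decomposition treats both variables as continuous; `ostreg`
implements the ordinal-on-ordinal version, for analysts of experience
sampling / EMA data who want the disaggregation without pretending their
7-point scales are interval measurements.

## Model

For subject *i*, occasion *j*, with ordinal predictor x<sub>ij</sub> and
response y<sub>ij</sub>, let x̃<sub>i</sub> be the subject's median predictor
level (the trait).  A latent continuous response

    l_ij = f(x̃_i, x_ij) + u_i + eps_ij,   u_i ~ N(0, sigma_u^2),  eps_ij ~ logistic

is cut at thresholds theta_1 < ... < theta_{My-1} (theta_1 = -1) to give the
observed category, i.e. logit P(Y_ij <= m) = theta_m - f(x̃_i, x_ij) - u_i.
The surface decomposes as f(r, s) = alpha + tau_r + gamma_{r,s} (trait and
state effects, with tau at the global median and gamma on the diagonal fixed
to 0).  Unrestricted, f has one coefficient per observed trait-state pair;
restricted to a linear surface it is the classical three-coefficient
between/within model.  `ostreg`'s estimator maximizes the marginal
likelihood minus a quadratic penalty

    (lambda/2) * J*(f),   J*(f) = sum (D_rr f)^2 + 2 sum (D_rs f)^2 + sum (D_ss f)^2,

the sum of squared discrete second differences of f, which vanishes exactly
on linear surfaces: lambda = 0 gives the saturated fit, lambda -> infinity
the linear model, and a Laplace-approximate marginal criterion picks lambda
in between.  Effective degrees of freedom tr[(H + lambda P)^{-1} H] quantify
the shrinkage, and AIC (with a shrinkage-uncertainty-corrected complexity
term) compares the penalized fit against both extremes.  See
`docs/methods.md` for details and numerical choices.

## Worked example

Simulate one replicate of the nonlinear benchmark setting (cube-root trait
and state effects, 400 subjects x 15 occasions) and fit the penalized model:

```python
import numpy as np
import ostreg

cfg = ostreg.SimConfig(p=1/3, seed=42)
panel = ostreg.trim_response_levels(
    ostreg.simulate_panel(cfg, np.random.default_rng(cfg.seed)))
traits = ostreg.person_medians(panel)
keys = ostreg.key_set(panel, traits)
layout = ostreg.coef_layout(keys, traits.global_median)
penalty = ostreg.build_penalty_spec(keys, layout)

spec = ostreg.ModelSpec(m_y=panel.m_y, mode="penalized",
                        layout=layout, penalty=penalty)
lam, res = ostreg.select_lambda(spec, panel, traits, keys)
print(f"selected lambda: {lam:.3g}")
print(f"fixed-effect EDF: {res.edf_fixed:.2f} of {layout.n_params}")
print(f"sigma_u: {res.sigma_u_hat:.3f}")

trait_fit = ostreg.fit_trait_only(panel, traits, keys)
rep = ostreg.R2Report.from_fits(res, trait_fit, panel, traits)
print(f"R2 state+trait: {rep.r2_state_trait:.3f}  "
      f"R2 trait-only: {rep.r2_trait_only:.3f}  ratio: {rep.ratio:.2f}")
```

Output:

```
selected lambda: 10
fixed-effect EDF: 12.08 of 40
sigma_u: 1.020
R2 state+trait: 0.160  R2 trait-only: 0.002  ratio: 0.01
```

The selector keeps 12 effective coefficients out of 40 — the data reject the
3-coefficient linear surface (the truth here is nonlinear) but do not
support the saturated one.  The random-intercept SD recovers the generating
value 1.  The latent R² of 0.16 drops to essentially zero when the state
term is deleted: this simulated relationship is almost purely state-driven,
matching the generating surface, whose state coefficient (−0.72) dominates
its trait coefficient (−0.15).

The same pipeline runs from the shell on a long-format CSV
(`subject,obs,x,y` columns):

```
ostreg fit mydata.csv --mode penalized --outdir results/
ostreg simulate --p 0.3333 --reps 5 --seed 1 --outdir sim/
ostreg grid ema.csv --vars pleasant,stressed,exhausted --outdir grid/
```

`fit` writes the fit summary (JSON), a coefficient table with standardized
estimates (CSV), the latent-R² report, and the fitted trait-by-state surface
as a matrix CSV; `grid` fits every ordered response-predictor pair and
tabulates R² ratios.

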