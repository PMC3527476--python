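# matlact

Two-stage Bayesian analysis of **maternal-lactation programming** in dairy
cattle: does it matter, for a cow's adult performance, whether her embryonic
and fetal development took place while her mother was lactating?

Most Holstein cows are conceived around the dam's lactation peak, when the
mammary gland and the conceptus compete for nutrients. The package estimates
the long-term effect of three maternal circumstances at conception —
presence and parity of an open maternal lactation, the dam's milk-yield
level, and maternal mastitis episodes — on three first-lactation traits of
the daughter:

* **MY** — 305-d standardized milk yield (kg),
* **FP** — milk fat/protein ratio (%), a metabolic-efficiency indicator,
* **DIM** — lifetime days in milk (d), a functional-longevity proxy.

Because the national milk-recording data this kind of study uses is
proprietary, the package ships a synthetic herd generator that emulates the
data's full structure (multi-generation half-sib pedigree, herd-year /
year-region / age-at-first-parity effects, dam lactation histories with
monthly test days, calibrated conception timing, mastitis flags) and plants
known maternal effects, so the entire pipeline is validated by parameter
recovery.

## The model

Stage 1 adjusts each trait for environment and genetics with a Bayesian
animal model,

```
y = X b + Z u + e,   u ~ N(0, A σ²_u),   e ~ N(0, I σ²_e),
```

where `A` is the pedigree numerator relationship matrix (built from
Meuwissen–Luo inbreeding coefficients; its sparse inverse by Henderson's
rules), `b` holds the environmental effects (plus a milk covariate for the
lifespan trait, making it functional longevity), and inference is
single-site Gibbs with conjugate normal / scaled-inverse-χ² conditionals.

Stage 2 regresses the posterior-mean residuals `ê = y − X E[b] − Z E[u]` on
one maternal factor at a time,

```
ê = μ1 + M m + e_m,
```

with flat-by-large-variance priors on `μ, m`. Each maternal level is
summarised against the reference (gestation in a non-lactating dam) by its
posterior-mean contrast, Monte-Carlo standard error (batch means), the
2.5–97.5% equal-tail interval, and a sign probability. A complementary
generalized linear model estimates the concurrence effect separately inside
the top and bottom deciles of estimated genetic merit.

## Worked example

```python
from matlact import (recovery_preset, simulate_herd, apply_filters,
                     assign_circumstance, a_inverse, build_stage1_model,
                     fit_animal_model, extract_residuals, GibbsConfig,
                     build_stage2_model, fit_maternal_model, contrast_table)

r = simulate_herd(recovery_preset())           # ~10,000 cows, ~25,000 pedigree
kept, log = apply_filters(r.phenotypes, r.testdays, r.pedigree)
circ = assign_circumstance(kept, r.testdays)   # maternal exposures per cow

model = build_stage1_model(kept, r.pedigree, "MY", a_inverse(r.pedigree))
chain = fit_animal_model(model, GibbsConfig(n_iter=5000, burn_in=500, seed=42))
res = extract_residuals(model, chain)

chain2 = fit_maternal_model(build_stage2_model(res, circ, "lact_group"),
                            GibbsConfig(n_iter=5000, burn_in=500, seed=7))
print(contrast_table(chain2).round(2).to_string(index=False))
```

Output (planted effects −18 / −47 / −91 kg for concurrence with maternal
lactation 1 / 2 / 3+ against gestation in a heifer):

```
    factor  level   mean  mcse   q2.5  q97.5  prob_negative
lact_group      1 -18.14  0.03 -22.67 -13.50            1.0
lact_group      2 -44.67  0.04 -49.87 -39.44            1.0
lact_group      3 -87.55  0.05 -93.71 -81.50            1.0
```

The posterior means recover the planted penalties: cows gestated during a
maternal lactation produce less milk as adults, and the deficit grows with
the dam's parity. The same machinery yields the lifespan and fat/protein
contrasts, the dam-yield-decile profile, the mastitis contrast, and the
merit-stratified coefficients.

A command-line pipeline wraps the same steps
(`matlact run-all --preset recovery --out-dir out --seed 1`), writing every
intermediate table as headered CSV with a JSON metadata sidecar.

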