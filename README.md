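# equiuse

Income-related inequality in the use of public health services, estimated
from two-wave cross-sectional survey microdata with jointly fitted two-part
hurdle models.

## The problem

Universal health systems promise access regardless of income, but an
economic shock can still shift *who uses which service*. Measuring that
shift from health-survey microdata requires solving several problems at
once, and this package implements the full chain as tested, reusable
components:

1. **Income harmonization** — the two survey waves report net family income
   in incompatible interval schemes (8 annual bands vs 10 monthly bands).
   A per-wave ordered probit on demographics places respondents on a
   common latent scale; the standardized score is the interval-censored
   conditional mean `E[y* | X, band]`, cut into within-wave quartiles
   (quartile 1 = poorest, the reference).
2. **Public/private split** — surveys record only the ownership of the
   *last* contact. Single-visit respondents reveal it directly; a logistic
   model fitted on them splits multi-visit totals into private
   (= round(total x p-hat), banker's rounding) and public, conserving
   `public + private = total` exactly.
3. **Annualization** — primary/specialist contacts are asked per 4 weeks
   and multiplied by 12 for users; for zero reporters, a delay model imputes
   a single annual contact when the predicted probability that care was
   sought after more than 4 weeks exceeds 0.5.
4. **Hurdle estimation** — for each service, ownership and wave, the use
   decision is a logistic regression (dispersion fixed at 1) and the
   frequency among users a zero-truncated negative binomial with NB1
   dispersion (`psi = mu/phi`), estimated **jointly**, optionally with a
   household Gaussian random intercept integrated by Gauss–Hermite
   quadrature under a penalised-complexity-style penalty on `sigma_u`.
5. **Inequality reporting** — quartile x wave descriptive tables (Wilcoxon
   rank-sum / Fisher exact wave comparisons, percent changes) and the
   nested Model 1→2→3 sequence (income only; + gender, age; + private
   insurance, GHQ-12), reported as odds/rate ratios against quartile 1.

A seeded synthetic-survey generator inverts the full model, so everything
is testable without access to restricted microdata.

Audience: health economists and biostatisticians working with utilization
counts from repeated cross-sectional surveys, and anyone needing a
reference implementation of a joint logistic x zero-truncated-NB1 hurdle
with random effects.

## The model

Part 1 (any use): `logit P(y>0 | X1) = X1'b1`, `Var = mu1(1-mu1)`.

Part 2 (frequency among users):

```
f2(y | y>0) = [ G(y+psi)/(G(psi) G(y+1)) * (mu2/(mu2+psi))^y ]
              / ( ((mu2+psi)/psi)^psi - 1 )
mu2 = exp(X2'b2),  psi = mu2/phi
```

The parts multiply in the likelihood and are maximized together; random
intercepts `u_j ~ N(0, sigma_u^2)` enter both linear predictors. See
`docs/methods.md` for the numerics, the penalty calibration and the design
discussion.

## Worked example

```python
from equiuse import (GeneratorConfig, generate_survey, run_pipeline,
                     run_model_sequence, descriptive_table)
from equiuse.report import format_descriptive_table

cfg = GeneratorConfig().scaled(5000, seed=42)   # 5,000 respondents per wave
records, truth = generate_survey(cfg)
out, stages = run_pipeline(records)             # quartiles, split, annualized

table = format_descriptive_table(descriptive_table(out))
print(table[(table.variable == "emergency_year_public")
            & (table.quartile.isin([0, 1, 4]))]
      [["variable", "quartile", "mean_2006", "mean_2011",
        "pct_change", "p_value"]].to_string(index=False))
```

```
             variable  quartile  mean_2006  mean_2011  pct_change  p_value
emergency_year_public         0      0.554      0.543        -1.9    0.920
emergency_year_public         1      0.712      0.712         0.0    0.601
emergency_year_public         4      0.370      0.413        11.5    0.214
```

Mean annual public emergency contacts: quartile 1 (poorest) uses the
service about twice as often as quartile 4, and neither cell shifts
significantly between waves (this generator run has no wave effect).
The adjusted model says the same thing as ratios against quartile 1:

```python
res = run_model_sequence(out, "emergency", "total", models=(3,))
r = res[2006].ratios
print(r[r.part == 1][["quartile", "ratio", "lower", "upper"]]
      .round(3).to_string(index=False))
```

```
quartile  ratio  lower  upper
      q2  0.694  0.581  0.831
      q3  0.545  0.452  0.657
      q4  0.416  0.340  0.509
```

Model 3 part-1 odds ratios: after adjusting for sex, age, insurance and
GHQ-12, richer quartiles are markedly less likely to use emergency services
(Q4 odds 0.42 times Q1's, CI 0.34–0.51) — recovering the pro-poor gradient
the generator was configured with (true Q4 log-odds -0.76, odds ratio 0.47).

The same stages are available from the shell:

```bash
equiuse simulate --config cfg.yaml --seed 12 --out survey.csv
equiuse standardize --in survey.csv --out scored.csv
equiuse fit --in survey.csv --model 3 --service emergency --out ratios.csv
equiuse report --in survey.csv --out table.csv
```

Each command writes a `.manifest.json` (seed, config hash, package
versions) next to its output.

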