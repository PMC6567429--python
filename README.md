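# hiequity

Income-related inequity analysis of healthcare utilization for
CHARLS-style survey data (a Chinese middle-aged/elderly health survey
with rural respondents split between two medical insurance schemes,
URRBMI and NCMS). The package is aimed at health-economics and
health-services researchers who want a tested, reproducible
implementation of the standard concentration-index workflow —
weighted fractional income ranks, Pearson chi-square group comparison,
weighted logistic regression with average marginal effects,
concentration-index decomposition, and the horizontal inequity (HI)
index — together with a synthetic survey generator so the whole
pipeline can be exercised without access to the restricted microdata.

## The statistics

For a utilization outcome `y` (e.g. "outpatient visit in the last
month") and the weighted fractional income rank `r` (midpoint
cumulative weighted population share, so `mean_w(r) = 1/2`), the
concentration index is

```
C = (2 / mu) * cov_w(y, r),        mu = mean_w(y),
```

equivalently twice the area between the concentration curve (cumulative
outcome share vs. cumulative population share, poorest first) and the
diagonal. `C > 0` means utilization concentrated among the rich,
`C < 0` among the poor.

Each outcome is modelled by weighted logit
`ln(p/(1-p)) = alpha + sum_j beta_j x_j` over need covariates (gender,
age band, self-assessed health, chronic disease) and socioeconomic
covariates (marital status, education, income quintile, region,
community). Writing `AME_j` for the average marginal effect of
regressor `j` on the probability scale, `C` decomposes as

```
C = sum_j (AME_j * xbar_j / ybar) * C_j  +  GC_u / ybar,
```

where `C_j` is regressor `j`'s concentration index against the same
rank vector and the last term is the residual. Summing the need terms
gives the need contribution, and

```
HI = C - (need contribution)
```

is the horizontal inequity index: the income-related inequality in
utilization that remains after differences justified by health need are
removed. `HI > 0` is pro-rich inequity, `HI < 0` pro-poor.

## Worked example

```
python analysis/01_simulate.py --seed 1   # synthetic survey, 9002 rows
python analysis/02_describe.py            # scheme comparison, chi-square
python analysis/03_fit_outcomes.py        # logit + dy/dx per scheme/outcome
python analysis/04_decompose.py           # CI decomposition and HI
```

The first step prints the realized margins of the generated survey:

```
wrote 9002 respondents (3593 URRBMI, 5409 NCMS)
outpatient 20.3%  inpatient 12.6%  chronic 77.4%
income quintile bounds (yuan): 17, 508, 2226, 9914
```

i.e. a heavily right-skewed income distribution (a fifth of respondents
below ~17 yuan per capita) with roughly one in five respondents using
outpatient care in the last month. The final step prints, per scheme
and outcome, the concentration index, its need/socioeconomic/residual
split, and the HI index:

```
URRBMI outpatient: C=-0.0014  need=-0.0122  socio=+0.0169  residual=-0.0061  HI=+0.0108 (pro-rich)
URRBMI inpatient: C=-0.0467  need=-0.0105  socio=-0.0256  residual=-0.0106  HI=-0.0362 (pro-poor)
NCMS outpatient: C=+0.0418  need=-0.0063  socio=+0.0542  residual=-0.0060  HI=+0.0481 (pro-rich)
NCMS inpatient: C=-0.0568  need=-0.0046  socio=-0.0399  residual=-0.0124  HI=-0.0522 (pro-poor)
```

Reading the first line: raw outpatient utilization in the URRBMI group
is essentially unrelated to income (`C ≈ 0`), but that balance is the
sum of a pro-poor need gradient (the poor are sicker, `need = -0.012`)
and a pro-rich socioeconomic gradient (`socio = +0.017`); removing the
need part leaves `HI = +0.011`, a pro-rich inequity in outpatient care
at equal need. Inpatient care shows the opposite, pro-poor pattern —
the sign structure the generator builds in.

The same stages are available as a CLI
(`hiequity simulate|describe|fit|decompose|run`) and as library
functions (`hiequity.estimate_hi`, `hiequity.run_full_analysis`).

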