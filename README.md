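# noiselag

Spatio-temporal lagged logistic modelling of call-for-service events on an
irregular areal lattice.

Municipal complaint data — typically calls to a local police force about
noise disturbances — arrive as timestamped events located in small
administrative areas (boroughs) grouped into districts. `noiselag` turns
such an event stream into a complete space-time panel and models the
probability that *at least one* call occurs in a given area, on a given
day, in a given period of the day (day 05:00–21:59 / night 22:00–04:59),
as a function of the calendar, the recent call history of the area and its
neighbors, and area-level socio-demographic and environmental covariates.
It is written for spatial epidemiologists and crime analysts who want an
interpretable, odds-ratio-based account of a "social noise" process and
short-term probability maps of where the next calls are likely.

## The model

For cell $(i, t, p)$ — unit $i$, study day $t$, period $p$ — the binary
response $Y_{itp} = \mathbb{1}\{\text{at least one call}\}$ follows a
binomial logistic model

$$
\operatorname{logit} P(Y_{itp} = 1) = \beta_0
  + \beta_{\text{wd}(t)} + \beta_{\text{mo}(t)} + \beta_p
  + \sum_{s=1}^{2}\sum_{\ell=0}^{2} \gamma_{s\ell}\, L^{(s\ell)}_{itp}
  + \beta_{d(i)} + \boldsymbol{\beta}^\top \mathbf{x}_{i,\text{yr}(t)},
$$

where $L^{(s\ell)}_{itp}$ dichotomizes the call count $s$ weeks earlier
($t - 7s$, same period) in unit $i$ itself ($\ell = 0$), in its first-order
contiguity neighborhood ($\ell = 1$: units sharing a border), or in its
second-order neighborhood ($\ell = 2$: units at border-graph distance
exactly two). Weekday, month, period and district enter through treatment
coding (references: Sunday, June, day, first district), population enters
as $\ln(\text{inhab})$, and the remaining covariates (age-structure
percentages, household size, bar/restaurant density, socio-economic
vulnerability index, main-road km, building age, educational/green land
use, and a *botellón* street-drinking indicator) enter untransformed.
$\exp(\beta)$ is the multiplicative change in the odds of a call per unit
covariate change; intervals are Wald, $\exp(\beta \pm 1.96\,\mathrm{SE})$.

Because the lag terms feed realized outcomes back into the linear
predictor, the same equation run forwards in time defines an autologistic
data generator; the package ships this simulator plus a parameter-recovery
harness, so the whole pipeline is testable without confidential call data.

## Worked example

`examples/` contains one short script per capability. Fitting a simulated
year on a 20-unit lattice (`examples/03_fit_and_odds_ratios.py`) prints:

```
n = 14640, residual df = 14600, deviance = 9206.5

selected odds ratios (true period effect 0.63, lag effects 0.13-0.20):
                beta     se  odds_ratio  ci_lower  ci_upper
term
period[night]  0.664  0.058       1.942     1.734     2.176
noisebin1      0.107  0.063       1.113     0.983     1.260
noisebin2      0.229  0.063       1.258     1.113     1.422
noisebin11     0.024  0.067       1.025     0.898     1.169
noisebin21     0.327  0.066       1.387     1.219     1.579
```

The night indicator multiplies the odds of a call by ≈1.9 relative to the
day period, and a call in the same unit two weeks earlier (`noisebin2`)
raises the odds by ≈26%; each estimate sits within sampling error of the
coefficient that generated the data. The scenario mapper
(`examples/04_probability_map.py`) then contrasts winter and summer nights:

```
Monday nights, January: mean probability 0.093
Sunday nights, June:    mean probability 0.323
```

with the five most probable units flagged in each map — summer weekend
nights triple the average call probability, and the top-5 set shifts with
each scenario's recent call history through the lag terms.

The command-line interface mirrors the library:
`noiselag simulate | build-panel | fit | deviance | map | recover`,
each writing CSV/GeoJSON outputs plus a JSON run manifest.

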