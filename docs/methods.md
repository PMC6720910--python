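# Methods

This note documents the modelling conventions, numerical choices and the
synthetic data generator behind `noiselag`, and states what the shipped
tests do and do not establish.

## Model and assumptions

The unit of analysis is the cell (areal unit, study day, period). The
response is the dichotomized call count: the model addresses *whether* at
least one call occurs, not how many. Conditional on the cell's own
covariates and the realized call history of the previous two weeks, cells
are treated as independent Bernoulli draws; all residual spatial structure
is carried by the district factor and the unit-level covariates, and all
residual temporal structure by the weekday/month/period terms and the six
lag indicators. There are no random effects, no CAR/spatial-error term,
and no overdispersion concept (none is needed for a Bernoulli response).
District rather than unit enters as the spatial-heterogeneity factor:
with ~70 units and year-level covariates, unit fixed effects would absorb
the covariates of interest and overfit.

## Panel construction conventions

* **Periods.** Day is 05:00–21:59 (17 hours), night 22:00–04:59 (7
  hours); the two partition the 24-hour cycle. Calls between 00:00 and
  04:59 belong to the *calendar date on which they occur*, not to the
  previous evening's night session — the one convention reproducible from
  the raw timestamp alone.
* **Lags are period-matched.** "One week before" means the same period on
  day $t-7$. A night cell looks back at night cells; day and night
  histories never mix, which preserves the day/night contrast the period
  term estimates.
* **Neighborhoods.** First order = units sharing a border (positive-length
  boundary contact for polygons — rook-style; corner contact does not
  count). Second order = units at border-graph distance exactly two, so
  the two neighbor sets are disjoint, as the separate order-1/order-2
  coefficients presuppose. Neighbor lag aggregates are *unweighted sums*
  of neighbor counts, dichotomized afterwards; after dichotomization the
  row-standardized $1/n_i$ weights cannot change the indicator, so the
  weighted and unweighted definitions coincide (the weight matrix is still
  computed and exportable). Isolated units get lag values of 0, not
  missing, and stay in the panel.
* **Trimming.** Cells in the first 14 study days have undefined two-week
  lags and are dropped before fitting, leaving $U \times (D-14) \times 2$
  records; for a 70-unit, 730-day window that is 100,240 rows and an
  intercept-only residual df of 100,239.

## Design and coding

Treatment coding throughout, with fixed full level sets for weekday,
month and period so that any two panels over the same units produce
column-compatible designs. Reference levels: Sunday, June, day, and the
first district in sorted order (all configurable via `DesignSpec`).
Population size enters as its natural logarithm, which makes
$\exp(\beta \cdot \ln m)$ the odds multiplier of a population growth
factor $m$. Categorical scenario levels and covariate joins are validated
eagerly with named errors (missing unit-year, non-positive population,
unknown level).

## Fitting numerics

Maximum likelihood by Newton–Raphson IRLS with step-halving (up to 20
halvings per step) to keep the deviance monotone. Stopping: largest score
component below `1e-8`, or relative deviance change below `1e-12`;
iteration cap 100. Standard errors come from the inverse observed
information at the optimum; Wald intervals use the fixed multiplier 1.96;
p-values are kept at full precision. A rank-deficient design raises an
error naming every column with weight in the design's null space (so all
members of a collinear group are reported). Separation — a diverging
coefficient norm with fitted probabilities saturating on correctly
classified observations, or any coefficient beyond ±30 — raises an error
rather than returning a silently divergent fit. The weight clip at
`1e-10` only guards degenerate cells and never binds in a regular fit.

The sequential analysis of deviance adds terms one at a time, each row
reporting the deviance reduction, its degrees of freedom and the
$\chi^2$ upper-tail p-value. The default order is the model's term order
with the district factor added *last*, which keeps the residual-df column
monotone; nested fits are warm-started from the previous solution but
converge to the same optimum as cold starts (the telescoping identity —
drops summing to null minus full deviance within `1e-8` — is asserted in
the tests).

Scenario probability maps evaluate the fitted inverse logit per unit
under a chosen (weekday, month, period, year), taking each unit's six lag
values from the most recent panel date inside the scenario year whose
weekday and month match the scenario — the map is conditioned on realized
recent history, exactly as the model would be used operationally. The
covariate correlation report masks Pearson coefficients whose two-sided
t-test p-value reaches the chosen level (default 0.05) and masks constant
columns entirely, with a warning.

## Synthetic data generator

The generator emulates a mid-sized Mediterranean city's call process at
the scale of ~70 boroughs in 16 districts over up to two years:

* **Lattice.** A 7×10 rook grid by default (or a Delaunay triangulation
  of random points for an irregular variant), with districts grown as
  spatially contiguous blocks by multi-source breadth-first search.
* **Covariates.** Populations are log-normal with median 8,000; the age
  split is a Dirichlet draw; bar/restaurant density is gamma; the
  socio-economic vulnerability index is uniform on [1, 5]; land-use
  shares are scaled betas; the botellón indicator is Bernoulli with
  probability increasing in bar density (reproducing its spatial
  association with nightlife). Second-year values are first-year values
  plus ~2% drift, clipped to their ranges.
* **Occurrence.** The model equation run forwards: the first 14 days are
  seeded exogenously at probability 0.16, after which each cell draws
  Bernoulli(inverse-logit of the assembled predictor), with lag
  indicators computed from the simulation's own realized history under
  the same period-matched rules the panel builder applies. The default
  true coefficients are of the magnitude typical for this kind of
  call-occurrence analysis (night +0.63; weekday/month effects between
  −1.0 and −0.08 against Sunday/June; lag effects 0.07–0.20 with one
  slightly negative order-2 term; covariate effects from −2.04
  for household size to +0.93 for log population, building age at
  −0.005 so the term stays estimable). The intercept default of −8.2 was
  calibrated once, at design time, so the long-run occurrence prevalence
  is ≈0.16 — a moderate rate matching the panel sparsity this kind of
  complaint data exhibits — and is not adjusted thereafter.
* **Counts and hours.** Occurrence is what the model can identify; an
  occurring cell receives $1 + \text{Poisson}(0.35)$ calls with hours
  uniform inside the period, enough for the emitted event stream to
  round-trip *exactly* through the panel builder (asserted as an
  invariant).

What the generator does **not** emulate: human mobility, weather,
holidays, within-period time-of-day structure, reporting behavior, count
clustering beyond the single Poisson overlay, or any covariate
measurement error. Passing tests therefore establish correctness of the
pipeline and calibration *under the model's own mechanism*, not that the
model is adequate for any particular city's data.

## Recovery harness and problem sizes

`parameter_recovery` runs, per replicate: simulate → emit events →
rebuild the panel through the panel module → trim → fit, recording each
term's estimate, Wald interval and p-value against the truth. The
calibration checks use 100 replicates at 70 units × 400 days — large
enough for per-term binomial tolerances to be meaningful while keeping a
full run in the low minutes on one CPU. Bands were fixed in advance:
per-term 95% interval coverage must lie within a binomial band around
0.95 whose half-width uses a Bonferroni-adjusted normal quantile across
the ~52 terms (≈0.95 ± 0.081 at 100 replicates), and with all six lag
coefficients truly zero the pooled Wald 5% rejection rate over the lag
terms must lie in 0.05 ± 0.04. Isolated replicate failures (an unlucky
quasi-separated draw) are recorded, not fatal.

## Known limitations

* Short panels are rejected at fit time in practice: the fixed full level
  sets mean a window that does not visit every month leaves structurally
  zero columns and a named rank error. Fit windows should cover a full
  year (the simulator's default and examples use ≥380 days).
* The Wald intervals are asymptotic; at very low per-unit event counts
  (tiny lattices, short horizons) they can undercover, and
  quasi-separation becomes more likely — both visible in the recovery
  report rather than silently absorbed.
* The probability map's lag-history rule (most recent matching date in
  the scenario year) is one defensible choice among several; scenarios
  whose weekday/month combination never occurs in the panel raise an
  error rather than extrapolating.
* GeoJSON handling covers polygon contiguity and property export only;
  choropleth rendering is deliberately out of scope.
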