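# Methods

## Scope and model

vlwkit monetizes health loss with the value-of-a-statistical-life-year
(VSLY) framework. The unit of health loss is the DALY; the unit of money
is the PPP constant 2021 international dollar (Int$), carried internally
at full precision and converted to millions only in reports. The chain per
country *i* and year *t*:

- benefit transfer: `VSL_i = VSL_ref · (GDPpc_i / GDPpc_ref)^IE`;
- annualization: `FLE_i = f · HALE_i`, `VSLY_i = VSL_i / FLE_i`;
- monetization: `VLW_i = DALYs_i · VSLY_i`, applied to the point estimate
  and both 95% UI bounds;
- normalization: `share_i = 100 · VLW_i / GDP_i`.

Assumptions inherited from the framework: the VSL depends on income alone
(no cultural, legal or health-system adjustment); income elasticity is
cross-nationally comparable; a single HALE estimate per location is applied
uniformly (HALE at the location level, not age-specific — an age-specific
HALE at the midpoint of the 15–39 band can be supplied through the econ
table if desired, since HALE enters only through one column); no
discounting of future life-years. The reference VSL is treated as already
expressed in Int$ at the reference country's price level, so no currency
conversion step exists.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `vsl_ref` | 11.8 × 10⁶ | Int$ (2021) | reference VSL (2021 US official estimate) |
| `gdp_pc_ref` | — (required) | Int$/person | per-capita GDP of the reference country |
| `income_elasticity` | 1.0 | — | VSL income scaling; sweep set {0.55, 1.0, 1.5}; accepted range [0.1, 3.0] |
| `fle_fraction` | 0.5 | — | FLE as a fraction of HALE |

At IE = 1 the VSL is proportional to income and the GDP *share* becomes
independent of the income level (it reduces to a rate/HALE ratio), which is
why elasticity choices move absolute VLW strongly but shares only through
the income-ratio exponent.

## Uncertainty propagation

Burden UIs are the only uncertainty source carried: VLW bounds are the DALY
bounds times the same VSLY (a monotone linear map, so interval ordering is
preserved at every stage). Aggregates sum bounds bound-wise across
countries — no independence assumption, hence conservative (wider than a
quadrature combination would be). No uncertainty is attached to the VSL,
to imputed macro values, or to projections by default.

## Readers and filtering rules

The burden reader accepts results-export CSVs (configurable dialect;
defaults: `location_name, sex_name, age_name, cause_name, metric_name,
measure_name, year, val, upper, lower`). It keeps DALY measures with metric
`Number` and the three diabetes causes; rows with other metrics, measures
or causes are dropped and every drop is counted in the log. Ages 15–39 may
arrive either as a single band or as the five 5-year bands; bands are
summed bound-wise, and the summation is order-independent. A combined-sex
stratum is preferred when present; otherwise male + female are summed
bound-wise. A point estimate outside its own interval is an error, never a
silent fix.

The econ reader accepts wide (years as columns, one row per
location × variable) or long (location/year/variable/value) layouts.
Missing cells are preserved as NaN for imputation; duplicate observations
and non-numeric cells are errors. The accounting identity
`gdp_total ≈ gdp_pc × population` is enforced within 1% on observed rows
only (regression-imputed cells need not satisfy it exactly).

## Imputation

Missing macro cells are filled per location by OLS of log(value) on year
(log scale because GDP evolves multiplicatively; a linear-in-level scale is
selectable), using all observed years in the window (default 2000–2021),
with a minimum of 3 observed points. Locations with 1–2 points are extended
from their nearest observation using the median per-year log-growth of
their region's countries (HALE, which moves slowly, is carried over flat).
Observed values are never touched (imputation is idempotent), every filled
cell is flagged in the table and logged, and burden values are never
imputed.

## Aggregation

Aggregate VLW is the bound-wise sum over member countries; the aggregate
share is `100 · ΣVLW / ΣGDP` (GDP-weighted), not the mean of country
shares — the only definition that keeps "percent of GDP" meaningful at
every level. Consequently the global total equals the sum over regions and
equals the sum over SDI quintiles (both partition the same country set),
and an aggregate share always lies between its members' shares.

`consistency_report` audits a wide report table for cause additivity
(|overall − T1 − T2|). The headline flag uses the VLW discrepancy with a
0.02-million default tolerance — twice the 0.01 slack created when
components are independently rounded to two decimals — and the share
analogue is reported under its own flag, because published share columns
are rounded coarsely relative to their magnitude and can disagree by more
than rounding alone explains.

## Projection

No standard method exists for projecting a monetized burden, so the module
makes every assumption explicit and configurable rather than claiming a
canonical one. Default: per location-cause OLS of log(DALY count) on year
over 2000–2021 (≥5 years required) gives a constant exponential rate g;
then `DALYs_t = DALYs_baseline · e^{g(t − baseline)}`; alternatives are
linear-in-count (floored at zero) and flat carry-forward. Each projected
year is re-valued with the same valuation core under an economic scenario:

- **static** (default): GDP and VSLY frozen at baseline, so
  `share_t / share_0 = VLW_t / VLW_0` identically;
- **dynamic**: per-capita and total GDP grow at a configured rate and the
  VSLY is re-derived each year.

Projections carry point estimates only by default; optionally the UI bounds
are scaled by the same growth factor. Extrapolating a 21-year log-linear
trend 29 years out is a strong assumption; the output is a scenario, not a
forecast with calibrated uncertainty.

## Synthetic worlds

The generator emulates the *structure* of the real inputs with known ground
truth, deliberately without calibrating magnitudes to real-world totals:

- incomes lognormal (`log GDPpc ~ N(9.5, 1.0)`, median ≈ Int$13k with a
  realistic cross-country spread); population lognormal; GDP identity exact;
- HALE = 25 + 4·log(GDPpc) + noise (≈ 55–75 years over the income range);
- overall DALY rates start at 400 per 100k persons aged 15–39 and are
  multiplied by `exp(−0.8 · income rank)`, so poorer countries carry higher
  rates — absolute VLW then concentrates in rich countries while VLW/GDP
  concentrates in poor ones, the qualitative pattern the method exposes;
- type 1 is 20% of the overall rate and type 2 the rest, so subtype
  additivity holds exactly by construction;
- DALYs grow at 2%/yr and GDP at 3%/yr back through 2000–2021, with
  optional lognormal observation noise (default 0 — the generator's truth
  path and the pipeline must then agree to floating-point);
- the richest country is designated the benefit-transfer reference.

Ground truth (per-country VSL, VSLY, VLW, share) is computed inside the
generator by plain closed-form arithmetic sharing no code with the
valuation module, so truth-vs-pipeline equality is a genuine oracle test.
What the synthetic world does **not** emulate: real GBD magnitudes and
country counts (30 countries, 6 regions by default — chosen for sub-second
tests), age/sex structure beyond a single band, correlated macro shocks,
non-stationary growth, and reporting artifacts of real extracts. Passing
tests therefore demonstrate correctness of the arithmetic, filters,
aggregation and propagation rules — not calibration against real data.

## Numerical choices and edge cases

- All money in float64 Int$; reports round to 2 decimals (millions /
  percent) at the very end.
- OLS fits use statsmodels; tests cross-check slopes against hand-coded
  normal equations.
- Degenerate inputs fail loudly: non-positive income, HALE or GDP, a point
  estimate outside its UI, an unmatched burden location, a horizon before
  the baseline, a log-scale fit on non-positive counts (the error suggests
  the linear model).
- Ties in the income rank (probability zero under continuous draws) would
  share a rank via argsort; the SDI quintile assignment floors rank × 5.

## Known limitations

- Benefit transfer from a single reference country ignores heterogeneity in
  willingness to pay beyond income.
- Bound-wise UI summation overstates aggregate uncertainty when country
  errors are independent.
- The FLE ≈ HALE/2 approximation treats every DALY as losing half a healthy
  life-year regardless of the age at which it is lost.
- The default projection holds the economy static, which understates VSLY
  growth in converging economies; the dynamic scenario bounds that effect
  but uses a single global growth rate.
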