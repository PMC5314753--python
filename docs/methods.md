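# Methods

This note documents the models implemented in `mhplan`, the defaults in
`src/mhplan/data/default.yaml`, and what the synthetic fixture does and
does not emulate.

## Synthetic study population

The pipeline is exercised on a generated, Syria-like population rather than
on external data tables.

**Pyramid.** `make_population` builds a quasi-stable age structure
n(a) ∝ e^(−g·a)·l(a) on single years of age 0–100 (100 closed terminal
age), with intrinsic growth g = 0.025/year and survivorship l from the
mortality schedule. This yields a young pyramid (38% under 15) typical of
the region. The total, 2.2×10⁶ / 0.129 ≈ 17.05 million, is anchored so that
a 12.9% PTSD prevalence produces ≈2.2 million cases; the companion
depression case count implies a smaller population at 7.6% prevalence, so
one anchor had to be chosen and the PTSD figure, being the analysis' lead
number, won. A consequence is that the fixture carries ≈1.30 million
depression cases rather than 1.1 million.

**Mortality.** Gompertz–Makeham hazard h(a) = A + B·e^(θa) with A = 0.002,
B = 5×10⁻⁵, θ = 0.09 per year, giving a period life expectancy at birth of
71.6 years (checked against a survivorship life table). There is no infant-
or conflict-mortality hump; the Makeham floor stands in for both.

**Prevalence curves.** A gamma density parameterised by mode (25 years) and
standard deviation (15 years) gives the unimodal age profile; the curve is
then rescaled so that its population-weighted mean equals the target
age-standardised prevalence *exactly* (tested to 1×10⁻⁹). Standardising
against the same population that generates the cases means age-standardised
and crude rates coincide here.

**Uncertainty distributions.** Stated 95% intervals become seeded draw
distributions: lognormal for rates (both interval endpoints matched in
closed form) and beta for proportions (both endpoints matched by least
squares on the two quantiles). Degenerate intervals produce constant
draws. Empirical 2.5/97.5 percentiles recover the stated bounds within 2%
relative at 10⁵ draws.

What the fixture does **not** emulate: sex-specific structure (a scalar
female share of 0.494 serves the perinatal computation), migration and
displacement, conflict-related excess mortality, and sampling noise in the
prevalence inputs. Passing tests therefore demonstrate the correctness of
the modelling chain under clean inputs, not robustness to real-data
artefacts.

## Severity models and disability weights

Each disorder's prevalent cases split into asymptomatic / mild / moderate /
severe classes; YLD = cases × Σ proportion × DW. The disability weights
are the GBD 2010 values (depression 0.159/0.406/0.655, anxiety
0.030/0.133/0.523, with their published 95% intervals); PTSD uses the
anxiety-disorders model as a proxy since PTSD is not assessed separately in
that framework. Class proportions respect the documented moderate+severe
shares (28% depression, 30% anxiety) and are otherwise set so that the
severity-weighted mean DW reproduces the published YLD totals from the
published case counts (within 2% for PTSD, 5% for depression). Comorbid
cases contribute to both disorders' burden; a multiplicative DW combination
1 − (1−dw₁)(1−dw₂) is available (`combine_dws`) but off by default, since
no implementable comorbidity-adjustment recipe accompanies the disorder-
level totals being reproduced.

Monte-Carlo propagation draws the standardised prevalence and each class DW
independently, scales cases proportionally, and reports the draw mean as
the point estimate (mirroring spreadsheet-bootstrap practice) alongside the
deterministic product; the 95% UI is the empirical 2.5/97.5 percentile.
With skewed prevalence intervals the draw mean sits above the deterministic
product — both are reported.

## Service and workforce model

Eligibility: moderate–severe cases aged 15+ per group (PTSD-only 30%,
depression-only and comorbid 28% of cases), plus a perinatal group of
women 15–44 × fertility 0.11 × perinatal-depression prevalence 0.15 ×
moderate–severe share 0.28. PTSD-only cases receive the depression packages
of care minus all inpatient treatment; comorbid cases receive the full
packages including inpatient care and are counted once.

Coverage ramps from a 1% baseline to each package's target over t = 0..14
(2015–2029): linearly, c(t) = c₀ + (c_T − c₀)·t/14, or exponentially,
c(t) = c₀·(c_T/c₀)^(t/14) — the named shapes admit these as the natural
interpolants. Both agree at the endpoints, and linear dominates between
them. The population (and with it the eligible pool) grows at 1.5%/year,
reaching ≈21 million in 2029.

Resource arithmetic, per year: visits = eligible × coverage × proportion
receiving × visits/person, by treatment type (primary care, ancillary,
outpatient); bed-days = eligible × coverage × percentage use × bed-days per
person; beds = bed-days/365 × 1.15 (86% occupancy); outpatient FTE per
provider = Σ_type visits × share / (consults/day × days/year); inpatient
FTE = beds/25 × staff per ward. Everything is kept unrounded internally;
reports round beds to integers and FTE to one decimal.

The numeric package/staffing defaults are free parameters of the tool. They
were chosen in the mhGAP style and **calibrated once** against the published
headline resource quantities (baseline ≈37,000 primary-care, 78,000
ancillary and 6,000 outpatient visits, ≈1,000 bed-days; 0.3 → ≈7.6 FTE per
100,000 with ≈1,600 workers in 2029 and the published provider mix), then
frozen; they are flagged `derived` in the YAML and should not be read as
source data. One structural observation from the calibration: the published
endpoint visit totals and FTE endpoints are only jointly satisfiable if
consultation rates differ by treatment type — brief primary-care contacts
(30/day) versus ancillary outreach (8.4/day) and outpatient sessions
(8/day) — which is how the defaults are set.

## Illness-death solver

States S (healthy), C (diseased), D (dead) with age-specific hazards:
incidence i (S→C), remission r (C→S), background mortality m (both→D) and
excess case mortality f (C→D, on top of m). Within each one-year step the
hazards are constant and the linear system is solved exactly with a 3×3
matrix exponential — not with independent annual probabilities — so
competing risks are treated consistently, mass is conserved to machine
precision, and the step agrees with a fine-grid ODE integration to 1×10⁻⁶
relative. Disorder defaults: depression r = 1.40/year (the printed value;
an annual duration of 37.7 weeks back-computes to ≈1.38 — the printed
figure is used), mortality RR 1.9 converted by the standard f = m·(RR−1);
PTSD r = 0.17/year with f ≡ 0.

`fit_incidence` back-calculates i(a) from a prevalence curve given r, f, m:
a bisection on i(a) ∈ [0, 10] (tolerance 1×10⁻⁸, ≤200 iterations) makes one
year of propagation land on the target prevalence at a+1, age by age.
Where prevalence declines faster than remission plus mortality allow,
incidence is clamped at zero and the age logged — real-world prevalence
inputs can be internally inconsistent, and the diagnostic makes that
visible. Round-trip (forward-propagate the fitted incidence) reproduces
the target within 1×10⁻⁶; recovery of a known generating incidence is
accurate to <1%.

## Multi-cohort Markov benefit model

Six adult cohorts (15–29, 30–44, 45–59, 60–69, 70–79, 80+) are represented
by mid-ages 22, 37, 52, 64.5, 74.5 and 85 — midpoints for the bands where
no mid-age is documented, 85 for the open band — and propagated 15 years,
with hazards interpolated at fractional ages and truncated at the terminal
age. Two disorder streams are modelled: PTSD (PTSD-only cases) and comorbid
depression/PTSD (depression parameters). Depression-only cases ride in the
comorbid stream by default (`include_depression_only`), so the whole
moderate–severe burden is covered; the option exists because the stream
definition nominally contains only comorbid cases.

Scenarios set the scale-up coverage series s(t): partial-null 0 (all
services removed — the comparator), current 1% constant, target30 and
target100 ramping from 1% to 30%/100%. Package k has overall efficacy e_k
and coverage share c_k; combined effectiveness is the WHO-CHOICE form
eff(t) = 1 − Π_k (1 − c_k·s(t)·e_k), isolated in one function so an
alternative combination rule can be swapped in. Effectiveness acts as
r′ = r·(1 + Δr·eff) and dw′ = dw·(1 − Δdw·eff); YLD(t) = C(t) ×
moderate–severe share × dw′(t), and DALY ≡ YLD (case fatality for these
disorders is too low for a meaningful YLL term). Percent averted =
100 × (comparator − scenario)/comparator. Discounting (sensitivity
analysis) divides year t by 1.03^t with t = 0 undiscounted; it moves the
target30 percent averted by ≈0.7 points.

The intervention effect sizes are not published for this configuration
(they derive from prior cost-effectiveness work), so the defaults
(Δr = 0.22, Δdw = 0.885; package efficacies 0.30/0.25/0.40 with shares
1.0/0.8/0.3) were **calibrated once** against the published outcome bands —
the percent averted under linear scale-up placed at 8.5% for the 30% target
(band 7–9%), which then yields 24.3% at full coverage (band 23–27%) without
further adjustment — and frozen, marked `derived` in the YAML. The
calibration is dominated by the disability-weight channel because the
remission channel saturates (doubling an already-fast remission of
1.40/year removes few prevalent case-years) and the multiplicative
combination rule compresses high-coverage effectiveness.

The engine contains no randomness: scenario results are pure functions of
the configuration.

## Numerical and design choices

- Ages are integer single years 0–100 everywhere; fractional mid-ages use
  linear interpolation of hazards.
- Case counts, visits, beds and FTE are real-valued internally; rounding
  (half-even for case reports, nearest integer for beds) happens only at
  report time.
- Comorbid cases are ρ × PTSD cases age by age (ρ = 0.50), clamped at the
  depression case count with a logged warning if exceeded.
- All generators take explicit seeds (default 20150101, recorded in the
  config); the pipeline writes a manifest with the config hash and seed so
  reruns are byte-identical.
- Validation is exhaustive: `load_config` reports every schema violation it
  finds, and a failed stage aborts the pipeline naming the stage.

## Problem sizes

The default test-and-demonstration configuration uses the full 101-age
grid, 2,000–100,000 Monte-Carlo draws depending on the check, six cohorts ×
two streams × eight scenario-mode combinations; the complete pipeline runs
in a few seconds on one CPU, which is the intended scale for interactive
planning use.

## Known limitations

- No YLL/mortality component in the DALY beyond state bookkeeping, no
  costing layer, and no disorders beyond depression, PTSD and their
  comorbidity; perinatal depression enters the service model only.
- The upstream prevalence meta-regression is out of scope: prevalences are
  fixed inputs with intervals, not re-estimated.
- Calibrated defaults reproduce published headline outputs by construction
  at the calibration points; away from those points they are plausible
  mhGAP-style settings, not measurements.
- The no-migration, fixed-growth population assumption is unrealistic for a
  population experiencing mass displacement; the service model accepts
  projected populations but ships with a smooth 1.5%/year default.
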