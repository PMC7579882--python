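# Methods

## Site-months planning model

The planner treats recruitment capacity as *site-months*: one site open
to recruitment for one month. A trial needing sample size N at per-site
intensity λ patients/site/month (λ = eligible patients/site/month ×
recruitment rate; the two factors only ever enter as a product, so
either reading of "recruitment rate" — consent fraction or absolute
rate — is accommodated by setting the other factor to 1) over an accrual
window of T months, with average opening latency L months, requires

    n = ceil( N / (λ (T − L)) )

sites. Rounding is **ceiling to whole sites**, which is the convention
that makes the worked 240/9 = 26.67 → 27 example come out; ceiling also
guarantees a surplus, n·λ·(T−L) ≥ N. The latency default is 6 months —
the observed median opening delay of 5.2 months rises to ~6 once
pharmacy sign-off is included — but it is a parameter everywhere, never
a constant.

Mid-trial top-ups are priced with two separate latencies, because a
shortfall is only visible after a *recognition* latency and the new
sites then need their own *opening* latency:
`ceil(shortfall / (T − L_recognise − L_open))`. When that window is zero
or negative the function raises (the CLI reports "not recoverable"): no
count of top-up sites can recover the capacity, which is the
quantitative argument for over-provisioning at the outset.

`plan_report` compares an optimistic plan (the latency assumed when the
grant was costed, default 3 months) against the realistic latency, and
reports planned sites, required vs achievable site-months, capacity
fraction, shortfall, and the implied top-up. All month↔day conversions
use 30.4375 days/month.

## Survival analysis of set-up delays

Site opening (and first-patient recruitment) are right-censored
time-to-event data: a site that has not opened by study close
contributes its observed waiting time without an event. The
product-limit estimator is implemented from first principles:

- S(t) = Π_{t_i ≤ t} (1 − d_i/n_i) over distinct observed event times;
  subjects censored at an event time are kept in that time's risk set
  (events-precede-censorings tie convention).
- Greenwood variance Var[S(t)] = S(t)² Σ d_i/(n_i(n_i−d_i)).
- Median: the **earliest event time with S(t) ≤ 0.5**, no interpolation
  (a 1e-12 absolute tolerance absorbs cumprod round-off when S sits
  exactly on one half). A curve that never reaches 0.5 yields an
  explicit "not reached" (`None`), not an error.
- Median CI by band inversion (Brookmeyer-Crowley): pointwise
  confidence limits on the log(−log S) scale,
  S^{exp(±z·se)} with se = sqrt(Σ d/(n(n−d)))/|log S|, and the CI bounds
  are the earliest times the lower/upper limit crosses 0.5; either bound
  may be "not reached". This matches lifelines' construction exactly,
  which the tests exploit as an independent oracle (agreement to 1e-12
  on the curve, exact on the CI).
- Two-sample log-rank (Mantel-Cox): Σ(O−E) with hypergeometric variance
  at each distinct event time, χ² reference with 1 df. A degenerate
  comparison with zero variance (e.g. identical curves) returns χ²=0,
  p=1 rather than 0/0.
- `combine_delays` adds per-site component durations (approval→open plus
  open→first patient); the combined event is observed only if both
  components were, otherwise the site is censored at its total observed
  time. Samples carrying site ids are aligned by id; mismatched site
  sets are an error.

Empty input, all-censored input, and one-group log-rank input raise
distinct errors (`ValueError` vs `AllCensoredError`).

## Synthetic site tables

The generator emulates the reported delay structure of a 48-site UK
rare-disease trial, which published summary statistics but no site-level
data. Defaults are that stated world:

| parameter | default | basis |
|---|---|---|
| n_sites | 48 | sites in the ethics submissions |
| open_probability | 43/48 | 43 (90%) opened |
| delay_median_days | 182 | median approval→open delay |
| delay_log_sd | 0.6196 | 613-day slowest site placed at the 97.5% point |
| pharmacy_holdup_probability | 4/43 | 4 (9%) sites held up by pharmacy |
| pharmacy_holdup_range_days | (10, 102) | reported range of pharmacy delays |
| first_patient_median_days | 87 | median open→first-patient delay |
| first_patient_log_sd | 0.6 | chosen to match the opening-delay skew |
| region_fraction_slow | 6/48 | six London sites |
| slow_region_delay_multiplier | 242/182 | London vs overall median delay |
| eligible × recruitment_rate | 1 × 0.4 | 120 patients / 20 sites / 15 months |
| study_end_day | 730 | ~2-year observation window |

Delays are **log-normal** — positive, right-skewed, and exactly
identified by a median plus one tail quantile, which is the information
such reports give. The reported range endpoints (18, 613) are treated as
approximate extreme order statistics, not truncation bounds;
`calibrate_lognormal` inverts the quantile function in closed form. The
"months" in the reported first-patient median ("87 months [41–130
days]") is taken as a typo for days.

Generation order per site: region, a would-open Bernoulli draw, a
log-normal base delay (× the slow-region multiplier), an optional
additive uniform pharmacy hold-up (pharmacy sign-off then coincides with
opening; otherwise sign-off is placed uniformly before opening), a
log-normal first-patient delay (also × the multiplier: the slow region
lagged at both stages in the source experience), and a Poisson
recruitment count at rate λ over the site's open time after its first
patient (so an observed first patient implies ≥1 recruit, and a censored
one implies 0). Any opening or first-patient time beyond
`study_end_day` is censored; would-never-open sites are censored there
too. Every site draws from its own spawn-keyed substream of the root
seed, so enlarging `n_sites` reproduces the earlier sites byte-for-byte.
Approvals all sit at day 0: every downstream quantity is a duration from
approval, so a staggered approval calendar would add a knob without
changing anything the package estimates.

What a green test does and does not establish: the generator reproduces
the *marginal* delay structure and group effect it was calibrated to; it
does not model the approval pipeline's internal stages, site-level
recruitment-rate heterogeneity beyond the region multiplier, seasonal
effects, or dropout, and real multicentre data violate the independence
of sites that everything here assumes.

An observation from the property tests worth recording: with
never-opening sites included, the *combined* approval→first-patient
log-rank can be less powerful than the open→first-patient comparison,
because unopened sites enter the combined sample as long censored
observations that dilute the risk sets. On the clean cohort where every
site opens, the combined comparison is the sharpest of the three — the
qualitative pattern reported in the source experience (only the combined
London comparison reached p < 0.05).

## Accrual simulation

Each replicate: site *i* opens at delay D_i drawn from the delay model
(fixed, or log-normal with an optional never-open probability), then
recruits as a homogeneous Poisson process at λ until the accrual horizon
— a site open for w days contributes Poisson(λw/30.4375) recruits at
i.i.d. uniform times; recruitment after the horizon is never counted
(fixed funding window). Replicates use spawn-keyed substreams, so
summaries are reproducible and seed-paired comparisons (monotonicity in
n_sites and λ) are exact.

`validate_formula` is the consistency check between simulator and closed
form: with n = required_sites(plan) sites and a delay distribution whose
**mean** equals the plan latency, expected recruits are
n·λ·(T−L) ≥ N. The formula prices latency as a point value, so the check
is exact only for deterministic delays; a right-skewed delay calibrated
by its *median* has a larger mean, making a median-calibrated plan
optimistic. By default a mean/latency mismatch raises; with
`require_mean_match=False` the report instead carries
`latency_consistent=False` and withholds the consistency verdict — both
behaviours are deliberate, because silently "passing" a median-calibrated
model would assert a guarantee the formula does not make.

## Numerical choices

- Ceiling with a 1e-9 guard (`ceil(x − 1e-9)`) so float noise cannot
  push an exactly attainable ratio to the next integer.
- Integer day offsets in stored tables; day 0 = study start; `NA` marks
  censored/absent values in the CSV dialect.
- Seeds: one root seed per artifact; per-site and per-replicate
  substreams via `SeedSequence(entropy=seed, spawn_key=(i,))`.
- Log-rank variance terms skip risk sets of size 1 (the hypergeometric
  variance factor (n−d)/(n−1) is undefined there and the term is 0).

## Limitations

- No Cox regression, covariate adjustment, or >2-group tests.
- No cost modelling; the planner prices capacity in site-months only.
- The simulator's consistency check quantifies, but does not correct,
  the optimism of median-calibrated latency assumptions.
- Reported site-level findings of the motivating trial (e.g. its exact
  median CI or the London p-values) are not reproducible without the
  unpublished raw data; the package instead demonstrates parameter
  recovery and calibration on synthetic cohorts generated from the
  published summaries.
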