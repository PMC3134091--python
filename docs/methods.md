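# Methods

## Decision problem and model structure

The package evaluates which NSAID to start in adults with ankylosing
spondylitis (base case: age 45) over horizons of 1, 5 and 30 annual
cycles.  Health states encode current treatment:

| # | State | Drug cost/yr (NOK) | BASFI/BASDAI source |
|---|-------|--------------------|---------------------|
| 1 | Initial NSAID | arm drug | background + arm CFB |
| 2 | Initial NSAID + PPI | arm drug + 3,050 | background + arm CFB |
| 3 | Alternative nsNSAID | 1,484 | background + mean(diclofenac, naproxen) CFB |
| 4 | Alternative nsNSAID + PPI | 1,484 + 3,050 | as state 3 |
| 5 | Alternative nsNSAID + PPI + aspirin | + 383 | as state 3 |
| 6 | Anti-TNFα | 143,322 | fixed (23, 19) |
| 7 | Anti-TNFα discontinued | 0 | fixed (55, 52) |
| 8 | Dead | 0 | — |

All patients start in state 1.  Background BASFI progresses by
Uniform(0, 1) points/yr on the 0–100 scale (mean 0.5/yr); background
BASDAI is constant.  The registry table prints the progression interval
as (0, 0.10); we read those bounds as being on a 0–10 scale, since the
accompanying text states 0.5 points per annum on the 0–100 scale.  Both
readings are expressible through the registry file.

### Within-cycle event allocation

Each cycle, a living NSAID-state patient faces (in this order, only for
the degenerate renormalisation case): thrombotic CV event, upper-GI PUB,
suspected PUB, minor GI symptoms, edema, hypertension, CHF, hepatic and
renal events, then lack-of-efficacy discontinuation.  Probabilities are
applied *unconditioned* to start-of-cycle occupancy, as mutually
exclusive slices; the no-event remainder is exposed to age-dependent
background mortality.  We chose unconditioned allocation over a
sequentially conditioned tree after implementing both: only the
unconditioned form reproduces the model's own printed single-cycle
component costs exactly (e.g. year-1 other-AE cost = p(CHF)×cost(CHF)
with no survival factors) and the stated ~11.2 expected years on NSAID
therapy, and it matches the stated convention that background mortality
applies to patients not experiencing an adverse event.  Sampled
probability sets never sum above one in practice (the engine renormalises
defensively and conserves occupancy to 1e-9 per cycle).

Routing: survived CV events lead to state 5 (from state 5, to anti-TNF);
survived PUBs lead from states 1–2 to state 4 and from states 3–5 to
anti-TNF; suspected PUB/minor GI add a PPI where none is present and
otherwise only generate cost/disutility; the five other adverse events
always switch to the next treatment line (a fraction < 1 is a config
knob in the event-tree builder via the probabilities themselves); lack
of efficacy moves initial states to state 3/4 and alternative states to
anti-TNF.  Second CV events use the same CV probability as the first.
The anti-TNF state has no adverse events and loses Beta(13.2, 118.8)
(mean 0.10) of its occupants per year, permanently.  Case fatalities:
PUB 3.6%; CV 13% (coxib) / 12.8% (nsNSAID); both fixed.

### Rewards

Rewards use start-of-cycle occupancy with no half-cycle correction;
discounting is `(1+r)^-(t-1)` (first cycle undiscounted) at r = 4%
(0%/8% in scenarios).  This convention is forced by the year-1 treatment
cost equalling the undiscounted annual drug cost.  State utility is
`clamp(c + b_f·BASFI + b_d·BASDAI, 0, 1)` with Normal-distributed
coefficients (c = 0.924 (0.017), b_f = b_d = −0.004); the registry's
0.924 constant is used, treating a 0.923 variant as rounding.  Event
disutilities and event costs accrue only in the cycle of occurrence.
Expected PUB cost/disutility weights the hospitalisation (Uniform(0.056,
0.358)), surgery-given-hospitalisation (Uniform(0.12, 0.39)) and
outpatient pathways; suspected PUBs weight the Beta(36.5, 109.5)
inpatient-investigation split; minor GI symptoms are always treated.
Only CHF among the "other" adverse events carries a cost (45,958 NOK).
Death in a cycle does not retract that cycle's rewards (dead-state
utility is zero from the next cycle).

## Evidence synthesis

Both MTC likelihoods share the linear predictor `mu_i + d_t` (reference:
placebo; `d_placebo = 0`) with Normal(0, 100²) priors.  BASDAI and
discontinuation evidence pool diclofenac/naproxen into one nsNSAID node,
mirroring how the trials report them.  The base case is fixed-effect —
with at most two trials per contrast, between-trial heterogeneity is
unidentifiable — and an arm-level random-effects variant with a
half-normal heterogeneity prior is available (it ignores multi-arm
correlation, acceptable for a config option at this network size).

Sampling uses a self-contained adaptive random-walk
Metropolis-within-Gibbs sampler (4 chains vectorised, 20,000
iterations/chain by default, 50% burn-in during which proposal scales
adapt toward ~44% acceptance).  Split-chain scale-reduction and a crude
autocorrelation-based effective sample size are reported; fits warn
above 1.05.

**Anchoring.**  Absolute treatment-level values are built per draw as
`anchor + d_t` (identity link) or `expit(anchor + d_t)` (logit), where
the anchor is the unweighted mean of the baselines of trials that
randomised placebo.  The evidence source reports absolute values without
stating its rule; this convention reproduces all of its printed
posterior means (e.g. etoricoxib BASFI −17.9, discontinuation 0.062,
pooled nsNSAID 0.148) and is documented as this implementation's choice.
Trial-duration-to-annual conversion for discontinuation is the identity.

## Parameter uncertainty

Registry entries published with explicit distributions (the Beta rows,
uniforms, the Normal utility coefficients) are used as printed.  Rows
published only as mean + 95% interval are moment-matched: the mean is
matched exactly and the single free scale parameter is solved by
root-finding so the central 95% width matches — lognormal for rate-like
safety parameters, beta for probabilities/disutilities, gamma for costs.
Width (not endpoint) matching is what a two-parameter family with a
fixed mean can deliver; for the published Beta(13.2, 118.8) example the
fit recovers (13.6, 122.1), within 3%.  Rows printed without
uncertainty (case fatalities, PPI risk reduction, drug costs, the CV and
CHF event costs) are fixed constants in the PSA.  Interval bounds
printed as 0.0000 are treated as rounded-to-zero quantiles.

Each PSA iteration shares one joint draw across all strategies (common
random numbers), which the per-draw increments, CEAC and P(best)
require; MTC outcomes are resampled jointly within an outcome and
independently across the three outcomes (they come from separate fits).
The combined celecoxib arm mixes the 200 mg and 400 mg dose parameters
50/50 at the parameter level (validated by the printed year-1 drug cost
4,977 = (3,318+6,636)/2); second-line nsNSAID efficacy is the mean of
the diclofenac and naproxen draws.  ICERs are ratios of mean increments
(per-draw ratios are unstable); NMB ties split probability mass evenly;
the WTP grid runs 0–1,000,000 NOK in 10,000 steps.

## Life table

No official annual mortality table is bundled; a Gompertz–Makeham
stand-in `qx = 1 − exp(−(c + a·e^{b·age}))` with a = 3.7898e-5,
b = 0.090, c = 0.0004 is generated by `ascea.synthetic` and shipped as
`data/lifetable.csv`.  The level parameter was calibrated once so the
base-case 30-year discounted life-years equal ~16.7 at 4% (the quantity
the cohort results pin down); the resulting q(45) ≈ 0.0026 is close to
the 2007 Norwegian population.  Any user-supplied `(age, qx)` file
overrides it.

## Scenarios and uncertainty attribution

Ten configurations: base case; celecoxib 200 mg replacing the combined
arm; GI events only; CV events only; no adverse events; 0% and 8%
discounting; stable BASFI; start age 20; anti-TNFα costs excluded.
Event classes are switched off by zeroing their probabilities after
sampling, leaving efficacy untouched.

Variance attribution uses an ANCOVA-style linear decomposition: for each
input group (discontinuation, CFB BASFI, CFB BASDAI, PUB/GI rates, CV
rates, utilities, costs) the drop in R² when the group's columns leave
the full regression, normalised so group shares sum to the total
explained share.  A draw-rank transform is available for robustness;
duplicated pooled-node columns are dropped, and collinear designs fall
back to the pseudo-inverse fit with a warning.

## What the synthetic generators do and do not show

The trial-network generator draws arm summaries around known contrasts
(normal CFB; binomial with logit-linear truth) — it exercises parameter
recovery, connectivity handling and file round-trips, but it emulates
arm-level summaries only, not patient-level data, unequal trial quality
or reporting bias.  The life-table stand-in has smooth parametric
mortality; real tables have cohort effects and young-adult excess the
model never sees.  Passing tests therefore demonstrate correctness of
the machinery and faithfulness to the published inputs, not external
validity of the clinical parameters.

## Problem sizes and numerical choices

The default analyses use 10,000 PSA iterations and 4×20,000 MTC
iterations; the test suite runs the MTC at 4×10,000 and the PSA at
2,000 iterations, sizes at which every checked quantity is stable to
well within its asserted tolerance.  The acceptance script uses 5,000
PSA iterations.  Occupancy row sums are asserted to 1e-9 every cycle;
NaNs in reward ledgers raise immediately; beta/gamma/lognormal width
solving brackets the unimodal width curve and root-finds on the correct
monotone branch.

## Known limitations

- Event-cost categories reproduce the reference results to ~3% but not
  exactly; the printed 1-year CV costs imply an effective per-event cost
  ~3% below the printed 95,555 NOK that cannot be derived from the
  printed inputs.  No headline quantity depends on it.
- No half-cycle correction, no tunnel states for post-event risk, no
  EVPI/EVPPI, no societal-perspective (disease-severity) costs.
- BASFI/BASDAI efficacy is assumed constant while on a drug; responders
  and non-responders are not distinguished beyond discontinuation.
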