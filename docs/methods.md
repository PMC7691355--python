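# Methods

## Model and assumptions

The package evaluates a screening test from one screening round plus the
interval cancers of the following inter-screen interval, under a
time-homogeneous progressive three-state model:

* state 0 — free of screen-detectable disease;
* state 1 — pre-clinical detectable phase (PCDP): asymptomatic, detectable
  by the test, not yet clinical;
* state 2 — clinical phase: the disease surfaces regardless of screening.

Dwell times are exponential with onset rate λ₁ (state 0→1, per person-year,
stratum-specific) and progression rate λ₂ = 1/MST (state 1→2). The model is
Markovian and homogeneous: rates do not depend on age or time since onset.
MST is a *known input* — the method corrects test metrics given a sojourn
time, it does not estimate one. The MST is also taken as independent of the
biomarker level; only λ₁ varies across strata.

The closed-form occupancy probabilities (see `markov.py`) follow from the
Kolmogorov forward equations. When λ₁ is within a relative 1e-9 of λ₂ the
two-rate form suffers catastrophic cancellation, so the analytic limit
`P₁(t) = λ₁ t e^{−λ₁t}` is used instead; the switch is continuous to ~1e-6
relative, which tests assert.

## Rate inversion

A stratum's interval-cancer proportion `r/n` estimates `P₂(Δ)` for a person
disease-free at the (negative) screen. Two inversions to λ₁ are offered:

* **exact** — bracketed Brent root-finding on `P₂(Δ; λ₁) − p`, bracket
  `[0, 10/Δ]` expanded geometrically, accepted only when the probability
  residual is ≤ 1e-12. Because `P₂(Δ) → 1 − e^{−Δ/MST}` as λ₁ → ∞, a
  proportion above that bound is rejected explicitly rather than silently
  truncated.
* **linear** — the small-rate linearisation
  `λ₁ = p / (Δ − MST·(1 − e^{−Δ/MST}))`, whose relative error against the
  exact root is first order in `p` (1.4% at p = 0.01 for Δ=4, MST=6.75).

The pipeline additionally accepts externally *supplied* rates. This matters
for the packaged trial data: the published per-stratum rates for strata
≥ 2.5 ng/ml came from an age-stratified estimation and deviate by up to
~13% from what homogeneous inversion of the stratum proportions gives. The
package does not attempt to reverse-engineer that design; supplying the
published rates reproduces every downstream published cell, and the
inversion paths are fully functional for user data and for simulated
cohorts.

## PCDP prevalence and the correction

The equilibrium PCDP prevalence λ₁·MST (flow balance between onset and
progression, valid for λ₁·MST ≪ 1 — the screening regime; requests outside
it raise) is the default and is what reproduces the published prevalence
cells; the finite-horizon occupancy `P₁(t)` is available for sensitivity
analysis. Expected latent cases per stratum, `n·λ₁·MST`, are carried
**unrounded** through every downstream formula; rounding (half-up, to the
printed precision: 4 dp for prevalences, integers for case counts, 1 dp for
percentages) happens only at presentation. Using rounded intermediate
counts changes several published percentage cells, so this is load-bearing.

At cutoff *i*, only the expected cases of strata **entirely below the
cutoff** enter the correction: they are added to the false negatives and
removed from the true negatives. The corrected operating point is literally
the standard 2×2 computation on the adjusted real-valued table, which makes
three identities automatic and they are asserted as invariants: PPV is
unchanged, the test-negative margin is conserved, and NPV equals
`(TN−x)/(TN+FN)`. The published pooled row (a single rate fitted to all
sub-threshold strata jointly) is exposed as an independent aggregate
(`pooled_pcdp`); it is *not* the sum of the stratum rows (417 vs ≈397
unrounded) and the corrected metrics always use the stratum-wise values.

Cutoffs must lie on stratum boundaries — grouped counts cannot resolve an
interior cutoff, and on the packaged fixture cutoffs 6 and 10 ng/ml are
rejected with an explicit error because the case distribution above
4 ng/ml is a single stratum.

## ROC and AUC

Grouped operating points give a polygonal ROC anchored at (0,0) and (1,1)
with trapezoidal AUC. On the packaged fixture the six-point polygons give
0.9514 (uncorrected) and 0.8623 (corrected), fixed by regression tests.
The published AUCs (0.959 / 0.770) and their confidence intervals were
computed from individual-level PSA values at 0.1 ng/ml steps, which are not
published; they are not reproducible from grouped data and the package does
not pretend otherwise — only the *ordering* (corrected < uncorrected) is a
claim the grouped analysis supports, and it is tested.

Standard errors use Hanley's closed form with Q₁ = A/(2−A),
Q₂ = 2A²/(1+A); the formula is exact under bi-exponential score
distributions, and a seeded Mann–Whitney resampling test (10,000 synthetic
cohorts of 25 cases / 40 non-cases at A = 0.75) checks the closed form
against the empirical spread within 15%. Confidence intervals are Wald,
truncated to [0,1]. The two-curve comparison uses
`SE² = se₁² + se₂² − 2·r·se₁·se₂` with r = 0 by default: the correlation
between a corrected and an uncorrected curve built from the same subjects
is not identified from grouped data, so it is an explicit user parameter
rather than a hidden assumption. The effective case margin of a corrected
curve is the observed cases plus the full unrounded expected-PCDP mass
(the denominator its sensitivities actually use) — an assumption, flagged
here.

## Cohort simulator

The simulator generates one screening round per person: an exponential
onset clock with the stratum's λ₁ runs from the start of a run-in period
(default 40 years, matching a screening age in the late 50s–60s and long
enough that PCDP prevalence among attenders is within ~0.5% relative of
λ₁·MST at screening-scale rates), followed by an exponential sojourn with
mean MST. People whose disease surfaced clinically before the screen do not
attend and are excluded. The biomarker stratum is a fixed person attribute;
no drift between rounds is modelled, and multi-round scheduling is out of
scope. One root seed is split into independent per-stratum streams, so
results are reproducible and invariant to stratum reordering.

Summarisation counts interval cancers **among persons disease-free at the
screen** — the estimand the rate inversion is defined for. Sub-threshold
PCDP occupants are returned separately as ground truth (`true_pcdp_counts`)
rather than folded into the interval-cancer counts: in real data they would
surface as interval cancers too, which is precisely the incomplete-
ascertainment problem, but mixing them into the counts would make the
recovery experiments test two confounded things at once. Consequences,
verified in tests:

* with **no run-in** (everyone disease-free at screen, the inversion
  model's own assumption) exact inversion recovers each generating λ₁
  within 3 Monte-Carlo SE at 200,000 per stratum;
* with the 40-year run-in the estimator has a small depletion bias
  (factor ≈ 1 − prevalence) which cancels almost exactly in the expected
  latent case count, so the corrected sensitivity still lands within 2
  percentage points of the true program sensitivity
  `TP/(TP + FN + latent PCDP below threshold)` — while naive sensitivity
  overshoots it by tens of points. This is the central bias story in
  silico.

Simulated cohorts emulate exponential natural history with stratum-constant
rates and perfect test classification by stratum. They do not emulate age
dependence, biomarker measurement noise or drift, overdiagnosis/cure, or
competing mortality — so passing recovery tests validate the estimation
machinery under the model's assumptions, not the model's fit to any real
population.

## Problem sizes and numerical choices

Test simulations use 200,000 per stratum (recovery, truth-tracking) and one
million (closed-form calibration); all complete in seconds. Root-finding
tolerances are given above; probability conservation is asserted at 1e-12
and closed-form vs RK4-oracle agreement at 1e-8 across λ₁ ∈ [0, 0.5],
MST ∈ [1, 20] y, t ∈ [0, 40] y. Ties in rounding go half-up via decimal
arithmetic on the shortest float representation.

## Known limitations

* Homogeneous rates: no age- or time-dependence; the published
  age-stratified rate estimates are accepted as inputs, not reproduced.
* MST must be supplied; sensitivity of results to MST is explored by
  rerunning (`reproduce --mst 5|10` shows the expected latent burden grow
  with MST), not by estimation.
* Grouped-data AUCs understate individual-level AUCs when the biomarker
  discriminates within strata; comparisons should stay within one grouping.
* Single-round evaluation only; no inference about periodic-programme
  schedule sensitivity.
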