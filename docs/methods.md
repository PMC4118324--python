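# Methods

This note records the models, conventions and numerical choices behind
`riskmatch`, and what the simulation-based tests do and do not establish.

## Illness-death simulator

Each subject starts in the initial state at `t = 0` and draws four
mutually independent latent times: `t12` (to exposure), `t13` (to the
final event without exposure), `t23` (duration from exposure to the final
event — the post-exposure clock restarts at exposure) and a censoring
time `C`. The observed record is one of four exclusive cases — censored
before anything, direct final event, exposed then censored, exposed then
event at `t12 + t23` — with administrative censoring folded in by
replacing `C` with `min(C, tmax)`, so every survivor is censored at the
horizon `tmax = 1000` even in the "no censoring" scheme. Exact ties are
measure-zero for continuous draws and resolve in the order
event ≺ exposure ≺ censoring.

Transition intensities come in three families, parametrized as:

* exponential — constant hazard `λ`;
* Weibull — hazard `γ λ0 (λ0 t)^(γ−1)` (rate parametrization);
* log-logistic — survival `1 / (1 + exp((log t − μ)/σ))`.

These conventions were fixed by two external requirements: the raw
intensity ratio of the tabulated configurations must stay within the
clinically plausible band (roughly 0.5–4) across the follow-up window,
and the resulting exposure frequencies per profile must land where the
reference design puts them. The common shape-scale Weibull form
`λ γ t^(γ−1)` fails the first requirement badly (ratios above 8) and was
rejected.

Covariates are three binary indicators; the 8 profiles get equal
allocation (250 subjects each by default). Tabulated intensities are
average-covariate intensities `λ(t, Z = Z̄)` with `Z̄ = (0.5, 0.5, 0.5)`,
so a profile `z` multiplies the hazard by `exp(β'(z − Z̄))`. All draws
use inverse-transform sampling through the closed-form inverse
cumulative hazards; one Philox generator per cohort, consumed in a fixed
profile-major order, makes cohorts bit-reproducible given a seed, and
replications receive independently spawned seeds.

The simulator emulates a randomized-allocation cohort with exactly
balanced profiles, continuous-time transitions and (optionally) uniform
independent censoring. It does not emulate covariate-dependent censoring,
measurement error, tied event times, delayed study entry at the cohort
level, or non-proportional covariate effects within a transition — so
passing tests say nothing about robustness to those features in real
data.

## Matching

Both methods match exactly on the full profile `(Z1, Z2, Z3)` — no
caliper, no distance. Exposed subjects are processed in ascending
exposure time (ties broken by subject id); the control is drawn uniformly
at random from the eligible set and consumed (a control serves in at most
one pair; a `with_replacement` flag exists but is off by default).
Exposed subjects with an empty eligible set are excluded and reported.
Under Method 2 a subject can appear once as a control and later once as an
exposed member; the two pairs are never simultaneously at risk because
her control spell is censored at her own exposure time.

## Counting-process construction and models

Rows are half-open `(start, stop]` intervals with the event attached to
`stop`. Both pair members enter at the formation time; person-time
outside any pair contributes no rows (pair labels are undefined there).
The stratified model censors the whole pair at the earlier of the two
members' exits; the marginal model follows each member to her own exit.
An imperfect control is censored at her own exposure time — by
construction that precedes her event, so no events are discarded.

Interval-specific effects use indicator columns `E_l(t) = E(t)·1{t ∈ I_l}`
obtained by splitting exposed person-time at the grid boundaries
(intervals are closed on the left). The default grid is `L = 4`
equal-width intervals of `[0, tmax]` (one interval for the constant-effect
configuration). Equal width was chosen over event-time quantiles as the
natural *a-priori* partition and because it reproduces the reference
aggregate summaries more faithfully; quantile grids remain available via
`IntervalGrid.from_event_quartiles`, and every fitting function accepts an
explicit grid.

Both engines maximize the Breslow partial likelihood (tied events share a
denominator; per-event processing makes this exact) by Newton–Raphson
with step halving: convergence when the maximal score component drops
below 1e−8 or the relative log-likelihood change below 1e−10, at most 50
iterations; a coefficient beyond |10| flags a monotone likelihood and the
fit is marked non-converged. All-zero design columns (e.g. interaction
terms in an interval without exposed person-time) are dropped with a
warning and reported as NaN. The unstratified engine computes every risk
sum from two suffix-cumulative arrays (rows sorted by stop and by start),
using `{start < t ≤ stop} = {stop ≥ t} \ {start ≥ t}`; the stratified
engine enumerates the (event, at-risk-row) incidence once per fit, which
is efficient for many two-subject strata. The cluster sandwich sums
martingale-based score residuals within pairs: `V = I⁻¹ B I⁻¹`. Both
engines are validated against brute-force enumeration of the partial
likelihood, lifelines, and R's `survival::coxph` (coefficients, naive and
robust standard errors).

The proportional-hazards check correlates scaled Schoenfeld residuals
with event time and refers `r sqrt((d−2)/(1−r²))` to a t distribution.
Because it tests a *linear* association with time, it has high power
against monotone time-varying effects and little against hump-shaped
ones; the tests exercise exactly that contrast.

## Reference ("true") effects

The estimand is the ratio of post- to pre-exposure final-event
intensities. Because a subject enters the post-exposure transition only
at exposure (delayed entry) and the post-exposure clock restarts, the
population post-exposure hazard is the hazard of the convolution
`f23*(t) = ∫ f23(t−u) f12(u) S13(u) du`, not the raw intensity. The time
axis is discretized into `K = 2000` steps (refinement exposed; a
Cauchy-style refinement check is part of the suite); the left-truncated
survival is the product of one-step conditional factors and the per-step
hazard is `−log[S23(t_k)/S23(t_{k−1})]/Δ`. Convolution integrals use
trapezoid end-point weights (pure rectangle weights distort the first
steps); entry/death/censoring masses use trapezoidal quadrature. Steps
where the at-risk denominator is numerically zero yield NaN and are
excluded downstream; a one-step death probability reaching 1 raises an
error asking for a finer grid.

Per-interval reference values average the log of the reference curve over
the interval, weighted by the expected exposed-event intensity
`Σ_z N23z(t) λ23z(t)` (per-profile curves use the profile's own weight).
An interval-indicator partial-likelihood fit aggregates information where
exposed events happen, so this weighting — not an unweighted time
average, which would be dominated by the earliest times when almost no
exposed subject is yet at risk — is what the fitted `γ_l` target. The
weighted averages agree with the empirical large-sample interval
coefficients to within Monte-Carlo error.

The covariate-adjusted average effect has no closed form; it is defined
empirically by fitting the adjusted interval model on one large simulated
cohort (200 000 subjects by default, seed mandatory). The same machinery
returns empirical unadjusted and per-profile curves, used as a
cross-validation of the discretized theory.

## Replication study and scoring

For each replication: simulate → match with both methods → build tables →
fit the requested models. Cell-level bias over S replications is
`mean(γ̂) − γ_true` with the `S−1`-denominator empirical variance and
`RMSE = sqrt(bias² + V)`; aggregates are plain means over intervals
and/or the 8 profiles (the aggregate RMSE averages per-cell RMSEs, not
the root of mean squares). Stratified and unadjusted-marginal fits are
scored against the average reference curve, the adjusted fit against the
empirical adjusted reference, and the interaction fit per profile against
`γ_l + α_l'z` from the per-profile curves. Non-converged or diverged fits
are excluded from cells with their count reported; a run aborts if more
than 20 % of fits fail. Replication seeds are spawned from one root
sequence, so the archive is bit-reproducible and order-independent.

Problem sizes: the shipped study and acceptance script use 200
replications of 2000-subject cohorts, a K = 2000 truth grid and a
100 000-subject cohort for the empirical adjusted reference — the
package's chosen desk-scale defaults; all are parameters.

## Known limitations

* The aggregate RMSE of the interaction model is sensitive to how
  non-converged fits are handled; excluding them (our choice) caps the
  variance of thin profile-by-interval cells, and published values that
  include near-divergent fits can be several times larger.
* A-posteriori matching is structurally biased even under a null exposure
  effect (controls conditioned on never being exposed are short
  survivors); the study design measures this bias rather than removing
  it.
* Alternative imperfect-pair policies (censoring the whole pair,
  re-matching the widowed exposed subject) are not implemented.
* Frailty models and spline-based time-varying effects are out of scope;
  time-varying effects are represented only by interval steps.
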