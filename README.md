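# riskmatch

Matched-pair survival analysis when the exposure is an event occurring
**over time**.

## The problem

In many clinical cohorts the "exposure" whose prognostic effect we want —
a subsequent pregnancy after breast-cancer treatment is the motivating
example — is not known at baseline: it happens (or not) at a
subject-specific time `t_E` during follow-up. Matched designs pair each
exposed subject with an unexposed one sharing the same prognostic profile
**Z**, hoping the pair also shares unmeasured prognosis (controlling the
"healthy mother effect": only subjects in good condition undertake the
exposure). But *when* and *how* the pairs are formed matters:

* **Method 1 (a posteriori)** — at the end of the study, match each exposed
  subject to one who was *never* exposed over the whole follow-up and was
  still event-free at `t_E`: eligibility set
  `R1(t_Ej) = {i ≠ j : t_i ≥ t_Ej and t_Ei = +∞}`.
* **Method 2 (real time)** — at each exposure time, match to a subject
  *not yet* exposed: `R2(t_Ej) = {i ≠ j : t_i ≥ t_Ej and t_Ei > t_Ej}`.
  A pair whose control is later exposed herself is *imperfect*: she is
  censored within her pair at her own exposure time and may then head her
  own pair as the exposed member.

Conditioning the control on *never* becoming exposed (Method 1) selects
short survivors and biases the estimated exposure effect downward even
when the exposure does nothing; Method 2 avoids this.

Both members of a pair enter the analysis risk set at the formation time
(delayed entry). Two semiparametric models for the resulting correlated
censored data are provided, with interval-specific exposure effects
`γ_l` on a partition `0 = a_0 < … < a_L = t_max`:

* **Stratified pair Cox model** (`StratifiedPairCox`): one baseline hazard
  per pair, `λ_i(t) = λ_0i(j)(t) exp(γ(t) E_i(t))` — the pair is censored
  at the first exit of either member, and matching covariates are
  inadmissible (absorbed by the stratum).
* **Marginal pair Cox model** (`MarginalPairCox`): common baseline
  `λ_i(t) = λ_0(t) exp(γ(t) E_i(t) [+ β'Z_i + α'(t) Z_i E_i(t)])` with
  pairs as clusters in a robust sandwich covariance `I⁻¹ B I⁻¹`;
  variants: unadjusted, covariate-adjusted, and with
  exposure-by-covariate interactions giving profile-specific effects
  `exp(γ_l + α_l'Z)`.

To measure how well each Method × Model combination estimates the true
effect, the package ships an illness-death cohort simulator
(initial state → exposure → final event, plus the direct path, with
2000 subjects split 250 per binary profile of `(Z1, Z2, Z3)`) and a
**truth engine**: the population post-exposure hazard under delayed entry
is the hazard of the convolution
`f_23(t) = ∫ f23(t−u) f12(u) S13(u) du`, discretized into K tiny steps,
and the reference average hazard ratio is the at-risk-weighted ratio

```
HRbar(t) = [Σ_z N23z(t) λ23z(t) / Σ_z N23z(t)] / [Σ_z N13z(t) λ13z(t) / Σ_z N13z(t)].
```

A replication study (`run_study`) then reports per-interval, per-profile
bias `b_lZ(w)`, its empirical variance, `RMSE_lZ(w) = sqrt(b² + V)` and
their averages over intervals and profiles (`b••`, `RMSE••`).

## Worked example

```python
import riskmatch as rm
from riskmatch.counting import IntervalGrid, build_counting_process

cfg = rm.described_scenario()            # increasing-then-decreasing HR(t)
cohort = rm.simulate_cohort(cfg, seed=42)
m1 = rm.RiskSetMatcher(method=1, random_state=0).match(cohort)
m2 = rm.RiskSetMatcher(method=2, random_state=0).match(cohort)
print(len(cohort), int(cohort.exposed.sum()))        # 2000 1064
print(m1.n_pairs, len(m1.unmatched_exposed))         # 557 507
print(m2.n_pairs, m2.n_imperfect())                  # 875 488
print(round(rm.relative_pair_difference(m1, m2), 2)) # 0.57

grid = IntervalGrid([0., 250., 500., 750., 1000.])
hp = rm.StratifiedPairCox().fit(build_counting_process(m1, "hp", grid=grid))
lwa = rm.MarginalPairCox(variant="unadjusted").fit(
    build_counting_process(m2, "lwa", grid=grid))
print(hp.gamma_.round(3))    # [-0.95  -1.144 -1.386 -1.204]
print(lwa.gamma_.round(3))   # [ 0.043  0.102 -0.003 -0.249]

truth = rm.compute_truth(cfg)
print(truth.interval_log_hr_bar(grid).round(3))  # [-0.374 -0.007  0.005 -0.119]
```

The same cohort, analyzed two ways: the a-posteriori pairs put the
interval log hazard ratios near −1.2 (a spurious "protective" exposure),
while the real-time pairs track the true interval-averaged values
(−0.37, −0.01, 0.01, −0.12) closely. Of the 1064 exposed subjects,
Method 1 can pair only 557 (the never-exposed pool is small in
high-exposure profiles) against 875 for Method 2 — a 57 % relative
difference in pair counts.

A command-line interface mirrors the library:

```bash
riskmatch simulate --config described --seed 1 --reps 10 --out cohorts/
riskmatch match    --cohort cohorts/cohort_0000.csv --method 2 --seed 4 --out pairs.csv
riskmatch fit      --pairs pairs.csv --cohort cohorts/cohort_0000.csv \
                   --model lwa_i --grid 250,500,750 --out fit.json
riskmatch truth    --config described --intervals 250,500,750 --out truth/
riskmatch study    --config described --reps 200 --seed 1 --out study/
```

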