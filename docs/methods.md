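# Methods

## Model overview

`stepcare` couples two simulation paradigms over a shared weekly clock.

**Disease progression (agent-based).** A closed population of `n0` adults
(no births, migration or replacement of deaths; the horizon is two years).
Each agent is in a health state (none / mild / moderate / severe) and,
while ill, a care state (untreated / in treatment). Disease-free agents
with a recently resolved episode carry a recurrence clock. There is no
direct agent–agent interaction (depression is not infectious); agents
interact only through the shared care system.

**Care pathways (stock and flow).** One continuous pathway per severity,
integrated with explicit Euler (`dL/dt = inflow − outflow`, default
`dt = 1` week, sub-stepping supported). Stages are first-order delays
(outflow `L/D` for mean stage duration `D`, clamped so stocks never go
negative) with branch fractions splitting each outflow. Stage entry
accrues resource units (e.g. 4 GP visits per person entering assessment);
the inpatient stage additionally meters occupancy (level × dt =
bed-weeks).

**Coupling.** Weekly, in fixed order: (1) agent transitions; (2) the
week's newly symptomatic untreated agents per severity form the demand;
(3) the coverage gate computes `entering = coverage × demand`,
integerised by stochastic rounding (floor plus a Bernoulli draw on the
fractional part — unbiased at small weekly counts); (4) that many agents,
sampled uniformly from the demand pool, are admitted: the agent draws its
treatment duration from the severity-specific triangular distribution, and
one person of inflow enters the pathway; (5) untreated severe agents reach
crisis care with a weekly emergency hazard (entering the pathway at the
CRHTT); (6) each agent-side discharge or in-treatment death removes one
unit of pathway mass. Pathway exits pool in a terminal
`awaiting_discharge` stock with no autonomous outflow, so discharge
timing is owned by the agent model and the pathway's total mass equals
the agent model's in-treatment head count exactly, week by week. Mass
balance (`admissions = stocks + discharges`) is exact by construction.

## Time-scale conventions

Published probabilities arrive on three scales and are converted to weekly
hazards geometrically, `h = 1 − (1 − q)^{1/W}`, so that compounding over
the window `W` reproduces `q` exactly:

* annual (death rate): `W = 52`;
* per untreated episode (remission, deterioration): `W =`
  `untreated_episode_weeks`, default 26 — the mode of the mild/moderate
  treatment-duration distribution; the sources state these probabilities
  without a time scale, so the window is an explicit, configurable
  assumption;
* per post-episode window (recurrence 33%, relapse 14%): zero hazard for
  the first `relapse_delay_weeks = 26` (recurrence/relapse are defined as
  falling ill again more than six months after the episode ends), then a
  weekly hazard over the remaining `relapse_window_weeks − delay = 26`
  weeks chosen so the per-episode probability is exact over the window;
  after the window the agent rejoins the fully susceptible pool.

Competing risks within a week resolve in a fixed order — death, then
remission/discharge, then deterioration/relapse — each on the survivors of
the previous draw. Weekly hazards are ≪ 1, so the ordering bias is far
below the stochastic noise; the fixed order buys exact reproducibility.
Death uses the single all-cause rate for every alive agent, including the
healthy (the published rate is a crude population rate; over two years the
choice is immaterial and keeps the closed-population bookkeeping uniform).
Triangular duration draws are ceiled to whole weeks (weekly clock), which
raises each mean by ≈ 0.5 weeks; the tests account for this.

## Service-offer policy

By default each episode receives **one** offer of care when it becomes
symptomatic (onset, relapse, deterioration — which starts a more severe
episode — or an unsuccessful discharge): the coverage level is then the
fraction of episodes ever treated, service use scales with coverage, and
the untreated pool is populated enough for deterioration, recurrence and
crisis admissions to respond visibly to coverage — the behaviour the
published results exhibit (service use roughly doubles from 47% to 80%
coverage; deterioration and relapse fall markedly). The alternative
policy, re-offering every untreated agent weekly (`reoffer_weekly=True`),
makes effective coverage ≈ `c/(c + remission hazard)` ≥ 88% even at the
47% baseline and suppresses all coverage effects; it is kept as a flag
for sensitivity analysis but is not the default.

Unsuccessful treated episodes (non-recovered discharges) return to the
untreated pool at unchanged severity with a fresh offer — stepped-care
re-entry — so "discharged" always means disease-free.

## Incidence calibration

The inputs give target prevalence, not incidence. Because mean episode
durations differ strongly by severity (a treated severe episode runs
≈ 51 weeks per course × ≈ 1.8 courses, versus ≈ 16 weeks for an untreated
mild episode), one onset hazard with an (a1, a2, a3) multinomial severity
split cannot reproduce the published per-severity prevalence, whose shares
match (a1, a2, a3) almost exactly. `calibrate_incidence` therefore fits
**three** weekly onset hazards so severity `i` carries `p·a_i·n0` agents:
an analytic balance-equation guess (inflow = target/mean episode length,
corrected for the treated/untreated mix and recurrence re-entries)
refined by multiplicative updates `λ_i ← λ_i · target_i / measured_i`
against pilot simulations. Pilots reproduce the reporting design itself —
104-week horizon, 26-week warm-up, disease-free start — because with
episode lengths up to ~90 weeks that window still contains ramp-up, and
the reported quantity, not a hypothetical infinite-horizon equilibrium, is
the calibration target. The pilot plan (4, 8, 16, 24 seeds over four
passes) leaves a residual calibration error of ≈ 1% per severity. The
incident severity split therefore equals the calibrated
(duration-adjusted) proportions; it is the *prevalent* split that matches
(a1, a2, a3), which is also what the structural validation battery
checks (alongside a χ² of incident cases against the calibrated
proportions).

## Pathway configuration defaults

Stage structure follows the stepped-care recommendation; the narrative
fixes the 6-week assessment, the 46-week medication course and the visit
allowances (4 GP assessment visits, up to 6 GP visits during medication,
up to 6 psychologist visits, 1 follow-up visit), but not every split or
duration. All are configuration with these one-time defaults:

| quantity | default | rationale |
| --- | --- | --- |
| remit during assessment | 0.6 / 0.4 / 0.2 (mild/mod/severe) | "majority remit within 6 weeks" for mild; graded down consistently with the untreated remission ordering |
| medication vs therapy | 0.5 | no published split |
| escalation after first line (mod/severe), psychiatrist share | 0.5 / 0.5 | no published split |
| direct-to-inpatient at severe entry | 0.1 | "some people" need admission at the initial stage |
| in-pathway crisis branch; CRHTT→inpatient | 0.1; 0.5 | crisis is the exception during active treatment; CRHTT exists to avert admissions |
| therapy / psychiatrist / intensive-therapy stage durations | 12 wk | ≈ 6 visits at fortnightly spacing |
| CMHT intake/follow-up, CRHTT | 4 wk | short engagement blocks |
| inpatient stay | 8 wk | typical acute admission for severe depression |
| emergency admission hazard (untreated severe) | 0.10 /week | severe depression is defined by suicide risk / unmanageability in open settings; median ≈ 7 weeks from rejection to crisis contact |

"Up to N" visit allowances are costed as exactly N per person entering
the stage (upper-bound capacity planning). Medication is counted once per
person entering a medication stage. At `coverage = 0` the emergency
channel is disabled too: that boundary scenario means total service
shutdown, and the validation battery requires every stock to stay at
zero.

The default unit-cost table is a clearly marked synthetic placeholder
(authoritative reference unit costs are not bundled);
`cost_report` accepts any user table and fails loudly on missing entries.

## Experimental design and problem sizes

The standard experiment is the published one: `n0 = 5000`, 104 weeks,
26-week warm-up, coverage 47% (baseline) / 65% / 80%, 10 replications
with seeds derived deterministically from a base seed (each
coverage × replication cell gets an independent stream; scenarios are
paired by replication index). Summaries are post-warm-up means with
t-based 95% CIs across replications; yearly service figures rescale the
78-week window by 52/78. One replication takes well under a second, a
full sweep with calibration a couple of minutes. The `iterations` knob
provides the outer repeat factor of the original design (50 × 10) without
making it the desk default.

## What the defaults do and do not emulate

The synthetic population reproduces the published point prevalence, its
severity composition, the per-episode transition probabilities and the
treatment-duration distributions. It does not model risk factors,
demographics beyond adulthood, agent heterogeneity in help-seeking,
bed-level capacity constraints or queue discipline (the system is
coverage-limited at entry, not finite-server), suicide-specific mortality,
or seasonality. Passing tests therefore demonstrate internal consistency
and faithfulness to the published parameterisation — not predictive
validity for any particular health economy; the pathway branch fractions
in particular are defaults standing in for unpublished values, so service
*magnitudes* are indicative while coverage *directions* are robust.

## Known limitations

* **The DALY-averted ordering is reversed.** With the published
  parameters, treated episodes are longer than untreated ones (treatment
  holds an agent symptomatic for the full drawn duration, and
  non-recovered discharges repeat courses), so raising coverage raises
  prevalence person-years and hence the YLD burden: DALYs rise
  ≈ 155 → 164 → 175 across 47/65/80% coverage, and "DALYs averted by
  moving 47%→80%" is *more negative* than for 65%→80% — the opposite of
  the published narrative claim. The published prevalence table itself
  points the same way (its means, weighted by the disability weights,
  increase with coverage), so we implement the computation faithfully and
  leave the corresponding acceptance test red rather than adjust
  parameters to force the claim.
* Total prevalence grows mildly with coverage (383 → 418 → 451 at seed 1)
  for the same reason, where the published table is flat across coverage;
  only the baseline column is calibrated.
* The 3%-band comparison of baseline prevalence is tighter than the
  sampling noise of a 10-replication estimator (inter-seed spread
  ≈ ±2.5% per severity); the pinned-seed test is deterministic and the
  reported values sit within 1.4% of the published ones.
* Euler integration at `dt = 1` week carries first-order error
  (≈ `t·dt/2D²` for a pure delay); halving `dt` changes 104-week
  trajectories by well under 2%, and the stage durations (≥ 2 weeks) keep
  the scheme stable.
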