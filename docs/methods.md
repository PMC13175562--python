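# Methods

This note records the modelling conventions, the reasoning behind the
choices that were genuinely open, and what the synthetic-data pipeline
does and does not establish.

## Cohort model and accrual convention

The model is a four-state (stable, nonserious exacerbation, serious
exacerbation, death) Markov cohort with annual cycles over an 8-year
horizon (the life expectancy remaining for the trial population). The
whole cohort starts in the stable state: trial patients were discharged
on home ventilation after reaching treatment targets, and no alternative
initial mix is reported. Death is absorbing with zero cost and utility.

Costs and QALYs accrue by state membership (not per transition event).
The engine evaluates occupancy at trace points t = 0..8 and weights them

* **half-cycle correction on (default):** trapezoidal weights — ½ at
  t = 0 and t = 8, 1 in between — each point discounted by (1.05)^(−t);
* **off:** full weight at t = 0..7, none at t = 8.

The source evaluation does not state its accrual convention. We fixed it
by reconstruction: the trapezoidal rule reproduces the published per-arm
totals to the cent (¥94,632.50 / ¥91,025.24; 3.494 / 3.250 QALYs), while
every convention without a half-cycle correction misses the QALY totals
by ~5%. The flag `ModelConfig(half_cycle_correction=False)` restores the
plain convention for exploration.

The published ICER (¥15,030.25/QALY) equals ΔC divided by the *rounded*
ΔE of 0.24; the exact ratio from unrounded totals is ¥14,781.57/QALY. The
package always reports the exact ratio, so ICER = ΔC/ΔE holds identically.

## Parameters

Every input is a `DistributionSpec`: base value, standard error, sampling
distribution (gamma for costs, beta for utilities and probabilities,
fitted by the method of moments so the distribution's mean and SE equal
the estimates exactly), and lower/upper bounds for one-way sensitivity
analysis. Printed bounds are consumed verbatim rather than recomputed,
because the source tables are not uniform about 1.96·SE vs ±10%.

The shipped file stores **exact (unrounded) method-of-moments shapes**.
Rounding them to integers reproduces the published shape columns within
±1 — with one systematic exception: in four transition rows (IoT
stable→serious, IoT nonserious→stable, IoT nonserious→serious, standard
stable→nonserious) the published β column actually carries the α+β total
(the printed pair would otherwise imply a mean 10–30% away from the
printed base value). The file stores the corrected β for these rows, so
every sampled distribution has exactly the stated mean and SE.

Transition matrices: off-diagonals are the six trial-derived entries per
arm plus death probabilities; stable→death and nonserious→death are the
fixed background mortality 0.0087/year (a given constant, not
re-derived); serious→death is trial-derived; the serious-state row is
identical for the two arms and is stored once, shared. Diagonals are
residuals (1 − row off-diagonal sum) and are never sampled.

The CAT→utility mapping is applied unclamped; values outside [0, 1]
trigger a warning only (all in-range trial states map to interior
values). Ages for the mapping advance with follow-up time from the age at
entry (we use the period's end; any point inside the period shifts
utilities by < 0.002).

## Estimation from patient-level data

States are classified per follow-up period: death; else hospitalized →
serious; else medication adjusted → nonserious; else stable. In the first
period the medication-adjustment flag is unobservable, so a non-serious,
non-fatal first period is *unknown* and excluded from transition counting
(the trial's own exclusion rule).

Transitions: consecutive classified period pairs are counted per arm and
from-state (serious pooled across arms). Within each period-length
stratum the transition fraction p̂ becomes a rate r = −ln(1−p̂)/t; stratum
rates are averaged weighted by person-time and converted to an annual
probability by 1 − exp(−r̄). This makes the estimator the exact inverse
(in expectation) of the generator's Markov mode, which the recovery tests
exploit. SEs propagate the binomial variance of p̂ through both
conversions by the delta method. A from-state never observed yields a
degenerate hold-or-die row with a warning by default (`strict=True`
raises instead); a serious row with no observed deaths still carries the
background hazard.

Utilities are pooled across arms (per-state means of mapped
per-observation utilities, sample SE); costs are estimated per arm, state
and item from period costs annualized by period length, with a pooled
fallback when a stratum is empty in one arm. Estimated parameters get
±1.96·SE bounds for OWSA.

## Sensitivity analysis

**OWSA** sweeps each cost and utility parameter between its stored
bounds, the discount rate over 0–8%, the three IoT service items jointly
by ±10% (their individual printed bounds are also ±10%), and the
background mortality by ±10% (it has no published SE). Transition
probabilities are excluded: they are correlated through the residual
diagonals. Entries record the raw ΔC/ΔE ratio at each bound and are
ranked by range for the tornado chart.

**PSA** redraws every gamma/beta parameter per iteration. Transition rows
stay coherent by sampling the off-diagonals and taking the diagonal as
the residual; draws giving a negative residual are rejected and redrawn
(counted, warned above 1%). The shared serious-state row is drawn once
per iteration, preserving the between-arm correlation built into the
inputs. Note that the rejection step truncates the joint distribution, so
the accepted-draw mean of a high-variance row (the IoT nonserious row
rejects ~12%) sits slightly below its base value; this is inherent to the
residual-diagonal scheme.

Cost items without an uncertainty distribution (the three fixed IoT
service items) are **excluded from the sampled cost totals by default**
(`fixed_cost_items="exclude"`). This reconstructs the published
probabilistic model, whose iteration totals evidently comprised only the
distribution-carrying parameters: with the fixed items excluded the PSA
reproduces the published probabilities (≈94% cost-effective, ≈80%
dominant at ¥70,100/QALY) across seeds, whereas holding them at base
shifts mean ΔC by +¥12.8k and yields ≈80%/≈38%. `fixed_cost_items="base"`
selects the latter, fully propagated variant; with it, an all-fixed
parameter set reproduces the base case exactly in every iteration. The
CEAC evaluates P(λ·ΔE − ΔC > 0) on a default grid of ¥0–150,000 in ¥2,500
steps, bracketing the threshold.

## Synthetic-trial generator

The generator emulates the source design: arms of 58 (IoT) and 67
(standard) patients, follow-up periods of 3, 3 and 6 months, ages from a
normal(70.18, 6.5²) truncated to [40, 80], 84% male. Latent states follow,
by default, a Markov chain over the shipped annual matrices (converted to
period length through the rate transform), so the full
simulate → estimate → compare pipeline is self-consistent and
parameter-recovery tests can close the loop. An independent
per-period occupancy mode exists for classification and goodness-of-fit
testing; its period-to-period churn generally implies annual transition
rates that are not feasible as probabilities, which is why it is not the
default. Hospitalization marks exactly the serious periods and medication
adjustment exactly the nonserious ones; period-1 adjustment flags are
always emitted as unknown to force the exclusion rule. CAT scores are
normal draws truncated to [0, 40] and rounded, with per-state means
chosen to invert the utility mapping near the published state utilities
at the trial's mean age; itemized costs are gamma draws of annual rates
scaled by period length, with means at the published cost table and
per-observation SDs set so stratum standard errors come out at the
reported order of magnitude.

What the generator does **not** emulate: loss to follow-up and censoring
mid-year (complete follow-up only; the source does not state how
person-time of dropouts was handled), within-patient correlation of costs
and CAT beyond the state process, seasonal exacerbation patterns, and any
dependence of mortality on age or sex. Passing recovery tests therefore
show the estimators are correct for data generated under the model's own
assumptions, not that those assumptions hold in any real cohort.

## Numerical choices

* Residual diagonals are clipped at 0 and a row sum violation beyond
  1e-9 raises; parameter-file row sums are checked at 1e-4 (printed
  precision).
* Degenerate per-stratum transition fractions of 1 are capped at
  (n−½)/n to keep the implied rate finite.
* PSA row rejection retries 1000 times before erroring.
* WTP comparison is strict (ICER equal to WTP is not cost-effective), and
  cost-effectiveness is decided by the sign of the incremental net
  monetary benefit, which coincides with the ICER-threshold rule in every
  quadrant; dominance labels replace meaningless negative ratios.
* All randomness flows from a single integer seed through
  `numpy.random.default_rng`; identical seeds give byte-identical CSVs.

## Problem sizes

The shipped analyses use the published sizes throughout: 8 annual cycles,
1000 PSA iterations. Recovery tests run the generator at 5,000 patients
per arm (property suite) and 1,200–1,500 per arm (module tests); the
acceptance script averages the PSA probabilities over five seeded
1000-iteration runs.

## Known limitations

* The accrual convention is a reconstruction; if the source model used a
  different variant that coincidentally matches the totals, increments
  could differ in later digits.
* The exclusion of fixed cost items from PSA totals mirrors the published
  probabilistic model but understates decision uncertainty relative to a
  fully propagated analysis; both modes are exposed.
* OWSA bound provenance is heterogeneous (95% CI vs ±10%), inherited from
  the source tables.
* Two-strategy comparison only; no efficiency frontier, no EVPI.
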