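# Methods

`ventburden` quantifies how the *intensity* of invasive mechanical
ventilation (dynamic mechanical power, J/min) and the *duration* for which
that intensity is sustained jointly associate with 28-day mortality in an
ICU cohort, and renders the association as a duration-intensity risk
surface with fitted iso-risk contours. This note documents the model, the
numerical conventions, the synthetic-data generator, and the choices made
where the design was genuinely open.

## Dynamic power and energy

Charted ventilator records (peak inspiratory pressure `Ppeak`, PEEP,
measured respiratory rate `RR`, tidal volume `VT`; roughly every 4 h) are
cleaned and converted to per-interval quantities:

- dynamic driving pressure `dP = Ppeak − PEEP` (cm H2O),
- dynamic mechanical power `MP = 0.098 · RR · VT · (Ppeak − 0.5·dP)`
  (J/min, with VT in litres),
- mechanical energy `E = MP · duration` (J) per exposure interval, where an
  interval runs from one charted timepoint to the next and the last
  interval is clipped at `min(extubation, day 28)`,
- whole-course average power `avg MP = ΣE / Σduration`.

"Dynamic" marks the use of peak rather than plateau pressure: plateau
pressure is charted too rarely to support a cohort-wide analysis, so
static compliance and transpulmonary quantities are out of scope.

Cleaning order is impute → winsorize → derive. Missing cells take the
value of the nearest-in-time record of the same patient and variable
(ties go to the earlier record, making the rule deterministic and
order-independent), falling back to the cohort median when a patient has
no value at all for a variable. Each variable is then winsorized
cohort-wide at the 1st/99th percentiles (linear-interpolation quantiles —
stated because quantile conventions differ; winsorizing is exactly
idempotent only once each tail holds several observations at the clip
value, and otherwise moves re-clipped values by at most the gap between
adjacent order statistics). A cleaned row with `Ppeak < PEEP` cannot give
a non-negative driving pressure; the pair is treated as missing and
re-imputed, and any remaining inversion is clamped to `dP = 0`.

## Cohort selection

Adults (≥ 18 y) with baseline data (age, gender, SOFA, SAPS-II, outcome)
and at least two charted timepoints, on their first ICU admission and
first ventilation episode, ventilated for at least 72 h. The 72 h bound is
inclusive (the exclusion is "duration < 72 h"); chart data strictly after
day 28 of ventilation are discarded (an event at exactly +28 d is kept).
Each step's exclusion count is recorded so a selection flowchart can be
reproduced; the cascade is idempotent.

## Exposure episodes and the count lattice

An *episode* at threshold `I` is a maximal run of consecutive intervals
with `MP > I` (strict exceedance); its duration is the sum of member
interval durations, accumulated in minutes so that threshold comparisons
are exact at lattice boundaries. Over the default lattice (5–30 J/min ×
1–72 h, 1 J/min × 1 h steps) the cell `(I, t)` counts episodes at
threshold `I` lasting at least `t` hours, split by 28-day outcome.
Duration qualification is inclusive (`≥ t`): episode durations are
arbitrary reals on an hourly lattice, and a strict comparison would make
an episode lasting exactly `t` hours uncountable at its own cell.

Counts are non-increasing along the duration axis by construction. They
are *not* monotone along the intensity axis: raising the threshold can
split one long episode into several shorter qualifying ones, so the total
episode count is unimodal in the threshold. This is a property of
maximal-run counting itself, not of the implementation; the grid
validator therefore enforces duration-axis monotonicity only. Episodes
are re-detected independently at every threshold, and the vectorised
counting path is tested cell-for-cell against a naive double-loop
enumeration.

## OR deviation surface and iso-risk contours

Counts are normalised to events per patient in each outcome group; the
cell OR is `avg_survivor / avg_nonsurvivor`, and the *deviation* is the
cell OR minus the overall OR. The overall OR is computed from
per-patient-normalised totals, `(Σ survivor counts / n_survivors) /
(Σ non-survivor counts / n_nonsurvivors)`, so it is commensurate with the
cell ORs; the raw total-count ratio (which differs by the constant group
size ratio) is available as a switch. Cells with a zero non-survivor
average have an undefined OR; they are flagged, excluded from fitting,
and rendered neutral. Negative deviation marks combinations
over-represented in non-survivors; −0.1 and −0.2 are read as 10% and 20%
mortality-risk increases.

Contours at a deviation level are located column-by-column: along each
duration column the first (lowest-intensity) crossing of the level
between adjacent defined cells is linearly interpolated; columns without
a crossing contribute no point. The point set is then smoothed with a
constrained monotone power law `i(t) = a + b·t^(−c)`, `b, c ≥ 0`, fitted
by least squares. The power law was chosen over a constrained exponential
`a + b·exp(−c·t)` because iso-risk fronts of burden-like surfaces are
close to hyperbolic (constant intensity × duration product), which the
power law nests exactly and the exponential cannot approximate to within
several tens of percent over a 4–72 h span; the exponential form remains
available via `form="exp"`. Fewer than three crossings yield the raw
points without a fitted curve. Heatmaps use a diverging blue–red map,
symmetric about zero with limits at ±max |deviation| over defined cells.

## Survival models

Patients are grouped by quartiles of whole-course average power
(membership by stable rank, so group sizes differ by at most one under
ties; cutoffs reported at the 25th/50th/75th percentiles). Kaplan–Meier
curves per quartile are compared with the k-sample log-rank test.
Univariate Cox proportional-hazards models screen age, gender, SOFA,
SAPS-II, average power and comorbidity flags at p < 0.2; backward
stepwise elimination then drops the largest-p variable (ties to the
lexicographically first name, making the output invariant to column
order) until all retained variables have p < 0.05. The full-candidate
model is reported alongside as a sensitivity analysis. Survivors are
censored at day 28; tied event times use the Efron approximation
(lifelines). The stepwise direction and stay threshold are conventions of
this package; they are stated because "stepwise elimination" alone does
not determine them.

## Synthetic cohort generator

Because the source data sit in a restricted-access clinical database, the
package ships a generator that emulates the extract's structure with a
known, configurable dose-response effect, so every downstream stage can
be validated against a planted truth.

Per patient: a P/F severity stratum (mix 0.392/0.153/0.278/0.177 for
> 300/200–300/100–200/≤ 100 mmHg), demographics and severity scores with
stratum-linked means, a log-normal ventilation duration (median 6 d,
log-SD 0.55, truncated to 1–45 d), and chart records every 4 h with ±25%
uniform jitter (preventing lattice artifacts) at minute resolution.
Patient-level parameter means scatter around stratum means — lognormally
for the pressures (matching the right-skew of charted Ppeak and PEEP) and
normally for rate and volume — with record-level noise on top. Stratum
means follow the clinical gradient (worse oxygenation → higher pressures
and rate), and the dispersions were calibrated so the cleaned cohort
reproduces the charted quartiles of a large adult MV cohort: Ppeak
≈ 16/19/24 cm H2O, PEEP ≈ 5/6/8 cm H2O, and whole-course average power
≈ 9/12/15 J/min with a total-energy median near 1e5 J. Measurements are
corrupted at realistic rates: 0.8% of cells deleted (missingness), 0.2%
multiplied by 3–5× (charting blunders, which the winsorizer is there to
absorb).

Mortality follows a piecewise-constant daily hazard over days 1–28:

    h_d = h0 · rho^(min(E_d, cap)/24) · exp(beta · (avgMP_28 − 11.8))

where `E_d` is the cumulative number of hours spent with *true* (pre-
corruption) power above the intensity threshold `I*` beyond the first
`T*` tolerated hours, as of the end of day `d`. `rho` is the hazard
multiplier per 24 excess hours; elevation persists once accrued
(accumulated injury) and saturates at `cap = 72 h` of excess.
`avgMP_28` is the true average power over the first 28 days — the same
window the analysis measures — and 11.8 J/min is a centring constant at
the cohort-median average power. Defaults: `I* = 15 J/min`, `T* = 24 h`,
`rho = 1` (no injected effect), `beta = 0`, and a baseline hazard
`h0 = 0.0126/day` calibrated by simulation so the default cohort's
28-day mortality is ≈ 30%, the scale of large adult MV cohorts. With
`rho = 1` and `beta = 0` the outcome is independent of ventilation — an
exact null for calibration checks; the association is monotone in `rho`.
Baseline hazard is deliberately *not* severity-linked: under harm
(`rho > 1`) the severity gradient in mortality emerges through exposure
itself, and under the null the avg-power hazard ratio is exactly 1,
uncontaminated by confounding.

What the generator does not emulate: multiple ICU admissions or
ventilation episodes (the corresponding filters are exercised with
hand-built fixtures), laboratory time series beyond a static P/F ratio,
informative censoring (ventilation records are generated independently of
the death time, so exposure measurement is decoupled from outcome
timing), within-patient temporal autocorrelation beyond a constant
patient mean, and care processes such as weaning or sedation. Passing
recovery tests therefore demonstrates that the pipeline measures what it
claims on data of this structure — not that the clinical association in
real cohorts is causal or unconfounded.

## Problem sizes and numerical conventions

Calibration and recovery checks in the test suite use 20 replicate
cohorts of 2000 patients per condition; the acceptance script uses 10
replicates of 2000 with all randomness derived from its `--seed`. These
sizes put Monte-Carlo noise well below the decision thresholds (for
instance, the avg-power hazard ratio is recovered with a replicate SD of
≈ 0.007 against a ±0.02 acceptance band). Episode durations are
accumulated in minutes (integral floats, exact in double precision) so
`duration ≥ t` comparisons at exact lattice boundaries are stable.
Contour fits use `scipy.optimize.curve_fit` with non-negativity bounds on
`b` and `c`; a fit that fails to converge returns the raw crossings.
Degenerate inputs (empty interval sequences, empty outcome groups, zero
total counts, all-missing variables, sub-4-patient cohorts) raise
`ValueError` with specific messages rather than propagating NaNs.

## Known limitations

- The OR is used as a relative-risk surrogate; at 30% mortality the two
  are not equivalent, and no confidence bands or multiplicity control are
  attached to the surface — the contours are descriptive.
- Episode counting at a threshold is blind to how far above the threshold
  power rises; a 10 h episode at 16 J/min and one at 29 J/min count the
  same at `I = 15`.
- The last exposure interval inherits its duration from the gap to
  extubation, so sparse charting near the end of ventilation stretches
  the final interval's weight.
- The 72 h minimum-duration filter conditions on surviving ventilation
  long enough to be analysed, a form of immortal-time selection inherent
  to the design being reproduced.
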