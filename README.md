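# ventburden

Duration–intensity burden of mechanical ventilation and 28-day mortality.

Positive-pressure ventilation delivers energy to the respiratory system;
too much of it, for too long, injures the lung. The rate of energy
delivery is summarised by the **dynamic mechanical power**

    MP = 0.098 · RR · VT · (Ppeak − 0.5 · ΔP)        [J/min],  ΔP = Ppeak − PEEP

computed from charted ventilator parameters (respiratory rate, tidal
volume in litres, peak inspiratory pressure, PEEP). A given power level
may be harmless for an hour and dangerous for a day, so intensity and
duration have to be analysed *jointly*. `ventburden` implements that
joint analysis for ICU cohort data:

1. **Cohort selection** — adults, first ICU admission, first ventilation
   episode, ventilated ≥ 72 h; chart data truncated at day 28; exclusion
   counts reported as a flowchart table.
2. **Series cleaning and energetics** — nearest-time imputation, 1%/99%
   winsorizing, per-interval power, mechanical energy, and whole-course
   average power per patient.
3. **Exposure-episode counting** — for every lattice cell
   (intensity `I` ∈ 5–30 J/min, duration `t` ∈ 1–72 h), the number of
   maximal episodes with `MP > I` lasting ≥ `t` hours, split by 28-day
   outcome.
4. **Risk surface** — events per patient in each group, cell odds ratio
   OR(I,t) = avg_survivor/avg_nonsurvivor, and its deviation from the
   cohort-wide overall OR; negative deviation flags combinations
   over-represented in non-survivors. Iso-risk contours (deviation 0,
   −0.1, −0.2 ≈ 0/10/20% risk increase) are interpolated column-wise and
   smoothed with a constrained monotone power law, giving an intensity
   bound for any duration.
5. **Survival models** — Kaplan–Meier by average-power quartiles with
   log-rank test, and univariate → backward-stepwise multivariate Cox
   models of 28-day mortality.

The original data source is a restricted-access clinical database, so the
package also ships a **synthetic cohort generator** that reproduces the
extract's structure (4-hourly jittered chart records, severity-linked
parameter distributions, realistic missingness and charting blunders)
with a *known, configurable* dose–response effect between cumulative
high-power exposure and mortality — every pipeline stage is validated
against that planted truth. See `docs/methods.md` for the model details.

Intended users: intensive-care and biostatistics researchers studying
time-varying exposure burden, and anyone needing a tested reference
implementation of the duration–intensity visualization method.

## Worked example

```python
import ventburden as vb

config = vb.SimulationConfig(n_patients=1000, seed=11).with_effect(rho=2.0)
patients, events = vb.generate_cohort(config)   # chart-extract-style tables
results = vb.VentilationBurdenModel(patients, events).fit()
print(results.summary())
```

```
Ventilation duration-intensity burden analysis
======================================================
patients analysed           899
  survivors                 469
  non-survivors             430
28-day mortality          47.8%
median avg power          11.8 J/min
overall OR                0.632
log-rank (quartiles)   chi2=326.4, p=1.9e-70

Selection cascade:
  baseline data available                    -0      -> 1000
  MV data available (>= 2 chart timepoints)  -0      -> 1000
  age >= 18                                  -0      -> 1000
  first MV episode                           -0      -> 1000
  first ICU admission                        -0      -> 1000
  MV duration >= 72 h                        -101    -> 899

Iso-risk intensity bounds (J/min):
  level      24 h    48 h    72 h
   0.00     10.7     9.6     9.0
  -0.10     11.2    10.2     9.6
  -0.20     11.7    10.7    10.1

Multivariate Cox model (28-day mortality):
  variable        HR    95% CI          p
  avg_mp         1.12  (1.11, 1.14)  9.2e-52
  chf            0.78  (0.63, 0.96)  0.02
```

Reading it: 101 of 1000 simulated patients were ventilated under 72 h and
drop out of the cascade. The planted harm (`rho=2`: the daily death
hazard doubles per 24 h spent above 15 J/min beyond the first tolerated
24 h) raises cohort mortality to 47.8% and is picked up by every stage —
the −0.1 iso-risk contour says that at this cohort's burden scale a
sustained 11.2 J/min over 24 h (or 9.6 J/min over 72 h) already carries a
10% mortality-risk increase, the quartile-4 survival curve separates
sharply (log-rank p ≈ 1e-70), and the Cox model attributes a hazard ratio
of 1.12 per J/min of average power. With `rho=1` (the default) the
outcome is independent of ventilation and all of these signals vanish.

Figures and tables:

```python
results.plot_heatmap("heatmap.png")        # blue-red OR-deviation surface
results.plot_contour_grid("gridplot.png")  # iso-risk curves on a grid
results.plot_km("km.png")                  # survival by power quartile
results.save("outputs/")                   # all CSVs + JSON manifest
```

Or from the shell, end to end:

```bash
ventburden run -n 1000 --seed 11 --out outputs/
ventburden simulate -n 500 --seed 1 --out cohort/
ventburden analyze --input cohort/ --out outputs/ --subset lt300
```

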