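# cricklight

Circadian analysis of event-count behavioural time series, built for
the question of what dim light at night does to nocturnal insects.
Field crickets partition their day sharply — males sing (stridulate)
at night and move about by day — and artificial light at night (ALAN)
can degrade that partitioning: individuals drift away from the 24-h
day (free-run), lose rhythmicity altogether, and fall out of phase
with each other. `cricklight` implements the full analysis chain used
to quantify these effects, plus a synthetic-cohort generator so every
estimator can be validated against known ground truth.

## What it computes

- **Preprocessing**: event binning into 10-min bouts, a ≥5-consecutive-
  day inclusion rule, per-individual mean- and max-normalization (the
  latter giving an activity index in [0, 1]), and objective day/night
  partitioning (kept on the 12:12 frame even under constant light).
- **Period estimation**: the Sokolove–Bushell chi-square periodogram

  `Q_P = N · Σ_h n_h (M_h − M̄)² / Σ_i (x_i − M̄)²`

  over candidate periods 20–28 h in 10-min steps, with the χ²(P−1)
  significance line; each individual is classified *synchronized*
  (period within one grid step of 24 h), *free-running*, or
  *arrhythmic*, and cohort period samples are cleaned with the
  3 × scaled-MAD outlier rule.
- **Acrophase and circular statistics**: single-component cosinor fits
  (`x(t) = M + A cos(ωt − φ)`), per-day acrophases averaged on the
  24-h circle, cohort mean vectors (R, θ̄), and the Rayleigh,
  Mardia–Watson–Wheeler, Watson–Williams, paired Hotelling and
  circular–linear correlation tests.
- **Group statistics**: Kruskal–Wallis + Dunn, Brown–Forsythe,
  paired t, Spearman, χ² independence, Bonferroni control.
- **Reporting**: double-plotted actograms, cohort mean daily profiles,
  per-treatment summaries, and a thin CLI
  (`cricklight simulate | analyze | report`).

## Worked example

```sh
python examples/simulate_and_classify.py
```

```
LD (n=20):
  synchronized 95% | free-run 5% | arrhythmic 0%
  median period 24.0 h, variance 0.019 h^2 (20 rhythmic individuals)
  phase mean vector R = 0.98

LL (n=20):
  synchronized 10% | free-run 70% | arrhythmic 20%
  median period 25.33 h, variance 0.434 h^2 (16 rhythmic individuals)
  phase mean vector R = 0.64
```

The control (LD) cohort entrains: nearly everyone holds a 24.0-h
period with tiny variance, and the long mean vector (R = 0.98) says
individuals sing in phase. Under constant light the same analysis
finds mostly free-running periods above 24 h, a fifth of the cohort
arrhythmic, an order-of-magnitude larger period variance, and a
shortened mean vector — the population losing synchrony. Other
examples show the periodogram on a single drifting individual
(`periodogram_demo.py`), the circular test battery
(`acrophase_circular_stats.py`), and actogram/profile rendering
(`actogram_and_profile.py`).

The same pipeline runs from the shell:

```sh
cricklight simulate --treatment LL2 --n 20 --seed 1 --out-dir run
cricklight analyze  --data run/counts.csv --out-dir run
cricklight report   --data run/counts.csv --calls run/calls.csv --out-dir run
```

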