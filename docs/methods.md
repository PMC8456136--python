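# Methods

`cricklight` analyses daily rhythms in event-count behavioural records —
cricket stridulation syllables and locomotion events are the motivating
case — and ships a synthetic-cohort generator that reproduces the
statistical structure such experiments assume, so that every stage of
the pipeline can be validated against known ground truth.

## Data model

Activity is assessed per animal and behaviour in 10-min bins
(half-open, left-closed; a timestamp on a boundary belongs to the later
bin). Recordings must contain at least five consecutive usable days;
days flagged upstream (equipment failure, no behaviour early in the
recording) are excluded per behaviour, and the longest run of clean
consecutive days is analysed. Two normalizations serve different
questions: division by the individual's mean (quantitative day/night
comparisons) and division by its maximum, giving an activity index in
[0, 1] (rhythmicity, period and acrophase analyses). Day/night
fractions are computed on raw counts; both normalizations are
scale-equivariant, so the choice does not affect the fractions.

Under constant light the day/night partition uses the *objective* 12:12
frame anchored at the recording start — the photoperiod clock the
animals were reared under — so LL recordings partition bin-for-bin like
LD recordings with the same start time.

## Synthetic cohorts

Counts are independent Poisson draws around a deterministic rate
template; the Poisson assumption is a modelling choice (real syllable
counts are likely over-dispersed within bouts; see Limitations).
Templates are raised-cosine bumps on a reference 24-h cycle whose first
half is the subjective day:

- **stridulation**: bump centred at hour 18 (mid subjective night),
  default half-width 5 h. With the default baseline (0.15 events/bin)
  and amplitude (6 events/bin) about 95% of expected activity falls in
  the subjective night, matching a strongly nocturnal caller.
- **locomotion**: bump centred at hour 6, half-width 6 h, plus a
  narrower dusk peak (half-width 1 h, default weight 0.5) centred just
  before lights-off — the sunset surge that precedes the night's first
  songs. Defaults put roughly 70% of expected activity in the day.

Rhythm types: *synchronized* individuals repeat the template every
24 h, phase-locked to the light schedule; *free-runners* repeat it
every `true_period_hours` (the template is evaluated at `t mod P`, so
activity onset drifts by `P − 24` hours per day against the light
cycle); *arrhythmic* individuals emit the flat baseline. Masking — the
immediate, non-clock response to light — is a separate multiplicative
gain applied to bins with ≥ 10 lux (daylight level, so dim 2/5-lux
nights do not mask). No quantitative masking magnitude is established
for this system; the default gain is 1.0 (off) and any other value is
an arbitrary dial the user must justify.

Cohorts draw each individual's rhythm type from a mixture, its phase
from `N(phase, phase_sd_hours²)`, and (for free-runners) its period
from a normal distribution snapped to the 10-min grid and kept at
least two grid steps away from 24 h, inside the 20–28 h scan range.
Treatment presets encode the qualitative pattern of light-at-night
disruption: the control (LD) mixture is almost entirely synchronized
with small phase scatter; dim-night groups (2 and 5 lux) are majority
free-running; constant light is mostly free-running or arrhythmic with
the widest phase scatter. These presets are configuration, not
findings, and are fully overridable. Per-individual random streams are
spawned from the master seed with `numpy.random.SeedSequence`, making
cohorts bit-reproducible while keeping individuals independent.

## Period estimation and classification

The chi-square periodogram folds the activity index at each candidate
period of `P` bins and computes

    Q_P = N · Σ_h n_h (M_h − M̄)² / Σ_i (x_i − M̄)²,

the between-column sum of squares over the total sum of squares scaled
by `N` — with `M_h` the mean of the `n_h` bins congruent to `h mod P`.
All `N` bins are used, so column counts may differ by one when the
series does not hold a whole number of cycles. Under an iid null `Q_P`
is asymptotically χ²(P−1) (verified by simulation: empirical type-I
0.039 at α = 0.05 with 10 recording days), which supplies the
per-candidate significance line. Note the between-column term must be
weighted by the column counts: the unweighted sum of squared column-mean
deviations is smaller by the cycle count and has no χ² calibration.

The candidate grid is 20–28 h in one-bin (10-min) steps, covering
commonly observed insect free-running periods with margin; it is
configurable. The period estimate is the candidate maximising
`Q − threshold` among significant candidates, reported in decimal
hours with half-up rounding to two decimals (154 bins → 25.67 h).

Classification: *synchronized* if the estimate lies within one grid
step of 24 h (the tolerance is applied to the unrounded grid period,
since e.g. 143 bins prints as 23.83 h, whose rounded distance from 24
slightly exceeds one step); *free-run* if significant elsewhere;
*arrhythmic* if nothing clears the line. Because the rhythmicity
decision scans ~49 candidates, using the raw per-candidate line would
declare some "significant" period in roughly 80% of truly arrhythmic
noisy series; `analyze_series` therefore requires the winning peak to
clear a Bonferroni-corrected line at α/n_candidates by default (the
uncorrected behaviour remains available, and the periodogram object
itself always carries the plain per-candidate line). A constant series
has no variance to fold; Q is defined as 0 and the series is flagged.

Cohort period samples are cleaned before group comparisons with the
scaled-MAD rule: a value is an outlier when its absolute deviation from
the median exceeds 3 × 1.4826 × MAD. Reported medians use the exact
lower order statistic for even n (no interpolation ambiguity). A
Lomb–Scargle periodogram is included as a non-authoritative
cross-check of peak location only.

## Acrophase and circular statistics

The acrophase is extracted by single-component cosinor: the linear
least-squares fit of `x(t) = M + β₁cos(ωt) + β₂sin(ωt)` with
`ω = 2π/τ` gives amplitude `A = √(β₁² + β₂²)` and peak time
`atan2(β₂, β₁)/ω mod τ`. An individual's *mean acrophase* is, by
default, the circular mean of per-day fits on consecutive 24-h windows
(five days), which is the only reading under which a "mean over days"
exists; a single five-day fit — optionally at the individual's own
estimated period — is provided as a variant. Angles are placed on the
24-h clock face in objective clock time, also for free-runners.

Group-level inference:

- **Mean vector** `R e^{iθ̄} = Σ e^{iθ}/n`: `R` measures phase
  concentration across individuals.
- **Rayleigh test** (z = nR², series-approximation p) screens for
  non-uniformity.
- **Mardia–Watson–Wheeler** uniform-scores test compares whole phase
  distributions between treatments (midranks for ties; χ² with
  2(g−1) df) — sensitive to location and spread alike.
- **Watson–Williams F** compares mean directions, with the standard
  1 + 3/(8κ̂) correction (κ̂ by Fisher's approximation from the mean
  resultant length); when the weighted mean resultant length falls
  below 0.45 the assumptions are violated and the result is flagged
  rather than suppressed.
- **Paired Hotelling T²** tests within-individual phase differences
  (stridulation vs locomotion of the same animal) via the mean of the
  per-individual difference vectors (cos θ₁ − cos θ₂, sin θ₁ − sin θ₂).
- **Circular–linear correlation** relates treatment intensity (coded
  ordinally) to phase; note that for a linear ramp wrapping a full
  circle the coefficient's direct evaluation is ≈ 0.78, not 1 — only
  monotone arcs short of a full turn approach 1.

All circular tests are invariant under a common rotation of the input
angles (property-tested). Pairwise circular comparisons across m
treatment pairs use Bonferroni-adjusted α = 0.05/m (0.0167 for three
pairs).

## Scalar group statistics

Activity levels and period samples are typically non-normal with
unequal variances, so comparisons default to medians and rank tests:
Kruskal–Wallis (tie-corrected) with Dunn's post hoc z comparisons on
pooled midranks (Bonferroni-adjusted — the most conservative
reproducible variant), Brown–Forsythe for equality of variances
(ANOVA on |x − group median|), paired t for within-individual
day/night contrasts, Spearman correlation, and the Pearson χ² test of
independence (no continuity correction) for rhythm-type × treatment
tables. Standard tests are delegated to scipy.stats behind this
module's uniform result type; Dunn's test is implemented here.

## Numerical choices and degenerate inputs

- Periodogram: series shorter than twice the longest candidate are
  rejected; constant series are flagged, not errored, downstream.
- Cosinor: windows shorter than half the fitting period are rejected;
  fitted amplitudes below 1e−10 of the data scale are declared
  degenerate (no acrophase) — a per-day degenerate fit drops that day.
- Paired t with zero-variance differences: identical vectors give
  t = 0, p = 1; a constant non-zero shift gives p = 0 with an infinite
  statistic, flagged by value rather than raising.
- Hotelling with all-identical pairs returns the exact null (T² = 0);
  a singular difference covariance otherwise raises.
- MAD filter with zero MAD removes only values strictly off the
  median, so all-equal samples lose nothing.

## Validation strategy and problem sizes

The test suite checks each operation against an independent route:
brute-force folding for the periodogram (tolerance 1e−9), a dense
profile grid search for the cosinor, explicit-sum T² for the paired
Hotelling, and pingouin's circular routines for mean vector, Rayleigh
and circular–linear correlation. Type-I calibration suites run 500
null replicates per test (periodogram at a single fixed candidate,
Rayleigh, Kruskal–Wallis, Mardia–Watson–Wheeler). Parameter-recovery
suites use 5–6 day cohorts at amplitude/baseline = 3 — the regime
where single-individual period estimates land within one grid step of
truth ≥ 95% of the time — and the phase-dispersion mechanism is
checked on a three-point jitter sweep (0.5, 1.5, 3 h; 200 simulated
cohorts each), where the mean cohort vector length must strictly
decrease. These sizes keep the full suite under a few minutes on one
CPU while leaving comfortable statistical margins.

## Limitations

- Poisson counts cannot represent the burstiness of real syllable
  trains; recovery rates measured here are optimistic for
  over-dispersed data.
- The generator's phase jitter is between individuals and constant in
  time; real free-runners also wander in period and phase within a
  recording.
- Masking is a crude step-gain; real masking is intensity- and
  history-dependent.
- Significance of the periodogram peak relies on the asymptotic χ²
  null, which is mildly conservative for the ratio statistic at these
  series lengths.
- Passing tests on synthetic cohorts demonstrates correctness of the
  estimators under the stated model, not the biological fidelity of
  the template shapes.
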