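"""Extract acrophases and compare phase distributions between groups.

Simulates a tightly-phased control cohort and a phase-scattered cohort
(as under bright nocturnal light), extracts each individual's mean
acrophase by per-day cosinor fits, and runs the circular test battery.
"""

import numpy as np

from cricklight import (
    CohortConfig,
    REGIMES,
    hotelling_paired,
    mardia_watson_wheeler,
    mean_acrophase,
    mean_vector,
    rayleigh_test,
    simulate_cohort,
    to_activity_index,
    watson_williams,
)


def cohort_angles(phase_sd, master_seed):
    cfg = CohortConfig(
        regime=REGIMES["LD"], n_individuals=15, behaviour="stridulation",
        mixture={"synchronized": 1.0}, phase_sd_hours=phase_sd,
        master_seed=master_seed,
    )
    angles = []
    for m in simulate_cohort(cfg).members:
        angle, _ = mean_acrophase(to_activity_index(m.series))
        angles.append(angle)
    return np.asarray(angles)


tight = cohort_angles(phase_sd=0.8, master_seed=1)
scattered = cohort_angles(phase_sd=4.0, master_seed=2)

for name, angles in (("tight", tight), ("scattered", scattered)):
    mv = mean_vector(angles)
    z, p = rayleigh_test(angles)
    hours = mv.direction * 24 / (2 * np.pi)
    print(f"{name:9s}: R = {mv.length:.2f}, mean phase {hours:.1f} h, "
          f"Rayleigh p = {p:.2g}")

w, df, p = mardia_watson_wheeler(tight, scattered)
print(f"distribution difference (uniform scores): W = {w:.1f}, p = {p:.3g}")
f, df, p, ok = watson_williams(tight, scattered)
print(f"mean-direction difference: F = {f:.2f}, p = {p:.3g}"
      + ("" if ok else "  [low concentration: interpret with care]"))
f, df, p = hotelling_paired(tight, scattered)
print(f"paired within-individual shift: F = {f:.2f}, p = {p:.3g}")

print("""
Both cohorts peak near the same clock time (the song peaks mid-night),
so the mean-direction test stays quiet, but the scattered cohort's far
shorter mean vector and the uniform-scores test expose its wider phase
distribution - the population-level fingerprint of degraded
entrainment.""")
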