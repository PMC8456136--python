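"""Estimate one free-running individual's period with the periodogram.

Simulates a cricket whose activity onset drifts +40 minutes per day
(true period 24 h 40 min), computes the Sokolove-Bushell chi-square
periodogram over candidate periods 20-28 h, and prints the peak.
"""

import numpy as np

from cricklight import (
    IndividualConfig,
    REGIMES,
    chi_square_periodogram,
    estimate_period,
    simulate_individual,
    to_activity_index,
)

cfg = IndividualConfig(
    behaviour="stridulation", rhythm_type="free_run",
    true_period_hours=24 + 40 / 60, baseline_rate=0.5, amplitude=5.0,
)
series = simulate_individual(cfg, REGIMES["LL2"], days=6, seed=4)
pg = chi_square_periodogram(to_activity_index(series))
tau, peak_q = estimate_period(pg)

k = int(np.argmax(pg.Q))
print(f"true period        : {cfg.true_period_hours:.2f} h")
print(f"estimated period   : {tau} h")
print(f"peak Q             : {peak_q:.1f} "
      f"(chi-square 5% line at {pg.threshold[k]:.1f})")
print(f"significant peaks  : {int(pg.significant.sum())} of "
      f"{len(pg.period_hours)} candidates")

print("""
Q compares between-column to total variance after folding the series at
each candidate period; the peak far above the chi-square line marks a
strong endogenous rhythm, and the estimate lands on the 10-min grid
value closest to the true drift.""")
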