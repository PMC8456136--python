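"""Simulate a control and a constant-light cohort, then classify rhythms.

Builds two synthetic treatment groups of singing crickets — one under a
12:12 light-dark cycle (LD), one under constant light (LL) — runs every
individual through the chi-square periodogram, and prints the rhythm-type
proportions and period statistics per group.
"""

from cricklight import analyze_cohort, simulate_cohort, summarize_cohort, \
    treatment_preset

for treatment in ("LD", "LL"):
    cfg = treatment_preset(treatment, behaviour="stridulation",
                           n_individuals=20, days=5, master_seed=1)
    cohort = simulate_cohort(cfg)
    calls = analyze_cohort(cohort)
    (cell,) = summarize_cohort(calls)
    print(f"\n{treatment} (n={cell.n}):")
    print(f"  synchronized {cell.pct_synchronized:.0f}% | "
          f"free-run {cell.pct_free_run:.0f}% | "
          f"arrhythmic {cell.pct_arrhythmic:.0f}%")
    print(f"  median period {cell.period_median} h, "
          f"variance {cell.period_variance:.3f} h^2 "
          f"({cell.n_rhythmic} rhythmic individuals)")
    print(f"  phase mean vector R = {cell.mean_vector_length:.2f}")

print("""
The LD group is dominated by 24 h entrained rhythms with a long phase
mean vector (individuals sing in phase); under constant light most
individuals free-run at periods off 24 h or lose rhythmicity, and the
shorter mean vector shows the cohort's phases scattering.""")
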