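"""Synthetic generator: light schedules, rate templates, cohorts."""

import numpy as np
import pytest
from scipy import stats

from cricklight.synth import (
    REGIMES,
    CohortConfig,
    IndividualConfig,
    LightRegime,
    make_light_schedule,
    rate_template,
    simulate_cohort,
    simulate_individual,
    treatment_preset,
)


class TestLightSchedule:
    def test_ld_one_day(self):
        sched = make_light_schedule(REGIMES["LD"], days=1, bin_minutes=10)
        assert len(sched) == 144
        assert np.all(sched.lux[:72] == 40.0) and np.all(sched.is_photophase[:72])
        assert np.all(sched.lux[72:] == 0.0) and not np.any(sched.is_photophase[72:])

    def test_ll_constant_light(self):
        sched = make_light_schedule(REGIMES["LL"], days=1, bin_minutes=10)
        assert len(sched) == 144
        assert np.all(sched.lux == 40.0)
        # the objective 12:12 frame is retained even under constant light
        assert sched.is_photophase.sum() == 72

    def test_ll2_periodic_extension(self):
        sched = make_light_schedule(REGIMES["LL2"], days=5, bin_minutes=10)
        assert len(sched) == 720
        one_day = np.concatenate([np.full(72, 40.0), np.full(72, 2.0)])
        assert np.array_equal(sched.lux, np.tile(one_day, 5))

    def test_half_photophase_every_cycle(self):
        for name in REGIMES:
            sched = make_light_schedule(REGIMES[name], days=3, bin_minutes=10)
            per_day = sched.is_photophase.reshape(3, 144).sum(axis=1)
            assert np.all(per_day == 72)

    def test_rejects_non_divisible_bin(self):
        with pytest.raises(ValueError, match="divide"):
            make_light_schedule(REGIMES["LD"], days=1, bin_minutes=7)

    def test_ll_requires_equal_lux(self):
        with pytest.raises(ValueError, match="constant light"):
            LightRegime("LL", day_lux=40.0, night_lux=5.0)


class TestRateTemplate:
    def _night_fraction(self, cfg, n=100_000):
        t = np.linspace(0, 24, n, endpoint=False)
        lam = rate_template(cfg.behaviour, t, cfg)
        return lam[t >= 12.0].sum() / lam.sum()

    def test_arrhythmic_is_flat(self):
        cfg = IndividualConfig(
            behaviour="stridulation", rhythm_type="arrhythmic",
            true_period_hours=None, baseline_rate=2.0,
        )
        lam = rate_template("stridulation", np.linspace(0, 23.9, 50), cfg)
        assert np.all(lam == 2.0)

    def test_zero_amplitude_is_constant(self):
        cfg = IndividualConfig(behaviour="locomotion", amplitude=0.0,
                               baseline_rate=1.5)
        lam = rate_template("locomotion", np.linspace(0, 23.9, 50), cfg)
        assert np.allclose(lam, 1.5)

    def test_stridulation_default_is_strongly_nocturnal(self):
        # mirrors the observed ~94% nocturnal share of calling song
        cfg = IndividualConfig(behaviour="stridulation")
        assert self._night_fraction(cfg) >= 0.9

    def test_locomotion_default_is_diurnal_with_dusk_peak(self):
        cfg = IndividualConfig(behaviour="locomotion", baseline_rate=2.0,
                               amplitude=6.0)
        t = np.linspace(0, 24, 100_000, endpoint=False)
        lam = rate_template("locomotion", t, cfg)
        day_frac = lam[t < 12.0].sum() / lam.sum()
        assert day_frac > 0.6
        # a secondary local maximum just before lights-off
        dusk = lam[(t > 11.2) & (t < 11.8)].max()
        trough = lam[(t > 12.8) & (t < 13.5)].max()
        assert dusk > trough + 1.0

    def test_night_fraction_monotone_in_concentration(self):
        # oscillatory mass only (baseline 0): concentrating the bump
        # (smaller width) never lowers the nocturnal share, and spilling
        # past the 12 h night strictly lowers it
        fracs = [
            self._night_fraction(
                IndividualConfig(behaviour="stridulation", width_hours=w,
                                 baseline_rate=0.0)
            )
            for w in (3.0, 5.0, 6.0, 8.0, 10.0)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(fracs, fracs[1:]))
        assert fracs[2] > fracs[3] > fracs[4]

    def test_day_fraction_monotone_for_locomotion(self):
        def day_frac(w):
            cfg = IndividualConfig(behaviour="locomotion", width_hours=w,
                                   baseline_rate=0.0, dusk_weight=0.0)
            t = np.linspace(0, 24, 100_000, endpoint=False)
            lam = rate_template("locomotion", t, cfg)
            return lam[t < 12.0].sum() / lam.sum()

        fracs = [day_frac(w) for w in (4.0, 6.0, 8.0, 10.0)]
        assert all(a >= b - 1e-12 for a, b in zip(fracs, fracs[1:]))
        assert fracs[1] > fracs[2] > fracs[3]

    def test_rejects_negative_parameters(self):
        with pytest.raises(ValueError):
            IndividualConfig(behaviour="stridulation", baseline_rate=-1.0)
        with pytest.raises(ValueError):
            IndividualConfig(behaviour="stridulation", amplitude=-0.1)

    def test_rejects_time_outside_cycle(self):
        cfg = IndividualConfig(behaviour="stridulation")
        with pytest.raises(ValueError, match="t_in_cycle"):
            rate_template("stridulation", np.array([24.0]), cfg)


class TestSimulateIndividual:
    def test_seed_determinism(self):
        cfg = IndividualConfig(behaviour="stridulation")
        a = simulate_individual(cfg, REGIMES["LD"], days=5, seed=7)
        b = simulate_individual(cfg, REGIMES["LD"], days=5, seed=7)
        assert np.array_equal(a.counts, b.counts)

    def test_zero_rate_gives_all_zero(self):
        cfg = IndividualConfig(behaviour="locomotion", baseline_rate=0.0,
                               amplitude=0.0)
        s = simulate_individual(cfg, REGIMES["LD"], days=5, seed=0)
        assert np.all(s.counts == 0)

    def test_total_count_within_poisson_bound(self):
        # flat rate 5/bin over 720 bins: total ~ Poisson(3600)
        cfg = IndividualConfig(behaviour="locomotion", baseline_rate=5.0,
                               amplitude=0.0)
        s = simulate_individual(cfg, REGIMES["LD"], days=5, seed=11)
        assert abs(s.counts.sum() - 3600) <= 4 * np.sqrt(3600)

    def test_empirical_mean_tracks_rate(self):
        # >= 1e4 bins of a flat-rate process: mean within 3 standard errors
        cfg = IndividualConfig(behaviour="stridulation",
                               rhythm_type="arrhythmic",
                               true_period_hours=None, baseline_rate=2.0)
        s = simulate_individual(cfg, REGIMES["LD"], days=70, seed=5)
        n = len(s.counts)
        assert n >= 10_000
        se = np.sqrt(2.0 / n)
        assert abs(s.counts.mean() - 2.0) <= 3 * se

    def test_period_must_sit_on_bin_grid(self):
        cfg = IndividualConfig(behaviour="stridulation",
                               true_period_hours=24.05)
        with pytest.raises(ValueError, match="bin width"):
            simulate_individual(cfg, REGIMES["LD"], days=5, seed=0)

    def test_noiseless_series_equals_template(self):
        cfg = IndividualConfig(behaviour="stridulation", baseline_rate=0.5,
                               amplitude=4.0)
        s = simulate_individual(cfg, REGIMES["LD"], days=5, noise="none")
        t = s.t_hours % 24.0
        lam = rate_template("stridulation", t, cfg)
        assert np.allclose(s.counts, lam)


class TestSimulateCohort:
    def test_pure_mixture_labels(self):
        cfg = CohortConfig(regime=REGIMES["LD"], n_individuals=10,
                           mixture={"synchronized": 1.0}, master_seed=1)
        cohort = simulate_cohort(cfg)
        assert len(cohort) == 10
        assert all(m.rhythm_type == "synchronized" for m in cohort.members)
        assert all(m.true_period_hours == 24.0 for m in cohort.members)

    def test_master_seed_reproducibility(self):
        cfg = treatment_preset("LL", n_individuals=6, master_seed=42)
        a, b = simulate_cohort(cfg), simulate_cohort(cfg)
        for ma, mb in zip(a.members, b.members):
            assert ma.rhythm_type == mb.rhythm_type
            assert np.array_equal(ma.series.counts, mb.series.counts)

    def test_mixture_counts_within_binomial_bounds(self):
        cfg = CohortConfig(
            regime=REGIMES["LL"], n_individuals=200,
            mixture={"free_run": 0.5, "arrhythmic": 0.5}, master_seed=9,
        )
        cohort = simulate_cohort(cfg)
        n_free = sum(m.rhythm_type == "free_run" for m in cohort.members)
        lo = stats.binom.ppf(0.005, 200, 0.5)
        hi = stats.binom.ppf(0.995, 200, 0.5)
        assert lo <= n_free <= hi

    def test_ground_truth_attached_to_every_member(self):
        cohort = simulate_cohort(treatment_preset("LL2", n_individuals=12,
                                                  master_seed=2))
        for m in cohort.members:
            assert m.rhythm_type in ("synchronized", "free_run", "arrhythmic")
            if m.rhythm_type == "arrhythmic":
                assert m.true_period_hours is None
            else:
                assert m.true_period_hours is not None

    def test_freerun_periods_on_grid_and_off_24(self):
        cfg = CohortConfig(regime=REGIMES["LL"], n_individuals=30,
                           mixture={"free_run": 1.0}, master_seed=3)
        for m in simulate_cohort(cfg).members:
            p_bins = m.true_period_hours * 6
            assert abs(p_bins - round(p_bins)) < 1e-9
            assert abs(m.true_period_hours - 24.0) > 10.0 / 60.0

    def test_invalid_mixture_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            CohortConfig(regime=REGIMES["LD"],
                         mixture={"synchronized": 0.6, "free_run": 0.6})
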