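"""Cosinor fits, acrophase averaging, circular statistics."""

import numpy as np
import pingouin as pg
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cricklight.phase import (
    acrophase_to_angle,
    angle_to_hours,
    circular_linear_correlation,
    fit_cosinor,
    hotelling_paired,
    mardia_watson_wheeler,
    mean_acrophase,
    mean_vector,
    rayleigh_test,
    watson_williams,
)
from cricklight.preprocess import ActivityIndexSeries

TWO_PI = 2 * np.pi

angle_lists = st.lists(
    st.floats(min_value=0, max_value=TWO_PI - 1e-6), min_size=4, max_size=40
)


def _ai_series(values):
    return ActivityIndexSeries(
        individual_id="x", behaviour="stridulation", treatment="LD",
        values=values,
    )


class TestCosinor:
    def test_pure_cosine_recovered_exactly(self):
        t = (np.arange(144) + 0.5) / 6.0
        x = 0.5 + 0.3 * np.cos(TWO_PI / 24 * (t - 6.0))
        fit = fit_cosinor(x, t, 24.0)
        assert np.isclose(fit.acrophase_hours, 6.0, atol=1e-9)
        assert np.isclose(fit.amplitude, 0.3)
        assert np.isclose(fit.mesor, 0.5)
        assert fit.rss < 1e-18

    def test_constant_series_degenerate(self):
        t = (np.arange(144) + 0.5) / 6.0
        fit = fit_cosinor(np.full(144, 0.4), t, 24.0)
        assert fit.degenerate and fit.acrophase_hours is None
        assert fit.amplitude == 0.0

    def test_window_must_cover_half_period(self):
        t = np.linspace(0, 8, 48)
        with pytest.raises(ValueError, match="shorter than half"):
            fit_cosinor(np.ones(48), t, 24.0)

    def test_noisy_fit_matches_grid_search(self, rng):
        # dense grid-search maximizer of the same model, as the oracle
        t = (np.arange(144) + 0.5) / 6.0
        x = 0.4 + 0.25 * np.cos(TWO_PI / 24 * (t - 15.0)) + rng.normal(0, 0.1, 144)
        fit = fit_cosinor(x, t, 24.0)
        phis = np.arange(0, 24, 0.01)
        best_phi, best_rss = None, np.inf
        for phi in phis:
            design = np.column_stack(
                [np.ones_like(t), np.cos(TWO_PI / 24 * (t - phi))]
            )
            beta, res, *_ = np.linalg.lstsq(design, x, rcond=None)
            rss = float(res[0]) if res.size else np.inf
            if beta[1] >= 0 and rss < best_rss:
                best_phi, best_rss = phi, rss
        assert abs(fit.acrophase_hours - best_phi) <= 0.5  # within 30 min


class TestMeanAcrophase:
    def test_five_identical_days(self):
        t = (np.arange(144) + 0.5) / 6.0
        day = 0.5 + 0.4 * np.cos(TWO_PI / 24 * (t - 18.0))
        s = _ai_series(np.tile(day / day.max(), 5))
        angle, n_days = mean_acrophase(s)
        assert n_days == 5
        assert np.isclose(angle_to_hours(angle), 18.0, atol=1e-6)

    def test_wraparound_midnight(self):
        # days peaking at 23 h and 1 h average to midnight, not noon
        t = (np.arange(144) + 0.5) / 6.0
        day_a = 0.5 + 0.4 * np.cos(TWO_PI / 24 * (t - 23.0))
        day_b = 0.5 + 0.4 * np.cos(TWO_PI / 24 * (t - 1.0))
        vals = np.concatenate([day_a, day_b])
        s = _ai_series(vals / vals.max())
        angle, _ = mean_acrophase(s, n_days=2)
        hours = angle_to_hours(angle)
        assert min(hours, 24 - hours) < 1e-6

    def test_single_fit_variant(self):
        t = (np.arange(720) + 0.5) / 6.0
        x = 0.5 + 0.4 * np.cos(TWO_PI / 24 * (t - 18.0))
        s = _ai_series(x / x.max())
        angle, n_days = mean_acrophase(s, per_day=False)
        assert np.isclose(angle_to_hours(angle), 18.0, atol=1e-6)

    def test_all_days_flat_rejected(self):
        s = _ai_series(np.ones(720))
        with pytest.raises(ValueError, match="degenerate"):
            mean_acrophase(s)


class TestMeanVector:
    def test_identical_angles_full_length(self):
        mv = mean_vector(np.full(7, 1.3))
        assert np.isclose(mv.length, 1.0)
        assert np.isclose(mv.direction, 1.3)

    def test_balanced_cross_cancels(self):
        mv = mean_vector([0, np.pi / 2, np.pi, 3 * np.pi / 2])
        assert mv.length < 1e-12
        assert mv.direction is None

    @given(angle_lists, st.floats(min_value=0, max_value=TWO_PI))
    def test_rotation_equivariance(self, angles, delta):
        a = np.asarray(angles)
        mv1, mv2 = mean_vector(a), mean_vector((a + delta) % TWO_PI)
        assert np.isclose(mv1.length, mv2.length, atol=1e-9)
        if mv1.direction is not None and mv1.length > 1e-6:
            d = (mv2.direction - mv1.direction - delta) % TWO_PI
            assert min(d, TWO_PI - d) < 1e-6

    def test_matches_pingouin(self, rng):
        a = rng.uniform(0, TWO_PI, 25)
        mv = mean_vector(a)
        assert np.isclose(mv.length, pg.circ_r(a))
        assert np.isclose(
            (mv.direction - pg.circ_mean(a)) % TWO_PI % TWO_PI, 0, atol=1e-9
        ) or np.isclose(mv.direction % TWO_PI, pg.circ_mean(a) % TWO_PI)


class TestRayleigh:
    def test_concentrated_sample_rejects(self, rng):
        a = rng.normal(1.0, 0.05, 10) % TWO_PI
        z, p = rayleigh_test(a)
        assert p < 0.001
        assert z > 9.0  # near n R^2 = 10 for a tight cluster

    def test_uniform_grid_is_null(self):
        a = np.arange(8) * TWO_PI / 8
        z, p = rayleigh_test(a)
        assert z < 1e-12 and p > 0.999

    def test_matches_pingouin(self, rng):
        for _ in range(5):
            a = rng.uniform(0, TWO_PI, 20)
            z, p = rayleigh_test(a)
            z_ref, p_ref = pg.circ_rayleigh(a)
            assert np.isclose(z, z_ref, atol=1e-9)
            assert np.isclose(p, p_ref, atol=1e-6)


class TestMardiaWatsonWheeler:
    def test_offset_groups_detected(self, rng):
        g1 = rng.normal(0.5, 0.3, 15) % TWO_PI
        g2 = (g1 + np.pi) % TWO_PI
        w, df, p = mardia_watson_wheeler(g1, g2)
        assert df == 2 and p < 0.01

    def test_rotation_invariance(self, rng):
        g1 = rng.uniform(0, TWO_PI, 12)
        g2 = rng.uniform(0, TWO_PI, 9)
        w1, *_ = mardia_watson_wheeler(g1, g2)
        # a common rotation permutes pooled ranks cyclically: W unchanged
        w2, *_ = mardia_watson_wheeler((g1 + 1.1) % TWO_PI, (g2 + 1.1) % TWO_PI)
        assert np.isclose(w1, w2, atol=1e-9)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            mardia_watson_wheeler([0.1, 0.2], [0.3])


class TestWatsonWilliams:
    def test_identical_concentrated_groups_null(self, rng):
        g = rng.normal(2.0, 0.2, 15) % TWO_PI
        f, df, p, ok = watson_williams(g, g.copy())
        assert ok
        assert f < 1e-9 and p > 0.999

    def test_quarter_turn_offset_detected(self, rng):
        g1 = rng.normal(1.0, 0.3, 15) % TWO_PI
        g2 = (g1 + np.pi / 2) % TWO_PI
        f, df, p, ok = watson_williams(g1, g2)
        assert ok and p < 0.01
        assert df == (1, 28)

    def test_rotation_invariance(self, rng):
        g1 = rng.normal(0.5, 0.4, 12) % TWO_PI
        g2 = rng.normal(1.5, 0.4, 10) % TWO_PI
        f1, *_ = watson_williams(g1, g2)
        f2, *_ = watson_williams((g1 + 2.2) % TWO_PI, (g2 + 2.2) % TWO_PI)
        assert np.isclose(f1, f2, atol=1e-9)

    def test_dispersed_samples_flagged(self, rng):
        g1 = rng.uniform(0, TWO_PI, 20)
        g2 = rng.uniform(0, TWO_PI, 20)
        *_, ok = watson_williams(g1, g2)
        assert not ok


class TestHotellingPaired:
    def test_identical_pairs_null(self):
        a = np.linspace(0.2, 5.8, 12)
        f, df, p = hotelling_paired(a, a.copy())
        assert f == 0.0 and p == 1.0

    def test_constant_offset_detected(self, rng):
        a = rng.normal(1.0, 0.15, 12) % TWO_PI
        b = (a + np.pi / 2 + rng.normal(0, 0.05, 12)) % TWO_PI
        f, df, p = hotelling_paired(a, b)
        assert df == (2, 10) and p < 0.01

    def test_swap_symmetry(self, rng):
        a = rng.uniform(0, TWO_PI, 10)
        b = rng.uniform(0, TWO_PI, 10)
        f1, _, p1 = hotelling_paired(a, b)
        f2, _, p2 = hotelling_paired(b, a)
        assert np.isclose(f1, f2) and np.isclose(p1, p2)


class TestCircularLinearCorrelation:
    def test_independent_near_zero(self, rng):
        x = rng.normal(0, 1, 400)
        a = rng.uniform(0, TWO_PI, 400)
        r, _ = circular_linear_correlation(x, a)
        assert r < 0.15

    def test_monotone_arc_near_one(self):
        # angles monotone in x over a quarter circle (no wrap): r -> 1
        x = np.arange(24, dtype=float)
        a = (np.pi / 2) * x / 24
        r, p = circular_linear_correlation(x, a)
        assert r > 0.99 and p < 1e-4

    def test_full_wrap_value_frozen_from_oracle(self):
        # a linear ramp against one full turn: cos/sin each correlate
        # only partially with the ramp; direct evaluation gives 0.7826
        x = np.arange(24, dtype=float)
        a = TWO_PI * x / 24
        r, p = circular_linear_correlation(x, a)
        assert np.isclose(r, 0.7826075514317908, atol=1e-9)
        assert p < 1e-3

    def test_location_invariance(self, rng):
        x = rng.normal(0, 1, 30)
        a = rng.uniform(0, TWO_PI, 30)
        r1, _ = circular_linear_correlation(x, a)
        r2, _ = circular_linear_correlation(x + 37.5, a)
        assert np.isclose(r1, r2)

    def test_matches_pingouin(self, rng):
        x = rng.normal(0, 1, 40)
        a = rng.uniform(0, TWO_PI, 40)
        r, _ = circular_linear_correlation(x, a)
        r_ref, _ = pg.circ_corrcl(a, x)  # pingouin takes (angles, linear)
        assert np.isclose(r, float(r_ref), atol=1e-9)


def test_angle_hour_roundtrip():
    for h in (0.0, 6.0, 18.0, 23.9):
        assert np.isclose(angle_to_hours(acrophase_to_angle(h)), h)
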