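"""Cosinor acrophase extraction and circular statistics.

Acrophases come from single-component cosinor fits: the least-squares
solution of ``x(t) = M + b1*cos(wt) + b2*sin(wt)`` with ``w = 2*pi/tau``
gives mesor ``M``, amplitude ``A = sqrt(b1^2 + b2^2)`` and the acrophase
as the time of the fitted maximum within ``[0, tau)``.  Per-individual
mean acrophases (circular mean of per-day fits over >= 5 days) are then
angles on the 24 h circle, and group-level questions — is a treatment's
phase distribution concentrated? do treatments share a mean direction?
does an individual keep distinct phases for its two behaviours? — are
answered with the Rayleigh, Mardia–Watson–Wheeler, Watson–Williams and
paired Hotelling tests plus the circular–linear correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .preprocess import ActivityIndexSeries

__all__ = [
    "CosinorFit",
    "MeanVector",
    "fit_cosinor",
    "mean_acrophase",
    "acrophase_to_angle",
    "angle_to_hours",
    "mean_vector",
    "rayleigh_test",
    "mardia_watson_wheeler",
    "watson_williams",
    "hotelling_paired",
    "circular_linear_correlation",
]

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class CosinorFit:
    """Mesor, amplitude and acrophase of a single-component cosinor fit.

    ``acrophase_hours`` is the time of the fitted peak within one fitting
    period; it is ``None`` (and ``degenerate`` is set) when the fitted
    amplitude vanishes, e.g. for a constant series.
    """

    mesor: float
    amplitude: float
    acrophase_hours: float | None
    period_hours: float
    rss: float
    degenerate: bool = False


@dataclass(frozen=True)
class MeanVector:
    """Resultant of unit vectors at the sample angles.

    ``length`` (R) measures phase concentration in [0, 1]; ``direction``
    is undefined (None) when R = 0.
    """

    length: float
    direction: float | None
    n: int


def fit_cosinor(values, t_hours, period_hours: float = 24.0) -> CosinorFit:
    """Least-squares cosinor fit of one rhythmic component.

    ``t_hours`` are the observation times (bin centres); the window must
    cover at least half the fitting period for the design to be sound,
    and a full period for a trustworthy acrophase.
    """
    x = np.asarray(values, dtype=float)
    t = np.asarray(t_hours, dtype=float)
    if x.shape != t.shape:
        raise ValueError("values and t_hours must have the same shape")
    if period_hours <= 0:
        raise ValueError("period_hours must be positive")
    span = t.max() - t.min()
    if span < period_hours / 2:
        raise ValueError(
            f"window of {span:.2f} h is shorter than half the "
            f"{period_hours} h fitting period"
        )
    w = TWO_PI / period_hours
    design = np.column_stack([np.ones_like(t), np.cos(w * t), np.sin(w * t)])
    beta, *_ = np.linalg.lstsq(design, x, rcond=None)
    mesor, b1, b2 = beta
    amplitude = float(np.hypot(b1, b2))
    resid = x - design @ beta
    rss = float(resid @ resid)
    scale = max(float(np.abs(x).max(initial=0.0)), 1.0)
    if amplitude <= 1e-10 * scale:
        return CosinorFit(float(mesor), 0.0, None, period_hours, rss, degenerate=True)
    # x(t) = M + A cos(wt - theta) peaks at t = theta / w
    theta = np.arctan2(b2, b1)
    acro = (theta / w) % period_hours
    return CosinorFit(float(mesor), amplitude, float(acro), period_hours, rss)


def acrophase_to_angle(acrophase_hours: float, period_hours: float = 24.0) -> float:
    """Map a peak time to an angle in [0, 2*pi) on the period's circle."""
    return (TWO_PI * acrophase_hours / period_hours) % TWO_PI


def angle_to_hours(angle: float, period_hours: float = 24.0) -> float:
    return (angle % TWO_PI) * period_hours / TWO_PI


def mean_acrophase(
    series: ActivityIndexSeries,
    period_hours: float = 24.0,
    n_days: int = 5,
    per_day: bool = True,
):
    """Mean acrophase of an individual's rhythm over ``n_days`` days.

    The default fits a cosinor to each consecutive 24 h window and takes
    the circular mean of the daily peak times, so a day mired in noise
    only drops out instead of corrupting the rest; days whose fit is
    degenerate are skipped.  ``per_day=False`` fits a single cosinor to
    the whole window instead (at ``period_hours``, which may be the
    individual's own estimated period).

    Returns ``(angle_radians, n_days_used)`` with the angle on the 24 h
    clock face.
    """
    bpd = series.bins_per_day
    if series.n_days < n_days:
        raise ValueError(f"need >= {n_days} complete days, have {series.n_days}")
    t = series.t_hours
    x = series.values
    if not per_day:
        fit = fit_cosinor(x[: n_days * bpd], t[: n_days * bpd], period_hours)
        if fit.acrophase_hours is None:
            raise ValueError("cosinor fit degenerate: no acrophase")
        # report on the 24 h clock regardless of the fitting period
        return acrophase_to_angle(fit.acrophase_hours % 24.0, 24.0), n_days
    angles = []
    for d in range(n_days):
        sl = slice(d * bpd, (d + 1) * bpd)
        fit = fit_cosinor(x[sl], t[sl], period_hours)
        if fit.acrophase_hours is None:
            continue
        angles.append(acrophase_to_angle(fit.acrophase_hours, period_hours))
    if not angles:
        raise ValueError("all daily cosinor fits were degenerate")
    mv = mean_vector(np.asarray(angles))
    if mv.direction is None:
        raise ValueError("daily acrophases cancel: mean direction undefined")
    return mv.direction % TWO_PI, len(angles)


def mean_vector(angles) -> MeanVector:
    """Mean resultant vector (R, theta-bar) of a sample of angles."""
    a = np.asarray(angles, dtype=float)
    if a.size < 1:
        raise ValueError("need at least one angle")
    c = np.cos(a).sum()
    s = np.sin(a).sum()
    r = float(np.hypot(c, s) / a.size)
    direction = float(np.arctan2(s, c)) % TWO_PI if r > 1e-12 else None
    return MeanVector(length=min(r, 1.0), direction=direction, n=a.size)


def rayleigh_test(angles) -> tuple[float, float]:
    """Rayleigh test of circular uniformity: returns (z, p).

    z = n R^2; p uses the standard series approximation, accurate for
    n >= 3 and conservative for tiny samples.
    """
    a = np.asarray(angles, dtype=float)
    n = a.size
    if n < 3:
        raise ValueError("Rayleigh test needs n >= 3")
    r = mean_vector(a).length
    big_r = n * r
    z = n * r**2
    p = np.exp(np.sqrt(1.0 + 4.0 * n + 4.0 * (n**2 - big_r**2)) - (1.0 + 2.0 * n))
    return float(z), float(min(max(p, 0.0), 1.0))


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def mardia_watson_wheeler(*groups) -> tuple[float, int, float]:
    """Uniform-scores (Mardia–Watson–Wheeler) test for >= 2 angle samples.

    The pooled angles are ranked (midranks for ties), mapped to uniform
    scores ``beta_i = 2*pi*rank_i/N``, and

        W = 2 * sum_j (C_j^2 + S_j^2) / n_j

    with ``C_j, S_j`` the cosine/sine sums of group ``j``'s scores; under
    equal distributions W is chi-square with ``2(g - 1)`` df.  Sensitive
    to any distributional difference (location or dispersion).
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    for g in gs:
        if g.size < 2:
            raise ValueError("every group needs n >= 2")
    pooled = np.concatenate(gs)
    n_total = pooled.size
    ranks = _midranks(pooled % TWO_PI)
    beta = TWO_PI * ranks / n_total
    w = 0.0
    start = 0
    for g in gs:
        b = beta[start : start + g.size]
        w += (np.cos(b).sum() ** 2 + np.sin(b).sum() ** 2) / g.size
        start += g.size
    w *= 2.0
    df = 2 * (len(gs) - 1)
    p = float(stats.chi2.sf(w, df))
    return float(w), df, p


def _kappa_ml(r: float) -> float:
    """Fisher's approximation to the ML concentration of a von Mises sample."""
    if r < 0.53:
        return 2 * r + r**3 + 5 * r**5 / 6
    if r < 0.85:
        return -0.4 + 1.39 * r + 0.43 / (1 - r)
    return 1.0 / (r**3 - 4 * r**2 + 3 * r)


def watson_williams(*groups) -> tuple[float, tuple[int, int], float, bool]:
    """Watson–Williams F-test for equal mean directions of >= 2 samples.

    Returns ``(F, (df1, df2), p, assumption_ok)``.  Assumes comparable,
    reasonably high concentrations; when the weighted mean resultant
    length falls below 0.45 the chi-square correction is unreliable and
    ``assumption_ok`` is False (the numbers are still returned).
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    n = sum(g.size for g in gs)
    g_count = len(gs)
    if n <= g_count:
        raise ValueError("need more angles than groups")
    resultants = []
    for g in gs:
        resultants.append(float(np.hypot(np.cos(g).sum(), np.sin(g).sum())))
    pooled = np.concatenate(gs)
    big_r = float(np.hypot(np.cos(pooled).sum(), np.sin(pooled).sum()))
    sum_rj = sum(resultants)
    rw = sum_rj / n
    kappa = _kappa_ml(rw)
    correction = 1.0 + 3.0 / (8.0 * kappa) if kappa > 0 else 1.0
    df1, df2 = g_count - 1, n - g_count
    denom = n - sum_rj
    if denom <= 0:
        return float("inf"), (df1, df2), 0.0, rw >= 0.45
    f = correction * ((sum_rj - big_r) / df1) / (denom / df2)
    f = max(f, 0.0)
    p = float(stats.f.sf(f, df1, df2))
    return float(f), (df1, df2), p, rw >= 0.45


def hotelling_paired(angles1, angles2) -> tuple[float, tuple[int, int], float]:
    """Paired Hotelling test for a within-individual phase difference.

    Each pair's difference vector ``d_i = (cos t1 - cos t2,
    sin t1 - sin t2)`` is a point in the plane; a one-sample Hotelling
    T^2 asks whether the mean difference vector is (0, 0).  Returns
    ``(F, (2, n - 2), p)``.
    """
    a1 = np.asarray(angles1, dtype=float)
    a2 = np.asarray(angles2, dtype=float)
    if a1.shape != a2.shape:
        raise ValueError("paired samples must have equal length")
    n = a1.size
    if n < 3:
        raise ValueError("paired Hotelling test needs n >= 3 pairs")
    d = np.column_stack([np.cos(a1) - np.cos(a2), np.sin(a1) - np.sin(a2)])
    if np.allclose(d, 0.0):  # every pair identical: nothing to test against
        return 0.0, (2, n - 2), 1.0
    dbar = d.mean(axis=0)
    cov = np.cov(d, rowvar=False, ddof=1)
    if np.linalg.matrix_rank(cov) < 2:
        raise ValueError("degenerate pairs: singular covariance")
    t2 = float(n * dbar @ np.linalg.solve(cov, dbar))
    f = t2 * (n - 2) / (2.0 * (n - 1))
    p = float(stats.f.sf(f, 2, n - 2))
    return float(f), (2, n - 2), p


def circular_linear_correlation(linear_values, angles) -> tuple[float, float]:
    """Circular–linear correlation coefficient r in [0, 1] and its p-value.

    Correlates a linear variable x with (cos, sin) of the angles:

        r^2 = (r_xc^2 + r_xs^2 - 2 r_xc r_xs r_cs) / (1 - r_cs^2)

    The p-value uses the chi-square(2) approximation for n r^2.
    """
    x = np.asarray(linear_values, dtype=float)
    a = np.asarray(angles, dtype=float)
    if x.shape != a.shape:
        raise ValueError("inputs must have equal length")
    n = x.size
    if n < 4:
        raise ValueError("need n >= 4")
    if np.ptp(x) == 0:
        raise ValueError("linear variable has zero variance")
    c, s = np.cos(a), np.sin(a)
    rxc = np.corrcoef(x, c)[0, 1]
    rxs = np.corrcoef(x, s)[0, 1]
    rcs = np.corrcoef(c, s)[0, 1]
    r2 = (rxc**2 + rxs**2 - 2 * rxc * rxs * rcs) / (1 - rcs**2)
    r = float(np.sqrt(max(r2, 0.0)))
    p = float(stats.chi2.sf(n * r**2, 2))
    return r, p
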