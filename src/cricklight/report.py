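"""Cohort-level orchestration: actograms, daily profiles, summaries.

Ties the pipeline together for a whole treatment group: run every
individual through normalization, periodogram classification and
acrophase extraction, then aggregate — rhythm-type proportions, period
medians and variances after MAD outlier filtering, and the cohort's
phase mean vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import phase as phase_mod
from . import rhythm as rhythm_mod
from .groupstats import lower_median
from .preprocess import ActivityIndexSeries, to_activity_index
from .synth import Cohort

__all__ = [
    "DoubleActogram",
    "build_double_actogram",
    "mean_daily_profile",
    "analyze_cohort",
    "summarize_cohort",
    "CohortSummary",
]


@dataclass(frozen=True)
class DoubleActogram:
    """Days x (2 x bins/day) matrix for the classic double-plotted raster.

    Row ``d`` shows days ``d`` and ``d + 1`` side by side, so each row's
    right half equals the next row's left half exactly.
    """

    matrix: np.ndarray
    day_labels: tuple
    light_bar: np.ndarray


def build_double_actogram(series: ActivityIndexSeries) -> DoubleActogram:
    """Fold an activity-index series into a double-plotted actogram."""
    bpd = series.bins_per_day
    n_days = series.n_days
    if n_days < 2:
        raise ValueError("need at least 2 complete days to double-plot")
    vals = series.values[: n_days * bpd].reshape(n_days, bpd)
    matrix = np.hstack([vals[:-1], vals[1:]])
    if series.is_photophase is not None:
        bar = np.concatenate(
            [series.is_photophase[:bpd], series.is_photophase[:bpd]]
        )
    else:
        bar = np.concatenate([np.arange(bpd) < bpd // 2] * 2)
    return DoubleActogram(
        matrix=matrix,
        day_labels=tuple(range(1, n_days)),
        light_bar=bar,
    )


def mean_daily_profile(series_list) -> pd.DataFrame:
    """Fold each individual to 24 h, then average across individuals.

    Returns a frame with per-bin ``mean`` and ``sem`` (standard error
    over individuals; 0 when there is a single individual).
    """
    if not series_list:
        raise ValueError("need at least one series")
    bpd = series_list[0].bins_per_day
    bm = series_list[0].bin_minutes
    folded = []
    for s in series_list:
        if s.bins_per_day != bpd or s.bin_minutes != bm:
            raise ValueError("all series must share the same bin grid")
        vals = np.asarray(
            s.values if isinstance(s, ActivityIndexSeries) else s.counts, float
        )
        n_days = len(vals) // bpd
        folded.append(vals[: n_days * bpd].reshape(n_days, bpd).mean(axis=0))
    stack = np.vstack(folded)
    mean = stack.mean(axis=0)
    if stack.shape[0] > 1:
        sem = stack.std(axis=0, ddof=1) / np.sqrt(stack.shape[0])
    else:
        sem = np.zeros(bpd)
    return pd.DataFrame(
        {
            "hour": (np.arange(bpd) + 0.5) * bm / 60.0,
            "mean": mean,
            "sem": sem,
        }
    )


def analyze_cohort(
    cohort: Cohort,
    alpha: float = 0.05,
    period_grid_bins: np.ndarray | None = None,
    acrophase_days: int = 5,
) -> pd.DataFrame:
    """Per-individual rhythm calls and mean acrophases for a cohort.

    Returns one row per individual: period estimate (hours), peak Q,
    significance, rhythm-type label, mean acrophase (hours on the 24 h
    clock) and the generating ground truth for recovery checks.
    """
    rows = []
    for member in cohort.members:
        s = member.series
        ai = to_activity_index(s)
        call = rhythm_mod.analyze_series(ai, period_grid_bins, alpha=alpha)
        acro_h = np.nan
        angle = np.nan
        days_used = 0
        try:
            angle, days_used = phase_mod.mean_acrophase(
                ai, period_hours=24.0, n_days=min(acrophase_days, ai.n_days)
            )
            acro_h = phase_mod.angle_to_hours(angle)
        except ValueError:
            pass
        rows.append(
            {
                "individual_id": s.individual_id,
                "behaviour": s.behaviour,
                "treatment": s.treatment,
                "period_hours": call.period_hours,
                "peak_Q": call.peak_Q,
                "significant": call.significant,
                "label": call.label,
                "acrophase_hours": acro_h,
                "acrophase_angle_rad": angle,
                "acrophase_days_used": days_used,
                "true_rhythm_type": member.rhythm_type,
                "true_period_hours": member.true_period_hours,
                "true_phase_hours": member.phase_hours,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CohortSummary:
    """Aggregates for one treatment x behaviour cell."""

    treatment: str
    behaviour: str
    n: int
    n_rhythmic: int
    period_median: float | None
    period_variance: float | None
    n_period_outliers: int
    pct_synchronized: float
    pct_free_run: float
    pct_arrhythmic: float
    mean_vector_length: float | None
    mean_vector_direction_hours: float | None

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def summarize_cohort(calls: pd.DataFrame, mad_k: float = 3.0) -> list[CohortSummary]:
    """Aggregate per-individual calls into per-cell cohort summaries.

    Period medians and variances are computed on significant periods
    after the 3-scaled-MAD outlier filter (when at least 3 periods are
    available); rhythm-type percentages are over all classified
    individuals; the phase mean vector is over individuals with a
    defined mean acrophase.
    """
    out: list[CohortSummary] = []
    for (treat, behav), cell in calls.groupby(["treatment", "behaviour"], sort=True):
        n = len(cell)
        labels = cell["label"]
        periods = cell.loc[cell["significant"], "period_hours"].dropna().to_numpy()
        n_out = 0
        med = var = None
        if periods.size >= 3:
            kept, removed = rhythm_mod.mad_outlier_filter(periods, k=mad_k)
            n_out = removed.size
            med = lower_median(kept)
            var = float(np.var(kept, ddof=1)) if kept.size > 1 else 0.0
        elif periods.size > 0:
            med = lower_median(periods)
            var = float(np.var(periods, ddof=1)) if periods.size > 1 else 0.0
        angles = cell["acrophase_angle_rad"].dropna().to_numpy()
        mv_len = mv_dir = None
        if angles.size:
            mv = phase_mod.mean_vector(angles)
            mv_len = mv.length
            mv_dir = (
                phase_mod.angle_to_hours(mv.direction)
                if mv.direction is not None
                else None
            )
        out.append(
            CohortSummary(
                treatment=treat,
                behaviour=behav,
                n=n,
                n_rhythmic=int(cell["significant"].sum()),
                period_median=med,
                period_variance=var,
                n_period_outliers=n_out,
                pct_synchronized=100.0 * (labels == "synchronized").mean(),
                pct_free_run=100.0 * (labels == "free_run").mean(),
                pct_arrhythmic=100.0 * (labels == "arrhythmic").mean(),
                mean_vector_length=mv_len,
                mean_vector_direction_hours=mv_dir,
            )
        )
    return out
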