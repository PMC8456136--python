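"""Event binning, inclusion rules, normalization and day/night partition.

The pipeline starts at the event level (timestamps of stridulation
syllables or motion events) or at pre-binned counts.  Activity is
assessed in 10-min bins per animal and behaviour; recordings must span
at least five consecutive usable days.  Two normalizations are used
downstream: by the individual's own mean (for quantitative day/night
comparisons) and by its own maximum, giving an activity index in
[0, 1] (for rhythmicity, period, and acrophase analyses).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .synth import LightRegime, LightSchedule, make_light_schedule

__all__ = [
    "BinnedSeries",
    "ActivityIndexSeries",
    "InclusionResult",
    "bin_events",
    "apply_inclusion_rules",
    "normalize_by_mean",
    "normalize_by_max",
    "to_activity_index",
    "partition_day_night",
    "day_night_fractions",
]


@dataclass(frozen=True)
class BinnedSeries:
    """One individual x behaviour activity record on a fixed bin grid.

    ``counts`` are events per bin (floats are allowed so that noiseless
    synthetic rates can flow through the same pipeline).  ``lux`` and
    ``is_photophase`` carry the light schedule; ``is_photophase`` is the
    objective 12:12 day flag even under constant light.
    """

    individual_id: str
    behaviour: str
    treatment: str
    counts: np.ndarray
    bin_minutes: float = 10.0
    lux: np.ndarray | None = None
    is_photophase: np.ndarray | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        for name in ("lux", "is_photophase"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr)
                object.__setattr__(self, name, arr)
                if len(arr) != len(counts):
                    raise ValueError(f"{name} length does not match counts")

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def bins_per_day(self) -> int:
        return int(round(24 * 60 / self.bin_minutes))

    @property
    def n_days(self) -> int:
        return len(self.counts) // self.bins_per_day

    @property
    def t_hours(self) -> np.ndarray:
        """Bin-centre times in hours from the recording start."""
        return (np.arange(len(self.counts)) + 0.5) * self.bin_minutes / 60.0


@dataclass(frozen=True)
class ActivityIndexSeries:
    """Max-normalized activity on the same grid: values in [0, 1]."""

    individual_id: str
    behaviour: str
    treatment: str
    values: np.ndarray
    bin_minutes: float = 10.0
    lux: np.ndarray | None = None
    is_photophase: np.ndarray | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if np.any(values < 0) or np.any(values > 1 + 1e-12):
            raise ValueError("activity index must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def bins_per_day(self) -> int:
        return int(round(24 * 60 / self.bin_minutes))

    @property
    def n_days(self) -> int:
        return len(self.values) // self.bins_per_day

    @property
    def t_hours(self) -> np.ndarray:
        return (np.arange(len(self.values)) + 0.5) * self.bin_minutes / 60.0


def bin_events(
    event_times_minutes: Sequence[float],
    t0_minutes: float,
    duration_minutes: float,
    bin_minutes: float = 10.0,
) -> np.ndarray:
    """Count events per half-open bin ``[start, start + bin)``.

    A timestamp exactly on a boundary belongs to the later bin.  Every
    event must fall inside ``[t0, t0 + duration)``; the first offending
    timestamp is reported otherwise.
    """
    n_bins = duration_minutes / bin_minutes
    if not np.isclose(n_bins, round(n_bins)):
        raise ValueError("duration must be a whole number of bins")
    n_bins = int(round(n_bins))
    times = np.asarray(event_times_minutes, dtype=float)
    if times.size:
        bad = (times < t0_minutes) | (times >= t0_minutes + duration_minutes)
        if np.any(bad):
            raise ValueError(
                f"event at {times[bad][0]} min lies outside "
                f"[{t0_minutes}, {t0_minutes + duration_minutes})"
            )
    idx = np.floor((times - t0_minutes) / bin_minutes).astype(int)
    return np.bincount(idx, minlength=n_bins).astype(float)


@dataclass(frozen=True)
class InclusionResult:
    """Outcome of the minimum-days inclusion rule for one recording."""

    accepted: bool
    series: BinnedSeries | None
    reason: str
    used_days: tuple[int, int] | None  # [start, stop) day indices of the run
    excluded_days: frozenset


def _longest_run(n_days: int, excluded: set[int]) -> tuple[int, int]:
    """Longest run of consecutive non-excluded day indices, as [start, stop)."""
    best = (0, 0)
    start = None
    for d in range(n_days + 1):
        if d < n_days and d not in excluded:
            if start is None:
                start = d
        else:
            if start is not None and d - start > best[1] - best[0]:
                best = (start, d)
            start = None
    return best


def apply_inclusion_rules(
    series: BinnedSeries,
    min_days: int = 5,
    excluded_days: Iterable[int] = (),
) -> InclusionResult:
    """Keep a recording only if it has >= ``min_days`` consecutive clean days.

    ``excluded_days`` are 0-based day indices flagged upstream (system
    failure, no behaviour in the first days).  Exclusions are applied
    per behaviour; the longest run of unexcluded consecutive days is
    used, and the series is trimmed to that run.
    """
    excluded = set(excluded_days)
    n_days = series.n_days
    bad = {d for d in excluded if not 0 <= d < n_days}
    if bad:
        raise ValueError(f"excluded day indices out of range: {sorted(bad)}")
    start, stop = _longest_run(n_days, excluded)
    if stop - start < min_days:
        return InclusionResult(
            accepted=False,
            series=None,
            reason=f"longest_run_{stop - start}_days_lt_{min_days}",
            used_days=None,
            excluded_days=frozenset(excluded),
        )
    bpd = series.bins_per_day
    sl = slice(start * bpd, stop * bpd)
    trimmed = replace(
        series,
        counts=series.counts[sl],
        lux=None if series.lux is None else series.lux[sl],
        is_photophase=None
        if series.is_photophase is None
        else series.is_photophase[sl],
    )
    return InclusionResult(
        accepted=True,
        series=trimmed,
        reason="ok",
        used_days=(start, stop),
        excluded_days=frozenset(excluded),
    )


def _values_of(series) -> np.ndarray:
    if isinstance(series, BinnedSeries):
        return series.counts
    if isinstance(series, ActivityIndexSeries):
        return series.values
    return np.asarray(series, dtype=float)


def normalize_by_mean(series) -> np.ndarray:
    """Relative activity: each value divided by the individual's own mean."""
    x = _values_of(series)
    m = x.mean()
    if m <= 0:
        raise ValueError("no activity to normalize (mean is zero)")
    return x / m


def normalize_by_max(series) -> np.ndarray:
    """Activity index in [0, 1]: each value divided by the individual's maximum."""
    x = _values_of(series)
    m = x.max(initial=0.0)
    if m <= 0:
        raise ValueError("no activity to normalize (max is zero)")
    return x / m


def to_activity_index(series: BinnedSeries) -> ActivityIndexSeries:
    """Max-normalize a binned series, keeping grid and light metadata."""
    return ActivityIndexSeries(
        individual_id=series.individual_id,
        behaviour=series.behaviour,
        treatment=series.treatment,
        values=normalize_by_max(series),
        bin_minutes=series.bin_minutes,
        lux=series.lux,
        is_photophase=series.is_photophase,
    )


def _photophase_mask(series, regime: LightRegime | None) -> np.ndarray:
    """Objective day mask: for LL the 12:12 frame anchored at the start."""
    if series.is_photophase is not None and (regime is None or regime.name != "LL"):
        return np.asarray(series.is_photophase, dtype=bool)
    if regime is None:
        raise ValueError("series carries no light schedule and no regime was given")
    n = len(series)
    sched = make_light_schedule(
        LightRegime("LD"), days=-(-n // series.bins_per_day), bin_minutes=series.bin_minutes
    )
    return sched.is_photophase[:n]


def partition_day_night(series, regime: LightRegime | None = None):
    """Indices of photophase and scotophase bins (disjoint and exhaustive).

    Under constant light the partition uses the objective day and night
    periods — the 12:12 frame the animals were reared in, anchored at the
    recording start — so it coincides bin-for-bin with an LD recording
    that started at the same time.
    """
    mask = _photophase_mask(series, regime)
    idx = np.arange(len(series))
    return idx[mask], idx[~mask]


def day_night_fractions(
    series, regime: LightRegime | None = None
) -> tuple[float, float]:
    """Percent of total activity occurring in the (objective) day and night.

    Fractions are scale-invariant, so raw counts and either
    normalization give the same answer.
    """
    x = _values_of(series)
    total = x.sum()
    if total <= 0:
        raise ValueError("no activity: day/night fractions undefined")
    day_idx, night_idx = partition_day_night(series, regime)
    day = 100.0 * x[day_idx].sum() / total
    return day, 100.0 - day
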