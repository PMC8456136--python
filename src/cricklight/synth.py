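"""Synthetic cohorts of cricket activity under light-at-night regimes.

Generates per-individual, per-behaviour event-count series with the
statistical structure the downstream analysis assumes: entrainment to a
12:12 light cycle, free-running drift against it, arrhythmia, optional
light masking, and treatment-dependent phase dispersion.  Counts are
independent Poisson draws around a smooth rate template, so every stage
of the pipeline can be exercised — and its estimates checked against
ground truth — without any recorded data.

Conventions
-----------
Time is measured in hours from the start of the recording; bins are
half-open ``[start, start + bin)`` and rates are evaluated at bin
centres.  The daily cycle starts at lights-on: hours 0-12 of each cycle
are the photophase, 12-24 the scotophase.  A free-running individual's
template repeats every ``true_period_hours`` instead of 24 h, so its
activity onset drifts by ``true_period_hours - 24`` per day against the
light schedule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LightRegime",
    "IndividualConfig",
    "CohortConfig",
    "CohortMember",
    "Cohort",
    "REGIMES",
    "make_light_schedule",
    "rate_template",
    "simulate_individual",
    "simulate_cohort",
]

#: Lux level at and above which a bin counts as "lit" for masking purposes.
#: Dim 2/5-lux ALAN nights are below it; the 40-lux daylight is above.
MASKING_LUX_THRESHOLD = 10.0

BEHAVIOURS = ("stridulation", "locomotion")
RHYTHM_TYPES = ("synchronized", "free_run", "arrhythmic")


@dataclass(frozen=True)
class LightRegime:
    """A rearing/recording light schedule.

    ``name`` is one of LD (12 h 40-lux day : 12 h dark), LL2 / LL5
    (12 h day : 12 h dim 2- or 5-lux night), or LL (constant 40-lux
    light).  Even under LL the 12:12 frame is kept as the *objective*
    day/night partition, anchored at the recording start.
    """

    name: str
    day_lux: float = 40.0
    night_lux: float = 0.0
    photophase_hours: float = 12.0
    cycle_hours: float = 24.0

    def __post_init__(self) -> None:
        if self.name not in ("LD", "LL2", "LL5", "LL"):
            raise ValueError(f"unknown regime name {self.name!r}")
        if self.night_lux < 0 or self.day_lux < 0:
            raise ValueError("lux levels must be non-negative")
        if not 0 < self.photophase_hours < self.cycle_hours:
            raise ValueError("photophase must lie strictly inside the cycle")
        if self.name == "LL" and self.day_lux != self.night_lux:
            raise ValueError("LL is constant light: day_lux must equal night_lux")

    @property
    def scotophase_hours(self) -> float:
        return self.cycle_hours - self.photophase_hours


#: The four treatment groups: control and three ALAN intensities.
REGIMES: dict[str, LightRegime] = {
    "LD": LightRegime("LD", night_lux=0.0),
    "LL2": LightRegime("LL2", night_lux=2.0),
    "LL5": LightRegime("LL5", night_lux=5.0),
    "LL": LightRegime("LL", night_lux=40.0),
}


@dataclass(frozen=True)
class LightSchedule:
    """Per-bin light state: lux level and objective day/night flag."""

    lux: np.ndarray
    is_photophase: np.ndarray
    bin_minutes: float

    def __len__(self) -> int:
        return len(self.lux)


def make_light_schedule(
    regime: LightRegime, days: int, bin_minutes: float = 10.0
) -> LightSchedule:
    """Expand a regime into one light state per bin over ``days`` cycles.

    The objective photophase flag follows the 12:12 frame for every
    regime, including LL, whose lux is constant.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    if 60.0 % bin_minutes != 0:
        raise ValueError(f"bin width {bin_minutes} min must divide 60 min")
    photo_min = regime.photophase_hours * 60.0
    if photo_min % bin_minutes != 0:
        raise ValueError(
            f"bin width {bin_minutes} min must divide the "
            f"{regime.photophase_hours} h photophase"
        )
    bins_per_cycle = int(round(regime.cycle_hours * 60.0 / bin_minutes))
    photo_bins = int(round(photo_min / bin_minutes))
    one_day = np.arange(bins_per_cycle) < photo_bins
    is_photo = np.tile(one_day, days)
    lux = np.where(is_photo, regime.day_lux, regime.night_lux)
    return LightSchedule(lux=lux, is_photophase=is_photo, bin_minutes=bin_minutes)


# ---------------------------------------------------------------------------
# Rate templates


@dataclass(frozen=True)
class IndividualConfig:
    """Ground-truth parameters for one simulated individual.

    ``baseline_rate`` and ``amplitude`` are in expected events per bin.
    ``phase_hours`` shifts the whole template (the time of the profile's
    landmark peak on day one moves by the same amount).  ``masking_gain``
    multiplies the rate during lit bins (lux >= 10); 1.0 means no
    masking.  ``width_hours`` is the half-width of the raised-cosine
    activity bump; smaller widths concentrate activity more sharply in
    the subjective night (stridulation) or day (locomotion).
    """

    behaviour: str
    rhythm_type: str = "synchronized"
    true_period_hours: float | None = 24.0
    phase_hours: float = 0.0
    baseline_rate: float = 0.15
    amplitude: float = 6.0
    masking_gain: float = 1.0
    width_hours: float | None = None
    dusk_weight: float = 0.5
    dispersion_sd_hours: float = 0.0

    def __post_init__(self) -> None:
        if self.behaviour not in BEHAVIOURS:
            raise ValueError(f"unknown behaviour {self.behaviour!r}")
        if self.rhythm_type not in RHYTHM_TYPES:
            raise ValueError(f"unknown rhythm_type {self.rhythm_type!r}")
        if self.baseline_rate < 0 or self.amplitude < 0:
            raise ValueError("baseline_rate and amplitude must be >= 0")
        if self.masking_gain < 0 or self.dusk_weight < 0:
            raise ValueError("masking_gain and dusk_weight must be >= 0")
        if self.dispersion_sd_hours < 0:
            raise ValueError("dispersion_sd_hours must be >= 0")
        if self.rhythm_type != "arrhythmic":
            if self.true_period_hours is None or self.true_period_hours <= 0:
                raise ValueError("rhythmic individuals need a positive period")
        if self.width_hours is not None and self.width_hours <= 0:
            raise ValueError("width_hours must be positive")

    @property
    def effective_width_hours(self) -> float:
        if self.width_hours is not None:
            return self.width_hours
        return 5.0 if self.behaviour == "stridulation" else 6.0


def _raised_cosine(u: np.ndarray, centre: float, half_width: float) -> np.ndarray:
    """Smooth unit-height bump on the 24 h circle, zero outside +-half_width."""
    d = (u - centre + 12.0) % 24.0 - 12.0
    inside = np.abs(d) < half_width
    out = np.zeros_like(u, dtype=float)
    out[inside] = 0.5 * (1.0 + np.cos(np.pi * d[inside] / half_width))
    return out


def rate_template(
    behaviour: str, t_in_cycle: np.ndarray | float, config: IndividualConfig
) -> np.ndarray:
    """Expected events per bin at cycle time ``t_in_cycle`` (hours).

    The cycle time runs over ``[0, true_period)``; it is mapped
    proportionally onto a 24 h reference cycle whose first half is the
    subjective day.  Stridulation is a raised-cosine bump centred in the
    subjective night (centre 18 h); locomotion is a broad bump centred in
    the subjective day (centre 6 h) plus a narrower dusk peak just before
    lights-off, echoing the sunset surge that precedes the first songs of
    the night.  Arrhythmic configurations are flat at ``baseline_rate``.
    """
    t = np.asarray(t_in_cycle, dtype=float)
    if config.rhythm_type == "arrhythmic":
        return np.full_like(t, config.baseline_rate, dtype=float)
    period = float(config.true_period_hours)
    if np.any(t < 0) or np.any(t >= period):
        raise ValueError("t_in_cycle must lie in [0, true_period)")
    u = t * (24.0 / period)  # position on the reference 24 h cycle
    w = config.effective_width_hours
    if behaviour == "stridulation":
        bump = _raised_cosine(u, centre=18.0, half_width=w)
    elif behaviour == "locomotion":
        bump = _raised_cosine(u, centre=6.0, half_width=w)
        bump = bump + config.dusk_weight * _raised_cosine(u, centre=11.5, half_width=1.0)
    else:
        raise ValueError(f"unknown behaviour {behaviour!r}")
    return config.baseline_rate + config.amplitude * bump


def _expected_rates(
    config: IndividualConfig,
    schedule: LightSchedule,
) -> np.ndarray:
    """Per-bin expected counts, including free-run drift and masking."""
    n = len(schedule)
    bin_h = schedule.bin_minutes / 60.0
    t_centre = (np.arange(n) + 0.5) * bin_h
    if config.rhythm_type == "arrhythmic":
        lam = np.full(n, config.baseline_rate)
    else:
        period = float(config.true_period_hours)
        t_cycle = (t_centre - config.phase_hours) % period
        lam = rate_template(config.behaviour, t_cycle, config)
    if config.masking_gain != 1.0:
        lit = schedule.lux >= MASKING_LUX_THRESHOLD
        lam = np.where(lit, lam * config.masking_gain, lam)
    return lam


def simulate_individual(
    config: IndividualConfig,
    regime: LightRegime,
    days: int = 5,
    bin_minutes: float = 10.0,
    seed: int | np.random.SeedSequence | None = 0,
    noise: str = "poisson",
    individual_id: str = "ind0",
):
    """Simulate one individual's binned activity record.

    With ``noise="poisson"`` (default) counts are independent Poisson
    draws with the template mean; the same seed gives bit-identical
    output.  ``noise="none"`` returns the deterministic rate itself,
    which is useful for exact period-recovery checks.
    """
    from .preprocess import BinnedSeries  # local import to avoid a cycle

    if config.rhythm_type != "arrhythmic":
        period_min = config.true_period_hours * 60.0
        if not math.isclose(period_min / bin_minutes, round(period_min / bin_minutes)):
            raise ValueError(
                f"true_period_hours={config.true_period_hours} is not a "
                f"multiple of the {bin_minutes} min bin width"
            )
    schedule = make_light_schedule(regime, days, bin_minutes)
    lam = _expected_rates(config, schedule)
    if noise == "poisson":
        rng = np.random.default_rng(seed)
        counts = rng.poisson(lam).astype(float)
    elif noise == "none":
        counts = lam.copy()
    else:
        raise ValueError(f"unknown noise model {noise!r}")
    return BinnedSeries(
        individual_id=individual_id,
        behaviour=config.behaviour,
        treatment=regime.name,
        counts=counts,
        bin_minutes=bin_minutes,
        lux=schedule.lux,
        is_photophase=schedule.is_photophase,
    )


# ---------------------------------------------------------------------------
# Cohorts


@dataclass(frozen=True)
class CohortConfig:
    """One treatment group's generating conditions.

    ``mixture`` gives the proportions of synchronized / free-running /
    arrhythmic individuals; labels are drawn per individual.  Free-run
    periods are drawn from a normal distribution centred at
    ``freerun_period_hours`` with ``freerun_period_sd_hours`` spread,
    snapped to the bin grid and kept away from 24 h.  ``phase_sd_hours``
    is the between-individual phase jitter: the dispersion that grows
    with ALAN intensity and shrinks the cohort mean vector.
    """

    regime: LightRegime
    n_individuals: int = 15
    behaviour: str = "stridulation"
    mixture: dict[str, float] = field(
        default_factory=lambda: {"synchronized": 1.0}
    )
    days: int = 5
    bin_minutes: float = 10.0
    baseline_rate: float = 0.15
    amplitude: float = 6.0
    freerun_period_hours: float = 25.5
    freerun_period_sd_hours: float = 0.5
    phase_hours: float = 0.0
    phase_sd_hours: float = 0.0
    masking_gain: float = 1.0
    noise: str = "poisson"
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.noise not in ("poisson", "none"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.days < 5:
            raise ValueError("recordings must span at least 5 days")
        if self.behaviour not in BEHAVIOURS:
            raise ValueError(f"unknown behaviour {self.behaviour!r}")
        bad = set(self.mixture) - set(RHYTHM_TYPES)
        if bad:
            raise ValueError(f"unknown rhythm types in mixture: {sorted(bad)}")
        total = sum(self.mixture.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"mixture proportions sum to {total}, not 1")


@dataclass(frozen=True)
class CohortMember:
    """A simulated series together with its generating ground truth."""

    series: "object"
    rhythm_type: str
    true_period_hours: float | None
    phase_hours: float


@dataclass(frozen=True)
class Cohort:
    config: CohortConfig
    members: tuple[CohortMember, ...]

    def __len__(self) -> int:
        return len(self.members)

    @property
    def series(self) -> list:
        return [m.series for m in self.members]


#: Default rhythm-type mixtures per treatment, qualitative: control
#: cohorts are almost all entrained; constant light drives free-running
#: and arrhythmic behaviour; dim ALAN sits in between.
TREATMENT_MIXTURES: dict[str, dict[str, float]] = {
    "LD": {"synchronized": 0.95, "free_run": 0.05, "arrhythmic": 0.0},
    "LL2": {"synchronized": 0.35, "free_run": 0.55, "arrhythmic": 0.10},
    "LL5": {"synchronized": 0.30, "free_run": 0.55, "arrhythmic": 0.15},
    "LL": {"synchronized": 0.10, "free_run": 0.60, "arrhythmic": 0.30},
}

#: Default between-individual phase jitter (hours) per treatment,
#: chosen so cohort mean-vector lengths fall off with ALAN intensity
#: the way the concentration of acrophases does in disrupted groups.
TREATMENT_PHASE_SD: dict[str, float] = {"LD": 1.0, "LL2": 2.5, "LL5": 2.5, "LL": 4.0}


def _snap_period(period_h: float, bin_minutes: float) -> float:
    """Snap a period to the bin grid, keeping it inside 20-28 h and off 24 h."""
    step = bin_minutes / 60.0
    p = round(period_h / step) * step
    p = min(max(p, 20.0 + 2 * step), 28.0 - 2 * step)
    if abs(p - 24.0) <= step:  # a free-runner must be distinguishable from 24 h
        p = 24.0 + 2 * step if period_h >= 24.0 else 24.0 - 2 * step
    return p


def simulate_cohort(cohort: CohortConfig) -> Cohort:
    """Simulate a full treatment group with ground-truth labels attached.

    Per-individual random streams are spawned from ``master_seed`` via
    ``numpy.random.SeedSequence``, so the whole cohort is reproducible
    while individuals stay statistically independent.
    """
    root = np.random.SeedSequence(cohort.master_seed)
    label_rng = np.random.default_rng(root.spawn(1)[0])
    types = list(cohort.mixture.keys())
    probs = np.array([cohort.mixture[t] for t in types], dtype=float)
    labels = label_rng.choice(types, size=cohort.n_individuals, p=probs)

    members: list[CohortMember] = []
    child_seeds = root.spawn(cohort.n_individuals + 1)[1:]
    for i, (label, child) in enumerate(zip(labels, child_seeds)):
        param_rng = np.random.default_rng(child.spawn(1)[0])
        phase = cohort.phase_hours
        if cohort.phase_sd_hours > 0:
            phase = phase + param_rng.normal(0.0, cohort.phase_sd_hours)
        if label == "free_run":
            raw = param_rng.normal(
                cohort.freerun_period_hours, cohort.freerun_period_sd_hours
            )
            period = _snap_period(raw, cohort.bin_minutes)
        elif label == "synchronized":
            period = 24.0
        else:
            period = None
        cfg = IndividualConfig(
            behaviour=cohort.behaviour,
            rhythm_type=str(label),
            true_period_hours=period,
            phase_hours=phase % 24.0 if period is not None else 0.0,
            baseline_rate=cohort.baseline_rate,
            amplitude=cohort.amplitude,
            masking_gain=cohort.masking_gain,
        )
        series = simulate_individual(
            cfg,
            cohort.regime,
            days=cohort.days,
            bin_minutes=cohort.bin_minutes,
            seed=child,
            noise=cohort.noise,
            individual_id=f"{cohort.regime.name}_{cohort.behaviour}_{i:03d}",
        )
        members.append(
            CohortMember(
                series=series,
                rhythm_type=str(label),
                true_period_hours=period,
                phase_hours=cfg.phase_hours,
            )
        )
    return Cohort(config=cohort, members=tuple(members))


def treatment_preset(
    name: str,
    behaviour: str = "stridulation",
    n_individuals: int = 20,
    days: int = 5,
    master_seed: int = 0,
    **overrides,
) -> CohortConfig:
    """A ready-made CohortConfig for one of the four treatment groups."""
    base = dict(
        regime=REGIMES[name],
        behaviour=behaviour,
        n_individuals=n_individuals,
        days=days,
        mixture=dict(TREATMENT_MIXTURES[name]),
        phase_sd_hours=TREATMENT_PHASE_SD[name],
        master_seed=master_seed,
    )
    base.update(overrides)
    return CohortConfig(**base)
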