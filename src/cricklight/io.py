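"""CSV / JSON / YAML interchange for cohorts and results.

Two input schemas are accepted: an event-level CSV
``(individual_id, behaviour, treatment, timestamp_minutes)`` and a
pre-binned tidy CSV ``(individual_id, behaviour, treatment, bin_index,
count, lux, is_photophase)`` as written by :func:`write_cohort_csv`.
Ground truth for synthetic cohorts travels in a sidecar JSON keyed by
individual id.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .preprocess import BinnedSeries, bin_events
from .synth import REGIMES, Cohort, CohortConfig

__all__ = [
    "write_cohort_csv",
    "write_truth_json",
    "read_binned_csv",
    "read_events_csv",
    "cohort_config_from_yaml",
]

BINNED_COLUMNS = [
    "individual_id",
    "behaviour",
    "treatment",
    "bin_index",
    "count",
    "lux",
    "is_photophase",
]


def write_cohort_csv(cohort: Cohort, path) -> None:
    """Write a cohort as tidy per-bin rows."""
    frames = []
    for m in cohort.members:
        s = m.series
        frames.append(
            pd.DataFrame(
                {
                    "individual_id": s.individual_id,
                    "behaviour": s.behaviour,
                    "treatment": s.treatment,
                    "bin_index": np.arange(len(s)),
                    "count": s.counts,
                    "lux": s.lux,
                    "is_photophase": s.is_photophase.astype(int),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_truth_json(cohort: Cohort, path) -> None:
    """Sidecar ground truth: rhythm type, period and phase per individual."""
    truth = {
        m.series.individual_id: {
            "rhythm_type": m.rhythm_type,
            "true_period_hours": m.true_period_hours,
            "phase_hours": m.phase_hours,
        }
        for m in cohort.members
    }
    Path(path).write_text(json.dumps(truth, indent=1))


def read_binned_csv(path, bin_minutes: float = 10.0) -> list[BinnedSeries]:
    """Read a tidy pre-binned CSV back into BinnedSeries objects."""
    df = pd.read_csv(path)
    missing = set(BINNED_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise ValueError(f"binned CSV is missing columns: {sorted(missing)}")
    out = []
    for (ind, behav, treat), g in df.groupby(
        ["individual_id", "behaviour", "treatment"], sort=True
    ):
        g = g.sort_values("bin_index")
        idx = g["bin_index"].to_numpy()
        if not np.array_equal(idx, np.arange(len(idx))):
            raise ValueError(f"non-contiguous bin grid for {ind}/{behav}")
        out.append(
            BinnedSeries(
                individual_id=str(ind),
                behaviour=str(behav),
                treatment=str(treat),
                counts=g["count"].to_numpy(float),
                bin_minutes=bin_minutes,
                lux=g["lux"].to_numpy(float) if "lux" in g else None,
                is_photophase=g["is_photophase"].to_numpy(bool)
                if "is_photophase" in g
                else None,
            )
        )
    return out


def read_events_csv(
    path, duration_minutes: float, bin_minutes: float = 10.0
) -> list[BinnedSeries]:
    """Bin an event-level CSV (timestamp_minutes from recording start)."""
    df = pd.read_csv(path)
    needed = {"individual_id", "behaviour", "treatment", "timestamp_minutes"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"event CSV is missing columns: {sorted(missing)}")
    out = []
    for (ind, behav, treat), g in df.groupby(
        ["individual_id", "behaviour", "treatment"], sort=True
    ):
        counts = bin_events(
            g["timestamp_minutes"].to_numpy(float), 0.0, duration_minutes, bin_minutes
        )
        out.append(
            BinnedSeries(
                individual_id=str(ind),
                behaviour=str(behav),
                treatment=str(treat),
                counts=counts,
                bin_minutes=bin_minutes,
            )
        )
    return out


def cohort_config_from_yaml(path, master_seed: int | None = None) -> CohortConfig:
    """Build a CohortConfig from a YAML/JSON mapping.

    The ``regime`` key names one of LD / LL2 / LL5 / LL; every other key
    mirrors a CohortConfig field.  ``master_seed`` given here overrides
    the file's value (the CLI passes --seed through this hook).
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or "regime" not in raw:
        raise ValueError("cohort config must be a mapping with a 'regime' key")
    raw = dict(raw)
    regime = raw.pop("regime")
    if isinstance(regime, str):
        regime = REGIMES[regime]
    if master_seed is not None:
        raw["master_seed"] = master_seed
    return CohortConfig(regime=regime, **raw)
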