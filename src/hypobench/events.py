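"""Hypotensive-event detection, non-event segments, and burden statistics.

A hypotensive event is MAP at or below 65 mmHg sustained for at least one
minute — at the 20-second sampling grid, a maximal run of >= 3 consecutive
below-threshold samples.  Negative material for ROC analysis comes from
30-minute non-event segments at least 20 minutes away from every event with
MAP above 75 mmHg throughout.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import (
    HYPOTENSION_THRESHOLD_MMHG,
    NONEVENT_MAP_FLOOR_MMHG,
    MonitoringRecord,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Minimum sustained duration for an event (seconds).
MIN_EVENT_DURATION_S = 60

#: Non-event segment length (seconds) and exclusion buffer around events.
NONEVENT_SEGMENT_S = 30 * 60
EVENT_EXCLUSION_S = 20 * 60


@dataclass(frozen=True)
class HypotensiveEvent:
    """A maximal sustained run of MAP <= 65 mmHg lasting >= 1 min.

    ``start_s`` is the time of the first below-threshold sample; ``end_s``
    extends one sampling interval past the last, so ``end_s - start_s``
    equals the covered duration.
    """

    patient_id: str
    start_s: int
    end_s: int
    duration_min: float
    mean_map_mmhg: float


@dataclass(frozen=True)
class NonEventSegment:
    """A 30-min window with MAP > 75 throughout, >= 20 min from any event."""

    patient_id: str
    start_s: int
    end_s: int


def _runs(mask: np.ndarray, breaks: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [i, j] index runs where ``mask`` holds and no break intervenes.

    ``breaks[k]`` True means the grid step between samples k and k+1 is a
    gap that runs may not bridge.
    """
    out = []
    n = len(mask)
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1] and not breaks[j]:
                j += 1
            out.append((i, j))
            i = j + 1
        else:
            i += 1
    return out


def detect_events(
    record: MonitoringRecord,
    threshold: float = HYPOTENSION_THRESHOLD_MMHG,
) -> list[HypotensiveEvent]:
    """Detect hypotensive events in one monitoring record.

    Maximal runs of consecutive samples with MAP <= ``threshold`` that span
    at least one minute (>= 3 samples at 20-s sampling).  A single sample
    above threshold terminates a run, and runs never bridge grid gaps
    larger than 1.5 nominal intervals.
    """
    dt = record.sample_interval_s
    min_samples = max(1, math.ceil(MIN_EVENT_DURATION_S / dt))
    mask = record.map_mmhg <= threshold
    breaks = record.gap_mask()
    if np.any(breaks):
        logger.info(
            "%s: %d grid gap(s) > 1.5 intervals; events do not bridge them",
            record.patient_id,
            int(breaks.sum()),
        )
    events = []
    for i, j in _runs(mask, breaks):
        if j - i + 1 < min_samples:
            continue
        events.append(
            HypotensiveEvent(
                patient_id=record.patient_id,
                start_s=int(record.times_s[i]),
                end_s=int(record.times_s[j] + dt),
                duration_min=(j - i + 1) * dt / 60.0,
                mean_map_mmhg=float(record.map_mmhg[i : j + 1].mean()),
            )
        )
    return events


def in_event_mask(record: MonitoringRecord, events: list[HypotensiveEvent]) -> np.ndarray:
    """Boolean mask over samples lying inside any detected event."""
    mask = np.zeros(record.n_samples, dtype=bool)
    for ev in events:
        mask |= (record.times_s >= ev.start_s) & (record.times_s < ev.end_s)
    return mask


def find_nonevent_segments(
    record: MonitoringRecord,
    events: list[HypotensiveEvent],
    segment_s: int = NONEVENT_SEGMENT_S,
    exclusion_s: int = EVENT_EXCLUSION_S,
    map_floor: float = NONEVENT_MAP_FLOOR_MMHG,
) -> list[NonEventSegment]:
    """Tile non-overlapping 30-min segments through qualifying regions.

    A sample qualifies when its covered interval is at least ``exclusion_s``
    from every event and its MAP exceeds ``map_floor``.  Within each maximal
    qualifying region, segments are placed greedily left to right.
    """
    dt = record.sample_interval_s
    t = record.times_s
    ok = record.map_mmhg > map_floor
    for ev in events:
        # sample interval [t, t+dt) must keep a >= exclusion_s buffer
        near = (t + dt > ev.start_s - exclusion_s) & (t < ev.end_s + exclusion_s)
        ok &= ~near
    breaks = record.gap_mask()
    seg_samples = int(round(segment_s / dt))
    segments = []
    for i, j in _runs(ok, breaks):
        k = i
        while k + seg_samples - 1 <= j:
            segments.append(
                NonEventSegment(
                    patient_id=record.patient_id,
                    start_s=int(t[k]),
                    end_s=int(t[k] + segment_s),
                )
            )
            k += seg_samples
    return segments


# ---------------------------------------------------------------------------
# Burden statistics
# ---------------------------------------------------------------------------

BURDEN_METRICS = [
    "monitoring_time_min",
    "n_events",
    "avg_event_duration_min",
    "total_event_duration_min",
    "total_event_duration_pct",
    "mean_map_under65_mmhg",
    "area_under65_mmhg_min",
    "twa_under65_mmhg",
]


def burden_summary(
    records: list[MonitoringRecord],
    events_by_patient: dict[str, list[HypotensiveEvent]],
    threshold: float = HYPOTENSION_THRESHOLD_MMHG,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-patient hypotension burden plus cohort median [25th, 75th] rows.

    Area under the threshold is rectangle-rule: sum of
    ``max(0, 65 - MAP) * dt`` over samples, dt in minutes; the
    time-weighted average (TWA) divides by total monitoring time.  The mean
    MAP during hypotension averages samples with MAP strictly below the
    threshold and is NaN for patients never hypotensive.

    Returns
    -------
    (per_patient, cohort) :
        ``per_patient`` has one row per patient and the columns in
        ``BURDEN_METRICS``; ``cohort`` has median/q25/q75 per metric.
    """
    rows = []
    for rec in records:
        span_min = rec.monitoring_time_min
        if span_min <= 0:
            raise ValidationError(f"{rec.patient_id}: zero monitoring time")
        evs = events_by_patient.get(rec.patient_id, [])
        total_min = sum(ev.duration_min for ev in evs)
        dt_min = rec.sample_interval_s / 60.0
        depth = np.maximum(0.0, threshold - rec.map_mmhg)
        area = float(depth.sum() * dt_min)
        under = rec.map_mmhg < threshold
        rows.append(
            {
                "patient_id": rec.patient_id,
                "arm": rec.arm,
                "monitoring_time_min": span_min,
                "n_events": len(evs),
                "avg_event_duration_min": total_min / len(evs) if evs else 0.0,
                "total_event_duration_min": total_min,
                "total_event_duration_pct": 100.0 * total_min / span_min,
                "mean_map_under65_mmhg": (
                    float(rec.map_mmhg[under].mean()) if under.any() else float("nan")
                ),
                "area_under65_mmhg_min": area,
                "twa_under65_mmhg": area / span_min,
            }
        )
    per_patient = pd.DataFrame(rows)
    cohort = pd.DataFrame(
        {
            "metric": BURDEN_METRICS,
            "median": [per_patient[m].median() for m in BURDEN_METRICS],
            "q25": [per_patient[m].quantile(0.25) for m in BURDEN_METRICS],
            "q75": [per_patient[m].quantile(0.75) for m in BURDEN_METRICS],
        }
    )
    return per_patient, cohort
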