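"""Labeled sample construction for ROC analysis.

Positive samples are index readings exactly t minutes (t = 5, 10 or 15)
before each hypotensive event onset; negative samples are one reading per
30-minute non-event segment.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .events import HypotensiveEvent, NonEventSegment, in_event_mask
from .records import MonitoringRecord

logger = logging.getLogger(__name__)

PREDICTION_HORIZONS_MIN = (5, 10, 15)


@dataclass(frozen=True)
class LabeledSample:
    """One (time, index value, label) pair at a fixed prediction horizon."""

    patient_id: str
    time_s: int
    index_value: float
    label: str  # "positive" | "negative"
    horizon_min: int | None
    source_start_s: int  # onset of the source event / start of the segment


def _nearest_grid_idx(times: np.ndarray, target: float) -> int:
    """Index of the grid sample nearest to ``target``; ties snap earlier."""
    pos = int(np.searchsorted(times, target))
    if pos == 0:
        return 0
    if pos >= len(times):
        return len(times) - 1
    before, after = times[pos - 1], times[pos]
    return pos - 1 if target - before <= after - target else pos


def extract_positive_samples(
    record: MonitoringRecord,
    events: list[HypotensiveEvent],
    horizon_min: int,
) -> list[LabeledSample]:
    """One positive sample per event, at event onset minus the horizon.

    The anchor snaps to the nearest grid sample (ties earlier).  An event
    contributes no sample when the anchor precedes the recording, falls
    inside another hypotensive event, or the index is missing there;
    exclusions are logged.
    """
    if horizon_min not in PREDICTION_HORIZONS_MIN:
        raise ValueError(f"horizon_min must be one of {PREDICTION_HORIZONS_MIN}")
    inside = in_event_mask(record, events)
    out = []
    for ev in events:
        target = ev.start_s - horizon_min * 60
        if target < record.times_s[0]:
            logger.info(
                "%s: event at %ds has no %d-min history; positive sample skipped",
                record.patient_id, ev.start_s, horizon_min,
            )
            continue
        i = _nearest_grid_idx(record.times_s, target)
        if inside[i]:
            logger.info(
                "%s: %d-min anchor of event at %ds lies inside another event; skipped",
                record.patient_id, horizon_min, ev.start_s,
            )
            continue
        if np.isnan(record.index_value[i]):
            logger.info(
                "%s: index missing at %ds; positive sample skipped",
                record.patient_id, int(record.times_s[i]),
            )
            continue
        out.append(
            LabeledSample(
                patient_id=record.patient_id,
                time_s=int(record.times_s[i]),
                index_value=float(record.index_value[i]),
                label="positive",
                horizon_min=horizon_min,
                source_start_s=ev.start_s,
            )
        )
    return out


def extract_negative_samples(
    record: MonitoringRecord,
    segments: list[NonEventSegment],
    placement: str = "midpoint",
    rng: np.random.Generator | None = None,
) -> list[LabeledSample]:
    """Exactly one negative sample per non-event segment.

    The default reads the index at the segment's midpoint grid sample; if
    missing there, the nearest in-segment sample with an index present is
    used.  ``placement="random"`` draws a uniform in-segment sample instead
    (seeded via ``rng``) for sensitivity analysis.
    """
    if placement not in ("midpoint", "random"):
        raise ValueError("placement must be 'midpoint' or 'random'")
    out = []
    for seg in segments:
        sel = (record.times_s >= seg.start_s) & (record.times_s < seg.end_s)
        idxs = np.flatnonzero(sel)
        with_index = idxs[~np.isnan(record.index_value[idxs])]
        if len(with_index) == 0:
            logger.info(
                "%s: segment at %ds has no index values; skipped",
                record.patient_id, seg.start_s,
            )
            continue
        if placement == "random":
            if rng is None:
                raise ValueError("random placement requires an rng")
            i = int(rng.choice(with_index))
        else:
            target = (seg.start_s + seg.end_s) / 2.0
            i = with_index[int(np.argmin(np.abs(record.times_s[with_index] - target)))]
        out.append(
            LabeledSample(
                patient_id=record.patient_id,
                time_s=int(record.times_s[i]),
                index_value=float(record.index_value[i]),
                label="negative",
                horizon_min=None,
                source_start_s=seg.start_s,
            )
        )
    return out
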