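"""Positive predictive value at the alarm threshold, intervention-aware.

A sample alarms when the index exceeds 85.  Alarms not followed by a
hypotensive event within 15 minutes are not necessarily wrong: a clinician
may have treated the impending hypotension.  Rapid MAP rises (> 5 mmHg in
20 s or > 8 mmHg in 2 min from a baseline below 75 mmHg) are taken as
proxies for treatment; a rise backed by a charted intervention (incision
or a vasopressor bolus within the preceding 5 min) converts the alarm to a
true positive, while an unexplained rise removes the alarm from the
analysis altogether.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .events import HypotensiveEvent, in_event_mask
from .records import Intervention, MonitoringRecord
from .roc import BootstrapResult, bootstrap_ci

RISE_20S_DELTA_MMHG = 5.0
RISE_2MIN_DELTA_MMHG = 8.0
RISE_BASELINE_MAX_MMHG = 75.0
SUPPORT_LOOKBACK_S = 5 * 60


@dataclass(frozen=True)
class RapidRise:
    """An abrupt MAP increase from a low baseline, one per baseline sample."""

    patient_id: str
    time_s: int  # time of the baseline sample the rise starts from
    rule: str  # "rise_20s" | "rise_2min"
    baseline_map_mmhg: float
    delta_mmhg: float
    supported: bool = False


@dataclass
class PpvResult:
    threshold: float
    n_true_positive: int
    n_false_positive: int
    n_excluded: int
    ppv: float
    ppv_ci_95: tuple[float, float]
    n_alarm_samples: int


def detect_rapid_rises(record: MonitoringRecord) -> list[RapidRise]:
    """Flag rapid MAP rises from each baseline sample with MAP < 75 mmHg.

    From a baseline sample, the 20-s rule fires when the very next sample
    exceeds the baseline by more than 5 mmHg; the 2-min rule fires when any
    sample within the following 2 minutes exceeds it by more than 8 mmHg.
    One rise per triggering baseline sample; the 20-s rule takes precedence
    when both fire.
    """
    t = record.times_s
    m = record.map_mmhg
    n = record.n_samples
    out = []
    for i in range(n - 1):
        base = m[i]
        if base >= RISE_BASELINE_MAX_MMHG:
            continue
        # 20-s rule: one grid step ahead
        if t[i + 1] - t[i] <= record.sample_interval_s and m[i + 1] - base > RISE_20S_DELTA_MMHG:
            out.append(
                RapidRise(
                    patient_id=record.patient_id,
                    time_s=int(t[i]),
                    rule="rise_20s",
                    baseline_map_mmhg=float(base),
                    delta_mmhg=float(m[i + 1] - base),
                )
            )
            continue
        # 2-min rule: any sample within the next 120 s
        j = i + 1
        best = 0.0
        while j < n and t[j] - t[i] <= 120:
            best = max(best, m[j] - base)
            j += 1
        if best > RISE_2MIN_DELTA_MMHG:
            out.append(
                RapidRise(
                    patient_id=record.patient_id,
                    time_s=int(t[i]),
                    rule="rise_2min",
                    baseline_map_mmhg=float(base),
                    delta_mmhg=float(best),
                )
            )
    return out


def annotate_support(
    rises: list[RapidRise],
    interventions: list[Intervention],
    lookback_s: int = SUPPORT_LOOKBACK_S,
) -> list[RapidRise]:
    """Mark rises preceded (within 5 min) by a charted intervention."""
    by_pid: dict[str, list[int]] = {}
    for iv in interventions:
        by_pid.setdefault(iv.patient_id, []).append(iv.time_s)
    for ts in by_pid.values():
        ts.sort()
    out = []
    for r in rises:
        ts = np.asarray(by_pid.get(r.patient_id, []))
        supported = bool(
            len(ts) and np.any((ts >= r.time_s - lookback_s) & (ts <= r.time_s))
        )
        out.append(replace(r, supported=supported))
    return out


def _classify_patient(
    record: MonitoringRecord,
    events: list[HypotensiveEvent],
    rises: list[RapidRise],
    threshold: float,
    window_min: float,
    strict: bool,
    include_in_event_samples: bool,
    require_full_window: bool,
) -> tuple[int, int, int]:
    """(true positives, false positives, excluded) alarm samples."""
    dt = record.sample_interval_s
    t = record.times_s
    idx = record.index_value
    alarm = (idx > threshold) if strict else (idx >= threshold)
    alarm &= ~np.isnan(idx)
    if not include_in_event_samples:
        alarm &= ~in_event_mask(record, events)
    if require_full_window:
        alarm &= t <= t[-1] - window_min * 60 - 2 * dt
    onsets = np.array(sorted(ev.start_s for ev in events), dtype=float)
    rise_times = np.array(sorted(r.time_s for r in rises), dtype=float)
    rise_supported = {r.time_s: r.supported for r in rises}
    # if several rises share a time the supported one wins
    for r in rises:
        if r.supported:
            rise_supported[r.time_s] = True

    tp = fp = excl = 0
    for ti in t[alarm]:
        w_end = ti + window_min * 60
        pos = np.searchsorted(onsets, ti, side="left" if include_in_event_samples else "right")
        if pos < len(onsets) and onsets[pos] <= w_end:
            tp += 1
            continue
        lo = np.searchsorted(rise_times, ti, side="left")
        hi = np.searchsorted(rise_times, w_end, side="right")
        window_rises = rise_times[lo:hi]
        if len(window_rises):
            if any(rise_supported[int(rt)] for rt in window_rises):
                tp += 1
            else:
                excl += 1
        else:
            fp += 1
    return tp, fp, excl


def ppv_at_threshold(
    records: list[MonitoringRecord],
    events_by_patient: dict[str, list[HypotensiveEvent]],
    rises_by_patient: dict[str, list[RapidRise]],
    threshold: float = 85.0,
    window_min: float = 15.0,
    strict: bool = True,
    mitigate: bool = True,
    include_in_event_samples: bool = False,
    require_full_window: bool = True,
    n_boot: int = 2000,
    seed: int = 0,
) -> PpvResult:
    """PPV over alarm samples, with rapid-rise mitigation of false positives.

    Each sample with index above ``threshold`` (strictly, by default) is a
    true positive when an event starts within the forward window.
    Otherwise, if a rapid rise occurs inside the window: a supported rise
    reclassifies the alarm as a true positive, an unsupported rise removes
    it from numerator and denominator.  Remaining alarms are false
    positives.  ``mitigate=False`` computes the naive PPV (no
    reclassification, no exclusion).  The CI is a patient-level bootstrap.
    """
    payloads = {}
    counts = {}
    for rec in records:
        rises = rises_by_patient.get(rec.patient_id, []) if mitigate else []
        tp, fp, excl = _classify_patient(
            rec,
            events_by_patient.get(rec.patient_id, []),
            rises,
            threshold,
            window_min,
            strict,
            include_in_event_samples,
            require_full_window,
        )
        counts[rec.patient_id] = (tp, fp, excl)
        payloads[rec.patient_id] = (tp, fp)

    tp = sum(c[0] for c in counts.values())
    fp = sum(c[1] for c in counts.values())
    excl = sum(c[2] for c in counts.values())
    if tp + fp + excl == 0:
        raise ValueError(f"no samples above threshold {threshold}")

    def stat(pairs):
        t_ = sum(p[0] for p in pairs)
        f_ = sum(p[1] for p in pairs)
        if t_ + f_ == 0:
            raise ZeroDivisionError("replicate without classified alarms")
        return t_ / (t_ + f_)

    if tp + fp == 0:
        # every alarm excluded: PPV undefined, nothing to bootstrap
        return PpvResult(
            threshold=threshold,
            n_true_positive=0,
            n_false_positive=0,
            n_excluded=excl,
            ppv=float("nan"),
            ppv_ci_95=(float("nan"), float("nan")),
            n_alarm_samples=excl,
        )
    boot: BootstrapResult = bootstrap_ci(payloads, stat, n_boot=n_boot, seed=seed)
    return PpvResult(
        threshold=threshold,
        n_true_positive=tp,
        n_false_positive=fp,
        n_excluded=excl,
        ppv=tp / (tp + fp) if tp + fp else float("nan"),
        ppv_ci_95=(boot.lo, boot.hi),
        n_alarm_samples=tp + fp + excl,
    )


def evaluate_ppv(
    records: list[MonitoringRecord],
    events_by_patient: dict[str, list[HypotensiveEvent]],
    interventions: list[Intervention],
    mitigate: bool = True,
    **kwargs,
) -> PpvResult:
    """Detect rises, annotate support from the intervention log, compute PPV.

    Mitigation exists because real charts under-record the interventions
    behind abrupt MAP rises; unexplained rises are therefore removed rather
    than called false alarms.  When the supplied intervention log is empty
    the log is taken as complete-and-empty — every rise is known to be
    spontaneous, nothing is "potentially consequent to an intervention",
    and mitigation reduces exactly to the naive PPV.
    """
    if mitigate and interventions:
        rises_by_patient: dict[str, list[RapidRise]] = {}
        for rec in records:
            rises = annotate_support(detect_rapid_rises(rec), interventions)
            rises_by_patient[rec.patient_id] = rises
        return ppv_at_threshold(
            records, events_by_patient, rises_by_patient, mitigate=True, **kwargs
        )
    return ppv_at_threshold(records, events_by_patient, {}, mitigate=False, **kwargs)
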