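"""Forward-window event-rate analysis by risk-index bin.

For every eligible index sample, a 15-minute forward search window asks
whether a hypotensive event starts within it; the fraction of event
samples per index decade (0-9, 10-19, ..., 90-99, and exactly 100) is the
observed event rate for that bin, and the gap between sample time and
event onset gives the warning-time distribution.  With a perfectly
calibrated index the per-bin rates fall on the identity line against the
bin's mean predicted probability.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .events import HypotensiveEvent, in_event_mask
from .records import MonitoringRecord

#: Bin lower edges; the last bin holds index == 100 exactly.
BIN_EDGES = [(lo, lo + 10) for lo in range(0, 100, 10)] + [(100, 100)]
N_BINS = len(BIN_EDGES)


@dataclass
class EventRateBin:
    """One row of the event-rate table (one index decade)."""

    bin_lo: float
    bin_hi: float
    n_event_samples: int
    n_total_samples: int
    event_rate_pct: float
    event_rate_ci_95: tuple[float, float]
    median_time_to_event_min: float
    median_ci_95: tuple[float, float]
    q25_time_to_event_min: float
    q25_ci_95: tuple[float, float]
    q75_time_to_event_min: float
    q75_ci_95: tuple[float, float]
    empty: bool = False

    @property
    def label(self) -> str:
        if self.bin_lo == 100:
            return "100"
        return f"{int(self.bin_lo)}-{int(self.bin_hi) - 1}"


def assign_bins(index_values: np.ndarray) -> np.ndarray:
    """Map index values in [0, 100] to bin numbers 0..10 (10 = exactly 100)."""
    b = np.minimum(np.floor(index_values / 10.0).astype(int), 9)
    return np.where(index_values >= 100.0, 10, b)


@dataclass
class _PatientBinData:
    """Per-patient per-bin tallies backing the cluster bootstrap."""

    n_event: np.ndarray  # (N_BINS,)
    n_total: np.ndarray  # (N_BINS,)
    tte_min: list[np.ndarray] = field(default_factory=list)  # per-bin arrays


def _forward_search(
    record: MonitoringRecord,
    events: list[HypotensiveEvent],
    window_min: float,
    include_in_event: bool,
    require_full_window: bool,
) -> _PatientBinData:
    dt = record.sample_interval_s
    t = record.times_s
    eligible = ~np.isnan(record.index_value)
    if not include_in_event:
        eligible &= ~in_event_mask(record, events)
    if require_full_window:
        # a run starting at the window's last sample still needs its first
        # three samples observed to be detectable as an event
        eligible &= t <= t[-1] - window_min * 60 - 2 * dt
    onsets = np.array(sorted(ev.start_s for ev in events), dtype=float)

    idx = record.index_value[eligible]
    te = t[eligible].astype(float)
    if len(onsets):
        side = "left" if include_in_event else "right"
        pos = np.searchsorted(onsets, te, side=side)
        has_next = pos < len(onsets)
        next_onset = np.where(has_next, onsets[np.minimum(pos, len(onsets) - 1)], np.inf)
    else:
        next_onset = np.full(len(te), np.inf)
    is_event = next_onset <= te + window_min * 60
    tte = (next_onset - te) / 60.0

    bins = assign_bins(idx)
    n_event = np.zeros(N_BINS, dtype=np.int64)
    n_total = np.zeros(N_BINS, dtype=np.int64)
    np.add.at(n_total, bins, 1)
    np.add.at(n_event, bins[is_event], 1)
    tte_by_bin = [np.sort(tte[is_event & (bins == b)]) for b in range(N_BINS)]
    return _PatientBinData(n_event=n_event, n_total=n_total, tte_min=tte_by_bin)


def _weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    """Inverted-CDF quantile of ``values`` (sorted) under integer ``weights``."""
    cum = np.cumsum(weights)
    total = cum[-1]
    if total <= 0:
        return float("nan")
    k = np.searchsorted(cum, q * total, side="left")
    return float(values[min(k, len(values) - 1)])


def _quantile(values: np.ndarray, q: float) -> float:
    if len(values) == 0:
        return float("nan")
    return _weighted_quantile(values, np.ones(len(values)), q)


def event_rate_by_bin(
    records: list[MonitoringRecord],
    events_by_patient: dict[str, list[HypotensiveEvent]],
    window_min: float = 15.0,
    n_boot: int = 2000,
    seed: int = 0,
    include_in_event_samples: bool = False,
    require_full_window: bool = True,
) -> list[EventRateBin]:
    """Observed hypotension rate and warning-time quantiles per index bin.

    Samples inside ongoing events are excluded from denominators by default
    (the forward search is a prediction, not a detection); pass
    ``include_in_event_samples=True`` for the alternative convention, under
    which an in-event sample counts as an event sample with zero time to
    event.  Samples whose forward window is cut short by the end of the
    recording are excluded whenever ``require_full_window`` is set.
    Confidence intervals come from the patient-level bootstrap; empty bins
    are reported with ``n_total = 0`` and NaN rates, never dropped.
    """
    per_patient = [
        _forward_search(
            rec,
            events_by_patient.get(rec.patient_id, []),
            window_min,
            include_in_event_samples,
            require_full_window,
        )
        for rec in records
    ]
    n_pat = len(per_patient)
    ev_counts = np.stack([p.n_event for p in per_patient])  # (n_pat, N_BINS)
    tot_counts = np.stack([p.n_total for p in per_patient])

    rng = np.random.default_rng(seed)
    # Multinomial patient weights are equivalent to resampling patients
    # with replacement and let every replicate reduce to weighted sums.
    W = rng.multinomial(n_pat, np.full(n_pat, 1.0 / n_pat), size=n_boot)
    ev_rep = W @ ev_counts  # (n_boot, N_BINS)
    tot_rep = W @ tot_counts
    with np.errstate(invalid="ignore", divide="ignore"):
        rate_rep = 100.0 * ev_rep / tot_rep

    out: list[EventRateBin] = []
    for b in range(N_BINS):
        lo, hi = BIN_EDGES[b]
        n_ev = int(ev_counts[:, b].sum())
        n_tot = int(tot_counts[:, b].sum())
        if n_tot == 0:
            out.append(
                EventRateBin(
                    bin_lo=lo, bin_hi=hi, n_event_samples=0, n_total_samples=0,
                    event_rate_pct=float("nan"), event_rate_ci_95=(float("nan"),) * 2,
                    median_time_to_event_min=float("nan"), median_ci_95=(float("nan"),) * 2,
                    q25_time_to_event_min=float("nan"), q25_ci_95=(float("nan"),) * 2,
                    q75_time_to_event_min=float("nan"), q75_ci_95=(float("nan"),) * 2,
                    empty=True,
                )
            )
            continue
        rate = 100.0 * n_ev / n_tot
        reps = rate_rep[:, b]
        reps = reps[~np.isnan(reps)]
        se = float(reps.std(ddof=1)) if len(reps) >= 2 else 0.0
        rate_ci = (rate - 1.96 * se, rate + 1.96 * se)

        # pooled warning times, with per-value patient ownership for the
        # weighted-bootstrap quantiles
        vals = np.concatenate([p.tte_min[b] for p in per_patient])
        owner = np.concatenate(
            [np.full(len(p.tte_min[b]), i) for i, p in enumerate(per_patient)]
        )
        order = np.argsort(vals, kind="stable")
        vals, owner = vals[order], owner[order]

        qs = {}
        for q in (0.5, 0.25, 0.75):
            point = _quantile(vals, q)
            if len(vals) == 0:
                qs[q] = (point, (float("nan"), float("nan")))
                continue
            rep_q = np.empty(n_boot)
            chunk = max(1, int(5_000_000 / max(len(vals), 1)))
            for s0 in range(0, n_boot, chunk):
                Wb = W[s0 : s0 + chunk, :][:, owner]  # (chunk, m)
                cum = np.cumsum(Wb, axis=1)
                tot = cum[:, -1]
                targets = q * tot
                ks = np.minimum(
                    (cum < targets[:, None]).sum(axis=1), len(vals) - 1
                )
                rep_q[s0 : s0 + len(ks)] = np.where(tot > 0, vals[ks], np.nan)
            rep_q = rep_q[~np.isnan(rep_q)]
            se_q = float(rep_q.std(ddof=1)) if len(rep_q) >= 2 else 0.0
            qs[q] = (point, (point - 1.96 * se_q, point + 1.96 * se_q))

        out.append(
            EventRateBin(
                bin_lo=lo, bin_hi=hi,
                n_event_samples=n_ev, n_total_samples=n_tot,
                event_rate_pct=rate, event_rate_ci_95=rate_ci,
                median_time_to_event_min=qs[0.5][0], median_ci_95=qs[0.5][1],
                q25_time_to_event_min=qs[0.25][0], q25_ci_95=qs[0.25][1],
                q75_time_to_event_min=qs[0.75][0], q75_ci_95=qs[0.75][1],
            )
        )
    return out


def mean_true_probability_by_bin(
    records: list[MonitoringRecord],
    events_by_patient: dict[str, list[HypotensiveEvent]],
    true_prob: dict[str, np.ndarray],
    window_min: float = 15.0,
    include_in_event_samples: bool = False,
    require_full_window: bool = True,
) -> np.ndarray:
    """Mean generator ground-truth probability of the samples in each bin.

    Companion to :func:`event_rate_by_bin` for identity-line checks on
    synthetic cohorts: applies the same eligibility rules and binning, but
    averages the known forward probabilities instead of observing outcomes.
    Returns an array of length ``N_BINS`` (NaN for empty bins).
    """
    sums = np.zeros(N_BINS)
    counts = np.zeros(N_BINS)
    for rec in records:
        events = events_by_patient.get(rec.patient_id, [])
        dt = rec.sample_interval_s
        t = rec.times_s
        eligible = ~np.isnan(rec.index_value)
        if not include_in_event_samples:
            eligible &= ~in_event_mask(rec, events)
        if require_full_window:
            eligible &= t <= t[-1] - window_min * 60 - 2 * dt
        bins = assign_bins(rec.index_value[eligible])
        p = true_prob[rec.patient_id][eligible]
        np.add.at(sums, bins, p)
        np.add.at(counts, bins, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


def event_aligned_trajectory(
    records: list[MonitoringRecord],
    events_by_patient: dict[str, list[HypotensiveEvent]],
    lookback_min: float = 15.0,
) -> dict[str, np.ndarray]:
    """Mean and SD of the index aligned to event onset.

    Offsets run from ``lookback_min`` minutes before onset to onset itself
    in sampling-interval steps; events with shorter recorded history
    contribute only to the offsets they cover.

    Returns a dict with ``offset_min`` (negative, 0 at onset), ``mean``,
    ``sd`` (sample SD; 0 where a single event contributes) and ``n``.
    """
    all_events = [ev for evs in events_by_patient.values() for ev in evs]
    if not all_events:
        raise ValueError("no events: event-aligned trajectory undefined")
    rec_by_id = {r.patient_id: r for r in records}
    dt = records[0].sample_interval_s
    L = int(round(lookback_min * 60 / dt))
    sums = np.zeros(L + 1)
    sqs = np.zeros(L + 1)
    ns = np.zeros(L + 1)
    for pid, evs in events_by_patient.items():
        rec = rec_by_id[pid]
        for ev in evs:
            i = int(np.searchsorted(rec.times_s, ev.start_s))
            for k in range(min(L, i) + 1):
                v = rec.index_value[i - k]
                if np.isnan(v):
                    continue
                sums[k] += v
                sqs[k] += v * v
                ns[k] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(ns > 0, sums / np.maximum(ns, 1), np.nan)
        var = np.where(
            ns > 1,
            (sqs - ns * mean**2) / np.maximum(ns - 1, 1),
            0.0,
        )
        sd = np.sqrt(np.maximum(var, 0.0))
        sd = np.where(ns == 0, np.nan, sd)
    # offset 0 = onset; negative offsets = minutes before onset
    offsets = -np.arange(L + 1) * dt / 60.0
    return {"offset_min": offsets, "mean": mean, "sd": sd, "n": ns}
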