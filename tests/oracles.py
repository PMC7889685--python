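"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by the most direct method available —
exhaustive window scans, path enumeration, pairwise comparison — staying
deliberately independent of the library's implementation choices.
"""
from __future__ import annotations

import itertools

import numpy as np


def event_samples_by_window_scan(
    times: np.ndarray,
    map_mmhg: np.ndarray,
    dt: int,
    threshold: float = 65.0,
    min_duration_s: int = 60,
) -> set[int]:
    """Indices of samples inside events, by testing every contiguous window.

    A sample is an event sample iff it lies in some contiguous window (no
    grid gap > 1.5 dt) whose samples are all at or below the threshold and
    whose length covers the minimum duration.
    """
    n = len(times)
    need = int(np.ceil(min_duration_s / dt))
    out: set[int] = set()
    for i in range(n):
        j = i
        # grow the window until a violation; any longer window from i also
        # violates, so stopping early loses nothing
        while j < n:
            if map_mmhg[j] > threshold:
                break
            if j > i and times[j] - times[j - 1] > 1.5 * dt:
                break
            if j - i + 1 >= need:
                out.update(range(i, j + 1))
            j += 1
    return out


def segments_by_feasibility_scan(
    times: np.ndarray,
    map_mmhg: np.ndarray,
    dt: int,
    events: list[tuple[int, int]],
    segment_s: int = 1800,
    exclusion_s: int = 1200,
    map_floor: float = 75.0,
) -> list[tuple[int, int]]:
    """Greedy left-to-right tiling over brute-force feasible 30-min windows.

    Feasibility of a window starting at sample k: the next ``segment_s/dt``
    samples exist, are contiguous (no gaps), all exceed the MAP floor, and
    each sample's covered interval keeps ``exclusion_s`` distance from
    every event interval.
    """
    n = len(times)
    need = int(round(segment_s / dt))

    def sample_ok(i: int) -> bool:
        if map_mmhg[i] <= map_floor:
            return False
        for (ev_start, ev_end) in events:
            if times[i] + dt > ev_start - exclusion_s and times[i] < ev_end + exclusion_s:
                return False
        return True

    def window_ok(k: int) -> bool:
        if k + need > n:
            return False
        for i in range(k, k + need):
            if not sample_ok(i):
                return False
            if i > k and times[i] - times[i - 1] > 1.5 * dt:
                return False
        return True

    out = []
    k = 0
    while k + need <= n:
        if window_ok(k):
            out.append((int(times[k]), int(times[k]) + segment_s))
            k += need
        else:
            k += 1
    return out


def auc_by_pairwise(pos: np.ndarray, neg: np.ndarray) -> float:
    """Concordance probability by explicit pairwise comparison."""
    p = np.asarray(pos)[:, None]
    n = np.asarray(neg)[None, :]
    wins = (p > n).sum() + 0.5 * (p == n).sum()
    return float(wins) / (len(pos) * len(neg))


def confusion_by_recount(pos, neg, threshold):
    """(tp, fn, tn, fp) by direct counting at one threshold (>= rule)."""
    tp = sum(1 for v in pos if v >= threshold)
    fp = sum(1 for v in neg if v >= threshold)
    return tp, len(pos) - tp, len(neg) - fp, fp


def run_completion_prob_by_enumeration(
    P: np.ndarray,
    below: np.ndarray,
    start: int,
    horizon: int,
    counter: int = 0,
) -> float:
    """P(>= 3 consecutive below-threshold steps within the horizon), by
    summing the probability of every length-``horizon`` path."""
    total = 0.0
    S = len(below)
    for path in itertools.product(range(S), repeat=horizon):
        prob = 1.0
        prev = start
        for s in path:
            prob *= P[prev, s]
            prev = s
        run = counter
        met = False
        for s in path:
            run = run + 1 if below[s] else 0
            if run >= 3:
                met = True
                break
        if met:
            total += prob
    return total


def event_start_prob_by_enumeration(
    P: np.ndarray,
    below: np.ndarray,
    start: int,
    horizon: int,
    counter: int,
    extra: int = 3,
) -> float:
    """Eligibility-conditioned probability that a detected event starts
    within the window, by enumerating paths of length horizon + extra.

    Conditioning: the run containing the current sample (length
    ``counter``) dies before reaching 3 samples.  An event start is the
    first sample of a fresh run that eventually reaches length 3, with
    that first sample inside the window.
    """
    S = len(below)
    num = 0.0
    den = 0.0
    L = horizon + extra
    for path in itertools.product(range(S), repeat=L):
        prob = 1.0
        prev = start
        for s in path:
            prob *= P[prev, s]
            prev = s
        b = [below[s] for s in path]
        # does the original run die before 3?
        run = counter
        ok = counter == 0
        bad = False
        for x in b:
            if not x:
                ok = True
                break
            run += 1
            if run >= 3:
                bad = True
                break
        if counter > 0 and (bad or not ok):
            continue  # ineligible path
        den += prob
        # fresh event start inside window (steps are 1-indexed over path)
        run = counter
        startpos = None
        hit = False
        for t, x in enumerate(b):
            if x:
                if run == 0:
                    startpos = t
                run += 1
                if run >= 3 and startpos is not None and startpos < horizon:
                    hit = True
                    break
            else:
                run = 0
                startpos = None
        if hit:
            num += prob
    return num / den if den > 0 else float("nan")
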