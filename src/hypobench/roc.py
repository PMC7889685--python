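"""ROC analysis with patient-level bootstrap confidence intervals.

The operating point reported per prediction horizon is the threshold
minimizing |sensitivity - specificity|.  Because the same patient
contributes many samples, uncertainty comes from a cluster bootstrap that
resamples whole patients with replacement (2000 replicates); confidence
intervals are asymptotic: point estimate +/- 1.96 bootstrap standard errors.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .samples import LabeledSample

logger = logging.getLogger(__name__)


class SingleClassError(ValueError):
    """Raised when positives or negatives are absent."""


@dataclass(frozen=True)
class RocPoint:
    threshold: float
    sensitivity: float
    specificity: float


@dataclass
class RocResult:
    """ROC summary for one prediction horizon."""

    horizon_min: int
    auc: float
    auc_ci_95: tuple[float, float]
    sensitivity: float
    sensitivity_ci_95: tuple[float, float]
    specificity: float
    specificity_ci_95: tuple[float, float]
    optimal_threshold: float
    n_pos: int
    n_neg: int


def _split(samples: list[LabeledSample]) -> tuple[np.ndarray, np.ndarray]:
    pos = np.array([s.index_value for s in samples if s.label == "positive"])
    neg = np.array([s.index_value for s in samples if s.label == "negative"])
    if len(pos) == 0:
        raise SingleClassError("no positive samples")
    if len(neg) == 0:
        raise SingleClassError("no negative samples")
    return pos, neg


def roc_curve(samples: list[LabeledSample]) -> list[RocPoint]:
    """Sensitivity/specificity at every distinct index value as threshold.

    A sample is test-positive when its index is >= the threshold.  Points
    are ordered by increasing threshold, so sensitivity is non-increasing
    and specificity non-decreasing along the curve.
    """
    pos, neg = _split(samples)
    thresholds = np.unique(np.concatenate([pos, neg]))
    # counts of pos/neg >= each threshold via sorted arrays
    pos_sorted = np.sort(pos)
    neg_sorted = np.sort(neg)
    n_pos, n_neg = len(pos), len(neg)
    tp = n_pos - np.searchsorted(pos_sorted, thresholds, side="left")
    fp = n_neg - np.searchsorted(neg_sorted, thresholds, side="left")
    return [
        RocPoint(float(th), tp_i / n_pos, (n_neg - fp_i) / n_neg)
        for th, tp_i, fp_i in zip(thresholds, tp, fp)
    ]


def auc(samples: list[LabeledSample]) -> float:
    """ROC AUC as the pairwise concordance probability, ties counted 1/2."""
    pos, neg = _split(samples)
    return _auc_values(pos, neg)


def _auc_values(pos: np.ndarray, neg: np.ndarray) -> float:
    ranks = rankdata(np.concatenate([pos, neg]))
    n_pos, n_neg = len(pos), len(neg)
    u = ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def trapezoid_auc(samples: list[LabeledSample]) -> float:
    """AUC by trapezoidal integration of the empirical ROC curve.

    Kept as an independent route to the same quantity as :func:`auc`; the
    two agree to numerical precision on any input.
    """
    pos, neg = _split(samples)
    thresholds = np.unique(np.concatenate([pos, neg]))
    pos_sorted, neg_sorted = np.sort(pos), np.sort(neg)
    # sweep thresholds from above the max down to the min, collecting
    # (FPR, TPR); between consecutive thresholds ties advance both axes,
    # which the trapezoid rule credits with half weight.
    tpr = [(len(pos) - np.searchsorted(pos_sorted, th, side="left")) / len(pos)
           for th in thresholds[::-1]]
    fpr = [(len(neg) - np.searchsorted(neg_sorted, th, side="left")) / len(neg)
           for th in thresholds[::-1]]
    tpr = np.concatenate([[0.0], tpr, [1.0]])
    fpr = np.concatenate([[0.0], fpr, [1.0]])
    return float(np.trapezoid(tpr, fpr))


def optimal_threshold(curve: list[RocPoint]) -> RocPoint:
    """Operating point minimizing |sensitivity - specificity|.

    Ties break toward higher sensitivity, then toward the lower threshold.
    """
    if not curve:
        raise ValueError("empty ROC curve")
    best = None
    for pt in curve:  # curve is ordered by increasing threshold
        d = abs(pt.sensitivity - pt.specificity)
        if best is None or d < best[0] or (d == best[0] and pt.sensitivity > best[1].sensitivity):
            best = (d, pt)
    return best[1]


# ---------------------------------------------------------------------------
# Patient-level bootstrap
# ---------------------------------------------------------------------------


@dataclass
class BootstrapResult:
    point: float
    lo: float
    hi: float
    se: float
    n_boot: int
    n_redrawn: int
    degenerate: bool = False


def bootstrap_ci(
    patient_data: dict[str, object],
    statistic,
    n_boot: int = 2000,
    seed: int = 0,
    z: float = 1.96,
) -> BootstrapResult:
    """Cluster bootstrap over patients with an asymptotic-normal CI.

    ``patient_data`` maps patient id to that patient's payload;
    ``statistic`` receives a list of payloads (the resampled cohort, with
    repetition) and returns a float.  Replicates on which the statistic is
    undefined (raises ``SingleClassError``/``ZeroDivisionError`` or returns
    NaN) are redrawn and logged; if more than half of all draws are
    invalid the bootstrap aborts.

    The CI is ``point +/- z * se`` where ``se`` is the standard deviation
    of the replicate statistics and ``point`` the full-cohort statistic.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    ids = list(patient_data.keys())
    payloads = list(patient_data.values())
    point = float(statistic(payloads))
    rng = np.random.default_rng(seed)
    reps = []
    n_redrawn = 0
    max_draws = 2 * n_boot
    draws = 0
    while len(reps) < n_boot and draws < max_draws:
        draws += 1
        pick = rng.integers(0, len(ids), size=len(ids))
        try:
            val = float(statistic([payloads[i] for i in pick]))
        except (SingleClassError, ZeroDivisionError):
            val = float("nan")
        if np.isnan(val):
            n_redrawn += 1
            continue
        reps.append(val)
    if len(reps) < n_boot:
        raise RuntimeError(
            f"statistic undefined on more than half of bootstrap draws "
            f"({n_redrawn} of {draws})"
        )
    if n_redrawn:
        logger.info("bootstrap: redrew %d invalid replicate(s)", n_redrawn)
    reps = np.asarray(reps)
    degenerate = n_boot < 2
    se = float(reps.std(ddof=1)) if n_boot >= 2 else 0.0
    if degenerate:
        logger.warning("bootstrap with n_boot=%d is degenerate; CI width 0", n_boot)
    return BootstrapResult(
        point=point,
        lo=point - z * se,
        hi=point + z * se,
        se=se,
        n_boot=n_boot,
        n_redrawn=n_redrawn,
        degenerate=degenerate,
    )


def evaluate_roc(
    samples_by_patient: dict[str, list[LabeledSample]],
    horizon_min: int,
    n_boot: int = 2000,
    seed: int = 0,
) -> RocResult:
    """Full per-horizon ROC summary with patient-level bootstrap CIs.

    The optimal threshold is determined once on the full cohort; replicate
    sensitivities/specificities are re-read at each replicate's own optimal
    threshold, mirroring an analysis pipeline re-run per resample.
    """
    pooled = [s for ss in samples_by_patient.values() for s in ss]
    curve = roc_curve(pooled)
    opt = optimal_threshold(curve)
    point_auc = auc(pooled)

    def stat_vec(payloads: list[list[LabeledSample]]) -> tuple[float, float, float]:
        flat = [s for ss in payloads for s in ss]
        c = roc_curve(flat)
        o = optimal_threshold(c)
        return auc(flat), o.sensitivity, o.specificity

    # One resampling pass yielding all three statistics per replicate.
    ids = list(samples_by_patient.keys())
    payloads = list(samples_by_patient.values())
    rng = np.random.default_rng(seed)
    reps = np.empty((0, 3))
    collected = []
    n_redrawn = 0
    draws = 0
    while len(collected) < n_boot and draws < 2 * n_boot:
        draws += 1
        pick = rng.integers(0, len(ids), size=len(ids))
        try:
            collected.append(stat_vec([payloads[i] for i in pick]))
        except SingleClassError:
            n_redrawn += 1
    if len(collected) < n_boot:
        raise RuntimeError("statistic undefined on more than half of bootstrap draws")
    if n_redrawn:
        logger.info("roc bootstrap: redrew %d invalid replicate(s)", n_redrawn)
    reps = np.asarray(collected)
    se = reps.std(axis=0, ddof=1) if n_boot >= 2 else np.zeros(3)

    n_pos = sum(1 for s in pooled if s.label == "positive")
    n_neg = len(pooled) - n_pos
    return RocResult(
        horizon_min=horizon_min,
        auc=point_auc,
        auc_ci_95=(point_auc - 1.96 * se[0], point_auc + 1.96 * se[0]),
        sensitivity=opt.sensitivity,
        sensitivity_ci_95=(opt.sensitivity - 1.96 * se[1], opt.sensitivity + 1.96 * se[1]),
        specificity=opt.specificity,
        specificity_ci_95=(opt.specificity - 1.96 * se[2], opt.specificity + 1.96 * se[2]),
        optimal_threshold=opt.threshold,
        n_pos=n_pos,
        n_neg=n_neg,
    )
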