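import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score

from hypobench import auc, bootstrap_ci, optimal_threshold, roc_curve, trapezoid_auc
from hypobench.roc import SingleClassError, evaluate_roc
from hypobench.samples import LabeledSample

from oracles import auc_by_pairwise, confusion_by_recount


def make_samples(pos, neg, pid="P1"):
    out = [
        LabeledSample(pid, 0, float(v), "positive", 15, 0) for v in pos
    ] + [
        LabeledSample(pid, 0, float(v), "negative", None, 0) for v in neg
    ]
    return out


def random_samples(rng, n_max=200, by_patient=False):
    n_pos = int(rng.integers(1, n_max // 2))
    n_neg = int(rng.integers(1, n_max // 2))
    # coarse values force plenty of ties
    pos = rng.choice(np.arange(0, 101, 5), size=n_pos).astype(float)
    neg = rng.choice(np.arange(0, 101, 5), size=n_neg).astype(float)
    return pos, neg


class TestRocCurve:
    def test_perfect_separation(self):
        curve = roc_curve(make_samples([80, 90], [10, 20]))
        opt = optimal_threshold(curve)
        assert opt.sensitivity == 1.0 and opt.specificity == 1.0
        assert 20 < opt.threshold <= 80

    def test_all_values_tied(self):
        curve = roc_curve(make_samples([50, 50], [50, 50]))
        assert len(curve) == 1
        assert (curve[0].sensitivity, curve[0].specificity) == (1.0, 0.0)

    def test_single_class_raises_named_error(self):
        with pytest.raises(SingleClassError, match="negative"):
            roc_curve(make_samples([1, 2], []))
        with pytest.raises(SingleClassError, match="positive"):
            roc_curve(make_samples([], [1, 2]))

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        pos, neg = random_samples(rng)
        curve = roc_curve(make_samples(pos, neg))
        sens = [p.sensitivity for p in curve]
        spec = [p.specificity for p in curve]
        assert all(a >= b for a, b in zip(sens, sens[1:]))
        assert all(a <= b for a, b in zip(spec, spec[1:]))

    @pytest.mark.parametrize("seed", range(5))
    def test_confusion_counts_match_recount(self, seed):
        rng = np.random.default_rng(seed)
        pos, neg = random_samples(rng)
        curve = roc_curve(make_samples(pos, neg))
        for pt in curve:
            tp, fn, tn, fp = confusion_by_recount(pos, neg, pt.threshold)
            assert pt.sensitivity == pytest.approx(tp / len(pos))
            assert pt.specificity == pytest.approx(tn / len(neg))


class TestAuc:
    def test_perfect_separation_is_one(self):
        assert auc(make_samples([80, 90], [10, 20])) == 1.0

    def test_identical_distributions_half(self):
        assert auc(make_samples([50, 50, 50], [50, 50])) == 0.5

    def test_four_pair_example(self):
        """Enumerating the 4 (positive, negative) pairs gives 3/4."""
        assert auc(make_samples([35, 80], [10, 40])) == pytest.approx(0.75)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_pairwise_oracle_and_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        pos, neg = random_samples(rng)
        samples = make_samples(pos, neg)
        got = auc(samples)
        assert got == pytest.approx(auc_by_pairwise(pos, neg), abs=1e-12)
        y = np.r_[np.ones(len(pos)), np.zeros(len(neg))]
        assert got == pytest.approx(roc_auc_score(y, np.r_[pos, neg]), abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        pos=st.lists(st.integers(0, 100), min_size=1, max_size=40),
        neg=st.lists(st.integers(0, 100), min_size=1, max_size=40),
    )
    def test_trapezoid_equals_concordance(self, pos, neg):
        samples = make_samples(pos, neg)
        assert trapezoid_auc(samples) == pytest.approx(auc(samples), abs=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        pos=st.lists(st.integers(0, 100), min_size=1, max_size=30),
        neg=st.lists(st.integers(0, 100), min_size=1, max_size=30),
    )
    def test_invariant_under_monotone_transform(self, pos, neg):
        base = auc(make_samples(pos, neg))
        f = lambda v: [100 * np.sqrt(x / 100) for x in v]  # strictly monotone
        assert auc(make_samples(f(pos), f(neg))) == pytest.approx(base, abs=1e-12)

    def test_noise_ladder_degrades_auc(self, calibration_cohort):
        """More index noise means less discrimination, on average."""
        from hypobench import extract_negative_samples, extract_positive_samples
        from hypobench import find_nonevent_segments
        rng = np.random.default_rng(123)
        records = calibration_cohort["records"][:150]
        events = calibration_cohort["events"]
        aucs = []
        for sd in (0.0, 0.1, 0.3):
            flat = []
            for rec in records:
                noisy = rec.index_value / 100.0 + rng.normal(0, sd, rec.n_samples)
                shadow = type(rec)(
                    patient_id=rec.patient_id,
                    times_s=rec.times_s,
                    map_mmhg=rec.map_mmhg,
                    index_value=np.clip(100 * noisy, 0, 100),
                    sample_interval_s=rec.sample_interval_s,
                )
                evs = events[rec.patient_id]
                segs = find_nonevent_segments(shadow, evs)
                flat += extract_positive_samples(shadow, evs, 5)
                flat += extract_negative_samples(shadow, segs)
            aucs.append(auc(flat))
        assert aucs[0] > aucs[1] > aucs[2]


class TestOptimalThreshold:
    def test_exact_balance_point_returned(self):
        curve = roc_curve(make_samples([10, 60, 80, 90], [5, 20, 40, 70]))
        opt = optimal_threshold(curve)
        scan = min(curve, key=lambda p: abs(p.sensitivity - p.specificity))
        assert abs(opt.sensitivity - opt.specificity) == pytest.approx(
            abs(scan.sensitivity - scan.specificity)
        )

    def test_tie_breaks_toward_higher_sensitivity(self):
        # two points equidistant in |sens - spec|
        from hypobench.roc import RocPoint
        curve = [
            RocPoint(10.0, 0.9, 0.7),  # diff 0.2, higher sensitivity
            RocPoint(20.0, 0.6, 0.8),  # diff 0.2
        ]
        assert optimal_threshold(curve).threshold == 10.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(200 + seed)
        pos, neg = random_samples(rng)
        curve = roc_curve(make_samples(pos, neg))
        opt = optimal_threshold(curve)
        best = None
        for pt in curve:
            d = abs(pt.sensitivity - pt.specificity)
            key = (d, -pt.sensitivity, pt.threshold)
            if best is None or key < best[0]:
                best = (key, pt)
        assert opt == best[1]


class TestBootstrap:
    def test_identical_patients_zero_se(self):
        data = {f"P{i}": 3.0 for i in range(10)}
        res = bootstrap_ci(data, lambda xs: sum(xs) / len(xs), n_boot=50, seed=0)
        assert res.se == 0.0
        assert res.lo == res.hi == res.point == 3.0

    def test_single_replicate_flagged_degenerate(self):
        data = {"A": 1.0, "B": 2.0}
        res = bootstrap_ci(data, lambda xs: sum(xs), n_boot=1, seed=0)
        assert res.degenerate and res.se == 0.0

    def test_seeded_determinism(self):
        rng = np.random.default_rng(1)
        data = {f"P{i}": float(v) for i, v in enumerate(rng.normal(size=20))}
        stat = lambda xs: float(np.mean(xs))
        a = bootstrap_ci(data, stat, n_boot=100, seed=7)
        b = bootstrap_ci(data, stat, n_boot=100, seed=7)
        assert (a.lo, a.hi, a.se) == (b.lo, b.hi, b.se)

    def test_undefined_replicates_redrawn_then_error(self):
        # statistic undefined whenever patient "B" dominates the resample
        data = {"A": 1.0, "B": float("nan")}
        def stat(xs):
            if any(np.isnan(x) for x in xs):
                return float("nan")
            return float(np.mean(xs))
        with pytest.raises(RuntimeError):
            bootstrap_ci(data, stat, n_boot=200, seed=0)

    def test_evaluate_roc_reports_counts(self, trial_cohort):
        from hypobench import extract_negative_samples, extract_positive_samples
        sbp = {}
        for rec in trial_cohort["records"]:
            pid = rec.patient_id
            sbp[pid] = extract_positive_samples(rec, trial_cohort["events"][pid], 5)
            sbp[pid] += extract_negative_samples(rec, trial_cohort["segments"][pid])
        res = evaluate_roc(sbp, horizon_min=5, n_boot=30, seed=2)
        assert res.n_pos == sum(1 for ss in sbp.values() for s in ss if s.label == "positive")
        assert res.auc_ci_95[0] <= res.auc <= res.auc_ci_95[1]
        assert 0 <= res.optimal_threshold <= 100
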