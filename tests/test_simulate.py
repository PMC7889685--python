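import numpy as np
import pytest

from hypobench import (
    SimulationConfig,
    TransitionKernel,
    calibration_config,
    detect_events,
    exact_event_start_probability,
    exact_forward_probability,
    simulate_cohort,
    simulate_trial_cohort,
)
from hypobench.simulate import ConfigurationError, InterventionPolicy

from oracles import (
    event_start_prob_by_enumeration,
    run_completion_prob_by_enumeration,
)


def quiet_kernel(**kwargs):
    """Kernel with the downward-episode machinery switched off."""
    defaults = dict(
        drop_hazard=0.0,
        drop_hazard_low=0.0,
        linger_top_mmhg=65.0,  # no decline band
    )
    defaults.update(kwargs)
    return TransitionKernel(**defaults)


def toy_kernel(seed=0, n_states=3):
    """Small dense random kernel straddling the 65-mmHg threshold."""
    rng = np.random.default_rng(seed)
    grid = np.linspace(55.0, 75.0, n_states)
    P = rng.dirichlet(np.ones(n_states), size=n_states)
    return P, grid


class TestKernelValidation:
    def test_rejects_unsorted_grid(self):
        with pytest.raises(ConfigurationError):
            TransitionKernel(map_grid=np.array([70.0, 60.0, 80.0]))

    def test_rejects_out_of_range_hazard(self):
        with pytest.raises(ConfigurationError):
            TransitionKernel(drop_hazard=1.5)

    def test_rows_are_distributions(self):
        P = TransitionKernel().matrix()
        assert np.all(P >= 0)
        assert np.allclose(P.sum(axis=1), 1.0)

    def test_non_stochastic_kernel_rejected_by_dp(self):
        P = np.array([[0.5, 0.2], [0.1, 0.9]])  # first row sums to 0.7
        with pytest.raises(ConfigurationError):
            exact_forward_probability((P, np.array([60.0, 70.0])), 5)


class TestForwardProbability:
    def test_counter_three_is_certain(self):
        P, grid = toy_kernel()
        probs = exact_forward_probability((P, grid), 5, counter=3)
        assert all(v == 1.0 for v in probs.values())

    def test_no_mass_below_threshold_gives_zero(self):
        grid = np.array([70.0, 80.0, 90.0])
        rng = np.random.default_rng(1)
        P = rng.dirichlet(np.ones(3), size=3)
        probs = exact_forward_probability((P, grid), 50)
        assert all(v == 0.0 for v in probs.values())

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("counter", [0, 1, 2])
    def test_matches_path_enumeration(self, seed, counter):
        """DP equals the sum over all 3^5 explicit paths."""
        P, grid = toy_kernel(seed)
        below = grid <= 65.0
        probs = exact_forward_probability((P, grid), 5, counter=counter)
        for s in range(len(grid)):
            expected = run_completion_prob_by_enumeration(P, below, s, 5, counter)
            assert probs[grid[s]] == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("counter", [0, 1, 2])
    def test_event_start_dp_matches_enumeration(self, counter):
        """Eligibility-conditioned event-start DP equals path enumeration."""
        P, grid = toy_kernel(3)
        below = grid <= 65.0
        tab = exact_event_start_probability((P, grid), 4)
        for s in range(len(grid)):
            if counter > 0 and not below[s]:
                continue
            expected = event_start_prob_by_enumeration(P, below, s, 4, counter)
            assert tab[counter, s] == pytest.approx(expected, abs=1e-12)

    def test_event_start_dp_matches_monte_carlo(self):
        """DP agrees with 1e5 simulated rollouts within 3 standard errors."""
        P, grid = toy_kernel(7, n_states=4)
        below = grid <= 65.0
        H = 6
        tab = exact_event_start_probability((P, grid), H)
        cum = np.cumsum(P, axis=1)
        rng = np.random.default_rng(42)
        n = 100_000
        for s0 in range(len(grid)):
            states = np.full(n, s0)
            b = np.empty((H + 5, n), dtype=bool)
            for t in range(H + 5):
                u = rng.random(n)
                states = (u[:, None] > cum[states]).sum(axis=1)
                b[t] = below[states]
            runlen = np.zeros(n, dtype=int)
            startpos = np.full(n, -1)
            got = np.zeros(n, dtype=bool)
            prev = np.zeros(n, dtype=bool)
            for t in range(H + 5):
                new = b[t] & ~prev
                startpos = np.where(new, t, startpos)
                runlen = np.where(b[t], runlen + 1, 0)
                got |= (runlen == 3) & (startpos < H)
                prev = b[t]
            mc = got.mean()  # counter-0 start (fresh history)
            se = np.sqrt(max(mc * (1 - mc), 1e-12) / n)
            assert abs(mc - tab[0, s0]) < 3 * se + 1e-4


class TestSimulateCohort:
    def test_seeded_determinism(self):
        cfg = SimulationConfig(n_patients=5, seed=42)
        r1, iv1, t1 = simulate_cohort(cfg)
        r2, iv2, t2 = simulate_cohort(SimulationConfig(n_patients=5, seed=42))
        for a, b in zip(r1, r2):
            assert np.array_equal(a.map_mmhg, b.map_mmhg)
            assert np.array_equal(a.index_value, b.index_value)
        assert iv1 == iv2
        for pid in t1.true_prob:
            assert np.array_equal(t1.true_prob[pid], t2.true_prob[pid])

    def test_zero_hazard_forbids_events(self):
        """With no downward-episode mechanism MAP stays near baseline."""
        cfg = SimulationConfig(n_patients=20, seed=1, kernel=quiet_kernel())
        records, _, _ = simulate_cohort(cfg)
        for rec in records:
            assert rec.map_mmhg.min() > 70.0
            assert detect_events(rec) == []

    def test_map_values_on_grid(self):
        cfg = SimulationConfig(n_patients=3, seed=2)
        records, _, _ = simulate_cohort(cfg)
        grid = set(cfg.kernel.map_grid)
        for rec in records:
            assert set(np.unique(rec.map_mmhg)) <= grid

    def test_noise_free_index_equals_scaled_probability(self):
        cfg = calibration_config(n_patients=3, seed=5)
        records, _, truth = simulate_cohort(cfg)
        for rec in records:
            expect = np.clip(100.0 * truth.true_prob[rec.patient_id], 0, 100)
            assert np.allclose(rec.index_value, expect)

    def test_episode_onsets_match_detector(self):
        cfg = calibration_config(n_patients=10, seed=6)
        records, _, truth = simulate_cohort(cfg)
        for rec in records:
            onsets = [ev.start_s for ev in detect_events(rec)]
            assert list(truth.episode_onsets[rec.patient_id]) == onsets

    def test_cohort_shape_matches_targets(self):
        """~60% of patients with >= 1 event; median event 2-3 min."""
        cfg = SimulationConfig(n_patients=1000, arm="blinded", seed=13)
        records, _, _ = simulate_cohort(cfg)
        events = [detect_events(r) for r in records]
        frac = np.mean([len(e) > 0 for e in events])
        durations = [ev.duration_min for e in events for ev in e]
        assert 0.5 < frac < 0.7
        assert 1.5 <= np.median(durations) <= 3.0

    def test_monitoring_duration_distribution(self):
        cfg = SimulationConfig(n_patients=400, seed=14)
        records, _, _ = simulate_cohort(cfg)
        spans = np.array([r.monitoring_time_min for r in records])
        assert 180 < np.median(spans) < 225
        q25, q75 = np.percentile(spans, [25, 75])
        assert 130 < q25 < 180 and 225 < q75 < 300

    def test_unblinded_arm_reduces_event_burden(self):
        """More aggressive intervention weakly lowers total event time."""
        totals = {}
        for arm in ("blinded", "unblinded"):
            cfg = SimulationConfig(n_patients=200, arm=arm, seed=15)
            records, _, _ = simulate_cohort(cfg)
            totals[arm] = np.mean(
                [sum(e.duration_min for e in detect_events(r)) for r in records]
            )
        assert totals["unblinded"] <= totals["blinded"]

    def test_interventions_logged_only_when_enabled(self):
        cfg = calibration_config(n_patients=10, seed=3)
        _, interventions, _ = simulate_cohort(cfg)
        assert interventions == []
        cfg2 = SimulationConfig(n_patients=10, seed=3)
        _, interventions2, _ = simulate_cohort(cfg2)
        assert len(interventions2) > 0

    def test_trial_cohort_merges_arms(self):
        records, _, truth = simulate_trial_cohort(4, 5, seed=9)
        arms = [r.arm for r in records]
        assert arms.count("blinded") == 4 and arms.count("unblinded") == 5
        assert len(truth.true_prob) == 9

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_patients=0)
        with pytest.raises(ConfigurationError):
            SimulationConfig(arm="open-label")
        with pytest.raises(ConfigurationError):
            InterventionPolicy(fire_prob=1.2)
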