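"""Synthetic intraoperative hemodynamics with exact forward event probabilities.

The generator emulates the statistical structure of a noncardiac-surgery
monitoring cohort: ~300 patients observed for a median of ~200 min on a
20-second grid, roughly 60% of patients experiencing at least one
hypotensive event (MAP <= 65 mmHg sustained >= 1 min), short events (median
2-3 min), and clinician interventions that produce rapid MAP rises.

MAP dynamics are a discrete-state Markov chain on a 1-mmHg grid rather than
a continuous diffusion.  That choice is deliberate: with a finite transition
matrix, the probability that a hypotensive event lies ahead within any
horizon is computable *exactly* by dynamic programming, so the risk index
can be made perfectly calibrated by construction (index = 100 x true
forward probability) and every downstream analysis has a known target.

Two forward probabilities are provided:

``exact_forward_probability``
    P(the chain, started in a given state, produces >= 3 consecutive steps
    at MAP <= 65 within the horizon).  Simple, unconditional, and checkable
    by brute-force path enumeration.

``exact_event_start_probability``
    P(a *detected event starts* strictly within the forward window | the
    sample is eligible), for each (MAP state, current consecutive-below-
    threshold run length).  This is the quantity the forward-window event-
    rate analysis actually measures for samples outside events, and is the
    one used as ground truth for the index.  "Eligible" conditions on the
    sample's own below-threshold run (if any) dying before it reaches the
    3-sample event criterion, because samples inside detected events are
    excluded from event-rate denominators.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .records import (
    DEFAULT_SAMPLE_INTERVAL_S,
    HYPOTENSION_THRESHOLD_MMHG,
    Intervention,
    MonitoringRecord,
)


class ConfigurationError(ValueError):
    """Raised for invalid simulation configurations or kernels."""


# ---------------------------------------------------------------------------
# Transition kernel
# ---------------------------------------------------------------------------


@dataclass
class TransitionKernel:
    """Markov transition kernel for MAP on a discrete mmHg grid.

    Per 20-s step the chain either follows a mean-reverting Gaussian walk
    toward ``baseline_mmhg`` or suffers an abrupt downward drop whose depth
    is ``drop_shift_mmhg`` plus a geometric excess with mean
    ``drop_mean_extra_mmhg``.  Two state dependencies shape the dynamics:

    * inside the "decline" band between the hypotension threshold and
      ``linger_top_mmhg`` the walk has a steady downward drift
      (``band_drift_mmhg``): an untreated downward trend progresses at
      roughly 1 mmHg/min, which is what makes impending hypotension
      foreseeable minutes ahead;
    * the drop hazard ramps up as MAP approaches the threshold
      (``drop_hazard`` at baseline to ``drop_hazard_low`` below
      ``drop_knee_mmhg``), accelerating the final descent;
    * upward "recovery" jumps (treatment or spontaneous autoregulation)
      fire at ``recovery_hazard`` below the threshold — they end events
      after a couple of minutes — and at the weaker
      ``band_recovery_hazard`` inside the band, where they abort a
      decline before it becomes an event.

    Parameters
    ----------
    map_grid : ndarray
        Strictly increasing MAP levels in mmHg (default 40..120 by 1).
    baseline_mmhg : float
        Attractor of the mean-reverting walk.
    reversion_rate, rescue_rate : float
        Fraction of the gap to baseline closed per step above the band /
        below the threshold, each in [0, 1].
    band_drift_mmhg : float
        Drift per 20-s step inside the decline band (negative).
    linger_top_mmhg : float
        Upper edge of the decline band.
    walk_sd_mmhg : float
        Standard deviation of the Gaussian innovation, mmHg per step.
    drop_hazard, drop_hazard_low : float
        Per-step drop probability at high MAP and near the threshold;
        interpolated by a logistic ramp centred at ``drop_knee_mmhg``
        with width ``drop_knee_width_mmhg``.
    drop_shift_mmhg, drop_mean_extra_mmhg : float
        Minimum drop size and mean geometric excess, mmHg.
    recovery_hazard, recovery_below_mmhg : float
        Per-step probability of an upward recovery jump at or below
        ``recovery_below_mmhg``.
    recovery_shift_mmhg, recovery_mean_extra_mmhg : float
        Minimum recovery jump and mean geometric excess, mmHg.
    """

    map_grid: np.ndarray = field(
        default_factory=lambda: np.arange(40.0, 121.0, 1.0)
    )
    baseline_mmhg: float = 88.0
    reversion_rate: float = 0.12
    band_drift_mmhg: float = -0.30
    rescue_rate: float = 0.015
    linger_top_mmhg: float = 82.0
    band_recovery_hazard: float = 0.015
    walk_sd_mmhg: float = 1.4
    drop_hazard: float = 0.0014
    drop_hazard_low: float = 0.10
    drop_knee_mmhg: float = 69.0
    drop_knee_width_mmhg: float = 1.5
    drop_shift_mmhg: float = 5.0
    drop_mean_extra_mmhg: float = 4.0
    recovery_hazard: float = 0.07
    recovery_below_mmhg: float = 65.0
    recovery_shift_mmhg: float = 10.0
    recovery_mean_extra_mmhg: float = 6.0

    def __post_init__(self) -> None:
        self.map_grid = np.asarray(self.map_grid, dtype=float)
        if self.map_grid.ndim != 1 or len(self.map_grid) < 2:
            raise ConfigurationError("map_grid must be a 1-d array of >= 2 levels")
        if not np.all(np.diff(self.map_grid) > 0):
            raise ConfigurationError("map_grid must be strictly increasing")
        for name in (
            "reversion_rate", "rescue_rate", "drop_hazard",
            "drop_hazard_low", "recovery_hazard", "band_recovery_hazard",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.walk_sd_mmhg <= 0:
            raise ConfigurationError("walk_sd_mmhg must be > 0")
        self._matrix: np.ndarray | None = None

    def _walk_mean(self) -> np.ndarray:
        """Conditional mean of the Gaussian walk component per state.

        Three regimes: above the band, ordinary reversion toward baseline;
        inside the "decline" band, a steady downward drift (an untreated
        downward trend progresses — the prodrome that makes hypotension
        foreseeable minutes ahead); below the event threshold, weak
        residual reversion (sharp recoveries are the recovery jumps).
        """
        g = self.map_grid
        mu = g + self.reversion_rate * (self.baseline_mmhg - g)
        band = (g > HYPOTENSION_THRESHOLD_MMHG) & (g < self.linger_top_mmhg)
        mu[band] = g[band] + self.band_drift_mmhg
        low = g <= HYPOTENSION_THRESHOLD_MMHG
        mu[low] = g[low] + self.rescue_rate * (self.baseline_mmhg - g[low])
        return mu

    def drop_hazard_by_state(self) -> np.ndarray:
        """Per-step probability of an abrupt downward episode, by MAP state.

        A logistic ramp from ``drop_hazard`` (stable, high MAP) up to
        ``drop_hazard_low`` below ``drop_knee_mmhg``: hemodynamic
        instability deepens as pressure falls, so declines cascade —
        which is what makes impending hypotension predictable minutes
        ahead rather than a memoryless surprise.
        """
        g = self.map_grid
        s = 1.0 / (1.0 + np.exp((g - self.drop_knee_mmhg) / self.drop_knee_width_mmhg))
        h = self.drop_hazard + (self.drop_hazard_low - self.drop_hazard) * s
        # below the event threshold active management takes over: no
        # further cascading drops, only the base hazard
        return np.where(g <= HYPOTENSION_THRESHOLD_MMHG, self.drop_hazard, h)

    @property
    def n_states(self) -> int:
        return len(self.map_grid)

    def below_threshold(self, threshold: float = HYPOTENSION_THRESHOLD_MMHG) -> np.ndarray:
        return self.map_grid <= threshold

    def matrix(self) -> np.ndarray:
        """Row-stochastic transition matrix over ``map_grid``."""
        if self._matrix is not None:
            return self._matrix
        g = self.map_grid
        S = len(g)
        # Gaussian walk, discretized by integrating the density between grid
        # midpoints; the tails are absorbed into the edge states.
        mu = self._walk_mean()
        mids = np.concatenate(([-np.inf], (g[:-1] + g[1:]) / 2.0, [np.inf]))
        z = (mids[None, :] - mu[:, None]) / self.walk_sd_mmhg
        cdf = norm.cdf(z)
        walk = np.diff(cdf, axis=1)

        def _jump_matrix(shift: float, mean_extra: float, sign: float) -> np.ndarray:
            # depth/height = shift + Geometric(mean extra), snapped to the
            # nearest grid state; mass beyond the grid piles on the edge.
            p_geo = 1.0 / (1.0 + mean_extra)
            out = np.zeros((S, S))
            span = g[-1] - g[0]
            kmax = int(math.ceil(span + 10 * mean_extra))
            ks = np.arange(kmax + 1)
            pmf = p_geo * (1.0 - p_geo) ** ks
            pmf[-1] = 1.0 - pmf[:-1].sum()  # fold the tail into the last k
            for i, m in enumerate(g):
                targets = m + sign * (shift + ks)
                idx = np.clip(np.searchsorted(g, targets), 0, S - 1)
                left = np.clip(idx - 1, 0, S - 1)
                idx = np.where(
                    np.abs(g[left] - targets) <= np.abs(g[idx] - targets), left, idx
                )
                np.add.at(out[i], idx, pmf)
            return out

        jump_down = _jump_matrix(self.drop_shift_mmhg, self.drop_mean_extra_mmhg, -1.0)
        jump_up = _jump_matrix(
            self.recovery_shift_mmhg, self.recovery_mean_extra_mmhg, +1.0
        )
        h_down = self.drop_hazard_by_state()
        band = (g > HYPOTENSION_THRESHOLD_MMHG) & (g < self.linger_top_mmhg)
        h_up = np.where(g <= self.recovery_below_mmhg, self.recovery_hazard, 0.0)
        h_up = np.where(band, self.band_recovery_hazard, h_up)
        scale = np.maximum(h_down + h_up, 1.0)  # keep rows stochastic
        h_down, h_up = h_down / scale, h_up / scale
        P = (
            (1.0 - h_down - h_up)[:, None] * walk
            + h_down[:, None] * jump_down
            + h_up[:, None] * jump_up
        )
        P /= P.sum(axis=1, keepdims=True)
        self._matrix = P
        return P


def _check_stochastic(P: np.ndarray) -> None:
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ConfigurationError("kernel matrix must be square")
    if np.any(P < -1e-12) or not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
        raise ConfigurationError("kernel rows are not probability distributions")


# ---------------------------------------------------------------------------
# Exact forward probabilities (dynamic programming)
# ---------------------------------------------------------------------------


def _resolve(kernel, threshold):
    if isinstance(kernel, TransitionKernel):
        P = kernel.matrix()
        grid = kernel.map_grid
    else:
        P, grid = kernel
        P = np.asarray(P, dtype=float)
        grid = np.asarray(grid, dtype=float)
    _check_stochastic(P)
    below = grid <= threshold
    return P, grid, below


def exact_forward_probability(
    kernel,
    horizon_steps: int,
    counter: int = 0,
    threshold: float = HYPOTENSION_THRESHOLD_MMHG,
) -> dict[float, float]:
    """Probability of >= 3 consecutive below-threshold steps within the horizon.

    The chain starts in each MAP state with ``counter`` consecutive
    below-threshold steps already accrued (the current sample included); the
    event criterion is met as soon as the counter reaches 3, after which the
    augmented chain is absorbing.

    Parameters
    ----------
    kernel : TransitionKernel or (matrix, grid) pair
    horizon_steps : int
        Number of future steps searched (>= 1).
    counter : int
        Consecutive below-threshold steps already accrued, 0..3.

    Returns
    -------
    dict mapping each MAP grid value to the event probability.
    """
    if horizon_steps < 1:
        raise ConfigurationError("horizon_steps must be >= 1")
    if counter not in (0, 1, 2, 3):
        raise ConfigurationError("counter must be in 0..3")
    P, grid, below = _resolve(kernel, threshold)
    if counter == 3:
        return {m: 1.0 for m in grid}
    S = len(grid)
    # U[c] = P(criterion met within r remaining steps | state, counter c)
    U = [np.zeros(S) for _ in range(3)]
    for _ in range(horizon_steps):
        nxt2 = P @ np.where(below, 1.0, U[0])
        nxt1 = P @ np.where(below, U[2], U[0])
        nxt0 = P @ np.where(below, U[1], U[0])
        U = [nxt0, nxt1, nxt2]
    return dict(zip(grid, U[counter]))


def exact_event_start_probability(
    kernel,
    horizon_steps: int,
    threshold: float = HYPOTENSION_THRESHOLD_MMHG,
) -> np.ndarray:
    """Eligibility-conditioned probability that an event *starts* in the window.

    Returns an array ``p[c, s]`` over run counters ``c = 0..3`` and MAP
    states ``s``: the probability that a detected hypotensive event (a run
    of >= 3 consecutive below-threshold samples, preceded by an
    above-threshold sample or the start of a fresh run) begins at one of the
    next ``horizon_steps`` samples.

    For ``c`` in 1..2 the current sample sits inside a live below-threshold
    run; the probability is conditional on that run dying before it reaches
    3 samples, because otherwise the sample would lie inside an event and be
    excluded from forward-window denominators.  ``c = 3`` gives the
    unconditional next-event-start probability from inside an ongoing event
    (used only to assign an index value to in-event samples).

    An event whose run *starts* inside the window but accumulates its third
    sample after the window still counts, matching a forward search against
    detected event onset times.
    """
    if horizon_steps < 1:
        raise ConfigurationError("horizon_steps must be >= 1")
    P, grid, below = _resolve(kernel, threshold)
    S = len(grid)
    belowf = below.astype(float)

    # q[c]: P(a live run of length c reaches 3 with no break), unbounded time
    q2 = P @ belowf
    q1 = P @ (belowf * q2)

    # F[j]: P(event-start within r remaining window steps | state, current
    # *fresh* run length j), where j >= 1 means that run started inside the
    # window.  At r = 0 a live fresh run still counts if it completes.
    F0 = np.zeros(S)
    F1 = q1.copy()
    F2 = q2.copy()
    F0_hist = [F0.copy()]
    for _ in range(horizon_steps):
        n0 = P @ np.where(below, F1, F0)
        n1 = P @ np.where(below, F2, F0)
        n2 = P @ np.where(below, 1.0, F0)
        F0, F1, F2 = n0, n1, n2
        F0_hist.append(F0.copy())

    # Live original run (counter 1 or 2): joint DP over (event-start in
    # window) and (run dies before reaching 3).  G3: ongoing event.
    An1 = np.zeros(S); Ad1 = 1.0 - q1
    An2 = np.zeros(S); Ad2 = 1.0 - q2
    G3 = np.zeros(S)
    for r in range(1, horizon_steps + 1):
        Fprev = F0_hist[r - 1]
        n_An2 = P @ np.where(below, 0.0, Fprev)
        n_Ad2 = P @ np.where(below, 0.0, 1.0)
        n_An1 = P @ np.where(below, An2, Fprev)
        n_Ad1 = P @ np.where(below, Ad2, 1.0)
        n_G3 = P @ np.where(below, G3, Fprev)
        An1, Ad1, An2, Ad2, G3 = n_An1, n_Ad1, n_An2, n_Ad2, n_G3

    out = np.zeros((4, S))
    out[0] = F0_hist[horizon_steps]
    with np.errstate(invalid="ignore", divide="ignore"):
        out[1] = np.where(Ad1 > 0, An1 / np.maximum(Ad1, 1e-300), 0.0)
        out[2] = np.where(Ad2 > 0, An2 / np.maximum(Ad2, 1e-300), 0.0)
    out[3] = G3
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


@dataclass
class InterventionPolicy:
    """How aggressively the simulated clinician treats low MAP.

    When MAP falls to ``trigger_mmhg`` or below, the clinician notices after
    ``response_delay_steps`` and then intervenes with probability
    ``fire_prob``: a vasopressor bolus that lifts MAP by a Gaussian total
    rise spread over ``rise_steps`` steps.  A refractory period prevents
    immediate re-triggering.  Skin incision is modelled as one additional
    charted intervention early in each case, with its own small MAP rise.
    """

    enabled: bool = True
    trigger_mmhg: float = 65.0
    response_delay_steps: int = 9
    fire_prob: float = 0.5
    rise_mean_mmhg: float = 12.0
    rise_sd_mmhg: float = 3.0
    rise_steps: int = 2
    refractory_steps: int = 15
    incision_rise_mmhg: float = 8.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fire_prob <= 1.0:
            raise ConfigurationError("fire_prob outside [0, 1]")
        if self.rise_steps < 1 or self.response_delay_steps < 0:
            raise ConfigurationError("invalid intervention timing parameters")


#: Arm-specific clinician aggressiveness: unblinded clinicians see the
#: continuous pressure trace and respond sooner and more reliably.
ARM_POLICIES = {
    "blinded": InterventionPolicy(response_delay_steps=9, fire_prob=0.5),
    "unblinded": InterventionPolicy(response_delay_steps=4, fire_prob=0.85),
}

_VASOPRESSOR_KINDS = ("ephedrine", "phenylephrine", "epinephrine")
_VASOPRESSOR_PROBS = (0.35, 0.60, 0.05)


@dataclass
class SimulationConfig:
    """Full specification of one simulated arm of the cohort.

    ``duration_median_min`` and ``duration_log_sd`` set a log-normal
    distribution of per-patient monitoring durations (median ~202 min,
    interquartile range ~[154, 258] min at the defaults).
    ``index_noise_sd`` is additive Gaussian noise on the latent probability
    scale before scaling to 0-100 and clipping; zero gives a perfectly
    calibrated index.
    """

    n_patients: int = 305
    duration_median_min: float = 202.0
    duration_log_sd: float = 0.38
    duration_range_min: tuple[float, float] = (60.0, 480.0)
    sample_interval_s: int = DEFAULT_SAMPLE_INTERVAL_S
    kernel: TransitionKernel = field(default_factory=TransitionKernel)
    intervention_policy: InterventionPolicy | None = None
    index_noise_sd: float = 0.05
    horizon_min: float = 15.0
    arm: str = "blinded"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        if self.sample_interval_s <= 0:
            raise ConfigurationError("sample_interval_s must be > 0")
        if self.arm not in ("blinded", "unblinded"):
            raise ConfigurationError(f"unknown arm {self.arm!r}")
        if self.index_noise_sd < 0:
            raise ConfigurationError("index_noise_sd must be >= 0")

    def policy(self) -> InterventionPolicy:
        if self.intervention_policy is not None:
            return self.intervention_policy
        return ARM_POLICIES[self.arm]

    @property
    def horizon_steps(self) -> int:
        return int(round(self.horizon_min * 60 / self.sample_interval_s))


@dataclass
class GroundTruth:
    """Exact per-sample forward event probabilities and episode bookkeeping.

    ``true_prob[pid][t]`` is the eligibility-conditioned probability that a
    hypotensive event starts within the forward horizon of sample ``t``
    (see :func:`exact_event_start_probability`); computed from the
    transition kernel, never estimated by sampling.  Interventions perturb
    the realized chain away from the kernel, so these probabilities are
    exact only for cohorts simulated with the intervention policy disabled.
    """

    horizon_min: float
    prob_table: np.ndarray  # (4 run-counter levels, n_states)
    true_prob: dict[str, np.ndarray] = field(default_factory=dict)
    episode_onsets: dict[str, np.ndarray] = field(default_factory=dict)
    intervention_times: dict[str, np.ndarray] = field(default_factory=dict)


def _nearest_index(grid: np.ndarray, values: np.ndarray) -> np.ndarray:
    idx = np.clip(np.searchsorted(grid, values), 0, len(grid) - 1)
    left = np.clip(idx - 1, 0, len(grid) - 1)
    return np.where(np.abs(grid[left] - values) <= np.abs(grid[idx] - values), left, idx)


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[list[MonitoringRecord], list[Intervention], GroundTruth]:
    """Simulate one arm's monitoring records, intervention log and ground truth.

    Deterministic given ``config.seed``.  MAP values lie on the kernel grid;
    the index is ``clip(100 * (p_true + noise), 0, 100)`` where ``p_true``
    is the exact forward event-start probability of the current
    (state, run counter) and noise is Gaussian with ``index_noise_sd``.
    """
    rng = np.random.default_rng(config.seed)
    kernel = config.kernel
    grid = kernel.map_grid
    P = kernel.matrix()
    cumP = np.cumsum(P, axis=1)
    below = kernel.below_threshold()
    S = len(grid)
    n = config.n_patients
    dt = config.sample_interval_s
    policy = config.policy()
    H = config.horizon_steps

    prob_table = exact_event_start_probability(kernel, H)

    # Monitoring durations: log-normal, clipped to a plausible range.
    dur_min = np.exp(
        np.log(config.duration_median_min)
        + config.duration_log_sd * rng.standard_normal(n)
    )
    dur_min = np.clip(dur_min, *config.duration_range_min)
    n_steps = np.maximum((dur_min * 60 / dt).astype(int), 2 * H)
    T = int(n_steps.max())

    # Initial states near baseline.
    states = _nearest_index(grid, kernel.baseline_mmhg + rng.normal(0.0, 2.0, n))

    # Per-patient dynamic bookkeeping.
    run_len = np.where(below[states], 1, 0)
    pending = np.full(n, -1)          # steps until clinician notices (-1 idle)
    refractory = np.zeros(n, dtype=int)
    boost_left = np.zeros(n, dtype=int)
    boost_step = np.zeros(n)

    state_hist = np.zeros((T, n), dtype=np.int16)
    run_hist = np.zeros((T, n), dtype=np.int8)
    state_hist[0] = states
    run_hist[0] = np.minimum(run_len, 3)

    interventions: list[Intervention] = []
    pids = [f"{config.arm[0].upper()}{i + 1:04d}" for i in range(n)]

    # One charted skin incision per patient, early in the case.
    incision_step = rng.integers(15, 90, size=n)
    incision_done = np.zeros(n, dtype=bool)

    for t in range(1, T):
        active = t < n_steps
        # Markov transition for all active patients.
        u = rng.random(n)
        nxt = (u[:, None] > cumP[states]).sum(axis=1)
        states = np.where(active, nxt, states)

        if policy.enabled:
            # Incision: charted intervention plus a modest MAP lift.
            fire_inc = active & (~incision_done) & (t >= incision_step)
            for i in np.flatnonzero(fire_inc):
                interventions.append(Intervention(pids[i], int(t * dt), "incision"))
            incision_done |= fire_inc
            inc_lift = np.where(fire_inc, policy.incision_rise_mmhg / 2.0, 0.0)
            inc_steps = np.where(fire_inc, 2, 0)

            # Vasopressor response to low MAP, after a recognition delay.
            low = active & (grid[states] <= policy.trigger_mmhg)
            start = low & (pending < 0) & (refractory == 0) & (boost_left == 0)
            pending = np.where(start, policy.response_delay_steps, pending)
            due = pending == 0
            pending = np.where(pending > 0, pending - 1, pending)
            if np.any(due):
                fire = due & (rng.random(n) < policy.fire_prob) & active
                for i in np.flatnonzero(fire):
                    kind = rng.choice(_VASOPRESSOR_KINDS, p=_VASOPRESSOR_PROBS)
                    interventions.append(Intervention(pids[i], int(t * dt), str(kind)))
                rise = np.maximum(
                    rng.normal(policy.rise_mean_mmhg, policy.rise_sd_mmhg, n), 4.0
                )
                boost_left = np.where(fire, policy.rise_steps, boost_left)
                boost_step = np.where(fire, rise / policy.rise_steps, boost_step)
                refractory = np.where(due, policy.refractory_steps, refractory)
                pending = np.where(due, -1, pending)

            boost_left = np.maximum(boost_left, inc_steps)
            step_lift = np.where(boost_left > 0, np.maximum(boost_step, inc_lift), 0.0)
            lifted = boost_left > 0
            if np.any(lifted):
                states = np.where(
                    lifted, _nearest_index(grid, grid[states] + step_lift), states
                )
            boost_left = np.maximum(boost_left - 1, 0)
            refractory = np.maximum(refractory - 1, 0)

        run_len = np.where(below[states], run_len + 1, 0)
        state_hist[t] = states
        run_hist[t] = np.minimum(run_len, 3)

    # Index noise, drawn in one block for determinism.
    noise = (
        rng.normal(0.0, config.index_noise_sd, size=(T, n))
        if config.index_noise_sd > 0
        else np.zeros((T, n))
    )

    records: list[MonitoringRecord] = []
    truth = GroundTruth(horizon_min=config.horizon_min, prob_table=prob_table)
    ages = np.clip(rng.normal(60.0, 9.0, n), 45.0, 90.0)
    weights = np.clip(rng.normal(98.0, 28.0, n), 40.0, 200.0)
    heights = np.clip(rng.normal(171.0, 10.0, n), 140.0, 205.0)
    sexes = rng.choice(["F", "M"], size=n)

    iv_by_pid: dict[str, list[int]] = {pid: [] for pid in pids}
    for iv in interventions:
        iv_by_pid[iv.patient_id].append(iv.time_s)

    for i, pid in enumerate(pids):
        k = int(n_steps[i])
        st = state_hist[:k, i].astype(int)
        rl = run_hist[:k, i].astype(int)
        p_true = prob_table[rl, st]
        index = np.clip(100.0 * (p_true + noise[:k, i]), 0.0, 100.0)
        times = np.arange(k, dtype=np.int64) * dt
        records.append(
            MonitoringRecord(
                patient_id=pid,
                times_s=times,
                map_mmhg=grid[st],
                index_value=index,
                age_years=float(round(ages[i], 1)),
                sex=str(sexes[i]),
                height_cm=float(round(heights[i], 1)),
                weight_kg=float(round(weights[i], 1)),
                arm=config.arm,
                sample_interval_s=dt,
            )
        )
        truth.true_prob[pid] = p_true
        # Episode onsets: first sample of each run of >= 3 below threshold,
        # the same criterion the event detector applies.
        b = below[st]
        onsets = []
        j = 0
        while j < k:
            if b[j]:
                j2 = j
                while j2 + 1 < k and b[j2 + 1]:
                    j2 += 1
                if j2 - j + 1 >= 3:
                    onsets.append(times[j])
                j = j2 + 1
            else:
                j += 1
        truth.episode_onsets[pid] = np.asarray(onsets, dtype=np.int64)
        truth.intervention_times[pid] = np.asarray(sorted(iv_by_pid[pid]), dtype=np.int64)

    return records, interventions, truth


def simulate_trial_cohort(
    n_blinded: int = 150,
    n_unblinded: int = 155,
    seed: int = 0,
    **overrides,
) -> tuple[list[MonitoringRecord], list[Intervention], GroundTruth]:
    """Simulate a two-arm trial cohort (blinded + unblinded clinicians).

    Arms are simulated independently with seeds derived from ``seed``;
    keyword overrides are applied to both arm configs.
    """
    ss = np.random.SeedSequence(seed).spawn(2)
    out_records: list[MonitoringRecord] = []
    out_iv: list[Intervention] = []
    truth_all: GroundTruth | None = None
    for arm, n_arm, child in (
        ("blinded", n_blinded, ss[0]),
        ("unblinded", n_unblinded, ss[1]),
    ):
        cfg = SimulationConfig(
            n_patients=n_arm,
            arm=arm,
            seed=int(child.generate_state(1)[0] % (2**31)),
            **overrides,
        )
        recs, ivs, truth = simulate_cohort(cfg)
        out_records.extend(recs)
        out_iv.extend(ivs)
        if truth_all is None:
            truth_all = truth
        else:
            truth_all.true_prob.update(truth.true_prob)
            truth_all.episode_onsets.update(truth.episode_onsets)
            truth_all.intervention_times.update(truth.intervention_times)
    assert truth_all is not None
    return out_records, out_iv, truth_all


def calibration_config(
    n_patients: int = 300, seed: int = 0, **overrides
) -> SimulationConfig:
    """Config for identity-line calibration studies: noise-free index,
    interventions disabled so the realized chain follows the kernel exactly."""
    kwargs = dict(
        n_patients=n_patients,
        index_noise_sd=0.0,
        intervention_policy=InterventionPolicy(enabled=False),
        seed=seed,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)
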