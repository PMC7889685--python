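import numpy as np
import pytest

from hypobench import (
    MonitoringRecord,
    SimulationConfig,
    calibration_config,
    detect_events,
    find_nonevent_segments,
    simulate_cohort,
    simulate_trial_cohort,
)


def make_record(
    map_mmhg,
    index=None,
    times=None,
    patient_id="P1",
    dt=20,
    **kwargs,
):
    """Build a small MonitoringRecord from plain lists."""
    map_mmhg = np.asarray(map_mmhg, dtype=float)
    n = len(map_mmhg)
    if times is None:
        times = np.arange(n) * dt
    if index is None:
        index = np.zeros(n)
    return MonitoringRecord(
        patient_id=patient_id,
        times_s=np.asarray(times),
        map_mmhg=map_mmhg,
        index_value=np.asarray(index, dtype=float),
        sample_interval_s=dt,
        **kwargs,
    )


@pytest.fixture(scope="session")
def trial_cohort():
    """Small two-arm cohort with interventions and index noise."""
    records, interventions, truth = simulate_trial_cohort(40, 40, seed=11)
    events = {r.patient_id: detect_events(r) for r in records}
    segments = {
        r.patient_id: find_nonevent_segments(r, events[r.patient_id]) for r in records
    }
    return {
        "records": records,
        "interventions": interventions,
        "truth": truth,
        "events": events,
        "segments": segments,
    }


@pytest.fixture(scope="session")
def calibration_cohort():
    """300 patients, noise-free calibrated index, interventions disabled."""
    cfg = calibration_config(n_patients=300, seed=0)
    records, interventions, truth = simulate_cohort(cfg)
    events = {r.patient_id: detect_events(r) for r in records}
    return {
        "config": cfg,
        "records": records,
        "truth": truth,
        "events": events,
    }
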