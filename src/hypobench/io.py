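"""Cohort CSV input/output and report rendering.

The interchange format is four flat CSV files on the 20-s grid — traces,
interventions, demographics, and (for synthetic cohorts) ground truth —
with times stored as integer seconds from monitoring start.
"""
from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .records import (
    CohortBundle,
    Intervention,
    MonitoringRecord,
    ValidationError,
)

logger = logging.getLogger(__name__)

TRACE_COLUMNS = ["patient_id", "time_s", "map_mmhg", "index"]
INTERVENTION_COLUMNS = ["patient_id", "time_s", "kind"]
DEMOGRAPHICS_COLUMNS = ["patient_id", "age", "sex", "height_cm", "weight_kg", "arm"]
GROUND_TRUTH_COLUMNS = ["patient_id", "time_s", "true_prob"]


def write_cohort(
    records: list[MonitoringRecord],
    interventions: list[Intervention],
    out_dir,
    true_prob: dict[str, np.ndarray] | None = None,
    config: dict | None = None,
) -> dict[str, Path]:
    """Write a cohort as traces/interventions/demographics (+ ground truth) CSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    traces = pd.concat(
        [
            pd.DataFrame(
                {
                    "patient_id": r.patient_id,
                    "time_s": r.times_s,
                    "map_mmhg": r.map_mmhg,
                    "index": r.index_value,
                }
            )
            for r in records
        ],
        ignore_index=True,
    )
    paths["traces"] = out_dir / "traces.csv"
    traces.to_csv(paths["traces"], index=False)

    iv = pd.DataFrame(
        [(i.patient_id, i.time_s, i.kind) for i in interventions],
        columns=INTERVENTION_COLUMNS,
    )
    paths["interventions"] = out_dir / "interventions.csv"
    iv.to_csv(paths["interventions"], index=False)

    demo = pd.DataFrame(
        [
            (r.patient_id, r.age_years, r.sex, r.height_cm, r.weight_kg, r.arm)
            for r in records
        ],
        columns=DEMOGRAPHICS_COLUMNS,
    )
    paths["demographics"] = out_dir / "demographics.csv"
    demo.to_csv(paths["demographics"], index=False)

    if true_prob is not None:
        gt = pd.concat(
            [
                pd.DataFrame(
                    {
                        "patient_id": r.patient_id,
                        "time_s": r.times_s,
                        "true_prob": true_prob[r.patient_id],
                    }
                )
                for r in records
            ],
            ignore_index=True,
        )
        paths["ground_truth"] = out_dir / "ground_truth.csv"
        gt.to_csv(paths["ground_truth"], index=False)

    if config is not None:
        paths["config"] = out_dir / "cohort_config.yaml"
        paths["config"].write_text(yaml.safe_dump(config, sort_keys=True))
    return paths


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")


def read_cohort(
    trace_path,
    intervention_path=None,
    demographics_path=None,
    sample_interval_s: int = 20,
) -> CohortBundle:
    """Read and validate a cohort from CSV files.

    Rows with non-numeric MAP or an index outside [0, 100] are rejected
    with row-level diagnostics (a blank index is a missing value, kept as
    NaN).  Duplicate (patient, time) rows and unsorted times raise schema
    errors naming the offending row; grid spacings deviating from the
    nominal interval are logged.
    """
    trace_path = Path(trace_path)
    traces = pd.read_csv(trace_path)
    if traces.empty:
        raise ValidationError(f"{trace_path}: empty trace file")
    _require_columns(traces, TRACE_COLUMNS, trace_path)

    n_raw = len(traces)
    traces["map_mmhg"] = pd.to_numeric(traces["map_mmhg"], errors="coerce")
    traces["index"] = pd.to_numeric(traces["index"], errors="coerce")
    bad_map = traces["map_mmhg"].isna() | (traces["map_mmhg"] <= 0)
    bad_idx = traces["index"].notna() & (
        (traces["index"] < 0) | (traces["index"] > 100)
    )
    n_rejected = int((bad_map | bad_idx).sum())
    if n_rejected:
        rows = traces.index[bad_map | bad_idx].tolist()[:10]
        logger.warning(
            "%s: rejected %d row(s) with invalid MAP/index (first rows: %s)",
            trace_path, n_rejected, rows,
        )
        traces = traces[~(bad_map | bad_idx)]
    if traces.empty:
        raise ValidationError(f"{trace_path}: no valid rows after validation")

    dupes = traces.duplicated(subset=["patient_id", "time_s"])
    if dupes.any():
        raise ValidationError(
            f"{trace_path}: duplicate (patient_id, time_s) at row "
            f"{int(traces.index[dupes][0])}"
        )

    demo = None
    if demographics_path is not None:
        demo = pd.read_csv(demographics_path)
        _require_columns(
            demo, ["patient_id", "age", "sex", "height_cm", "weight_kg"], demographics_path
        )
        demo = demo.set_index("patient_id")

    records = []
    for pid, grp in traces.groupby("patient_id", sort=True):
        times = grp["time_s"].to_numpy(dtype=np.int64)
        if not np.all(np.diff(times) > 0):
            row = int(grp.index[np.argmin(np.diff(times) > 0) + 1])
            raise ValidationError(f"{trace_path}: unsorted times for {pid} at row {row}")
        dt = np.diff(times)
        off_grid = int(np.sum(dt != sample_interval_s))
        if off_grid:
            logger.info(
                "%s: %d step(s) deviate from the nominal %d-s grid", pid, off_grid,
                sample_interval_s,
            )
        kwargs = {}
        if demo is not None and pid in demo.index:
            d = demo.loc[pid]
            kwargs = dict(
                age_years=float(d["age"]),
                sex=str(d["sex"]),
                height_cm=float(d["height_cm"]),
                weight_kg=float(d["weight_kg"]),
            )
            if "arm" in demo.columns:
                kwargs["arm"] = str(d["arm"])
        records.append(
            MonitoringRecord(
                patient_id=str(pid),
                times_s=times,
                map_mmhg=grp["map_mmhg"].to_numpy(dtype=float),
                index_value=grp["index"].to_numpy(dtype=float),
                sample_interval_s=sample_interval_s,
                **kwargs,
            )
        )

    interventions = []
    if intervention_path is not None:
        iv = pd.read_csv(intervention_path)
        if len(iv):
            _require_columns(iv, INTERVENTION_COLUMNS, intervention_path)
            interventions = [
                Intervention(str(r.patient_id), int(r.time_s), str(r.kind))
                for r in iv.itertuples()
            ]

    provenance = {
        "trace_path": str(trace_path),
        "intervention_path": str(intervention_path) if intervention_path else None,
        "demographics_path": str(demographics_path) if demographics_path else None,
        "n_rows_read": n_raw,
        "n_rows_rejected": n_rejected,
    }
    return CohortBundle(records=records, interventions=interventions, provenance=provenance)


def read_ground_truth(path) -> dict[str, np.ndarray]:
    """Read the per-sample true forward probabilities written by the simulator."""
    gt = pd.read_csv(path)
    _require_columns(gt, GROUND_TRUTH_COLUMNS, path)
    return {
        str(pid): grp.sort_values("time_s")["true_prob"].to_numpy(dtype=float)
        for pid, grp in gt.groupby("patient_id")
    }


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------


def _fmt(x, nd=1) -> str:
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return "–"  # en dash for empty cells
    return f"{x:.{nd}f}"


def write_report(report, out_dir) -> dict[str, Path]:
    """Write an :class:`~hypobench.pipeline.EvaluationReport` to disk.

    Emits the burden table, ROC table, event-rate table and PPV summary as
    CSVs, a human-readable text rendering (rates and times to 1 decimal,
    AUC to 2), and a machine-readable run manifest.  Regenerating from the
    same report object produces byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["burden_patients"] = out_dir / "burden_per_patient.csv"
    report.burden_per_patient.to_csv(paths["burden_patients"], index=False)
    paths["burden"] = out_dir / "burden_table.csv"
    report.burden_cohort.to_csv(paths["burden"], index=False)

    roc_df = pd.DataFrame(
        [
            {
                "horizon_min": r.horizon_min,
                "auc": r.auc,
                "auc_lo": r.auc_ci_95[0],
                "auc_hi": r.auc_ci_95[1],
                "sensitivity": r.sensitivity,
                "sensitivity_lo": r.sensitivity_ci_95[0],
                "sensitivity_hi": r.sensitivity_ci_95[1],
                "specificity": r.specificity,
                "specificity_lo": r.specificity_ci_95[0],
                "specificity_hi": r.specificity_ci_95[1],
                "threshold": r.optimal_threshold,
                "n_pos": r.n_pos,
                "n_neg": r.n_neg,
            }
            for r in report.roc_results
        ]
    )
    paths["roc"] = out_dir / "roc_table.csv"
    roc_df.to_csv(paths["roc"], index=False)

    er_df = pd.DataFrame(
        [
            {
                "bin": b.label,
                "event_rate_pct": b.event_rate_pct,
                "rate_lo": b.event_rate_ci_95[0],
                "rate_hi": b.event_rate_ci_95[1],
                "median_tte_min": b.median_time_to_event_min,
                "median_lo": b.median_ci_95[0],
                "median_hi": b.median_ci_95[1],
                "q25_tte_min": b.q25_time_to_event_min,
                "q75_tte_min": b.q75_time_to_event_min,
                "n_event_samples": b.n_event_samples,
                "n_total_samples": b.n_total_samples,
            }
            for b in report.event_rate_bins
        ]
    )
    paths["event_rate"] = out_dir / "event_rate_table.csv"
    er_df.to_csv(paths["event_rate"], index=False)

    ppv_df = pd.DataFrame(
        [
            {
                "threshold": report.ppv.threshold,
                "ppv": report.ppv.ppv,
                "ppv_lo": report.ppv.ppv_ci_95[0],
                "ppv_hi": report.ppv.ppv_ci_95[1],
                "n_true_positive": report.ppv.n_true_positive,
                "n_false_positive": report.ppv.n_false_positive,
                "n_excluded": report.ppv.n_excluded,
            }
        ]
    )
    paths["ppv"] = out_dir / "ppv_summary.csv"
    ppv_df.to_csv(paths["ppv"], index=False)

    lines = []
    lines.append("Hypotension burden (median [q25, q75])")
    for _, row in report.burden_cohort.iterrows():
        lines.append(
            f"  {row['metric']:<28s} {_fmt(row['median'], 2)} "
            f"[{_fmt(row['q25'], 2)}, {_fmt(row['q75'], 2)}]"
        )
    lines.append("")
    lines.append("ROC by prediction horizon (optimal threshold: |sens - spec| minimal)")
    for r in report.roc_results:
        lines.append(
            f"  {r.horizon_min:>2d} min  AUC {_fmt(r.auc, 2)} "
            f"[{_fmt(r.auc_ci_95[0], 2)}, {_fmt(r.auc_ci_95[1], 2)}]  "
            f"sens {_fmt(r.sensitivity, 2)}  spec {_fmt(r.specificity, 2)}  "
            f"threshold {_fmt(r.optimal_threshold, 0)}  "
            f"({r.n_pos} pos / {r.n_neg} neg)"
        )
    lines.append("")
    lines.append("Event rate by index bin (15-min forward window)")
    for b in report.event_rate_bins:
        lines.append(
            f"  {b.label:>6s}  rate {_fmt(b.event_rate_pct)}% "
            f"[{_fmt(b.event_rate_ci_95[0])}, {_fmt(b.event_rate_ci_95[1])}]  "
            f"median tte {_fmt(b.median_time_to_event_min)} min "
            f"[{_fmt(b.q25_time_to_event_min)}, {_fmt(b.q75_time_to_event_min)}]  "
            f"{b.n_event_samples}/{b.n_total_samples}"
        )
    lines.append("")
    p = report.ppv
    lines.append(
        f"PPV at index > {_fmt(p.threshold, 0)}: {_fmt(p.ppv, 2)} "
        f"[{_fmt(p.ppv_ci_95[0], 2)}, {_fmt(p.ppv_ci_95[1], 2)}] "
        f"(TP {p.n_true_positive}, FP {p.n_false_positive}, excluded {p.n_excluded})"
    )
    paths["text"] = out_dir / "report.txt"
    paths["text"].write_text("\n".join(lines) + "\n")

    paths["manifest"] = out_dir / "manifest.json"
    paths["manifest"].write_text(json.dumps(report.manifest, indent=2, sort_keys=True) + "\n")
    return paths


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
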