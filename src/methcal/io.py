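"""CSV readers and writers for Ct tables, trace matrices and result tables.

All tables are UTF-8 CSV with a header row and "." decimals. Ct tables use
long format (sample_id, condition, replicate, ct) with an empty ct cell
meaning no amplification. Trace matrices put time (seconds) in the first
column and one ROI per remaining column. Sample indices in outputs are
0-based.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .calcium import ActivitySummary, EventSet, RawTrace
from .methqpcr import (
    CONDITIONS,
    NO_AMPLIFICATION,
    CtMeasurement,
    MethylationEstimate,
)

__all__ = [
    "read_ct_table",
    "write_ct_table",
    "read_calibration_table",
    "write_calibration_table",
    "read_trace_matrix",
    "write_trace_matrix",
    "write_estimates",
    "write_event_table",
    "write_activity_summaries",
    "write_ground_truth",
]

CT_COLUMNS = ("sample_id", "condition", "replicate", "ct")


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def _parse_ct_rows(df: pd.DataFrame, path: Path) -> dict[tuple[str, str], list[tuple[int, float]]]:
    groups: dict[tuple[str, str], list[tuple[int, float]]] = {}
    seen: set[tuple[str, str, int]] = set()
    for row_number, row in enumerate(df.itertuples(index=False), start=2):
        sample_id = str(row.sample_id)
        condition = str(row.condition)
        if condition not in CONDITIONS:
            raise ValueError(
                f"{path}, row {row_number}: unknown condition {condition!r}; "
                f"expected one of {CONDITIONS}"
            )
        try:
            replicate = int(row.replicate)
        except (TypeError, ValueError):
            raise ValueError(
                f"{path}, row {row_number}: non-integer replicate {row.replicate!r}"
            ) from None
        key = (sample_id, condition, replicate)
        if key in seen:
            raise ValueError(
                f"{path}, row {row_number}: duplicate (sample, condition, replicate) {key}"
            )
        seen.add(key)
        raw_ct = row.ct
        if raw_ct is None or (isinstance(raw_ct, float) and np.isnan(raw_ct)) or raw_ct == "":
            ct = NO_AMPLIFICATION
        else:
            try:
                ct = float(raw_ct)
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}, row {row_number}: non-numeric ct value {raw_ct!r}"
                ) from None
            if not np.isfinite(ct) or ct <= 0:
                raise ValueError(
                    f"{path}, row {row_number}: ct must be finite and > 0, got {ct!r}"
                )
        groups.setdefault((sample_id, condition), []).append((replicate, ct))
    return groups


def read_ct_table(path: str | Path) -> list[CtMeasurement]:
    """Read a long-format Ct table into per-(sample, condition) measurements.

    Rows are grouped by (sample_id, condition); replicates are ordered by
    their replicate number. Empty ct cells become the no-amplification
    sentinel; unknown condition labels and duplicate replicate keys are
    rejected with the offending row number.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"ct": "object"})
    _require_columns(df, CT_COLUMNS, path)
    groups = _parse_ct_rows(df[list(CT_COLUMNS)], path)
    measurements = []
    for (sample_id, condition), reps in sorted(groups.items()):
        reps.sort()
        measurements.append(
            CtMeasurement(
                sample_id=sample_id,
                condition=condition,
                ct_values=tuple(ct for _, ct in reps),
            )
        )
    return measurements


def group_by_sample(
    measurements: Iterable[CtMeasurement],
) -> dict[str, dict[str, CtMeasurement]]:
    """Index measurements as sample_id -> condition -> measurement."""
    by_sample: dict[str, dict[str, CtMeasurement]] = {}
    for m in measurements:
        by_sample.setdefault(m.sample_id, {})[m.condition] = m
    return by_sample


def _ct_rows(measurements: Iterable[CtMeasurement]) -> list[dict]:
    rows = []
    for m in measurements:
        for replicate, ct in enumerate(m.ct_values):
            rows.append(
                {
                    "sample_id": m.sample_id,
                    "condition": m.condition,
                    "replicate": replicate,
                    "ct": "" if ct == NO_AMPLIFICATION else ct,
                }
            )
    return rows


def write_ct_table(measurements: Iterable[CtMeasurement], path: str | Path) -> None:
    pd.DataFrame(_ct_rows(measurements), columns=list(CT_COLUMNS)).to_csv(path, index=False)


def write_calibration_table(
    calibration: Sequence[tuple[float, Mapping[str, CtMeasurement]]],
    path: str | Path,
) -> None:
    """Calibration tables add a known_fraction column to the Ct layout."""
    rows = []
    for fraction, conditions in calibration:
        for row in _ct_rows(conditions.values()):
            rows.append({"known_fraction": fraction, **row})
    columns = ["known_fraction", *CT_COLUMNS]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


def read_calibration_table(
    path: str | Path,
) -> list[tuple[float, dict[str, CtMeasurement]]]:
    """Read a calibration Ct table (columns: known_fraction + Ct layout)."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"ct": "object"})
    _require_columns(df, ("known_fraction", *CT_COLUMNS), path)
    out = []
    for fraction, sub in df.groupby("known_fraction", sort=True):
        fraction = float(fraction)
        if not 0.0 <= fraction <= 1.0:
            raise ValueError(f"{path}: known_fraction must lie in [0, 1], got {fraction}")
        groups = _parse_ct_rows(sub[list(CT_COLUMNS)], path)
        conditions: dict[str, CtMeasurement] = {}
        for (sample_id, condition), reps in sorted(groups.items()):
            reps.sort()
            conditions[condition] = CtMeasurement(
                sample_id=sample_id,
                condition=condition,
                ct_values=tuple(ct for _, ct in reps),
            )
        out.append((fraction, conditions))
    return out


def read_trace_matrix(path: str | Path, sampling_interval: float) -> list[RawTrace]:
    """Read a trace matrix CSV into one RawTrace per ROI column.

    The first column is a time stamp or sample index and is ignored in favor
    of the declared sampling interval. Ragged rows, fewer than 4 samples and
    non-positive or non-finite intensities are rejected.
    """
    path = Path(path)
    if sampling_interval <= 0:
        raise ValueError("sampling_interval must be > 0")
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed CSV ({exc})") from exc
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need a time/index column plus at least one ROI column")
    if df.shape[0] < 4:
        raise ValueError(f"{path}: traces need at least 4 samples, got {df.shape[0]}")
    traces = []
    for roi_id in df.columns[1:]:
        col = pd.to_numeric(df[roi_id], errors="coerce").to_numpy(dtype=float)
        bad = ~np.isfinite(col)
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 2
            raise ValueError(f"{path}, row {row}, column {roi_id!r}: non-finite or non-numeric value")
        nonpos = col <= 0
        if nonpos.any():
            row = int(np.flatnonzero(nonpos)[0]) + 2
            raise ValueError(f"{path}, row {row}, column {roi_id!r}: non-positive intensity")
        traces.append(
            RawTrace(roi_id=str(roi_id), sampling_interval=sampling_interval, intensities=col)
        )
    return traces


def write_trace_matrix(traces: Sequence[RawTrace], path: str | Path) -> None:
    if not traces:
        raise ValueError("no traces to write")
    n = traces[0].n_samples
    interval = traces[0].sampling_interval
    for t in traces:
        if t.n_samples != n:
            raise ValueError("all traces in one matrix must share a length")
    data = {"time_s": np.arange(n) * interval}
    for t in traces:
        data[t.roi_id] = t.intensities
    pd.DataFrame(data).to_csv(path, index=False)


def write_estimates(estimates: Sequence[MethylationEstimate], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": e.sample_id,
                "fraction": e.fraction,
                "raw_fraction": e.raw_fraction,
                "R": e.relative_amplification,
                "clamped": e.clamped,
                "qc_pass": e.qc_pass,
            }
            for e in estimates
        ],
        columns=["sample_id", "fraction", "raw_fraction", "R", "clamped", "qc_pass"],
    ).to_csv(path, index=False)


def write_event_table(event_sets: Sequence[EventSet], path: str | Path) -> None:
    """Per-event rows; event_index is the 0-based sample index of the peak."""
    rows = []
    for es in event_sets:
        for idx, amp in zip(es.event_indices, es.amplitudes):
            rows.append(
                {
                    "roi_id": es.roi_id,
                    "event_index": idx,
                    "amplitude_dff": amp,
                    "threshold_dff": es.threshold,
                }
            )
    pd.DataFrame(
        rows, columns=["roi_id", "event_index", "amplitude_dff", "threshold_dff"]
    ).to_csv(path, index=False)


def write_activity_summaries(
    summaries: Sequence[ActivitySummary], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {
                "roi_id": s.roi_id,
                "n_events": s.n_events,
                "duration_s": s.duration,
                "rate_per_min": s.rate,
                "included": s.included,
            }
            for s in summaries
        ],
        columns=["roi_id", "n_events", "duration_s", "rate_per_min", "included"],
    ).to_csv(path, index=False)


def write_ground_truth(truth, path: str | Path) -> None:
    """JSON sidecar for simulation ground truth."""
    payload = {}
    if truth.true_methylation_fraction is not None:
        payload["true_methylation_fraction"] = truth.true_methylation_fraction
    if truth.event_onsets is not None:
        payload["event_onsets"] = [list(cell) for cell in truth.event_onsets]
    Path(path).write_text(json.dumps(payload, indent=2))
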