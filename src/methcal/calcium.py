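"""Calcium-transient detection on ROI fluorescence time series.

Pipeline per ROI: dF/F0 normalization against a low-percentile baseline,
candidate detection on a three-difference pattern (rise, non-positive change,
fall), a dynamic threshold of 2x the unscaled MAD of the normalized trace
with a fixed floor, de-duplication of candidates not separated by a
sub-threshold dip, and an events-per-minute activity rate. Cells with no
retained event are flagged excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "RawTrace",
    "NormalizedTrace",
    "DetectionParams",
    "EventSet",
    "ActivitySummary",
    "DetectionScore",
    "normalize_dff",
    "compute_threshold",
    "detect_candidates",
    "filter_by_threshold",
    "deduplicate_events",
    "activity_rate",
    "detect_events",
    "evaluate_detection",
]


@dataclass
class RawTrace:
    """One ROI's raw fluorescence trace at a fixed sampling interval."""

    roi_id: str
    sampling_interval: float
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.sampling_interval <= 0:
            raise ValueError(f"ROI {self.roi_id!r}: sampling_interval must be > 0")
        if self.intensities.ndim != 1 or self.intensities.size < 4:
            raise ValueError(
                f"ROI {self.roi_id!r}: trace must be 1-D with at least 4 samples"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError(f"ROI {self.roi_id!r}: trace contains non-finite values")
        if np.any(self.intensities <= 0):
            raise ValueError(f"ROI {self.roi_id!r}: intensities must be positive")

    @property
    def n_samples(self) -> int:
        return int(self.intensities.size)

    @property
    def duration(self) -> float:
        """Session duration in seconds (n_samples x sampling_interval)."""
        return self.n_samples * self.sampling_interval


@dataclass
class NormalizedTrace:
    roi_id: str
    dff: np.ndarray
    f0: float
    sampling_interval: float

    @property
    def n_samples(self) -> int:
        return int(self.dff.size)

    @property
    def duration(self) -> float:
        return self.n_samples * self.sampling_interval


@dataclass(frozen=True)
class DetectionParams:
    """Detection constants. Defaults: threshold = max(2 x MAD, 0.1); baseline
    F0 = lower 5th percentile of the session; events anchored at the peak."""

    mad_multiplier: float = 2.0
    threshold_floor: float = 0.1
    f0_percentile: float = 5.0
    anchor: str = "peak"  # "peak" or "onset" (sample before the rise)

    def __post_init__(self) -> None:
        if self.mad_multiplier <= 0:
            raise ValueError("mad_multiplier must be > 0")
        if self.threshold_floor < 0:
            raise ValueError("threshold_floor must be >= 0")
        if not 0 <= self.f0_percentile <= 100:
            raise ValueError("f0_percentile must lie in [0, 100]")
        if self.anchor not in ("peak", "onset"):
            raise ValueError("anchor must be 'peak' or 'onset'")


@dataclass(frozen=True)
class EventSet:
    """Retained transient events for one ROI.

    Invariants: indices strictly increasing, every amplitude strictly above
    the threshold, and the dF/F0 trace dips below the threshold between
    consecutive events.
    """

    roi_id: str
    event_indices: tuple[int, ...]
    amplitudes: tuple[float, ...]
    threshold: float

    def __post_init__(self) -> None:
        if len(self.event_indices) != len(self.amplitudes):
            raise ValueError("event_indices and amplitudes must have equal length")
        if any(b <= a for a, b in zip(self.event_indices, self.event_indices[1:])):
            raise ValueError("event indices must be strictly increasing")
        if any(a <= self.threshold for a in self.amplitudes):
            raise ValueError("every event amplitude must exceed the threshold")

    @property
    def n_events(self) -> int:
        return len(self.event_indices)


@dataclass(frozen=True)
class ActivitySummary:
    roi_id: str
    n_events: int
    duration: float  # seconds
    rate: float  # events per minute
    included: bool


@dataclass(frozen=True)
class DetectionScore:
    precision: float
    recall: float
    n_matched: int
    n_detected: int
    n_true: int
    precision_defined: bool


def normalize_dff(trace: RawTrace, params: DetectionParams = DetectionParams()) -> NormalizedTrace:
    """dF/F0 = (F - F0) / F0 with F0 the ``f0_percentile``-th percentile of
    the session (linear interpolation between order statistics)."""
    f0 = float(np.percentile(trace.intensities, params.f0_percentile))
    if f0 <= 0:
        raise ValueError(
            f"ROI {trace.roi_id!r}: baseline percentile F0 = {f0} is not positive"
        )
    dff = (trace.intensities - f0) / f0
    return NormalizedTrace(
        roi_id=trace.roi_id, dff=dff, f0=f0, sampling_interval=trace.sampling_interval
    )


def compute_threshold(
    norm: NormalizedTrace, params: DetectionParams = DetectionParams()
) -> float:
    """Dynamic threshold: max(mad_multiplier x MAD, threshold_floor).

    MAD is the raw median absolute deviation from the median, without the
    1.4826 normal-consistency factor.
    """
    med = np.median(norm.dff)
    mad = float(np.median(np.abs(norm.dff - med)))
    return max(params.mad_multiplier * mad, params.threshold_floor)


def detect_candidates(
    norm: NormalizedTrace, anchor: str = "peak"
) -> np.ndarray:
    """Candidate events from the pattern of three consecutive differences:
    positive, then non-positive, then negative.

    With d[i] = dff[i+1] - dff[i], sample t is a candidate iff d[t-1] > 0,
    d[t] <= 0 and d[t+1] < 0 — i.e. t is the local peak (or plateau start).
    No candidate can occur at the first sample or the last two. ``anchor``
    "onset" shifts reported indices to the sample before the rise.
    """
    d = np.diff(norm.dff)
    hits = (d[:-2] > 0) & (d[1:-1] <= 0) & (d[2:] < 0)
    candidates = np.flatnonzero(hits) + 1
    if anchor == "onset":
        candidates = candidates - 1
    elif anchor != "peak":
        raise ValueError("anchor must be 'peak' or 'onset'")
    return candidates


def filter_by_threshold(
    candidates: Sequence[int], norm: NormalizedTrace, threshold: float
) -> np.ndarray:
    """Keep candidates whose dF/F0 strictly exceeds the threshold."""
    candidates = np.asarray(candidates, dtype=int)
    if candidates.size == 0:
        return candidates
    return candidates[norm.dff[candidates] > threshold]


def deduplicate_events(
    events: Sequence[int], norm: NormalizedTrace, threshold: float
) -> EventSet:
    """Merge events not separated by a sub-threshold dip into single peaks.

    Consecutive supra-threshold events belong to the same peak unless the
    trace drops strictly below the threshold somewhere strictly between them.
    Each group is represented by its highest-amplitude member (earliest on
    ties).
    """
    events = sorted(int(e) for e in events)
    dff = norm.dff
    groups: list[list[int]] = []
    for e in events:
        if groups:
            prev = groups[-1][-1]
            between = dff[prev + 1 : e]
            separated = between.size > 0 and float(between.min()) < threshold
        else:
            separated = True
        if separated:
            groups.append([e])
        else:
            groups[-1].append(e)
    kept: list[int] = []
    for group in groups:
        best = max(group, key=lambda i: (dff[i], -i))
        kept.append(best)
    return EventSet(
        roi_id=norm.roi_id,
        event_indices=tuple(kept),
        amplitudes=tuple(float(dff[i]) for i in kept),
        threshold=float(threshold),
    )


def activity_rate(events: EventSet, duration: float) -> ActivitySummary:
    """Events per minute over the session; zero-event cells are excluded."""
    if duration <= 0:
        raise ValueError(f"ROI {events.roi_id!r}: duration must be > 0")
    n = events.n_events
    return ActivitySummary(
        roi_id=events.roi_id,
        n_events=n,
        duration=float(duration),
        rate=n / (duration / 60.0),
        included=n > 0,
    )


def detect_events(
    trace: RawTrace, params: DetectionParams = DetectionParams()
) -> tuple[EventSet, ActivitySummary]:
    """Full staged detector: normalize, threshold, candidates, filter,
    de-duplicate, rate."""
    norm = normalize_dff(trace, params)
    threshold = compute_threshold(norm, params)
    candidates = detect_candidates(norm, anchor=params.anchor)
    retained = filter_by_threshold(candidates, norm, threshold)
    events = deduplicate_events(retained, norm, threshold)
    summary = activity_rate(events, trace.duration)
    return events, summary


def evaluate_detection(
    detected: Sequence[int], truth: Sequence[int], tolerance: int = 3
) -> DetectionScore:
    """Greedy earliest-first one-to-one matching of detected event indices to
    true onsets within +/- tolerance samples.

    Precision with zero detections is reported as 0 and flagged undefined.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    detected = sorted(int(i) for i in detected)
    truth = sorted(int(i) for i in truth)
    matched = 0
    j = 0
    for d in detected:
        while j < len(truth) and truth[j] < d - tolerance:
            j += 1
        if j < len(truth) and abs(truth[j] - d) <= tolerance:
            matched += 1
            j += 1
    precision_defined = len(detected) > 0
    precision = matched / len(detected) if precision_defined else 0.0
    recall = matched / len(truth) if truth else (1.0 if not detected else 0.0)
    return DetectionScore(
        precision=precision,
        recall=recall,
        n_matched=matched,
        n_detected=len(detected),
        n_true=len(truth),
        precision_defined=precision_defined,
    )
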