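"""Synthetic generators with known ground truth for both assay arms.

Digestion arm: a locus with a known allele configuration is digested in
silico; a template copy survives the methylation-sensitive digest when it is
methylated or escapes cutting. With surviving template fraction s, the
simulated threshold cycle is ``base_ct - log(s)/log(E)`` plus replicate
noise, so relative amplification recovers s exactly in the noiseless limit.

Calcium arm: per-cell fluorescence traces are a positive baseline modulated
by slow sinusoidal drift, plus transients (linear rise to a drawn amplitude,
then single-exponential decay) at Poisson onsets thinned by a refractory
window, plus additive Gaussian noise. Ground-truth event indices are the
kernel peak samples, which is where the detector anchors events.

One seed drives everything through independent per-unit substreams
(``numpy.random.SeedSequence.spawn``), so enlarging a session does not
perturb previously generated cells.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .calcium import RawTrace
from .methqpcr import (
    CONTROL_DIGEST,
    INSENSITIVE_DIGEST,
    NO_AMPLIFICATION,
    SENSITIVE_DIGEST,
    CtMeasurement,
)

__all__ = [
    "METHYLATED",
    "UNMETHYLATED",
    "AlleleConfig",
    "DigestionSimSpec",
    "CalciumSimSpec",
    "GroundTruth",
    "simulate_digestion_qpcr",
    "simulate_calibration_series",
    "simulate_calcium_traces",
]

logger = logging.getLogger(__name__)

METHYLATED = "methylated"
UNMETHYLATED = "unmethylated"

#: Default calibration series; the assay's standards are mixtures of fully
#: methylated and fully unmethylated genomic DNA.
DEFAULT_CALIBRATION_FRACTIONS = (0.0, 0.25, 0.5, 0.75, 1.0)


@dataclass(frozen=True)
class AlleleConfig:
    """Allele copies at the assayed locus, e.g. one methylated (maternal) and
    one unmethylated (paternal) copy for a biparental diploid."""

    alleles: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if not self.alleles:
            raise ValueError("allele configuration must contain at least one allele")
        for state, copies in self.alleles:
            if state not in (METHYLATED, UNMETHYLATED):
                raise ValueError(f"unknown methylation state {state!r}")
            if int(copies) < 1:
                raise ValueError(f"copy count must be >= 1, got {copies!r}")

    @property
    def total_copies(self) -> int:
        return sum(copies for _, copies in self.alleles)

    @property
    def methylation_fraction(self) -> float:
        meth = sum(copies for state, copies in self.alleles if state == METHYLATED)
        return meth / self.total_copies

    @classmethod
    def from_counts(cls, methylated: int = 0, unmethylated: int = 0) -> "AlleleConfig":
        alleles = []
        if methylated:
            alleles.append((METHYLATED, methylated))
        if unmethylated:
            alleles.append((UNMETHYLATED, unmethylated))
        return cls(tuple(alleles))


@dataclass(frozen=True)
class DigestionSimSpec:
    config: AlleleConfig
    cut_efficiency_sensitive: float = 1.0
    cut_efficiency_insensitive: float = 1.0
    pcr_efficiency: float = 2.0
    base_ct: float = 20.0
    noise_sd: float = 0.0
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.cut_efficiency_sensitive <= 1.0:
            raise ValueError("cut_efficiency_sensitive must lie in [0, 1]")
        if not 0.0 <= self.cut_efficiency_insensitive <= 1.0:
            raise ValueError("cut_efficiency_insensitive must lie in [0, 1]")
        if not 1.0 < self.pcr_efficiency <= 2.0:
            raise ValueError("pcr_efficiency must lie in (1, 2]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.base_ct <= 0:
            raise ValueError("base_ct must be > 0")


@dataclass(frozen=True)
class CalciumSimSpec:
    n_cells: int = 10
    n_samples: int = 600
    sampling_interval: float = 1.0
    event_rate: float = 2.0  # events per minute
    amplitude_range: tuple[float, float] = (0.4, 0.8)  # dF/F0 units
    decay_tau: float = 5.0  # seconds
    rise_samples: int = 1
    baseline: float = 100.0
    drift_amplitude: float = 0.0  # fraction of baseline
    noise_sd: float = 0.0  # fluorescence units
    refractory_samples: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.n_samples < 4:
            raise ValueError("need n_cells >= 1 and n_samples >= 4")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be > 0")
        if self.event_rate < 0:
            raise ValueError("event_rate must be >= 0")
        lo, hi = self.amplitude_range
        if lo > hi or lo < 0:
            raise ValueError("amplitude_range must satisfy 0 <= min <= max")
        if self.decay_tau <= 0:
            raise ValueError("decay_tau must be > 0")
        if self.rise_samples < 0 or self.refractory_samples < 0:
            raise ValueError("rise_samples and refractory_samples must be >= 0")
        if self.baseline <= 0:
            raise ValueError("baseline must be > 0")
        if self.drift_amplitude < 0 or self.drift_amplitude >= 1.0:
            raise ValueError("drift_amplitude must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def duration(self) -> float:
        return self.n_samples * self.sampling_interval


@dataclass(frozen=True)
class GroundTruth:
    """Latent truth behind a simulation: the methylation fraction for the
    digestion arm, per-cell event peak indices for the calcium arm."""

    true_methylation_fraction: float | None = None
    event_onsets: tuple[tuple[int, ...], ...] | None = None


# ---------------------------------------------------------------------------
# Digestion-qPCR arm
# ---------------------------------------------------------------------------

def _ct_measurement(
    sample_id: str,
    condition: str,
    surviving: float,
    spec: DigestionSimSpec,
    rng: np.random.Generator,
) -> CtMeasurement:
    # Always consume the noise draws so the stream layout is independent of
    # the surviving fraction.
    noise = rng.normal(0.0, spec.noise_sd, spec.n_replicates)
    if surviving <= 0.0:
        cts = (NO_AMPLIFICATION,) * spec.n_replicates
    else:
        ct0 = spec.base_ct - math.log(surviving) / math.log(spec.pcr_efficiency)
        cts = tuple(float(ct0 + e) for e in noise)
    return CtMeasurement(sample_id=sample_id, condition=condition, ct_values=cts)


def _simulate_conditions(
    sample_id: str,
    methylation_fraction: float,
    spec: DigestionSimSpec,
    rng: np.random.Generator,
) -> dict[str, CtMeasurement]:
    m = methylation_fraction
    # A copy survives the sensitive digest if methylated, or unmethylated but
    # missed by the enzyme; the insensitive isoschizomer cuts regardless.
    s_sensitive = m + (1.0 - m) * (1.0 - spec.cut_efficiency_sensitive)
    s_insensitive = 1.0 - spec.cut_efficiency_insensitive
    return {
        SENSITIVE_DIGEST: _ct_measurement(sample_id, SENSITIVE_DIGEST, s_sensitive, spec, rng),
        INSENSITIVE_DIGEST: _ct_measurement(
            sample_id, INSENSITIVE_DIGEST, s_insensitive, spec, rng
        ),
        CONTROL_DIGEST: _ct_measurement(sample_id, CONTROL_DIGEST, 1.0, spec, rng),
    }


def simulate_digestion_qpcr(
    spec: DigestionSimSpec, sample_id: str = "sample"
) -> tuple[dict[str, CtMeasurement], GroundTruth]:
    """Simulate the three digestion conditions for one sample.

    Returns measurements keyed by condition plus the latent methylation
    fraction. Deterministic for a given spec (the seed is part of the spec).
    """
    rng = np.random.default_rng(spec.seed)
    m = spec.config.methylation_fraction
    measurements = _simulate_conditions(sample_id, m, spec, rng)
    return measurements, GroundTruth(true_methylation_fraction=m)


def simulate_calibration_series(
    fractions: Sequence[float],
    spec: DigestionSimSpec,
    id_prefix: str = "cal",
) -> list[tuple[float, dict[str, CtMeasurement]]]:
    """Simulate standards mixed at the given known methylation fractions.

    Each standard is an independent substream of the spec seed, under the
    same digestion and noise model as :func:`simulate_digestion_qpcr`.
    """
    fractions = list(fractions)
    if not fractions:
        raise ValueError("calibration series requires at least one fraction")
    for f in fractions:
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"calibration fraction must lie in [0, 1], got {f!r}")
    # Spawned child streams are independent of the root stream that
    # simulate_digestion_qpcr uses for the test sample under the same seed.
    children = np.random.SeedSequence(spec.seed).spawn(len(fractions))
    series = []
    for i, (f, child) in enumerate(zip(fractions, children)):
        rng = np.random.default_rng(child)
        sample_id = f"{id_prefix}_{i}"
        series.append((f, _simulate_conditions(sample_id, f, spec, rng)))
    return series


# ---------------------------------------------------------------------------
# Calcium-imaging arm
# ---------------------------------------------------------------------------

def _draw_onsets(spec: CalciumSimSpec, rng: np.random.Generator) -> list[int]:
    """Poisson-process onsets in sample units, refractory-thinned.

    Onsets whose kernel peak would fall within two samples of either session
    edge are discarded: the detector by contract never reports events there,
    and the generator only places fully observable transients.
    """
    if spec.event_rate == 0.0:
        return []
    rate_per_sample = spec.event_rate / 60.0 * spec.sampling_interval
    onsets: list[int] = []
    t = 0.0
    last_kept = -math.inf
    while True:
        t += rng.exponential(1.0 / rate_per_sample)
        if t >= spec.n_samples:
            break
        idx = int(t)
        peak = idx + spec.rise_samples
        if peak < 2 or peak > spec.n_samples - 3:
            continue
        if idx - last_kept <= spec.refractory_samples:
            continue
        onsets.append(idx)
        last_kept = idx
    return onsets


def _transient_kernel(
    n_samples: int, onset: int, amplitude: float, spec: CalciumSimSpec
) -> np.ndarray:
    """dF/F0-unit kernel: linear rise from the onset sample to the peak, then
    exponential decay with decay_tau."""
    k = np.zeros(n_samples)
    peak = onset + spec.rise_samples
    if spec.rise_samples > 0:
        for j in range(1, spec.rise_samples + 1):
            if onset + j < n_samples:
                k[onset + j] = amplitude * j / spec.rise_samples
    else:
        k[onset] = amplitude
    tail = np.arange(1, n_samples - peak)
    if tail.size:
        k[peak + 1 :] = amplitude * np.exp(-tail * spec.sampling_interval / spec.decay_tau)
    return k


def simulate_calcium_traces(
    spec: CalciumSimSpec,
) -> tuple[list[RawTrace], GroundTruth]:
    """Simulate one imaging session; returns raw traces and true event peaks.

    Each cell uses an independent substream of the session seed. Non-positive
    fluorescence values (possible under heavy noise) are clipped to a small
    positive floor with a logged warning.
    """
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_cells)
    t = np.arange(spec.n_samples)
    traces: list[RawTrace] = []
    all_peaks: list[tuple[int, ...]] = []
    n_clipped = 0
    for cell, child in enumerate(children):
        rng = np.random.default_rng(child)
        phase = rng.uniform(0.0, 2.0 * math.pi)
        onsets = _draw_onsets(spec, rng)
        signal = np.zeros(spec.n_samples)
        peaks = []
        for onset in onsets:
            amplitude = rng.uniform(*spec.amplitude_range)
            signal += _transient_kernel(spec.n_samples, onset, amplitude, spec)
            peaks.append(onset + spec.rise_samples)
        drift = spec.drift_amplitude * np.sin(
            2.0 * math.pi * t / spec.n_samples + phase
        )
        f = spec.baseline * (1.0 + drift + signal)
        if spec.noise_sd > 0:
            f = f + rng.normal(0.0, spec.noise_sd, spec.n_samples)
        bad = f <= 0
        if bad.any():
            n_clipped += int(bad.sum())
            f = np.clip(f, 1e-9, None)
        traces.append(
            RawTrace(
                roi_id=f"cell_{cell:03d}",
                sampling_interval=spec.sampling_interval,
                intensities=f,
            )
        )
        all_peaks.append(tuple(peaks))
    if n_clipped:
        logger.warning(
            "clipped %d non-positive fluorescence samples to a positive floor",
            n_clipped,
        )
    return traces, GroundTruth(event_onsets=tuple(all_peaks))
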