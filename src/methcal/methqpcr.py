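"""Methylation-fraction estimation from methylation-sensitive digestion qPCR.

The assay digests genomic DNA in parallel reactions: a methylation-sensitive
enzyme (plus a carrier enzyme), a methylation-insensitive isoschizomer (plus
the carrier), and the carrier enzyme alone. qPCR across the assayed amplicon
then reads out the surviving template fraction of each digest. The relative
amplification of the sensitive digest versus the carrier-only digest is
calibrated against a standard curve of known methylation fractions; the
insensitive digest serves as a completeness-of-digestion control.

A comparative-Ct (ddCt) helper for expression data is included because it
shares the same cycle-to-quantity arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "NO_AMPLIFICATION",
    "CONDITIONS",
    "SENSITIVE_DIGEST",
    "INSENSITIVE_DIGEST",
    "CONTROL_DIGEST",
    "CtMeasurement",
    "StandardCurve",
    "MethylationEstimate",
    "ExpressionResult",
    "relative_amplification",
    "fit_standard_curve",
    "estimate_methylation",
    "digestion_qc",
    "relative_expression_ddct",
    "build_standard_curve",
    "estimate_sample",
]

#: Sentinel replicate value for a reaction that never crossed the qPCR
#: threshold. Infinity is the natural encoding: efficiency**(-inf) == 0.
NO_AMPLIFICATION = float("inf")

SENSITIVE_DIGEST = "sensitive_digest"
INSENSITIVE_DIGEST = "insensitive_digest"
CONTROL_DIGEST = "control_digest"
CONDITIONS = (SENSITIVE_DIGEST, INSENSITIVE_DIGEST, CONTROL_DIGEST)

#: Default residual relative amplification tolerated for the
#: methylation-insensitive digestion control.
DEFAULT_MAX_RESIDUAL = 0.05


def _validate_efficiency(pcr_efficiency: float) -> None:
    if not 1.0 < pcr_efficiency <= 2.0:
        raise ValueError(
            f"pcr_efficiency must lie in (1, 2], got {pcr_efficiency!r}"
        )


@dataclass(frozen=True)
class CtMeasurement:
    """Replicate threshold-cycle values for one sample under one digest.

    ``ct_values`` holds finite positive cycle numbers; a replicate that never
    amplified is recorded as :data:`NO_AMPLIFICATION`.
    """

    sample_id: str
    condition: str
    ct_values: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )
        if len(self.ct_values) < 1:
            raise ValueError(f"sample {self.sample_id!r}: at least one replicate required")
        for ct in self.ct_values:
            if ct == NO_AMPLIFICATION:
                continue
            if not math.isfinite(ct) or ct <= 0:
                raise ValueError(
                    f"sample {self.sample_id!r}: Ct values must be finite and > 0, got {ct!r}"
                )

    @property
    def finite_cts(self) -> tuple[float, ...]:
        return tuple(ct for ct in self.ct_values if ct != NO_AMPLIFICATION)

    @property
    def no_amplification(self) -> bool:
        """True when no replicate crossed the detection threshold."""
        return len(self.finite_cts) == 0

    @property
    def mean_ct(self) -> float:
        """Mean over amplifying replicates (inf when none amplified)."""
        finite = self.finite_cts
        if not finite:
            return NO_AMPLIFICATION
        return float(np.mean(finite))


@dataclass(frozen=True)
class StandardCurve:
    """Least-squares line mapping known methylation fraction to relative
    amplification R, inverted at estimation time."""

    slope: float
    intercept: float
    r_squared: float
    points: tuple[tuple[float, float], ...]

    @property
    def invertible(self) -> bool:
        return self.slope != 0.0

    def predict(self, fraction: float) -> float:
        return self.slope * fraction + self.intercept

    def invert(self, r: float) -> float:
        if not self.invertible:
            raise ValueError("standard curve has zero slope and cannot be inverted")
        return (r - self.intercept) / self.slope


@dataclass(frozen=True)
class MethylationEstimate:
    fraction: float
    raw_fraction: float
    relative_amplification: float
    clamped: bool
    qc_pass: bool
    sample_id: str = ""


@dataclass(frozen=True)
class ExpressionResult:
    delta_ct: float
    delta_delta_ct: float
    relative_quantity: float


def relative_amplification(
    digest: CtMeasurement,
    control: CtMeasurement,
    pcr_efficiency: float = 2.0,
) -> float:
    """Relative amplification R of a digest versus the carrier-only control.

    R = efficiency ** -(mean Ct_digest - mean Ct_control). A digest in which
    no replicate amplified yields R = 0. Replicates that did not amplify are
    excluded from the mean when others did.
    """
    _validate_efficiency(pcr_efficiency)
    if digest.sample_id != control.sample_id:
        raise ValueError(
            f"sample_id mismatch: digest {digest.sample_id!r} vs control {control.sample_id!r}"
        )
    if control.no_amplification:
        raise ValueError(
            f"sample {control.sample_id!r}: control digest did not amplify; "
            "relative amplification is undefined"
        )
    if digest.no_amplification:
        return 0.0
    return float(pcr_efficiency ** -(digest.mean_ct - control.mean_ct))


def fit_standard_curve(points: Iterable[tuple[float, float]]) -> StandardCurve:
    """Ordinary least squares of observed R on known methylation fraction.

    Requires at least two distinct fractions. A zero-variance response gives
    slope 0, which is reported but flagged non-invertible.
    """
    pts = tuple((float(f), float(r)) for f, r in points)
    if len(pts) < 2:
        raise ValueError("standard curve requires at least 2 calibration points")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if len(set(x.tolist())) < 2:
        raise ValueError("standard curve requires at least 2 distinct fractions")

    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    sxy = float(((x - xm) * (y - ym)).sum())
    slope = sxy / sxx
    intercept = ym - slope * xm

    ss_tot = float(((y - ym) ** 2).sum())
    ss_res = float(((y - (slope * x + intercept)) ** 2).sum())
    r_squared = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return StandardCurve(slope=slope, intercept=intercept, r_squared=r_squared, points=pts)


def estimate_methylation(
    r: float,
    curve: StandardCurve,
    qc_pass: bool = True,
    sample_id: str = "",
) -> MethylationEstimate:
    """Invert the standard curve at relative amplification ``r``.

    The raw inverse prediction is kept alongside the [0, 1]-clamped fraction;
    ``clamped`` marks estimates that overshot either endpoint.
    """
    raw = curve.invert(r)
    fraction = min(1.0, max(0.0, raw))
    return MethylationEstimate(
        fraction=fraction,
        raw_fraction=raw,
        relative_amplification=r,
        clamped=not (0.0 <= raw <= 1.0),
        qc_pass=qc_pass,
        sample_id=sample_id,
    )


def digestion_qc(
    insensitive_digest_r: float, max_residual: float = DEFAULT_MAX_RESIDUAL
) -> bool:
    """Completeness-of-digestion check on the insensitive isoschizomer digest.

    Passes when the residual relative amplification is at most
    ``max_residual`` (boundary inclusive).
    """
    if insensitive_digest_r < 0:
        raise ValueError(f"relative amplification must be >= 0, got {insensitive_digest_r!r}")
    return insensitive_digest_r <= max_residual


def relative_expression_ddct(
    target_ct: float,
    reference_ct: float,
    calibrator_delta_ct: float,
    pcr_efficiency: float = 2.0,
) -> ExpressionResult:
    """Comparative-Ct relative quantification against a reference gene and a
    calibrator condition. The raw delta Ct is exposed for downstream stats."""
    _validate_efficiency(pcr_efficiency)
    for name, ct in (
        ("target_ct", target_ct),
        ("reference_ct", reference_ct),
        ("calibrator_delta_ct", calibrator_delta_ct),
    ):
        if not math.isfinite(ct):
            raise ValueError(f"{name} must be finite, got {ct!r}")
    delta_ct = target_ct - reference_ct
    delta_delta_ct = delta_ct - calibrator_delta_ct
    return ExpressionResult(
        delta_ct=delta_ct,
        delta_delta_ct=delta_delta_ct,
        relative_quantity=float(pcr_efficiency ** -delta_delta_ct),
    )


# ---------------------------------------------------------------------------
# Convenience pipeline helpers used by the CLI and the simulation round trip.
# ---------------------------------------------------------------------------

def build_standard_curve(
    calibration: Sequence[tuple[float, Mapping[str, CtMeasurement]]],
    pcr_efficiency: float = 2.0,
) -> StandardCurve:
    """Fit a standard curve from calibration measurement sets.

    ``calibration`` pairs each known methylation fraction with the digest
    measurements of that standard (at minimum the sensitive digest and the
    carrier-only control).
    """
    points = []
    for fraction, conditions in calibration:
        digest = conditions[SENSITIVE_DIGEST]
        control = conditions[CONTROL_DIGEST]
        points.append((fraction, relative_amplification(digest, control, pcr_efficiency)))
    return fit_standard_curve(points)


def estimate_sample(
    conditions: Mapping[str, CtMeasurement],
    curve: StandardCurve,
    pcr_efficiency: float = 2.0,
    max_residual: float = DEFAULT_MAX_RESIDUAL,
) -> MethylationEstimate:
    """Full per-sample estimate: relative amplification, digestion QC if the
    insensitive digest was run, then inverse prediction from the curve."""
    digest = conditions[SENSITIVE_DIGEST]
    control = conditions[CONTROL_DIGEST]
    r = relative_amplification(digest, control, pcr_efficiency)
    qc = True
    if INSENSITIVE_DIGEST in conditions:
        r_insensitive = relative_amplification(
            conditions[INSENSITIVE_DIGEST], control, pcr_efficiency
        )
        qc = digestion_qc(r_insensitive, max_residual)
    return estimate_methylation(r, curve, qc_pass=qc, sample_id=digest.sample_id)
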