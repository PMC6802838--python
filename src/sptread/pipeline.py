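"""End-to-end wheal measurement workflow and agreement statistics.

The pipeline chains global-surface removal, LoG detection, patch
extraction, centering and parametric fitting into a list of per-wheal
measurements, each flagged positive when the longest diameter reaches the
clinical threshold (3 mm by default; the flag never filters - sub-visual
wheals are still reported).

The statistics mirror the standard reproducibility/agreement toolkit for
paired measurements: coefficient of variation CV = 100 * SD / mean with the
unbiased (n-1) SD, and Bland-Altman mean difference with 1.96-SD limits of
agreement.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass, field

import numpy as np

from .blob_detection import DetectionConfig, detect_wheals, extract_patches
from .heightfield_io import HeightField
from .parametric_fit import (
    DegeneratePatchError,
    FitConfig,
    center_patch,
    fit_wheal,
)
from .surface_removal import PyramidConfig, remove_global_surface

__all__ = [
    "WhealMeasurement",
    "AgreementStats",
    "PipelineConfig",
    "measure_spt",
    "coefficient_of_variation",
    "agreement_stats",
    "limits_of_agreement",
]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    pyramid: PyramidConfig = field(default_factory=PyramidConfig)
    detect: DetectionConfig = field(default_factory=DetectionConfig)
    fit: FitConfig = field(default_factory=FitConfig)
    positive_threshold_mm: float = 3.0
    report_decimals: int = 2


@dataclass
class WhealMeasurement:
    """One measured wheal: position, longest diameter and fit diagnostics."""

    id: int
    center_global: tuple[float, float]  # (x, y) mm
    diameter_mm: float
    model_kind: str
    positive: bool
    rms_residual: float
    converged: bool
    fallback_used: bool = False


@dataclass
class AgreementStats:
    """Bland-Altman summary of paired differences (reference - estimate)."""

    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int


def _global_center(patch, params) -> tuple[float, float]:
    """Map a fitted center from the rotated, centered frame back to mm."""
    ct, st = math.cos(params.theta), math.sin(params.theta)
    # inverse of x' = x cos - y sin, y' = x sin + y cos
    dx = params.x0p * ct + params.y0p * st
    dy = -params.x0p * st + params.y0p * ct
    return (patch.centroid[0] + dx, patch.centroid[1] + dy)


def measure_spt(S: HeightField, config: PipelineConfig | None = None) -> list[WhealMeasurement]:
    """Measure every wheal on a forearm height map.

    Runs surface removal, detection, patch extraction, centering and model
    fitting; candidates with degenerate patches are dropped with a logged
    warning. With ``fit.model = "both"`` each wheal yields one measurement
    per model (same id).
    """
    config = config or PipelineConfig()
    t0 = time.perf_counter()
    S_prime = remove_global_surface(S, config.pyramid)
    t1 = time.perf_counter()
    candidates = detect_wheals(S_prime, config.detect)
    patches = extract_patches(S_prime, candidates, config.detect)
    t2 = time.perf_counter()

    kinds = (
        ["paraboloid", "super_gaussian"] if config.fit.model == "both" else [config.fit.model]
    )
    measurements: list[WhealMeasurement] = []
    wheal_id = 0
    for patch in patches:
        try:
            centered = center_patch(patch)
        except DegeneratePatchError as exc:
            log.warning("dropping candidate at %s: %s", patch.source.center_mm, exc)
            continue
        for kind in kinds:
            fit = fit_wheal(centered, kind, config.fit)
            d = fit.diameter_mm
            measurements.append(
                WhealMeasurement(
                    id=wheal_id,
                    center_global=_global_center(centered, fit.params)
                    if fit.converged
                    else patch.source.center_mm,
                    diameter_mm=d,
                    model_kind=fit.model_kind,
                    positive=d >= config.positive_threshold_mm,
                    rms_residual=fit.rms_residual,
                    converged=fit.converged,
                    fallback_used=fit.fallback_used,
                )
            )
        wheal_id += 1
    t3 = time.perf_counter()
    log.info(
        "pipeline: surface removal %.2fs, detection %d candidates %.2fs, "
        "fitting %d measurements %.2fs",
        t1 - t0,
        len(candidates),
        t2 - t1,
        len(measurements),
        t3 - t2,
    )
    return measurements


def coefficient_of_variation(values) -> float:
    """CV in percent: 100 * unbiased SD / arithmetic mean."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("CV needs at least 2 values")
    mean = values.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(100.0 * values.std(ddof=1) / mean)


def limits_of_agreement(mean_diff: float, sd: float) -> tuple[float, float]:
    """95% limits of agreement (mean_diff -/+ 1.96 SD)."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    return (mean_diff - 1.96 * sd, mean_diff + 1.96 * sd)


def agreement_stats(reference, estimated) -> AgreementStats:
    """Bland-Altman statistics of paired measurements.

    Differences are reference - estimated, so a negative mean difference
    means the estimates run larger than the reference on average.
    """
    reference = np.asarray(reference, dtype=float)
    estimated = np.asarray(estimated, dtype=float)
    if reference.shape != estimated.shape:
        raise ValueError("reference and estimated must have equal length")
    if reference.size < 2:
        raise ValueError("need at least 2 pairs")
    diffs = reference - estimated
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    low, high = limits_of_agreement(mean, sd)
    return AgreementStats(mean_diff=mean, sd_diff=sd, loa_low=low, loa_high=high, n=diffs.size)
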