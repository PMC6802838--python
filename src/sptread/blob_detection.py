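"""Wheal candidate detection as scale-space maxima of a multi-scale LoG.

Raised bumps in the band-selected surface S' are detected with a
scale-normalized Laplacian-of-Gaussian filter bank: the response
-sigma^2 * laplacian(G_sigma * S') peaks, for a blob of radius r, at
sigma = r / sqrt(2), with a peak magnitude comparable across scales and in
the same units (mm) as the surface. Strict 3x3x3 non-maximum suppression
over the (scale, row, col) stack yields candidates, weaker members of
strongly overlapping pairs are pruned, and a square patch proportional to
the detected scale is cut around each survivor for the parametric fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .heightfield_io import HeightField

__all__ = [
    "DetectionConfig",
    "BlobCandidate",
    "WhealPatch",
    "log_response",
    "detect_wheals",
    "extract_patches",
]

_SQRT2 = math.sqrt(2.0)


@dataclass
class DetectionConfig:
    """Scale ladder and pruning thresholds for the LoG detector.

    The defaults cover wheal diameters of roughly 3-14 mm through the
    radius-scale relation r = sigma * sqrt(2).
    """

    sigma_min: float = 1.0  # mm
    sigma_max: float = 5.0  # mm
    n_scales: int = 12  # geometric spacing
    response_threshold: float = 0.03  # mm
    overlap_threshold: float = 0.5  # fraction of the smaller circle
    patch_halfwidth_factor: float = 2.0  # half-width = k * sigma * sqrt(2)

    def __post_init__(self) -> None:
        if not (0 < self.sigma_min < self.sigma_max):
            raise ValueError("need 0 < sigma_min < sigma_max")
        if self.n_scales < 2:
            raise ValueError("n_scales must be >= 2")
        if self.response_threshold < 0 or self.overlap_threshold < 0:
            raise ValueError("thresholds must be >= 0")

    def sigma_ladder(self) -> np.ndarray:
        return np.geomspace(self.sigma_min, self.sigma_max, self.n_scales)


@dataclass
class BlobCandidate:
    """A scale-space maximum: grid position, physical center, scale, response."""

    row: int
    col: int
    center_mm: tuple[float, float]
    scale_sigma: float  # mm
    response: float  # mm

    @property
    def radius_mm(self) -> float:
        return self.scale_sigma * _SQRT2


@dataclass
class WhealPatch:
    """Square cut of S' around a candidate (possibly clipped at borders).

    ``points_centered``, ``theta_init``, ``centroid`` and ``baseline`` are
    filled by the parametric-fit stage.
    """

    surface: np.ndarray
    mask: np.ndarray
    origin_global: tuple[float, float]
    pitch: float
    source: BlobCandidate
    clipped: bool = False
    points_centered: np.ndarray | None = None
    theta_init: float | None = None
    centroid: tuple[float, float] | None = None
    baseline: float = 0.0


def log_response(S_prime: HeightField, sigma: float) -> np.ndarray:
    """Scale-normalized negative LoG response, in mm, for one scale.

    Positive peaks correspond to raised bumps. ``sigma`` is in mm and must
    be at least half a pixel.
    """
    pitch = S_prime.pitch
    sigma_px = sigma / pitch
    if sigma_px < 0.5:
        raise ValueError(f"sigma {sigma} mm is below half a pixel ({pitch / 2} mm)")
    heights = np.where(S_prime.mask, S_prime.heights, 0.0)
    # the Laplacian annihilates constants, but the truncated discrete kernel
    # leaks a small DC term; removing the mean first makes the response of a
    # flat field exactly zero
    heights = heights - heights.mean()
    # sigma_mm^2 * laplacian_mm = sigma_px^2 * laplacian_px: pitch cancels;
    # truncate=6 keeps the kernel's residual moments negligible so linear
    # fields are annihilated to ~1e-8
    return -(sigma_px**2) * ndimage.gaussian_laplace(
        heights, sigma_px, mode="reflect", truncate=6.0
    )


def _overlap_fraction(dist: float, r1: float, r2: float) -> float:
    """Area of intersection of two discs over the area of the smaller one."""
    rs, rl = min(r1, r2), max(r1, r2)
    if dist >= rs + rl:
        return 0.0
    if dist <= rl - rs:
        return 1.0
    d1 = (dist**2 + rl**2 - rs**2) / (2 * dist)
    d2 = dist - d1
    area = (
        rl**2 * math.acos(np.clip(d1 / rl, -1, 1))
        - d1 * math.sqrt(max(rl**2 - d1**2, 0.0))
        + rs**2 * math.acos(np.clip(d2 / rs, -1, 1))
        - d2 * math.sqrt(max(rs**2 - d2**2, 0.0))
    )
    return area / (math.pi * rs**2)


def detect_wheals(
    S_prime: HeightField, config: DetectionConfig | None = None
) -> list[BlobCandidate]:
    """Detect wheal candidates, strongest first.

    Builds the sigma-ladder response stack, keeps strict 3x3x3 scale-space
    maxima at or above the response threshold, and greedily suppresses the
    weaker of any pair whose r = sigma*sqrt(2) circles overlap by more than
    the overlap threshold.
    """
    config = config or DetectionConfig()
    sigmas = config.sigma_ladder()
    stack = np.stack([log_response(S_prime, s) for s in sigmas])

    footprint = np.ones((3, 3, 3), dtype=bool)
    footprint[1, 1, 1] = False
    neighbors = ndimage.maximum_filter(stack, footprint=footprint, mode="constant", cval=-np.inf)
    peaks = (stack > neighbors) & (stack >= config.response_threshold)
    peaks &= S_prime.mask[None, :, :]
    # responses of residual large-scale background (e.g. arm-curvature
    # ridges) grow monotonically with sigma and pile up on the coarsest
    # plane; a genuine blob inside the ladder peaks at an interior scale
    peaks[-1] = False

    ox, oy = S_prime.origin
    pitch = S_prime.pitch
    candidates = [
        BlobCandidate(
            row=int(r),
            col=int(c),
            center_mm=(ox + c * pitch, oy + r * pitch),
            scale_sigma=float(sigmas[s]),
            response=float(stack[s, r, c]),
        )
        for s, r, c in zip(*np.nonzero(peaks))
    ]
    candidates.sort(key=lambda b: (-b.response, b.row, b.col))

    kept: list[BlobCandidate] = []
    for cand in candidates:
        keep = True
        for strong in kept:
            dist = math.hypot(
                cand.center_mm[0] - strong.center_mm[0],
                cand.center_mm[1] - strong.center_mm[1],
            )
            if _overlap_fraction(dist, cand.radius_mm, strong.radius_mm) > config.overlap_threshold:
                keep = False
                break
        if keep:
            kept.append(cand)
    return kept


def extract_patches(
    S_prime: HeightField,
    candidates: list[BlobCandidate],
    config: DetectionConfig | None = None,
) -> list[WhealPatch]:
    """Cut a square window of half-width round(k * sigma * sqrt(2) / pitch)
    around each candidate, clipping (and flagging) at field borders."""
    config = config or DetectionConfig()
    rows, cols = S_prime.shape
    pitch = S_prime.pitch
    patches = []
    for cand in candidates:
        hw = int(round(config.patch_halfwidth_factor * cand.radius_mm / pitch))
        r0, r1 = cand.row - hw, cand.row + hw + 1
        c0, c1 = cand.col - hw, cand.col + hw + 1
        clipped = r0 < 0 or c0 < 0 or r1 > rows or c1 > cols
        r0, c0 = max(r0, 0), max(c0, 0)
        r1, c1 = min(r1, rows), min(c1, cols)
        patches.append(
            WhealPatch(
                surface=S_prime.heights[r0:r1, c0:c1].copy(),
                mask=S_prime.mask[r0:r1, c0:c1].copy(),
                origin_global=(
                    S_prime.origin[0] + c0 * pitch,
                    S_prime.origin[1] + r0 * pitch,
                ),
                pitch=pitch,
                source=cand,
                clipped=clipped,
            )
        )
    return patches
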