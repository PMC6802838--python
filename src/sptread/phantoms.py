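"""Synthetic forearm scans and validation objects with known ground truth.

No real scans accompany the measurement method, so this module emulates
them: a cylindrical forearm section carrying super-Gaussian wheal bumps
(flat-topped, 3-12 mm across, 0.1-0.5 mm high), band-limited skin
micro-texture, and white sensor noise at the system's stated depth accuracy
(SD 0.01 mm). It also builds the two physical validation objects - spherical
caps of known base diameter and a 0.100 mm staircase - together with the
measurement procedures used on them (least-squares sphere fit and
region-mean differencing).

All generators are pure functions of (config, seed): equal seeds give
bit-identical fields.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .heightfield_io import HeightField
from .parametric_fit import Model2Params, eval_model

__all__ = [
    "SyntheticWheal",
    "PhantomConfig",
    "make_forearm",
    "make_spherical_caps",
    "make_steps",
    "measure_cap_diameter",
    "measure_step_heights",
]


@dataclass
class SyntheticWheal:
    """Ground-truth wheal: a super-Gaussian bump with known diameter."""

    center: tuple[float, float]  # (x, y) mm
    sigma_x: float
    sigma_y: float
    beta_x: float
    beta_y: float
    gamma: float  # peak height, mm
    theta: float  # radians

    @property
    def true_diameter(self) -> float:
        return max(4 * self.sigma_x, 4 * self.sigma_y)

    def params(self) -> Model2Params:
        return Model2Params(
            x0p=0.0,
            y0p=0.0,
            sigma_x=self.sigma_x,
            sigma_y=self.sigma_y,
            beta_x=self.beta_x,
            beta_y=self.beta_y,
            gamma=self.gamma,
            theta=self.theta,
        )


@dataclass
class PhantomConfig:
    """Study-condition defaults for the synthetic forearm."""

    grid_shape: tuple[int, int] = (300, 700)  # rows, cols
    pitch: float = 0.2  # mm
    arm_radius: float = 40.0  # mm, cylinder radius
    noise_sd: float = 0.01  # mm, sensor depth accuracy
    texture_amplitude: float = 0.02  # mm, skin micro-texture SD
    n_wheals: int = 8
    diameter_range: tuple[float, float] = (3.0, 12.0)  # mm
    height_range: tuple[float, float] = (0.1, 0.5)  # mm
    min_separation: float = 15.0  # mm between wheal centers
    border_margin: float = 10.0  # mm from field edge
    seed: int = 0


def _sample_centers(rng, width, height, n, margin, separation):
    centers: list[tuple[float, float]] = []
    for _ in range(20000):
        if len(centers) == n:
            break
        x = rng.uniform(margin, width - margin)
        y = rng.uniform(margin, height - margin)
        if all(math.hypot(x - cx, y - cy) >= separation for cx, cy in centers):
            centers.append((x, y))
    if len(centers) < n:
        raise ValueError(
            f"could not place {n} wheals {separation} mm apart on a "
            f"{width:.0f}x{height:.0f} mm field"
        )
    return centers


def _sample_wheals(rng, config: PhantomConfig) -> list[SyntheticWheal]:
    width = (config.grid_shape[1] - 1) * config.pitch
    height = (config.grid_shape[0] - 1) * config.pitch
    centers = _sample_centers(
        rng, width, height, config.n_wheals, config.border_margin, config.min_separation
    )
    wheals = []
    for cx, cy in centers:
        d = rng.uniform(*config.diameter_range)
        aspect = rng.uniform(0.6, 1.0)
        wheals.append(
            SyntheticWheal(
                center=(cx, cy),
                sigma_x=d / 4.0,
                sigma_y=aspect * d / 4.0,
                beta_x=rng.uniform(1.0, 2.5),
                beta_y=rng.uniform(1.0, 2.5),
                gamma=rng.uniform(*config.height_range),
                theta=rng.uniform(-math.pi / 2, math.pi / 2),
            )
        )
    return wheals


def add_wheals(heights: np.ndarray, pitch: float, wheals: list[SyntheticWheal]) -> None:
    """Accumulate super-Gaussian bumps in place (evaluated on local windows)."""
    rows, cols = heights.shape
    for w in wheals:
        reach = 5.0 * max(w.sigma_x, w.sigma_y)  # tail < exp(-12.5) beyond
        c0 = max(int((w.center[0] - reach) / pitch), 0)
        c1 = min(int((w.center[0] + reach) / pitch) + 2, cols)
        r0 = max(int((w.center[1] - reach) / pitch), 0)
        r1 = min(int((w.center[1] + reach) / pitch) + 2, rows)
        xs = np.arange(c0, c1) * pitch - w.center[0]
        ys = np.arange(r0, r1) * pitch - w.center[1]
        xx, yy = np.meshgrid(xs, ys)
        coords = np.stack([xx, yy], axis=-1)
        heights[r0:r1, c0:c1] += eval_model("super_gaussian", w.params(), coords)


def transform_wheals(
    wheals: list[SyntheticWheal],
    translation: tuple[float, float] = (0.0, 0.0),
    rotation_deg: float = 0.0,
    pivot: tuple[float, float] | None = None,
) -> list[SyntheticWheal]:
    """Rigidly re-pose a wheal constellation (skin slides, sizes invariant).

    Centers rotate by ``rotation_deg`` (counter-clockwise) about ``pivot``
    (default: constellation centroid) and then translate. Each wheal's model
    angle theta decreases by the pose rotation, because the model rotates
    coordinates: a bump whose long axis lies at spatial angle -theta keeps
    d and its shape, only re-oriented.
    """
    if pivot is None:
        pivot = (
            float(np.mean([w.center[0] for w in wheals])),
            float(np.mean([w.center[1] for w in wheals])),
        )
    phi = math.radians(rotation_deg)
    ct, st = math.cos(phi), math.sin(phi)
    out = []
    for w in wheals:
        dx, dy = w.center[0] - pivot[0], w.center[1] - pivot[1]
        cx = pivot[0] + dx * ct - dy * st + translation[0]
        cy = pivot[1] + dx * st + dy * ct + translation[1]
        out.append(
            SyntheticWheal(
                center=(cx, cy),
                sigma_x=w.sigma_x,
                sigma_y=w.sigma_y,
                beta_x=w.beta_x,
                beta_y=w.beta_y,
                gamma=w.gamma,
                theta=w.theta - phi,
            )
        )
    return out


def make_forearm(
    config: PhantomConfig | None = None,
    seed: int | None = None,
    wheals: list[SyntheticWheal] | None = None,
) -> tuple[HeightField, list[SyntheticWheal]]:
    """Synthetic forearm scan: cylinder + wheals + texture + sensor noise.

    The cylinder axis runs along the grid's long dimension; curvature spans
    the short one, which must fit inside the cylinder diameter. Passing
    ``wheals`` renders that exact set (e.g. a re-posed constellation)
    instead of sampling one.
    """
    config = config or PhantomConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rows, cols = config.grid_shape
    pitch = config.pitch

    across_axis = 0 if rows <= cols else 1
    n_across = config.grid_shape[across_axis]
    half_extent = (n_across - 1) * pitch / 2.0
    if half_extent >= config.arm_radius:
        raise ValueError(
            f"short grid extent {2 * half_extent:.0f} mm exceeds the cylinder "
            f"diameter {2 * config.arm_radius:.0f} mm"
        )
    u = np.arange(n_across) * pitch - half_extent
    profile = np.sqrt(config.arm_radius**2 - u**2) - config.arm_radius
    heights = (
        np.tile(profile[:, None], (1, cols))
        if across_axis == 0
        else np.tile(profile[None, :], (rows, 1))
    )

    if wheals is None:
        wheals = _sample_wheals(rng, config)
    add_wheals(heights, pitch, wheals)

    if config.texture_amplitude > 0:
        tex = ndimage.gaussian_filter(rng.standard_normal(config.grid_shape), 1.0)
        heights += tex * (config.texture_amplitude / tex.std())
    if config.noise_sd > 0:
        heights += rng.normal(0.0, config.noise_sd, size=config.grid_shape)
    return HeightField(heights, pitch), wheals


# ---------------------------------------------------------------------------
# validation objects


def make_spherical_caps(
    base_diameters: list[float],
    cap_height: float = 2.0,
    pitch: float = 0.1,
    noise_sd: float = 0.0,
    seed: int = 0,
    margin: float = 4.0,
) -> tuple[HeightField, list[tuple[float, float]]]:
    """Spherical caps of known base diameter laid out in a row on a flat plate.

    Each cap is a sphere section over a base circle of diameter d: with base
    radius r = d/2 and height h the sphere radius is R = (r^2 + h^2) / (2h)
    and z = sqrt(R^2 - rho^2) - (R - h) inside the base circle, 0 outside.
    """
    base_diameters = [float(d) for d in base_diameters]
    if any(d <= 0 for d in base_diameters) or cap_height <= 0:
        raise ValueError("base diameters and cap height must be positive")
    radii = [d / 2.0 for d in base_diameters]
    centers = []
    x = margin + radii[0]
    for i, r in enumerate(radii):
        if i > 0:
            x += radii[i - 1] + 2 * margin + r
        # snap cap apexes onto grid nodes so the peak height is exact
        centers.append(round(x / pitch) * pitch)
    width = centers[-1] + radii[-1] + margin
    height_mm = 2 * (max(radii) + margin)
    yc = round(height_mm / 2.0 / pitch) * pitch
    for (x1, r1), (x2, r2) in zip(zip(centers, radii), zip(centers[1:], radii[1:])):
        if x2 - x1 < r1 + r2:
            raise ValueError("spherical caps overlap on the grid")

    rows = int(round(height_mm / pitch)) + 1
    cols = int(round(width / pitch)) + 1
    xs = np.arange(cols) * pitch
    ys = np.arange(rows) * pitch
    heights = np.zeros((rows, cols))
    for xc, r in zip(centers, radii):
        R = (r**2 + cap_height**2) / (2 * cap_height)
        rho2 = (xs[None, :] - xc) ** 2 + (ys[:, None] - yc) ** 2
        inside = rho2 <= r**2
        heights[inside] += np.sqrt(R**2 - rho2[inside]) - (R - cap_height)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        heights += rng.normal(0.0, noise_sd, size=heights.shape)
    return HeightField(heights, pitch), [(xc, yc) for xc in centers]


def make_steps(
    step_heights: list[float],
    pitch: float = 0.1,
    noise_sd: float = 0.0,
    seed: int = 0,
    band_shape: tuple[int, int] = (100, 60),
) -> tuple[HeightField, np.ndarray]:
    """Staircase of equal-width vertical bands at the given heights.

    ``step_heights`` must be non-decreasing and start at 0 (the reference
    band R0). Returns the field and an integer label grid (band k -> k).
    """
    step_heights = [float(h) for h in step_heights]
    if len(step_heights) < 2:
        raise ValueError("need at least 2 steps")
    if step_heights[0] != 0.0:
        raise ValueError("first step must be the reference height 0")
    if any(b < a for a, b in zip(step_heights, step_heights[1:])):
        raise ValueError("step heights must be non-decreasing")
    rows, band_cols = band_shape
    labels = np.repeat(np.arange(len(step_heights)), band_cols)[None, :]
    labels = np.broadcast_to(labels, (rows, labels.shape[1])).copy()
    heights = np.asarray(step_heights, dtype=float)[labels]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        heights = heights + rng.normal(0.0, noise_sd, size=heights.shape)
    return HeightField(heights, pitch), labels


# ---------------------------------------------------------------------------
# analog measurement procedures


def measure_cap_diameter(
    fieldobj: HeightField,
    center_hint: tuple[float, float],
    search_radius: float = 8.0,
) -> float:
    """Base-circle diameter of a cap near ``center_hint`` by sphere fitting.

    Cells within the search radius whose elevation exceeds 10% of the local
    peak enter an algebraic least-squares sphere fit; the base diameter is
    the chord of the fitted sphere at the z = 0 plane, 2*sqrt(R^2 - z_c^2).
    """
    xs = fieldobj.x_coords()[None, :]
    ys = fieldobj.y_coords()[:, None]
    near = (xs - center_hint[0]) ** 2 + (ys - center_hint[1]) ** 2 <= search_radius**2
    near &= fieldobj.mask
    if not near.any():
        raise ValueError("no valid cells near the center hint")
    local = fieldobj.heights[near]
    peak = local.max()
    sel = near & (fieldobj.heights > 0.1 * peak)
    z = fieldobj.heights[sel]
    if z.size < 16 or (z.max() - z.min()) < 0.05:
        raise ValueError("sphere fit ill-conditioned: region is too flat")
    rows, cols = np.nonzero(sel)
    x = fieldobj.origin[0] + cols * fieldobj.pitch
    y = fieldobj.origin[1] + rows * fieldobj.pitch

    # algebraic fit: x^2+y^2+z^2 = 2ax + 2by + 2cz + k
    A = np.column_stack([2 * x, 2 * y, 2 * z, np.ones_like(z)])
    rhs = x**2 + y**2 + z**2
    coef, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    a, b, c, k = coef
    R2 = k + a**2 + b**2 + c**2
    if R2 <= c**2:
        raise ValueError("fitted sphere does not intersect the base plane")
    return float(2.0 * math.sqrt(R2 - c**2))


def measure_step_heights(
    fieldobj: HeightField,
    regions: np.ndarray,
    order: list[int] | None = None,
) -> np.ndarray:
    """Mean height of each region relative to the reference region.

    ``order`` lists region labels with the reference first; defaults to
    sorted labels. Results follow ``order`` (not spatial position).
    """
    regions = np.asarray(regions)
    if regions.shape != fieldobj.shape:
        raise ValueError("label grid shape must match the field")
    if order is None:
        order = sorted(np.unique(regions).tolist())
    means = []
    for lab in order:
        sel = (regions == lab) & fieldobj.mask
        if not sel.any():
            raise ValueError(f"region {lab} is empty")
        means.append(fieldobj.heights[sel].mean())
    ref = means[0]
    return np.array([m - ref for m in means[1:]])
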