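"""Validation studies on synthetic phantoms.

Three self-contained procedures mirror the validation experiments used to
qualify a wheal-measurement system:

* spherical caps of known base diameter, re-measured across placements
  (transversal accuracy),
* a staircase of 0.100 mm steps (depth accuracy),
* one wheal constellation re-posed rigidly across the field and re-measured
  with the full pipeline (reproducibility, reported as per-wheal CV).

Each study is a pure function of its seed and returns a small dict of
results suitable for JSON serialization.
"""

from __future__ import annotations

import math

import numpy as np

from .phantoms import (
    PhantomConfig,
    SyntheticWheal,
    make_forearm,
    make_spherical_caps,
    make_steps,
    measure_cap_diameter,
    measure_step_heights,
    transform_wheals,
)
from .pipeline import PipelineConfig, coefficient_of_variation, measure_spt

__all__ = [
    "CAP_REFERENCE_DIAMETERS_MM",
    "STEP_REFERENCE_HEIGHTS_MM",
    "cap_accuracy_study",
    "step_accuracy_study",
    "reposing_study",
]

# reference diameters of the six machined spherical caps (caliper-measured)
CAP_REFERENCE_DIAMETERS_MM = (9.08, 7.42, 5.65, 8.88, 7.42, 5.50)
# staircase of adhesive-paper steps, 0.100 mm per layer, above the base R0
STEP_REFERENCE_HEIGHTS_MM = (0.100, 0.200, 0.300)


def cap_accuracy_study(
    seed: int = 0,
    diameters: tuple[float, ...] = CAP_REFERENCE_DIAMETERS_MM,
    n_positions: int = 7,
    pitch: float = 0.1,
    noise_sd: float = 0.01,
    cap_height: float = 2.0,
) -> dict:
    """Measure each cap at several placements; report signed/absolute errors.

    A placement differs by its sensor-noise draw and by a sub-millimetre
    shift of the caps against the sampling grid (margin jitter), emulating
    re-positioning across the field of view.
    """
    errors = np.empty((n_positions, len(diameters)))
    for pos in range(n_positions):
        field, centers = make_spherical_caps(
            list(diameters),
            cap_height=cap_height,
            pitch=pitch,
            noise_sd=noise_sd,
            seed=seed + pos,
            margin=4.0 + 0.13 * pos,
        )
        for i, (center, ref) in enumerate(zip(centers, diameters)):
            errors[pos, i] = measure_cap_diameter(field, center) - ref
    return {
        "reference_mm": list(diameters),
        "errors_mm": errors.tolist(),
        "max_abs_error_mm": float(np.abs(errors).max()),
        "mean_abs_error_mm": float(np.abs(errors).mean()),
        "n_measurements": int(errors.size),
    }


def step_accuracy_study(
    seed: int = 0,
    heights: tuple[float, ...] = STEP_REFERENCE_HEIGHTS_MM,
    pitch: float = 0.1,
    noise_sd: float = 0.01,
    band_shape: tuple[int, int] = (100, 75),
) -> dict:
    """Recover staircase step heights relative to the base region."""
    field, labels = make_steps(
        [0.0, *heights], pitch=pitch, noise_sd=noise_sd, seed=seed, band_shape=band_shape
    )
    recovered = measure_step_heights(field, labels)
    errors = recovered - np.asarray(heights)
    return {
        "reference_mm": list(heights),
        "recovered_mm": recovered.tolist(),
        "max_abs_error_mm": float(np.abs(errors).max()),
        "band_cells": int(band_shape[0] * band_shape[1]),
    }


def _sample_pose_wheals(rng, config: PhantomConfig, n_wheals, diameter_range, box):
    """Wheal constellation inside a central box that survives every pose.

    The box is a narrow strip along the arm, so wheals are laid out at even
    x spacing (guaranteeing the minimum separation) with random y.
    """
    x0, x1, y0, y1 = box
    if n_wheals > 1 and (x1 - x0) / (n_wheals - 1) < config.min_separation:
        raise ValueError("pose-study box too small for the requested wheal count")
    xs = np.linspace(x0, x1, n_wheals)
    centers = [(float(x), float(rng.uniform(y0, y1))) for x in xs]
    wheals = []
    for cx, cy in centers:
        d = rng.uniform(*diameter_range)
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


def reposing_study(
    seed: int = 0,
    n_poses: int = 5,
    n_wheals: int = 6,
    diameter_range: tuple[float, float] = (4.0, 11.0),
    config: PipelineConfig | None = None,
    match_radius_mm: float = 2.0,
) -> dict:
    """One wheal set rendered under rigid poses, re-measured per pose.

    Poses draw translations up to +/-20 mm along the arm (+/-4 mm across),
    in-plane rotations up to +/-10 degrees about the constellation
    centroid, and fresh sensor noise. Reports the per-wheal coefficient of
    variation of the pipeline diameters across poses.
    """
    config = config or PipelineConfig()
    phantom = PhantomConfig(seed=seed)
    rng = np.random.default_rng(seed)
    width = (phantom.grid_shape[1] - 1) * phantom.pitch
    height = (phantom.grid_shape[0] - 1) * phantom.pitch
    # central box: border margin + translation reach + rotation drift
    box = (32.0, width - 32.0, height / 2 - 7.0, height / 2 + 7.0)
    base = _sample_pose_wheals(rng, phantom, n_wheals, diameter_range, box)

    margin = phantom.border_margin
    diameters = np.full((n_wheals, n_poses), np.nan)
    for pose in range(n_poses):
        for _ in range(1000):
            tx = rng.uniform(-20.0, 20.0)
            ty = rng.uniform(-4.0, 4.0)
            phi = rng.uniform(-10.0, 10.0)
            posed = transform_wheals(base, (tx, ty), phi)
            if all(
                margin <= w.center[0] <= width - margin
                and margin <= w.center[1] <= height - margin
                for w in posed
            ):
                break
        else:
            raise RuntimeError("could not draw an in-bounds pose")
        field, _ = make_forearm(phantom, seed=seed * 1000 + pose + 1, wheals=posed)
        measurements = measure_spt(field, config)
        for i, w in enumerate(posed):
            best = None
            for m in measurements:
                dist = math.hypot(
                    m.center_global[0] - w.center[0], m.center_global[1] - w.center[1]
                )
                if dist <= match_radius_mm and (best is None or dist < best[0]):
                    best = (dist, m.diameter_mm)
            if best is not None:
                diameters[i, pose] = best[1]

    cvs = []
    for i in range(n_wheals):
        found = diameters[i, np.isfinite(diameters[i])]
        if found.size < 2:
            raise RuntimeError(f"wheal {i} recovered in fewer than 2 poses")
        cvs.append(coefficient_of_variation(found))
    return {
        "true_diameters_mm": [w.true_diameter for w in base],
        "diameters_mm": diameters.tolist(),
        "per_wheal_cv_percent": cvs,
        "max_cv_percent": float(max(cvs)),
        "n_poses": n_poses,
        "n_missing": int(np.isnan(diameters).sum()),
    }
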