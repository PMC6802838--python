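"""Parametric surface models for the wheal longest diameter.

Two models are fitted to the centered point set of each wheal patch, both in
a coordinate frame rotated by an angle theta that is itself a fit parameter
(x' = x cos(theta) - y sin(theta), y' = x sin(theta) + y cos(theta)):

* Model 1, an inverted elliptical paraboloid
      f1 = beta - (1/c) * ((x'-x0')^2 / wx^2 + (y'-y0')^2 / wy^2),
  whose zero-level set is an ellipse with semi-axes a = wx*sqrt(beta*c),
  b = wy*sqrt(beta*c); the diameter is d = max{2a, 2b}. Only the products
  wx^2*c and wy^2*c are identifiable, so the fitter pins c = 1.

* Model 2, a 2D super-Gaussian
      f2 = gamma * exp(-((x'-x0')^2/(2 sx^2))^bx - ((y'-y0')^2/(2 sy^2))^by),
  whose flatness exponents bx, by > 1 flatten the top as observed on real
  wheals; the diameter is d = max{4 sx, 4 sy}.

Fitting uses bounded trust-region-reflective nonlinear least squares.
The paraboloid diverges below the skin plane, so its residuals are
restricted to points above a small fraction of the patch peak (plus a
one-pixel annulus); the super-Gaussian is fitted on the full patch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from scipy.optimize import least_squares

from .blob_detection import WhealPatch

__all__ = [
    "Model1Params",
    "Model2Params",
    "ModelFit",
    "FitConfig",
    "DegeneratePatchError",
    "center_patch",
    "eval_model",
    "fit_wheal",
    "diameter",
]

_SQRT2 = math.sqrt(2.0)


class DegeneratePatchError(ValueError):
    """Patch has no usable elevation for centering or fitting."""


@dataclass
class Model1Params:
    """Inverted elliptical paraboloid parameters (mm, radians)."""

    x0p: float
    y0p: float
    wx: float
    wy: float
    c: float
    beta: float
    theta: float

    @property
    def a(self) -> float:
        return self.wx * math.sqrt(self.beta * self.c)

    @property
    def b(self) -> float:
        return self.wy * math.sqrt(self.beta * self.c)


@dataclass
class Model2Params:
    """2D super-Gaussian parameters (mm, dimensionless exponents, radians)."""

    x0p: float
    y0p: float
    sigma_x: float
    sigma_y: float
    beta_x: float
    beta_y: float
    gamma: float
    theta: float


@dataclass
class ModelFit:
    model_kind: str  # "paraboloid" | "super_gaussian"
    params: Model1Params | Model2Params
    diameter_mm: float
    rms_residual: float
    converged: bool
    n_points: int
    fallback_used: bool = False


@dataclass
class FitConfig:
    """Optimizer settings; see module docstring for the model definitions."""

    model: str = "super_gaussian"  # "paraboloid" | "super_gaussian" | "both"
    max_iter: int = 500
    tol: float = 1e-8
    support_fraction: float = 0.05  # model-1 residual support, fraction of peak
    fallback_range_mm: tuple[float, float] = (1.0, 20.0)
    sigma_bounds_mm: tuple[float, float] = (0.25, 15.0)
    flatness_bounds: tuple[float, float] = (0.5, 10.0)


def _wrap_half_pi(theta: float) -> float:
    """Map an angle to [-pi/2, pi/2)."""
    t = (theta + math.pi / 2) % math.pi - math.pi / 2
    return -math.pi / 2 if t >= math.pi / 2 else t


def center_patch(patch: WhealPatch, subtract_baseline: bool = True) -> WhealPatch:
    """Shift the patch to its elevation-weighted center of mass.

    By default the patch median is removed first as a local baseline (the
    band-passed surface is defined only up to a smooth offset; disable when
    fitting data that is already baseline-free). Cell positions become
    points (x', y', z) with weights max(z, 0); the principal axis of the
    weighted second-moment matrix supplies the rotation initialization
    ``theta_init`` in [-pi/2, pi/2).
    """
    valid = patch.mask
    if not valid.any():
        raise DegeneratePatchError("patch has no valid cells")
    z_grid = patch.surface
    baseline = float(np.median(z_grid[valid])) if subtract_baseline else 0.0
    zc = z_grid - baseline

    rows, cols = np.nonzero(valid)
    x = patch.origin_global[0] + cols * patch.pitch
    y = patch.origin_global[1] + rows * patch.pitch
    z = zc[rows, cols]
    w = np.clip(z, 0.0, None)

    peak = z.max(initial=-np.inf)
    if peak <= 0:
        raise DegeneratePatchError("all patch heights at or below the baseline")
    if int((w > 0).sum()) < 8:
        raise DegeneratePatchError("fewer than 8 usable points above the baseline")

    wsum = w.sum()
    cx = float((w * x).sum() / wsum)
    cy = float((w * y).sum() / wsum)
    dx, dy = x - cx, y - cy

    cxx = float((w * dx * dx).sum() / wsum)
    cyy = float((w * dy * dy).sum() / wsum)
    cxy = float((w * dx * dy).sum() / wsum)
    # spatial angle of the principal axis; the model rotates coordinates,
    # so theta_init is its negative
    phi = 0.5 * math.atan2(2 * cxy, cxx - cyy)
    theta_init = _wrap_half_pi(-phi)

    out = replace(patch)
    out.points_centered = np.column_stack([dx, dy, z])
    out.theta_init = theta_init
    out.centroid = (cx, cy)
    out.baseline = baseline
    return out


def _rotate(theta: float, x: np.ndarray, y: np.ndarray):
    ct, st = math.cos(theta), math.sin(theta)
    return x * ct - y * st, x * st + y * ct


def eval_model(kind: str, params, coords: np.ndarray) -> np.ndarray:
    """Evaluate a model on (N, 2) coordinates in mm."""
    if kind not in ("paraboloid", "super_gaussian"):
        raise ValueError(f"unknown model kind: {kind!r}")
    coords = np.asarray(coords, dtype=float)
    xr, yr = _rotate(params.theta, coords[..., 0], coords[..., 1])
    if kind == "paraboloid":
        if params.wx <= 0 or params.wy <= 0:
            raise ValueError("paraboloid widths must be positive")
        return params.beta - (
            (xr - params.x0p) ** 2 / params.wx**2 + (yr - params.y0p) ** 2 / params.wy**2
        ) / params.c
    if kind == "super_gaussian":
        if params.sigma_x <= 0 or params.sigma_y <= 0 or params.gamma <= 0:
            raise ValueError("super-Gaussian widths and height must be positive")
        ux = (xr - params.x0p) ** 2 / (2 * params.sigma_x**2)
        uy = (yr - params.y0p) ** 2 / (2 * params.sigma_y**2)
        return params.gamma * np.exp(-(ux**params.beta_x) - uy**params.beta_y)
    raise ValueError(f"unknown model kind: {kind!r}")


def diameter(kind: str, params) -> float:
    """Longest diameter implied by fitted parameters.

    Paraboloid: the zero-level ellipse gives d = max{2a, 2b} and requires
    beta*c > 0. Super-Gaussian: d = max{4 sigma_x, 4 sigma_y}.
    """
    if kind == "paraboloid":
        if params.beta * params.c <= 0:
            raise ValueError("paraboloid has no real zero-level ellipse (beta*c <= 0)")
        return max(2 * params.a, 2 * params.b)
    if kind == "super_gaussian":
        return max(4 * params.sigma_x, 4 * params.sigma_y)
    raise ValueError(f"unknown model kind: {kind!r}")


def _moment_sigmas(pts: np.ndarray, theta: float) -> tuple[float, float, float]:
    """Weighted moment SDs along the rotated axes, and the peak height."""
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    w = np.clip(z, 0.0, None)
    wsum = w.sum()
    xr, yr = _rotate(theta, x, y)
    sx = math.sqrt(max((w * xr**2).sum() / wsum, 1e-6))
    sy = math.sqrt(max((w * yr**2).sum() / wsum, 1e-6))
    return sx, sy, float(z.max())


def _model1_support(patch: WhealPatch, frac: float) -> np.ndarray:
    """Boolean selector over points_centered: z above frac*peak, dilated 1 px."""
    zc = patch.surface - patch.baseline
    peak = zc[patch.mask].max()
    core = (zc >= frac * peak) & patch.mask
    core = ndimage.binary_dilation(core, iterations=1)
    return core[patch.mask]


def _solve(residual_fn, p0, lower, upper, config: FitConfig):
    p0 = np.clip(p0, lower + 1e-12, upper - 1e-12)
    return least_squares(
        residual_fn,
        p0,
        bounds=(lower, upper),
        method="trf",
        xtol=config.tol,
        ftol=config.tol,
        gtol=config.tol,
        max_nfev=config.max_iter * len(p0),
    )


def fit_wheal(patch: WhealPatch, kind: str | None = None, config: FitConfig | None = None) -> ModelFit:
    """Fit one model to a centered patch and derive the longest diameter.

    Initialization comes from patch statistics (peak height, weighted
    moment SDs, PCA angle). If the optimizer fails even after a restart at
    theta0 + 45 deg, or the diameter falls outside the plausible range, the
    fallback diameter 2*sqrt(2)*scale_sigma from the detection stage is
    reported with ``converged=False``.
    """
    config = config or FitConfig()
    kind = kind or config.model
    if kind not in ("paraboloid", "super_gaussian"):
        raise ValueError(f"unknown model kind: {kind!r}")
    if patch.points_centered is None:
        raise ValueError("patch is not centered; call center_patch first")
    pts = patch.points_centered
    theta0 = patch.theta_init or 0.0
    sx0, sy0, peak = _moment_sigmas(pts, theta0)

    half_x = float(np.abs(pts[:, 0]).max())
    half_y = float(np.abs(pts[:, 1]).max())
    s_lo, s_hi = config.sigma_bounds_mm
    b_lo, b_hi = config.flatness_bounds

    if kind == "super_gaussian":
        sel = np.ones(len(pts), dtype=bool)
        x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]

        def residual(p):
            pars = Model2Params(*p)
            return eval_model("super_gaussian", pars, np.column_stack([x, y])) - z

        lower = np.array([-half_x, -half_y, s_lo, s_lo, b_lo, b_lo, 1e-4, -math.pi / 2])
        upper = np.array([half_x, half_y, s_hi, s_hi, b_hi, b_hi, 2 * peak, math.pi / 2])
        p0 = np.array([0.0, 0.0, sx0, sy0, 1.0, 1.0, peak, theta0])
        make_params = lambda p: Model2Params(*p)
    else:
        sel = _model1_support(patch, config.support_fraction)
        x, y, z = pts[sel, 0], pts[sel, 1], pts[sel, 2]

        def residual(p):
            x0, y0, wx, wy, beta, theta = p
            pars = Model1Params(x0, y0, wx, wy, 1.0, beta, theta)
            return eval_model("paraboloid", pars, np.column_stack([x, y])) - z

        # with c pinned to 1, a = wx*sqrt(beta): start the zero crossing
        # near twice the moment SD
        wx0 = 2 * sx0 / math.sqrt(peak)
        wy0 = 2 * sy0 / math.sqrt(peak)
        lower = np.array([-half_x, -half_y, s_lo, s_lo, 1e-6, -math.pi / 2])
        upper = np.array([half_x, half_y, s_hi, s_hi, 2 * peak, math.pi / 2])
        p0 = np.array([0.0, 0.0, wx0, wy0, peak, theta0])
        make_params = lambda p: Model1Params(p[0], p[1], p[2], p[3], 1.0, p[4], p[5])

    n_par = len(p0)
    if len(z) < 2 * n_par:
        raise DegeneratePatchError(f"{len(z)} points cannot constrain {n_par} parameters")

    res = _solve(residual, p0, lower, upper, config)
    if res.status <= 0:
        p0r = p0.copy()
        p0r[-1] = _wrap_half_pi(theta0 + math.pi / 4)
        res = _solve(residual, p0r, lower, upper, config)

    params = make_params(res.x)
    params = _canonicalize(kind, params)
    converged = res.status > 0
    try:
        d = diameter(kind, params)
    except ValueError:
        d = math.nan
        converged = False

    lo, hi = config.fallback_range_mm
    fallback = not converged or not (lo <= d <= hi)
    if fallback:
        if patch.source is None:
            raise ValueError("fit failed and no detection scale for a fallback diameter")
        d = 2 * _SQRT2 * patch.source.scale_sigma
        converged = False
    rms = float(np.sqrt(np.mean(res.fun**2)))
    return ModelFit(
        model_kind=kind,
        params=params,
        diameter_mm=float(d),
        rms_residual=rms,
        converged=converged,
        n_points=int(sel.sum()),
        fallback_used=fallback,
    )


def _canonicalize(kind: str, params):
    """Resolve the axis-swap degeneracy: report the wider axis as x'."""
    if kind == "super_gaussian":
        if params.sigma_x < params.sigma_y:
            # theta -> theta + 90 deg maps (x', y') to (-y', x')
            return Model2Params(
                x0p=-params.y0p,
                y0p=params.x0p,
                sigma_x=params.sigma_y,
                sigma_y=params.sigma_x,
                beta_x=params.beta_y,
                beta_y=params.beta_x,
                gamma=params.gamma,
                theta=_wrap_half_pi(params.theta + math.pi / 2),
            )
    else:
        if params.wx < params.wy:
            return Model1Params(
                x0p=-params.y0p,
                y0p=params.x0p,
                wx=params.wy,
                wy=params.wx,
                c=params.c,
                beta=params.beta,
                theta=_wrap_half_pi(params.theta + math.pi / 2),
            )
    return params
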