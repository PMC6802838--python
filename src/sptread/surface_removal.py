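"""Global surface removal by band-selective Laplacian-pyramid reconstruction.

The forearm's global curvature lives at very coarse scales and fine sensor
noise plus skin micro-texture (pores, follicles, wrinkles) at the finest
scales, while wheal-sized bumps (3-12 mm across) concentrate in the
intermediate Laplacian bands. Decomposing the height map into a standard
Gaussian-Laplacian pyramid and collapsing only the wheal band therefore
isolates the wheals:

    G_0 = S,  G_{l+1} = (G_l * g) downsampled by 2
    L_l = G_l - expand(G_{l+1}),  L_n = G_n

With n = 7 levels the kept band defaults to levels {2, 3, 4, 5}; levels
{0, 1} carry noise/texture and the top of the pyramid the arm itself.

Note that a Laplacian band of a smoothly curved surface is not zero but a
near-constant proportional to the local curvature, so the band-selected
reconstruction S' of a curved arm carries a smooth quasi-constant offset.
Downstream stages treat S' as defined up to a local baseline.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .heightfield_io import HeightField

__all__ = [
    "PyramidConfig",
    "Pyramid",
    "reduce",
    "expand",
    "decompose",
    "collapse",
    "remove_global_surface",
]

log = logging.getLogger(__name__)

# 5-tap binomial approximation to a Gaussian; the classic pyramid kernel.
_BINOMIAL5 = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


def _default_reduce_kernel() -> np.ndarray:
    return _BINOMIAL5.copy()


def _default_expand_kernel() -> np.ndarray:
    # sum 2 so that zero-inserted upsampling preserves the mean
    return 2.0 * _BINOMIAL5


@dataclass
class PyramidConfig:
    """Pyramid depth, kernels, kept band and border handling.

    ``keep_levels`` is interpreted in units of the full-resolution pyramid:
    if ``n_levels`` ends up lower (small grids), absent kept levels are
    silently dropped with a logged warning.
    """

    n_levels: int = 7
    reduce_kernel: np.ndarray = field(default_factory=_default_reduce_kernel)
    expand_kernel: np.ndarray = field(default_factory=_default_expand_kernel)
    keep_levels: frozenset[int] = frozenset({2, 3, 4, 5})
    border_mode: str = "reflect"
    detrend_degree: int | None = 6

    def __post_init__(self) -> None:
        self.reduce_kernel = np.asarray(self.reduce_kernel, dtype=float)
        self.expand_kernel = np.asarray(self.expand_kernel, dtype=float)
        self.keep_levels = frozenset(int(l) for l in self.keep_levels)
        if self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")
        if not math.isclose(self.reduce_kernel.sum(), 1.0, abs_tol=1e-12):
            raise ValueError("reduce kernel taps must sum to 1")
        if not math.isclose(self.expand_kernel.sum(), 2.0, abs_tol=1e-12):
            raise ValueError("expand kernel taps must sum to 2")
        # keep_levels refers to full-resolution pyramid levels; entries above
        # the actual depth are tolerated (dropped with a warning at collapse)
        bad = [l for l in self.keep_levels if l < 0]
        if bad:
            raise ValueError(f"negative keep_levels: {bad}")


@dataclass
class Pyramid:
    """Gaussian levels G_0..G_n and Laplacian levels L_0..L_n (L_n = G_n)."""

    gaussian_levels: list[np.ndarray]
    laplacian_levels: list[np.ndarray]
    level_shapes: list[tuple[int, int]]
    config: PyramidConfig
    pitch: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    mask: np.ndarray | None = None

    @property
    def n_levels(self) -> int:
        return len(self.laplacian_levels) - 1


def _sepconv(arr: np.ndarray, taps: np.ndarray, mode: str) -> np.ndarray:
    out = ndimage.correlate1d(arr, taps, axis=0, mode=mode)
    return ndimage.correlate1d(out, taps, axis=1, mode=mode)


def reduce(level: np.ndarray, config: PyramidConfig | None = None) -> np.ndarray:
    """Low-pass with g and decimate by 2 keeping even samples (ceil-half dims)."""
    config = config or PyramidConfig()
    arr = np.asarray(level, dtype=float)
    if arr.size == 0:
        raise ValueError("empty grid")
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("grid must be at least 2x2 to reduce")
    return _sepconv(arr, config.reduce_kernel, config.border_mode)[::2, ::2]


# np.pad equivalents of ndimage border modes (for padding coarse levels)
_NDIMAGE_TO_NP_PAD = {
    "reflect": "symmetric",
    "mirror": "reflect",
    "nearest": "edge",
    "constant": "constant",
    "wrap": "wrap",
}


def _upsample_axis(arr: np.ndarray, target_len: int, taps: np.ndarray, axis: int, mode: str) -> np.ndarray:
    """Zero-insertion upsampling by 2 along one axis, border-extended first.

    The coarse samples are padded *before* zero insertion so that the
    border extension respects the sample/zero alternation; reflecting the
    interleaved array would duplicate samples next to zeros and break
    constant preservation at the edges.
    """
    pad = len(taps) // 2
    pad_widths = [(0, 0)] * arr.ndim
    pad_widths[axis] = (pad, pad)
    padded = np.pad(arr, pad_widths, mode=_NDIMAGE_TO_NP_PAD.get(mode, "symmetric"))
    up_shape = list(padded.shape)
    up_shape[axis] = 2 * padded.shape[axis] - 1
    up = np.zeros(up_shape, dtype=float)
    sl = [slice(None)] * arr.ndim
    sl[axis] = slice(None, None, 2)
    up[tuple(sl)] = padded
    out = ndimage.correlate1d(up, taps, axis=axis, mode="constant", cval=0.0)
    crop = [slice(None)] * arr.ndim
    crop[axis] = slice(2 * pad, 2 * pad + target_len)
    return out[tuple(crop)]


def expand(
    level: np.ndarray, target_shape: tuple[int, int], config: PyramidConfig | None = None
) -> np.ndarray:
    """Zero-insertion upsampling to ``target_shape`` followed by smoothing with h."""
    config = config or PyramidConfig()
    arr = np.asarray(level, dtype=float)
    expect = (-(-target_shape[0] // 2), -(-target_shape[1] // 2))
    if arr.shape != expect:
        raise ValueError(
            f"input shape {arr.shape} incompatible with target {target_shape} "
            f"(ceil-half would be {expect})"
        )
    out = _upsample_axis(arr, target_shape[0], config.expand_kernel, 0, config.border_mode)
    return _upsample_axis(out, target_shape[1], config.expand_kernel, 1, config.border_mode)


def _infill(heights: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Fill invalid cells by normalized convolution with escalating width."""
    if valid.all():
        return heights.copy()
    if not valid.any():
        raise ValueError("cannot decompose an all-invalid field")
    filled = np.where(valid, heights, 0.0)
    weights = valid.astype(float)
    out = heights.copy()
    todo = ~valid
    sigma = 2.0
    while todo.any():
        num = ndimage.gaussian_filter(filled, sigma, mode="constant")
        den = ndimage.gaussian_filter(weights, sigma, mode="constant")
        ok = todo & (den > 1e-6)
        out[ok] = num[ok] / den[ok]
        todo &= ~ok
        sigma *= 2.0
        if sigma > 4.0 * max(heights.shape):
            out[todo] = heights[valid].mean()
            break
    return out


def decompose(S: HeightField | np.ndarray, config: PyramidConfig | None = None) -> Pyramid:
    """Build the full Gaussian-Laplacian pyramid of a height field.

    Grids too small for the configured depth get the largest feasible depth
    (both dimensions must stay >= 2 at the top Gaussian level); invalid cells
    are infilled by normalized convolution first, and the mask is kept so
    that collapse can reapply it.
    """
    config = config or PyramidConfig()
    if isinstance(S, HeightField):
        heights, pitch, origin, mask = S.heights, S.pitch, S.origin, S.mask
    else:
        heights = np.asarray(S, dtype=float)
        pitch, origin, mask = 1.0, (0.0, 0.0), np.isfinite(heights)
    heights = _infill(heights, mask)

    n = config.n_levels
    max_n = int(math.floor(math.log2(min(heights.shape)))) if min(heights.shape) >= 2 else 0
    if max_n < n:
        log.warning("grid %s too small for %d pyramid levels; using %d", heights.shape, n, max_n)
        n = max_n
    if n < 1:
        raise ValueError("grid too small for any pyramid level")

    gaussians = [heights]
    for _ in range(n):
        gaussians.append(reduce(gaussians[-1], config))
    laplacians = [
        gaussians[l] - expand(gaussians[l + 1], gaussians[l].shape, config) for l in range(n)
    ]
    laplacians.append(gaussians[n])
    return Pyramid(
        gaussian_levels=gaussians,
        laplacian_levels=laplacians,
        level_shapes=[g.shape for g in gaussians],
        config=config,
        pitch=pitch,
        origin=origin,
        mask=mask,
    )


def collapse(pyramid: Pyramid, keep_levels: set[int] | None = None) -> HeightField:
    """Reconstruct keeping only ``keep_levels`` (others zeroed), coarse to fine."""
    config = pyramid.config
    keep = frozenset(keep_levels) if keep_levels is not None else config.keep_levels
    n = pyramid.n_levels
    absent = [l for l in keep if l > n]
    if absent:
        log.warning("kept levels %s absent from a %d-level pyramid", sorted(absent), n)
    recon = (
        pyramid.laplacian_levels[n]
        if n in keep
        else np.zeros(pyramid.level_shapes[n], dtype=float)
    )
    for l in range(n - 1, -1, -1):
        recon = expand(recon, pyramid.level_shapes[l], config)
        if l in keep:
            recon = recon + pyramid.laplacian_levels[l]
    return HeightField(recon, pyramid.pitch, pyramid.origin, pyramid.mask)


def _polynomial_trend(heights: np.ndarray, valid: np.ndarray, degree: int) -> np.ndarray:
    """Least-squares 2D polynomial (total degree) fitted to the valid cells."""
    rows, cols = heights.shape
    # normalized coordinates for conditioning
    y = np.linspace(-1.0, 1.0, rows)[:, None]
    x = np.linspace(-1.0, 1.0, cols)[None, :]
    terms = [
        (x**i * y**j).ravel() for i in range(degree + 1) for j in range(degree + 1 - i)
    ]
    A = np.column_stack(terms)
    sel = valid.ravel()
    coef, *_ = np.linalg.lstsq(A[sel], heights.ravel()[sel], rcond=None)
    return (A @ coef).reshape(rows, cols)


def remove_global_surface(
    S: HeightField, config: PyramidConfig | None = None, pad: int | None = None
) -> HeightField:
    """Band-selected surface S': decompose then collapse with the kept band.

    Two conditioning steps bracket the pyramid, both targeting content the
    kept band is meant to discard anyway:

    * a global low-order polynomial trend (default total degree 6) is
      subtracted first. A Laplacian band of a curved surface is a smooth
      offset proportional to the local curvature, so feeding the raw arm
      into the pyramid leaves curvature 'ridges' in S' that rival the
      wheals; the detrended residual is flat enough for the band output to
      be curvature-free. The trend is entirely coarse-scale, so S' still
      represents the kept Laplacian band of the input.
    * the residual is padded by antisymmetric (odd) reflection, which
      continues the slope across the border - plain reflection of a sloped
      surface creates a crease whose band-pass energy dwarfs the wheals.

    The pad is cropped away again, so the result has the same shape, pitch,
    origin and mask as the input.
    """
    config = config or PyramidConfig()
    heights = _infill(S.heights, S.mask)
    if config.detrend_degree is not None:
        heights = heights - _polynomial_trend(heights, S.mask, config.detrend_degree)
    if pad is None:
        pad = 2**config.n_levels
    pad = min(pad, S.shape[0] - 1, S.shape[1] - 1)
    padded = np.pad(heights, pad, mode="reflect", reflect_type="odd")
    pyramid = decompose(padded, config)
    recon = collapse(pyramid, config.keep_levels).heights
    if pad:
        recon = recon[pad:-pad, pad:-pad]
    return HeightField(recon, S.pitch, S.origin, S.mask.copy())
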