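import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage
from scipy.signal import convolve2d

from sptread.heightfield_io import HeightField
from sptread.phantoms import PhantomConfig, make_forearm
from sptread.surface_removal import (
    PyramidConfig,
    collapse,
    decompose,
    expand,
    reduce,
    remove_global_surface,
)

CFG = PyramidConfig()
G5 = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


def brute_reduce(arr):
    """Direct 2D convolution with the separable kernel, then decimation."""
    padded = np.pad(arr, 2, mode="symmetric")
    return convolve2d(padded, np.outer(G5, G5), mode="valid")[::2, ::2]


def brute_expand(arr, target):
    """Pad the coarse grid, zero-insert, direct 2D convolution, crop."""
    padded = np.pad(arr, 2, mode="symmetric")
    up = np.zeros((2 * padded.shape[0] - 1, 2 * padded.shape[1] - 1))
    up[::2, ::2] = padded
    kernel = np.outer(2 * G5, 2 * G5)
    full = convolve2d(up, kernel, mode="same")
    return full[4 : 4 + target[0], 4 : 4 + target[1]]


# --------------------------------------------------------------------------
# reduce / expand


def test_reduce_preserves_constants():
    out = reduce(np.full((16, 16), 3.0), CFG)
    assert out.shape == (8, 8)
    assert np.allclose(out, 3.0, atol=1e-12)


def test_reduce_ceil_half_convention():
    assert reduce(np.zeros((8, 257)), CFG).shape == (4, 129)


def test_reduce_rejects_tiny_grids():
    with pytest.raises(ValueError):
        reduce(np.zeros((1, 8)), CFG)


@given(
    rows=st.integers(3, 16),
    cols=st.integers(3, 16),
    seed=st.integers(0, 2**31 - 1),
)
@settings(max_examples=40, deadline=None, derandomize=True)
def test_reduce_matches_direct_convolution(rows, cols, seed):
    arr = np.random.default_rng(seed).normal(size=(rows, cols))
    assert np.allclose(reduce(arr, CFG), brute_reduce(arr), atol=1e-12)


@given(
    rows=st.integers(3, 8),
    cols=st.integers(3, 8),
    odd_r=st.booleans(),
    odd_c=st.booleans(),
    seed=st.integers(0, 2**31 - 1),
)
@settings(max_examples=40, deadline=None, derandomize=True)
def test_expand_matches_direct_convolution(rows, cols, odd_r, odd_c, seed):
    target = (2 * rows - (1 if odd_r else 0), 2 * cols - (1 if odd_c else 0))
    arr = np.random.default_rng(seed).normal(size=(rows, cols))
    assert np.allclose(expand(arr, target, CFG), brute_expand(arr, target), atol=1e-12)


def test_expand_preserves_constants():
    out = expand(np.full((5, 5), 2.5), (9, 9), CFG)
    assert out.shape == (9, 9)
    assert np.allclose(out, 2.5, atol=1e-12)


def test_expand_rejects_incompatible_target():
    with pytest.raises(ValueError, match="incompatible"):
        expand(np.zeros((5, 5)), (12, 12), CFG)


def test_expand_reduce_is_near_identity_on_lowpass_field(rng):
    """Band-limited content survives a reduce/expand round trip (<5% RMS)."""
    field = ndimage.gaussian_filter(rng.normal(size=(64, 64)), 8.0, mode="reflect")
    rec = expand(reduce(field, CFG), field.shape, CFG)
    rel = np.sqrt(((rec - field) ** 2).mean()) / np.sqrt((field**2).mean())
    assert rel < 0.05


# --------------------------------------------------------------------------
# decompose / collapse


def test_decompose_level_shapes_and_identity():
    S = np.random.default_rng(0).normal(size=(256, 256))
    pyr = decompose(S, CFG)
    assert pyr.level_shapes == [(s, s) for s in (256, 128, 64, 32, 16, 8, 4, 2)]
    assert np.array_equal(pyr.gaussian_levels[0], S)
    assert np.array_equal(pyr.laplacian_levels[-1], pyr.gaussian_levels[-1])


def test_constant_field_has_no_detail():
    pyr = decompose(np.full((256, 256), 1.7), CFG)
    for lap in pyr.laplacian_levels[:-1]:
        assert np.abs(lap).max() < 1e-9
    assert np.allclose(pyr.laplacian_levels[-1], 1.7, atol=1e-9)


@given(
    rows=st.integers(16, 48),
    cols=st.integers(16, 48),
    seed=st.integers(0, 2**31 - 1),
)
@settings(max_examples=25, deadline=None, derandomize=True)
def test_perfect_reconstruction_property(rows, cols, seed):
    """Collapsing with every level reproduces the input to 1e-9 mm."""
    S = np.random.default_rng(seed).normal(size=(rows, cols))
    pyr = decompose(S, PyramidConfig(n_levels=4))
    rec = collapse(pyr, set(range(pyr.n_levels + 1)))
    assert np.abs(rec.heights - S).max() < 1e-9


def test_collapse_empty_keep_is_zero():
    pyr = decompose(np.random.default_rng(1).normal(size=(64, 64)), PyramidConfig(n_levels=5))
    assert np.abs(collapse(pyr, set()).heights).max() == 0.0


def test_collapse_additive_over_disjoint_band_sets():
    pyr = decompose(np.random.default_rng(2).normal(size=(128, 128)), CFG)
    a = collapse(pyr, {0, 2, 5}).heights
    b = collapse(pyr, {1, 3, 7}).heights
    both = collapse(pyr, {0, 1, 2, 3, 5, 7}).heights
    assert np.abs(both - (a + b)).max() < 1e-9


def test_band_energy_monotone_on_smooth_field(rng):
    """On a low-frequency field, growing the kept band grows reconstructed energy."""
    field = ndimage.gaussian_filter(rng.normal(size=(64, 64)), 6.0, mode="reflect")
    pyr = decompose(field, PyramidConfig(n_levels=5))
    keep, prev = set(), 0.0
    for level in range(pyr.n_levels + 1):
        keep.add(level)
        energy = float((collapse(pyr, keep).heights ** 2).sum())
        assert energy >= prev - 1e-12
        prev = energy


def test_small_grid_lowers_depth_with_warning(caplog):
    with caplog.at_level(logging.WARNING, logger="sptread.surface_removal"):
        pyr = decompose(np.zeros((40, 40)), CFG)
    assert pyr.n_levels == 5
    assert any("pyramid levels" in r.message for r in caplog.records)


def test_masked_cells_are_infilled_and_mask_propagates(rng):
    heights = rng.normal(0, 0.1, size=(256, 256))
    heights[100:105, 40:45] = np.nan
    field = HeightField(heights, pitch=0.2)
    out = remove_global_surface(field)
    assert out.shape == field.shape
    assert (out.mask == field.mask).all()
    assert np.isfinite(out.heights).all()


# --------------------------------------------------------------------------
# remove_global_surface


def test_all_zero_field_stays_zero():
    out = remove_global_surface(HeightField(np.zeros((256, 256)), pitch=0.2))
    assert np.abs(out.heights).max() < 1e-9


def test_remove_global_surface_is_linear(rng):
    S1 = rng.normal(size=(128, 128))
    S2 = rng.normal(size=(128, 128))
    a, b = 1.7, -0.4
    cfg = PyramidConfig(detrend_degree=None)
    combined = remove_global_surface(HeightField(a * S1 + b * S2, 0.2), cfg).heights
    parts = (
        a * remove_global_surface(HeightField(S1, 0.2), cfg).heights
        + b * remove_global_surface(HeightField(S2, 0.2), cfg).heights
    )
    assert np.abs(combined - parts).max() < 1e-9


def test_plane_removed_and_bump_retained():
    """A tilted plane is wiped out while a wheal-scale bump keeps 60-100% height."""
    pitch = 0.2
    xs = np.arange(256) * pitch
    xx, yy = np.meshgrid(xs, xs)
    plane = 0.05 * xx + 0.02 * yy
    bump = 0.3 * np.exp(-(((xx - 25.6) ** 2 + (yy - 25.6) ** 2) / (2 * 1.5**2)))
    plane_out = remove_global_surface(HeightField(plane, pitch)).heights
    assert np.sqrt((plane_out**2).mean()) < 0.05 * np.sqrt((plane**2).mean())
    both_out = remove_global_surface(HeightField(plane + bump, pitch)).heights
    assert 0.6 * 0.3 <= both_out.max() <= 1.0 * 0.3


def test_pure_cylinder_leaves_negligible_residual():
    cfg = PhantomConfig(n_wheals=0, noise_sd=0.0, texture_amplitude=0.0)
    field, _ = make_forearm(cfg)
    out = remove_global_surface(field)
    assert np.sqrt((out.heights**2).mean()) <= 0.02


def test_config_validation():
    with pytest.raises(ValueError):
        PyramidConfig(n_levels=0)
    with pytest.raises(ValueError):
        PyramidConfig(keep_levels={-1})
    with pytest.raises(ValueError):
        PyramidConfig(reduce_kernel=np.array([1.0, 1.0]))
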