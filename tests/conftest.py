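import math

import numpy as np
import pytest

from sptread.blob_detection import BlobCandidate, WhealPatch
from sptread.parametric_fit import Model2Params, eval_model


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def sample_model2_patch(
    params: Model2Params,
    pitch: float = 0.15,
    half_mm: float = 6.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    scale_sigma: float = 1.8,
) -> WhealPatch:
    """Sample a super-Gaussian surface on a square patch grid."""
    n = int(round(half_mm / pitch))
    xs = np.arange(-n, n + 1) * pitch
    xx, yy = np.meshgrid(xs, xs)
    z = eval_model("super_gaussian", params, np.stack([xx, yy], axis=-1))
    if noise_sd:
        z = z + np.random.default_rng(seed).normal(0.0, noise_sd, z.shape)
    return WhealPatch(
        surface=z,
        mask=np.ones_like(z, dtype=bool),
        origin_global=(-half_mm, -half_mm),
        pitch=pitch,
        source=BlobCandidate(n, n, (0.0, 0.0), scale_sigma, 0.2),
    )


def gaussian_bump_field(
    h: float, sigma_b: float, pitch: float = 0.2, n: int = 200
) -> np.ndarray:
    xs = (np.arange(n) - n // 2) * pitch
    xx, yy = np.meshgrid(xs, xs)
    return h * np.exp(-(xx**2 + yy**2) / (2 * sigma_b**2))


def rotate_deg(theta_deg: float):
    t = math.radians(theta_deg)
    return t
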