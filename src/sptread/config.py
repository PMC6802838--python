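"""Flat key-value configuration files for the pipeline.

Keys are dotted (``pyramid.n_levels``, ``detect.sigma_min``, ``fit.model``,
``report.positive_threshold_mm``) and map onto the stage config
dataclasses. YAML nesting is also accepted and flattened.
"""

from __future__ import annotations

import os

import yaml

from .blob_detection import DetectionConfig
from .parametric_fit import FitConfig
from .pipeline import PipelineConfig
from .surface_removal import PyramidConfig

__all__ = ["load_config", "config_from_mapping"]

_KEYMAP = {
    "pyramid.n_levels": ("pyramid", "n_levels", int),
    "pyramid.keep_levels": ("pyramid", "keep_levels", lambda v: frozenset(int(x) for x in v)),
    "pyramid.border_mode": ("pyramid", "border_mode", str),
    "detect.sigma_min": ("detect", "sigma_min", float),
    "detect.sigma_max": ("detect", "sigma_max", float),
    "detect.n_scales": ("detect", "n_scales", int),
    "detect.response_threshold": ("detect", "response_threshold", float),
    "detect.overlap": ("detect", "overlap_threshold", float),
    "detect.patch_factor": ("detect", "patch_halfwidth_factor", float),
    "fit.model": ("fit", "model", str),
    "fit.max_iter": ("fit", "max_iter", int),
    "fit.tol": ("fit", "tol", float),
    "fit.support_fraction": ("fit", "support_fraction", float),
    "fit.fallback_range_mm": ("fit", "fallback_range_mm", lambda v: tuple(float(x) for x in v)),
    "report.positive_threshold_mm": (None, "positive_threshold_mm", float),
    "report.decimals": (None, "report_decimals", int),
}


def _flatten(mapping: dict, prefix: str = "") -> dict:
    flat = {}
    for key, value in mapping.items():
        name = f"{prefix}{key}"
        if isinstance(value, dict):
            flat.update(_flatten(value, f"{name}."))
        else:
            flat[name] = value
    return flat


def config_from_mapping(mapping: dict) -> PipelineConfig:
    flat = _flatten(mapping or {})
    config = PipelineConfig(
        pyramid=PyramidConfig(), detect=DetectionConfig(), fit=FitConfig()
    )
    for key, value in flat.items():
        if key not in _KEYMAP:
            raise KeyError(f"unknown config key: {key!r}")
        section, attr, conv = _KEYMAP[key]
        target = config if section is None else getattr(config, section)
        setattr(target, attr, conv(value))
    config.pyramid.__post_init__()
    config.detect.__post_init__()
    return config


def load_config(path: str | os.PathLike) -> PipelineConfig:
    with open(path) as fh:
        return config_from_mapping(yaml.safe_load(fh) or {})
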