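"""YAML configuration loading for the command-line interface.

Recognised keys (all optional, defaults shown in the dataclasses):

.. code-block:: yaml

    gabor:    {orientations, wavelength, envelope_sizes, ratio}
    glcm:     {features, window_radius, step, levels}
    seeding:  {sigma_mode, sigma_value, window_size, similarity_factor}
    range:    {mode, n_s, r, spacing_m, propagate_every}
    levelset: {model, alpha, epsilon, theta, v_const, max_iterations,
               check_every, volume_delta_fraction, keep_components,
               normalize_data}
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

from .levelset import ConvergenceParams, SpeedParams
from .seeding import SeedingParams, SliceRangeSpec
from .texture import GaborConfig, GLCMConfig

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    gabor: GaborConfig
    glcm: GLCMConfig
    seeding: SeedingParams
    range_spec: SliceRangeSpec
    speed: SpeedParams
    conv: ConvergenceParams
    keep_components: int | None = None


def _pick(section: dict, mapping: dict[str, str]) -> dict:
    return {dst: section[src] for src, dst in mapping.items() if src in section}


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file (or defaults)."""
    raw = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}

    gabor = GaborConfig(
        **_pick(
            raw.get("gabor", {}),
            {
                "orientations": "orientations",
                "wavelength": "wavelength",
                "envelope_sizes": "envelope_sizes",
                "ratio": "ratio",
            },
        )
    )
    glcm = GLCMConfig(
        **_pick(
            raw.get("glcm", {}),
            {
                "features": "features",
                "window_radius": "window_radius",
                "step": "step",
                "levels": "levels",
            },
        )
    )
    seeding = SeedingParams(
        **_pick(
            raw.get("seeding", {}),
            {
                "sigma_mode": "sigma_mode",
                "sigma_value": "sigma_value",
                "window_size": "window_size",
                "similarity_factor": "similarity_factor",
            },
        )
    )
    range_spec = SliceRangeSpec(
        **_pick(
            raw.get("range", {}),
            {
                "mode": "mode",
                "n_s": "n_s",
                "r": "r",
                "spacing_m": "spacing_m",
                "propagate_every": "propagate_every",
            },
        )
    )
    ls = raw.get("levelset", {})
    speed = SpeedParams(
        **_pick(
            ls,
            {
                "model": "model",
                "alpha": "alpha",
                "epsilon": "epsilon",
                "theta": "theta",
                "v_const": "v_const",
                "normalize_data": "normalize_data",
            },
        )
    )
    conv = ConvergenceParams(
        check_every_j=int(ls.get("check_every", 10)),
        volume_delta_threshold=ls.get("volume_delta_threshold"),
        max_iterations=int(ls.get("max_iterations", 200)),
        volume_delta_fraction=float(ls.get("volume_delta_fraction", 0.005)),
    )
    keep = ls.get("keep_components")
    return PipelineConfig(gabor, glcm, seeding, range_spec, speed, conv, keep)
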