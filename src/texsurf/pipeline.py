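"""End-to-end segmentation: seeding -> level-set evolution -> optional cleanup."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .levelset import (
    ConvergenceParams,
    FeatureStats,
    SpeedParams,
    evolve,
    init_phi,
    intensity_data_term,
    postprocess_components,
    texture_data_term,
)
from .seeding import (
    SeedContour,
    SeedingParams,
    SliceRangeSpec,
    assign_contours_to_slices,
    build_seed_mask,
)
from .texture import GaborConfig, GLCMConfig, FeatureStack, gabor_stack, glcm_features, standardize_stack
from .volume_io import MaskVolume, Volume

__all__ = ["SegmentationResult", "segment", "bridge_slices"]


@dataclass
class SegmentationResult:
    """Final mask plus the intermediate products useful for inspection."""

    mask: MaskVolume
    seed_mask: MaskVolume
    history: list[tuple[int, int]]
    target_T: float | None = None
    iterations: int = 0
    converged: bool = False


def bridge_slices(seed: MaskVolume, spacing_m: int) -> MaskVolume:
    """Close the start region along z across unprocessed slices.

    With a slice spacing of ``m`` the start regions are plates on every
    m-th slice.  A voxel exactly between two plates is a stationary point
    of the upwind level-set update (zero one-sided and central gradients),
    so the gaps would never fill; bridging them at initialisation restores
    the solid start volume the plates stand for.
    """
    if spacing_m <= 1:
        return seed
    structure = np.ones((spacing_m + 1, 1, 1), dtype=bool)
    closed = ndimage.binary_closing(seed.as_bool(), structure=structure)
    return MaskVolume(closed.astype(np.uint8), seed.spacing, seed.origin)


def _texture2d_data_term(
    volume: Volume,
    seed: MaskVolume,
    assigned: list[tuple[int, SeedContour]],
    gabor_config: GaborConfig,
    glcm_config: GLCMConfig,
    params: SpeedParams,
) -> np.ndarray:
    """Per-slice binary texture term; slices without seed content get -v."""
    data = np.asarray(volume.data, dtype=np.float64)
    seed_arr = seed.as_bool()
    D = np.full(data.shape, -params.v_const, dtype=np.float64)
    for z in sorted({z for z, _ in assigned}):
        if not seed_arr[z].any():
            continue
        maps = dict(gabor_stack(data[z], gabor_config))
        maps.update(dict(glcm_features(data[z], glcm_config)))
        stack = standardize_stack(FeatureStack(maps))
        stats = FeatureStats.from_stack(stack, seed_arr[z])
        D[z] = texture_data_term(stack, stats, params)
    return D


def segment(
    volume: Volume,
    contours: list[SeedContour],
    range_spec: SliceRangeSpec,
    gabor_config: GaborConfig | None = None,
    glcm_config: GLCMConfig | None = None,
    seeding_params: SeedingParams | None = None,
    speed_params: SpeedParams | None = None,
    conv_params: ConvergenceParams | None = None,
    keep_components: int | None = None,
    roi: tuple[int, int, int, int] | None = None,
) -> SegmentationResult:
    """Run the full pipeline on a volume with user seed contours.

    The start region is built from the Gabor texture probability maps,
    the level set is initialised as a signed distance to it and evolved
    under the configured model.  For the 3D intensity model the target
    ``T`` is the mean volume intensity over the start region (unless the
    caller fixed ``speed_params.target_T``).
    """
    gabor_config = gabor_config or GaborConfig()
    glcm_config = glcm_config or GLCMConfig()
    seeding_params = seeding_params or SeedingParams()
    speed_params = speed_params or SpeedParams()
    conv_params = conv_params or ConvergenceParams()

    seed = build_seed_mask(
        volume, contours, range_spec, gabor_config, seeding_params, roi=roi
    )
    if seed.voxel_count() == 0:
        raise ValueError("seeding produced an empty start region")
    if speed_params.model == "intensity3d":
        start = bridge_slices(seed, range_spec.spacing_m)
    else:
        start = seed  # the 2D model evolves the processed slices only
    field_ = init_phi(start)

    if speed_params.model == "intensity3d":
        if speed_params.target_T is None:
            t_value = float(np.asarray(volume.data)[start.as_bool()].mean())
            speed_params = SpeedParams(
                alpha=speed_params.alpha,
                epsilon=speed_params.epsilon,
                target_T=t_value,
                theta=speed_params.theta,
                v_const=speed_params.v_const,
                model=speed_params.model,
                normalize_data=speed_params.normalize_data,
            )
        D = intensity_data_term(volume, speed_params)
    else:
        assigned = assign_contours_to_slices(
            contours, range_spec, volume.shape[0]
        )
        D = _texture2d_data_term(
            volume, seed, assigned, gabor_config, glcm_config, speed_params
        )

    mask, history = evolve(field_, D, speed_params, conv_params)
    iterations = history[-1][0] if history else 0
    converged = iterations < conv_params.max_iterations
    if keep_components:
        mask = postprocess_components(
            MaskVolume(mask.data, volume.spacing, volume.origin), keep_components
        )
    result_mask = MaskVolume(mask.data, volume.spacing, volume.origin)
    return SegmentationResult(
        mask=result_mask,
        seed_mask=seed,
        history=history,
        target_T=speed_params.target_T,
        iterations=iterations,
        converged=converged,
    )
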