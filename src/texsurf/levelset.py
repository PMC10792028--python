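"""Level-set active-surface evolution with intensity or texture data terms.

The segmented object is the positive region of a scalar field ``phi``
evolved under::

    d(phi)/dt = |grad phi| * F,     F = alpha * D + (1 - alpha) * kappa

where ``D`` is the image data term, ``kappa = div(grad phi / |grad phi|)``
the mean curvature of the implicit surface and ``alpha`` a balance weight.
``phi > 0`` marks the inside, so positive ``D`` (tissue similar to the
seeds) expands the object and negative ``D`` retracts it.

Two data terms are provided.  The 3D intensity model uses a tolerance band
around the mean seed intensity ``T``::

    D(p) = epsilon - |I(p) - T|

The 2D texture model tests every feature map against its seed statistics:
a point gets ``+v`` when no feature deviates from its seed mean by more
than ``theta`` standard deviations, and ``-v`` otherwise; slices evolve
independently with 2D stencils.

Discretisation: explicit Euler with a Godunov upwind gradient for the data
part, central differences for curvature, replicated (Neumann) boundaries,
and ``phi`` clamped to a fixed band around the surface.  The time step is
a conservative CFL bound derived from the data-term magnitude and the
parabolic curvature limit, so runs are stable without reinitialisation.
Evolution halts when the object voxel count changes by less than a
threshold between successive checks (every ``check_every_j`` iterations),
or at ``max_iterations``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .texture import FeatureStack
from .volume_io import MaskVolume, Volume

__all__ = [
    "LevelSetField",
    "SpeedParams",
    "ConvergenceParams",
    "FeatureStats",
    "init_phi",
    "intensity_data_term",
    "texture_data_term",
    "curvature_term",
    "evolve",
    "check_convergence",
    "default_volume_threshold",
    "postprocess_components",
]

#: Numerical guards of the discretisation (see module docstring).
ADVECTIVE_CFL = 0.9
DIFFUSIVE_CFL = 0.45
PHI_BAND = 5.0
CURVATURE_CLAMP = 1.0
CURVATURE_ETA = 1e-8
DATA_CLAMP = 4.0


@dataclass
class LevelSetField:
    """The implicit surface: ``phi > 0`` inside, zero level = surface."""

    phi: np.ndarray
    iteration: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.phi).all():
            raise ValueError("phi must be finite everywhere")

    def object_mask(self) -> np.ndarray:
        return self.phi > 0


@dataclass
class SpeedParams:
    """Speed-function parameters.

    alpha:
        Balance between the data term and curvature smoothing, in [0, 1].
    epsilon:
        Intensity tolerance (HU) of the 3D model.
    target_T:
        Intensity target: the mean intensity over the initial regions.
    theta:
        Texture sensitivity of the 2D model (deviation threshold in
        per-feature standard deviations).
    v_const:
        Magnitude of the binary texture data term.
    model:
        ``'intensity3d'`` or ``'texture2d'``.
    normalize_data:
        When true, the intensity data term is scaled by ``1/epsilon`` and
        clamped to ``+-DATA_CLAMP`` so data and curvature magnitudes are
        commensurate; default is the raw term with an adaptive time step.
    """

    alpha: float = 0.0125
    epsilon: float = 750.0
    target_T: float | None = None
    theta: float = 4.0
    v_const: float = 2.0
    model: str = "intensity3d"
    normalize_data: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.v_const <= 0:
            raise ValueError("v_const must be positive")
        if self.model not in ("intensity3d", "texture2d"):
            raise ValueError("model must be 'intensity3d' or 'texture2d'")


@dataclass
class ConvergenceParams:
    """Stopping rule: volume-change check every ``check_every_j`` iterations.

    ``volume_delta_threshold=None`` resolves at run time to
    ``volume_delta_fraction`` (default 0.5%) of the seed voxel count -- an
    estimate of the target volume -- floored at 50 voxels.
    """

    check_every_j: int = 10
    volume_delta_threshold: float | None = None
    max_iterations: int = 200
    volume_delta_fraction: float = 0.005

    def __post_init__(self) -> None:
        if self.check_every_j < 1:
            raise ValueError("check_every_j must be >= 1")
        if self.volume_delta_threshold is not None and self.volume_delta_threshold < 0:
            raise ValueError("volume_delta_threshold must be >= 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.volume_delta_fraction < 0:
            raise ValueError("volume_delta_fraction must be >= 0")


@dataclass
class FeatureStats:
    """Per-feature mean and standard deviation inside the initial regions."""

    mean: dict[str, float]
    std: dict[str, float]

    @classmethod
    def from_stack(cls, stack: FeatureStack, seed_mask: np.ndarray) -> "FeatureStats":
        seed_mask = np.asarray(seed_mask, dtype=bool)
        if not seed_mask.any():
            raise ValueError("empty seed region for feature statistics")
        mean, std = {}, {}
        for name, m in stack:
            values = m[seed_mask]
            mean[name] = float(values.mean())
            std[name] = float(values.std())
        return cls(mean, std)


def default_volume_threshold(seed_voxel_count: int, fraction: float = 0.005) -> float:
    """A fraction of the estimated target volume, floored at 50 voxels."""
    return max(50.0, fraction * float(seed_voxel_count))


def init_phi(seed: MaskVolume) -> LevelSetField:
    """Signed Euclidean distance to the seed boundary (voxel units).

    Positive inside the seed, negative outside; the zero level sits half a
    voxel outside the seed's outermost voxel centers.
    """
    inside = seed.as_bool()
    if not inside.any():
        raise ValueError("empty initialization")
    if inside.all():
        return LevelSetField(np.full(inside.shape, PHI_BAND, dtype=np.float64))
    d_in = ndimage.distance_transform_edt(inside)
    d_out = ndimage.distance_transform_edt(~inside)
    phi = np.where(inside, d_in - 0.5, -(d_out - 0.5))
    return LevelSetField(np.clip(phi, -PHI_BAND, PHI_BAND))


def intensity_data_term(volume: Volume, params: SpeedParams) -> np.ndarray:
    """``D(p) = epsilon - |I(p) - T|`` per voxel."""
    if params.target_T is None:
        raise ValueError("target_T must be set (mean seed intensity)")
    data = np.asarray(volume.data, dtype=np.float64)
    return params.epsilon - np.abs(data - params.target_T)


def texture_data_term(
    stack: FeatureStack, stats: FeatureStats, params: SpeedParams
) -> np.ndarray:
    """Binary texture term: ``+v`` where no feature deviates, ``-v`` otherwise.

    A feature deviates at ``p`` when ``|m(p) - mean(m)| > theta * std(m)``;
    features with zero seed standard deviation deviate iff the value
    differs from the mean.
    """
    deviating: np.ndarray | None = None
    for name, m in stack:
        if name not in stats.mean:
            raise ValueError(f"missing statistics for feature {name!r}")
        mu, sd = stats.mean[name], stats.std[name]
        dev = np.abs(m - mu) > params.theta * sd if sd > 0 else m != mu
        deviating = dev if deviating is None else (deviating | dev)
    assert deviating is not None
    return np.where(deviating, -params.v_const, params.v_const)


def _gradients(phi: np.ndarray, axes: tuple[int, ...]) -> list[np.ndarray]:
    return [np.gradient(phi, axis=a) for a in axes]


def curvature_term(field: LevelSetField | np.ndarray, axes: tuple[int, ...] | None = None) -> np.ndarray:
    """Mean curvature ``div(grad phi / |grad phi|)`` by central differences.

    ``axes`` restricts the stencil (e.g. in-plane axes for the slice-wise
    2D model).  The denominator is guarded by a small eta and the result
    clamped to ``+-CURVATURE_CLAMP``.  For a signed distance function that
    is positive inside a sphere of radius ``rho`` the value near the
    surface is about ``-2/rho`` in 3D (``-1/rho`` in 2D).
    """
    phi = field.phi if isinstance(field, LevelSetField) else np.asarray(field)
    if not np.issubdtype(phi.dtype, np.floating):
        phi = phi.astype(np.float64)
    if axes is None:
        axes = tuple(range(phi.ndim))
    grads = _gradients(phi, axes)
    grad_sq = sum(g**2 for g in grads)
    num = np.zeros_like(phi)
    for i, ai in enumerate(axes):
        others = sum(grads[j] ** 2 for j in range(len(axes)) if j != i)
        num += np.gradient(grads[i], axis=ai) * others
    for i in range(len(axes)):
        for j in range(i + 1, len(axes)):
            cross = np.gradient(grads[i], axis=axes[j])
            num -= 2.0 * grads[i] * grads[j] * cross
    kappa = num / (grad_sq**1.5 + CURVATURE_ETA)
    return np.clip(kappa, -CURVATURE_CLAMP, CURVATURE_CLAMP)


def _upwind_gradnorm(phi: np.ndarray, positive_speed: np.ndarray, axes: tuple[int, ...]) -> np.ndarray:
    """Godunov upwind |grad phi| for a data speed of the given sign.

    Sign convention: phi > 0 inside and F > 0 expands the object (phi
    grows), so information for an expanding front travels from high phi to
    low phi -- the scheme for F > 0 keeps descending backward slopes and
    ascending forward slopes, and swaps them for F < 0.
    """
    g_pos = np.zeros_like(phi)
    g_neg = np.zeros_like(phi)
    for a in axes:
        fwd = np.diff(phi, axis=a, append=np.take(phi, [-1], axis=a))
        bwd = np.diff(phi, axis=a, prepend=np.take(phi, [0], axis=a))
        g_pos += np.minimum(bwd, 0.0) ** 2 + np.maximum(fwd, 0.0) ** 2
        g_neg += np.maximum(bwd, 0.0) ** 2 + np.minimum(fwd, 0.0) ** 2
    return np.sqrt(np.where(positive_speed, g_pos, g_neg))


def _central_gradnorm(phi: np.ndarray, axes: tuple[int, ...]) -> np.ndarray:
    return np.sqrt(sum(g**2 for g in _gradients(phi, axes)))


def evolve(
    field: LevelSetField,
    data_term: np.ndarray,
    params: SpeedParams,
    conv: ConvergenceParams | None = None,
    ignore_convergence: bool = False,
) -> tuple[MaskVolume, list[tuple[int, int]]]:
    """Evolve the level set until volume-change convergence.

    Returns the final object mask (``phi > 0``) and the history of
    ``(iteration, object voxel count)`` at every convergence check.  With
    ``ignore_convergence=True`` the loop always runs to ``max_iterations``
    (used to probe stability after convergence).  The input field is
    updated in place (``phi`` and ``iteration``).
    """
    conv = conv or ConvergenceParams()
    phi = np.asarray(field.phi, dtype=np.float32).copy()
    D = np.asarray(data_term, dtype=np.float32)
    if D.shape != phi.shape:
        raise ValueError("data term shape must match phi")

    axes = (1, 2) if params.model == "texture2d" else tuple(range(phi.ndim))
    if params.model == "texture2d" and phi.ndim != 3:
        axes = tuple(range(max(0, phi.ndim - 2), phi.ndim))

    if params.normalize_data and params.model == "intensity3d":
        D = np.clip(D / params.epsilon, -DATA_CLAMP, DATA_CLAMP)

    max_d = float(np.abs(D).max())
    # combined stability bound: advective Courant number for the data part
    # plus the parabolic limit for the curvature part
    denom = (
        params.alpha * max_d / ADVECTIVE_CFL
        + (1.0 - params.alpha) * 2.0 * len(axes) / DIFFUSIVE_CFL
    )
    dt = 1.0 / denom if denom > 0 else DIFFUSIVE_CFL
    positive_speed = D > 0

    threshold = conv.volume_delta_threshold
    if threshold is None:
        threshold = default_volume_threshold(
            int((phi > 0).sum()), conv.volume_delta_fraction
        )

    history: list[tuple[int, int]] = []
    alpha = params.alpha
    for n in range(1, conv.max_iterations + 1):
        update = np.zeros_like(phi)
        if alpha > 0:
            update += alpha * D * _upwind_gradnorm(phi, positive_speed, axes)
        if alpha < 1:
            kappa = curvature_term(phi, axes)
            update += (1.0 - alpha) * kappa * _central_gradnorm(phi, axes)
        phi += dt * update
        np.clip(phi, -PHI_BAND, PHI_BAND, out=phi)
        if not np.isfinite(phi).all():
            raise FloatingPointError(
                f"non-finite phi at iteration {n} (CFL violation)"
            )
        if n % conv.check_every_j == 0:
            counts = [c for _, c in history] + [int((phi > 0).sum())]
            history.append((n, counts[-1]))
            if not ignore_convergence and check_convergence(
                counts, ConvergenceParams(conv.check_every_j, threshold, conv.max_iterations)
            ):
                break

    field.phi = phi
    field.iteration += history[-1][0] if history else conv.max_iterations
    mask = MaskVolume((phi > 0).astype(np.uint8))
    return mask, history


def check_convergence(history: list[float], conv: ConvergenceParams) -> bool:
    """True iff the last two checkpoint counts differ by at most the threshold.

    ``history`` holds object voxel counts at successive checks (spaced
    ``check_every_j`` iterations apart); fewer than two checkpoints means
    not converged.
    """
    if len(history) < 2:
        return False
    threshold = conv.volume_delta_threshold
    if threshold is None:
        raise ValueError("volume_delta_threshold must be resolved before checking")
    return abs(float(history[-1]) - float(history[-2])) <= threshold


def postprocess_components(mask: MaskVolume, keep_n: int) -> MaskVolume:
    """Keep the ``keep_n`` largest 26-connected components of a mask."""
    if keep_n < 1:
        raise ValueError("keep_n must be >= 1")
    structure = np.ones((3, 3, 3), dtype=bool)
    labels, n = ndimage.label(mask.as_bool(), structure=structure)
    if n <= keep_n:
        return mask
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = np.argsort(sizes)[::-1][:keep_n] + 1
    out = np.isin(labels, keep).astype(np.uint8)
    return MaskVolume(out, mask.spacing, mask.origin)
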