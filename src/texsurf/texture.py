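"""Slice-wise texture features: Gabor filter bank and windowed GLCM statistics.

The Gabor bank characterises oriented band-pass structure of the lung
parenchyma; the grey-level co-occurrence matrix (GLCM) features summarise
local second-order statistics.  Both are computed per slice (2D), even for
3D volumes, because seeding and the 2D texture model operate image by image.

Gabor kernel convention
-----------------------
A kernel is a real cosine carrier of the given wavelength along the
orientation axis, modulated by an anisotropic Gaussian with along-carrier
standard deviation ``sigma`` and cross-carrier standard deviation
``sigma / ratio``.  The support is the smallest odd square covering three
standard deviations in both directions and the kernel is made zero-mean
(DC-corrected) so constant regions give a null response.  The feature map
is the magnitude of the 2D convolution response with edge replication at
the borders.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.signal import fftconvolve

from .volume_io import Volume

__all__ = [
    "GaborConfig",
    "GLCMConfig",
    "FeatureStack",
    "gabor_kernel",
    "gabor_bank",
    "apply_gabor_bank",
    "gabor_stack",
    "glcm_features",
    "standardize_stack",
]

GLCM_FEATURE_NAMES = ("contrast", "entropy", "homogeneity", "energy", "correlation")


@dataclass
class GaborConfig:
    """Parameters of the Gabor filter bank.

    Defaults follow the reference configuration used for lung CT: three
    orientations (0, 45, 90 degrees), wavelength 8 px, two Gaussian
    envelope sizes (1 and 2 px) and envelope aspect ratio 0.25, giving a
    bank of six filters.
    """

    orientations: tuple[float, ...] = (0.0, 45.0, 90.0)
    wavelength: float = 8.0
    envelope_sizes: tuple[float, ...] = (1.0, 2.0)
    ratio: float = 0.25

    def __post_init__(self) -> None:
        self.orientations = tuple(float(o) for o in self.orientations)
        self.envelope_sizes = tuple(float(s) for s in self.envelope_sizes)
        if not self.orientations:
            raise ValueError("at least one orientation required")
        if self.wavelength <= 0 or self.ratio <= 0:
            raise ValueError("wavelength and ratio must be positive")
        if not all(s > 0 for s in self.envelope_sizes):
            raise ValueError("envelope sizes must be positive")


@dataclass
class GLCMConfig:
    """Parameters of the per-pixel windowed GLCM features.

    ``features`` selects among contrast, entropy, homogeneity, energy and
    correlation.  Pairs are accumulated over the ``(2*window_radius+1)**2``
    window around each pixel at the four standard offsets (0/45/90/135
    degrees, Chebyshev length ``step``), symmetrised and normalised.
    Grey levels are linearly quantised over the image min-max range.
    """

    features: tuple[str, ...] = GLCM_FEATURE_NAMES
    window_radius: int = 3
    step: int = 1
    levels: int = 32
    angles_deg: tuple[int, ...] = (0, 45, 90, 135)

    def __post_init__(self) -> None:
        self.features = tuple(self.features)
        unknown = set(self.features) - set(GLCM_FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown GLCM features: {sorted(unknown)}")
        if self.window_radius < 1:
            raise ValueError("window_radius must be >= 1")
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if set(self.angles_deg) - {0, 45, 90, 135}:
            raise ValueError("angles_deg must be a subset of {0, 45, 90, 135}")


@dataclass
class FeatureStack:
    """An ordered collection of named scalar feature maps.

    Maps are 2D (per slice) or 3D (per volume, computed slice-wise) and all
    share the source image's in-plane shape; every map is finite-valued.
    """

    maps: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if not self.maps:
            raise ValueError("feature stack must contain at least one map")
        shapes = {m.shape for m in self.maps.values()}
        if len(shapes) != 1:
            raise ValueError("all maps must share the source shape")
        for name, m in self.maps.items():
            if not np.isfinite(m).all():
                raise ValueError(f"map {name!r} contains non-finite values")

    @property
    def names(self) -> list[str]:
        return list(self.maps)

    @property
    def shape(self) -> tuple[int, ...]:
        return next(iter(self.maps.values())).shape

    def __len__(self) -> int:
        return len(self.maps)

    def __iter__(self):
        return iter(self.maps.items())

    def __getitem__(self, name: str) -> np.ndarray:
        return self.maps[name]

    def slice_stack(self, z: int) -> "FeatureStack":
        """Extract the 2D stack for slice ``z`` from 3D maps."""
        return FeatureStack({name: m[z] for name, m in self.maps.items()})


def gabor_kernel(
    orientation_deg: float,
    wavelength_px: float,
    envelope_sigma_px: float,
    ratio: float,
) -> np.ndarray:
    """Build one real, zero-mean Gabor kernel (see module docstring)."""
    if wavelength_px <= 0 or envelope_sigma_px <= 0 or ratio <= 0:
        raise ValueError("wavelength, envelope sigma and ratio must be positive")
    sigma_along = envelope_sigma_px
    sigma_cross = envelope_sigma_px / ratio
    half = int(math.ceil(3.0 * max(sigma_along, sigma_cross)))
    y, x = np.mgrid[-half : half + 1, -half : half + 1]
    theta = math.radians(orientation_deg)
    xr = x * math.cos(theta) + y * math.sin(theta)
    yr = -x * math.sin(theta) + y * math.cos(theta)
    kernel = np.cos(2.0 * np.pi * xr / wavelength_px) * np.exp(
        -(xr**2 / (2.0 * sigma_along**2) + yr**2 / (2.0 * sigma_cross**2))
    )
    return kernel - kernel.mean()


def gabor_bank(config: GaborConfig) -> dict[str, np.ndarray]:
    """One kernel per (orientation, envelope size) pair, in deterministic order."""
    kernels: dict[str, np.ndarray] = {}
    for orientation in config.orientations:
        for sigma in config.envelope_sizes:
            name = f"gabor_o{orientation:g}_s{sigma:g}"
            kernels[name] = gabor_kernel(
                orientation, config.wavelength, sigma, config.ratio
            )
    return kernels


def _convolve_replicated(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    # FFT convolution on an edge-padded image == spatial convolution with
    # replicated borders; kernels are point-symmetric so flip is immaterial.
    hy, hx = kernel.shape[0] // 2, kernel.shape[1] // 2
    padded = np.pad(image.astype(np.float64), ((hy, hy), (hx, hx)), mode="edge")
    return fftconvolve(padded, kernel, mode="valid")


def gabor_stack(image: np.ndarray, config: GaborConfig | None = None) -> FeatureStack:
    """Gabor response magnitudes of a single 2D image."""
    config = config or GaborConfig()
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("gabor_stack expects a 2D image")
    return FeatureStack(
        {
            name: np.abs(_convolve_replicated(image, kernel))
            for name, kernel in gabor_bank(config).items()
        }
    )


def apply_gabor_bank(volume: Volume, config: GaborConfig | None = None) -> FeatureStack:
    """Gabor response magnitudes for every slice of a volume (3D maps)."""
    config = config or GaborConfig()
    kernels = gabor_bank(config)
    data = np.asarray(volume.data, dtype=np.float64)
    maps = {
        name: np.stack(
            [np.abs(_convolve_replicated(data[z], kernel)) for z in range(data.shape[0])]
        )
        for name, kernel in kernels.items()
    }
    return FeatureStack(maps)


_OFFSETS_BY_ANGLE = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@njit(cache=False)
def _glcm_maps(q, levels, radius, offsets):  # pragma: no cover - numba kernel
    h, w = q.shape
    n_off = offsets.shape[0]
    out = np.zeros((5, h, w))
    glcm = np.zeros((levels, levels))
    for cy in range(h):
        y0 = cy - radius if cy - radius > 0 else 0
        y1 = cy + radius if cy + radius < h - 1 else h - 1
        for cx in range(w):
            x0 = cx - radius if cx - radius > 0 else 0
            x1 = cx + radius if cx + radius < w - 1 else w - 1
            glcm[:, :] = 0.0
            total = 0.0
            for yy in range(y0, y1 + 1):
                for xx in range(x0, x1 + 1):
                    for k in range(n_off):
                        y2 = yy + offsets[k, 0]
                        x2 = xx + offsets[k, 1]
                        if y0 <= y2 <= y1 and x0 <= x2 <= x1:
                            i = q[yy, xx]
                            j = q[y2, x2]
                            glcm[i, j] += 1.0
                            glcm[j, i] += 1.0
                            total += 2.0
            if total == 0.0:
                # no valid pair in the (clipped) window: degenerate values
                out[2, cy, cx] = 1.0
                out[3, cy, cx] = 1.0
                continue
            contrast = 0.0
            entropy = 0.0
            homogeneity = 0.0
            energy = 0.0
            mu_i = 0.0
            mu_j = 0.0
            for i in range(levels):
                for j in range(levels):
                    p = glcm[i, j] / total
                    if p > 0.0:
                        contrast += p * (i - j) * (i - j)
                        entropy -= p * np.log(p)
                        homogeneity += p / (1.0 + abs(i - j))
                        energy += p * p
                        mu_i += p * i
                        mu_j += p * j
            var_i = 0.0
            var_j = 0.0
            cov = 0.0
            for i in range(levels):
                for j in range(levels):
                    p = glcm[i, j] / total
                    if p > 0.0:
                        var_i += p * (i - mu_i) * (i - mu_i)
                        var_j += p * (j - mu_j) * (j - mu_j)
                        cov += p * (i - mu_i) * (j - mu_j)
            denom = np.sqrt(var_i * var_j)
            correlation = cov / denom if denom > 0.0 else 0.0
            out[0, cy, cx] = contrast
            out[1, cy, cx] = entropy
            out[2, cy, cx] = homogeneity
            out[3, cy, cx] = energy
            out[4, cy, cx] = correlation
    return out


def quantize(image: np.ndarray, levels: int) -> np.ndarray:
    """Linear min-max binning of an image into ``levels`` integer bins."""
    image = np.asarray(image, dtype=np.float64)
    lo, hi = image.min(), image.max()
    if hi == lo:
        return np.zeros(image.shape, dtype=np.int32)
    q = np.floor((image - lo) / (hi - lo) * levels).astype(np.int32)
    return np.clip(q, 0, levels - 1)


def glcm_features(image: np.ndarray, config: GLCMConfig | None = None) -> FeatureStack:
    """Per-pixel GLCM feature maps of a 2D image (see :class:`GLCMConfig`)."""
    config = config or GLCMConfig()
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("glcm_features expects a 2D image")
    if not np.isfinite(image).all():
        raise ValueError("image must be finite")
    window = 2 * config.window_radius + 1
    if image.shape[0] < window or image.shape[1] < window:
        raise ValueError("window exceeds image")
    q = quantize(image, config.levels)
    offsets = np.array(
        [
            (dy * config.step, dx * config.step)
            for angle, (dy, dx) in _OFFSETS_BY_ANGLE.items()
            if angle in config.angles_deg
        ],
        dtype=np.int64,
    )
    all_maps = _glcm_maps(q, config.levels, config.window_radius, offsets)
    by_name = dict(zip(GLCM_FEATURE_NAMES, all_maps))
    return FeatureStack({f"glcm_{name}": by_name[name] for name in config.features})


def standardize_stack(stack: FeatureStack) -> FeatureStack:
    """Z-score each map over its slice; constant maps become all-zero."""
    out = {}
    for name, m in stack:
        std = m.std()
        out[name] = (m - m.mean()) / std if std > 0 else np.zeros_like(m)
    return FeatureStack(out)
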