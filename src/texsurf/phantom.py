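"""Deterministic synthetic CT-like phantoms for end-to-end testing.

A phantom contains ellipsoidal "lung" targets filled with an oriented,
speckle-modulated cosine grating, embedded in a background carrying a
grating of a different orientation, plus bright tubular vessel-like
clutter crossing the targets and additive Gaussian noise.  Intensities are
loosely Hounsfield-like: targets oscillate around -800 HU (aerated
parenchyma), the background sits around +200 HU (mediastinal/chest-wall
soft tissue, outside the default intensity tolerance band around the seed
mean), and vessels are bright against the parenchyma (-100 HU) yet still
inside the band, like the small intrapulmonary vessels that reference lung
masks keep.

The speckle modulation (a smooth random gain on the grating amplitude)
matters: it gives the texture stationary small-scale variability, so a
seed contour placed anywhere inside a target samples statistics that are
representative of the whole region -- the property real parenchyma has and
pure gratings lack.  Without it the window-similarity criterion of the
seeding stage degenerates, because the contour region would be
unrepresentatively homogeneous.

Gratings make the Gabor separability of the two regions provable: the
generator checks that the matched-orientation filters of the default bank
respond at least three times more strongly on their own texture than on
the other one (rendered full-frame, noise-free) and rejects specs that
fail, so seeding tests are well-posed by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .seeding import SeedContour, SliceRangeSpec
from .texture import GaborConfig, gabor_stack
from .volume_io import MaskVolume, Volume

__all__ = [
    "TextureSpec",
    "PhantomSpec",
    "LesionSpec",
    "generate_phantom",
    "degrade_phantom",
    "separability_ratio",
    "suggested_range",
]


@dataclass(frozen=True)
class TextureSpec:
    """An oriented cosine grating with optional speckle amplitude modulation.

    The pattern is ``base + amplitude * cos(2*pi*u/wavelength) * g`` with
    ``u`` the coordinate along ``orientation_deg`` and ``g`` a smooth
    random gain field ``1 + speckle * N(0,1)`` low-pass filtered at
    ``speckle_scale`` pixels.
    """

    wavelength: float
    orientation_deg: float
    amplitude: float
    base: float
    speckle: float = 0.5
    speckle_scale: float = 2.0

    def _carrier(self, shape: tuple[int, int]) -> np.ndarray:
        y, x = np.mgrid[: shape[0], : shape[1]]
        theta = math.radians(self.orientation_deg)
        u = x * math.cos(theta) + y * math.sin(theta)
        return np.cos(2.0 * np.pi * u / self.wavelength)

    def _gain(self, shape, rng: np.random.Generator | None) -> np.ndarray | float:
        if self.speckle <= 0 or rng is None:
            return 1.0
        f = ndimage.gaussian_filter(rng.normal(size=shape), self.speckle_scale)
        # clip the modulation tail so the texture swing stays bounded
        return 1.0 + self.speckle * np.clip(f / f.std(), -2.0, 2.0)

    def render(
        self, shape: tuple[int, int], rng: np.random.Generator | None = None
    ) -> np.ndarray:
        """Render one 2D frame of the texture."""
        return self.base + self.amplitude * self._carrier(shape) * self._gain(shape, rng)

    def render_volume(
        self, shape: tuple[int, int, int], rng: np.random.Generator | None = None
    ) -> np.ndarray:
        """Render a 3D field: the in-plane carrier under a 3D speckle gain.

        The gain varies along z as well, so out-of-band texture extremes
        are compact blobs rather than columns through the whole stack.
        """
        carrier = self._carrier(shape[1:])[None, :, :]
        return self.base + self.amplitude * carrier * self._gain(shape, rng)


@dataclass
class PhantomSpec:
    """Recipe for a synthetic two-texture CT-like volume.

    Defaults give two side-by-side ellipsoidal targets wide enough that
    the default Gabor bank's kernel footprint does not swallow their
    interior, target intensities whose full swing stays inside the default
    level-set tolerance band, and a background strictly outside it.
    """

    shape: tuple[int, int, int] = (40, 256, 256)
    n_targets: int = 2
    target_texture: TextureSpec = field(
        default_factory=lambda: TextureSpec(8.0, 0.0, 350.0, -800.0)
    )
    background_texture: TextureSpec = field(
        default_factory=lambda: TextureSpec(8.0, 90.0, 50.0, 200.0)
    )
    noise_sigma: float = 20.0
    n_vessels: int = 3
    vessel_radius: float = 1.5
    vessel_intensity: float = -100.0
    rng_seed: int = 0
    seed_radius: float = 8.0
    #: optional explicit [(center_zyx, semi_zyx), ...]; default geometry
    #: places n_targets ellipsoids side by side along x
    target_geometry: list[tuple[tuple[float, float, float], tuple[float, float, float]]] | None = None

    def __post_init__(self) -> None:
        if len(self.shape) != 3:
            raise ValueError("shape must have three axes")
        self.shape = tuple(int(s) for s in self.shape)
        if any(a < b for a, b in zip(self.shape, (16, 32, 32))):
            raise ValueError("shape must be at least (16, 32, 32)")
        if self.n_targets < 1:
            raise ValueError("need at least one target")
        same_wl = self.target_texture.wavelength == self.background_texture.wavelength
        same_or = (
            self.target_texture.orientation_deg
            == self.background_texture.orientation_deg
        )
        if same_wl and same_or:
            raise ValueError(
                "target and background textures must differ in wavelength or orientation"
            )
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass(frozen=True)
class LesionSpec:
    """A spherical texture-destroying lesion inside a target.

    The lesion region is re-filled with a background-like grating at an
    elevated base intensity, emulating dense pathological tissue; the
    ground-truth mask is deliberately left unchanged.
    """

    center: tuple[int, int, int]
    radius: float
    base_intensity: float = -300.0
    wavelength: float = 8.0
    orientation_deg: float = 90.0
    amplitude: float = 60.0


def _target_geometry(
    spec: PhantomSpec,
) -> list[tuple[tuple[float, float, float], tuple[float, float, float]]]:
    """Centers and semi-axes (z, y, x) of the target ellipsoids."""
    if spec.target_geometry is not None:
        return list(spec.target_geometry)
    nz, ny, nx = spec.shape
    n = spec.n_targets
    semi = (0.36 * nz, 0.32 * ny, 0.34 * nx / n)
    return [
        ((nz / 2.0, ny / 2.0, (2 * k + 1) * nx / (2.0 * n)), semi) for k in range(n)
    ]


def _ellipsoid_mask(shape, center, semi) -> np.ndarray:
    z, y, x = np.ogrid[: shape[0], : shape[1], : shape[2]]
    cz, cy, cx = center
    az, ay, ax = semi
    return ((z - cz) / az) ** 2 + ((y - cy) / ay) ** 2 + ((x - cx) / ax) ** 2 <= 1.0


def separability_ratio(spec: PhantomSpec) -> float:
    """Noise-free Gabor response ratio between the two textures.

    Each texture is rendered full-frame (no region boundary, so the
    intensity step between regions cannot leak edge responses into the
    comparison) without speckle or noise, and filtered with the default
    bank.  For the filters oriented with the target grating the ratio is
    the mean response on the target texture over the mean response on the
    background texture, and conversely for the background-oriented
    filters; the certificate is the minimum of the two.
    """
    shape = spec.shape[1:]
    margin = 25  # discard the replication border of the widest default kernel
    stacks = {
        "target": gabor_stack(spec.target_texture.render(shape), GaborConfig()),
        "background": gabor_stack(spec.background_texture.render(shape), GaborConfig()),
    }

    def _mean(which: str, orientation: float) -> float:
        maps = [
            m[margin:-margin, margin:-margin]
            for name, m in stacks[which]
            if f"_o{orientation:g}_" in name
        ]
        return float(sum(m.mean() for m in maps)) if maps else 0.0

    o_t = spec.target_texture.orientation_deg
    o_b = spec.background_texture.orientation_deg
    r_target = _mean("target", o_t) / max(_mean("background", o_t), 1e-30)
    r_background = _mean("background", o_b) / max(_mean("target", o_b), 1e-30)
    return min(r_target, r_background)


def _generate(spec: PhantomSpec, check: bool = True):
    rng = np.random.default_rng(spec.rng_seed)
    nz, ny, nx = spec.shape
    targets = _target_geometry(spec)

    for center, semi in targets:
        for c, a, n in zip(center, semi, spec.shape):
            if c - a < 1 or c + a > n - 1:
                raise ValueError("targets would overlap the volume border")

    tg_field = spec.target_texture.render_volume(spec.shape, rng)
    bg_field = spec.background_texture.render_volume(spec.shape, rng)
    data = bg_field.copy()

    mask = np.zeros(spec.shape, dtype=bool)
    for center, semi in targets:
        ell = _ellipsoid_mask(spec.shape, center, semi)
        mask |= ell
        data[ell] = tg_field[ell]

    # vessels: bright cylinders along y, clipped to the target interiors and
    # kept clear of the seed-contour slices in z
    for k in range(spec.n_vessels):
        center, semi = targets[k % len(targets)]
        dz = float(rng.uniform(0.25, 0.45) * semi[0]) * (1 if k % 2 == 0 else -1)
        dx = float(rng.uniform(-0.5, 0.5) * semi[2])
        z0, x0 = center[0] + dz, center[2] + dx
        zg, _, xg = np.ogrid[:nz, :1, :nx]
        cyl = (zg - z0) ** 2 + (xg - x0) ** 2 <= spec.vessel_radius**2
        data[np.broadcast_to(cyl, spec.shape) & mask] = spec.vessel_intensity

    if spec.noise_sigma > 0:
        data = data + rng.normal(0.0, spec.noise_sigma, spec.shape)

    seeds: list[SeedContour] = []
    for center, semi in targets:
        for frac in (-0.6, 0.0, 0.6):
            z = int(round(center[0] + frac * semi[0]))
            z = min(max(z, 0), nz - 1)
            seeds.append(
                SeedContour(z, (float(center[1]), float(center[2])), spec.seed_radius)
            )

    volume = Volume(data.astype(np.float64))
    gt = MaskVolume(mask.astype(np.uint8))
    if check:
        ratio = separability_ratio(spec)
        if ratio < 3.0:
            raise ValueError(
                f"textures are not Gabor-separable (ratio {ratio:.2f} < 3)"
            )
    return volume, gt, seeds


def generate_phantom(spec: PhantomSpec | None = None):
    """Generate ``(Volume, ground-truth MaskVolume, seed contours)``.

    Deterministic for a fixed ``rng_seed``; the ground-truth mask is the
    union of the target ellipsoids (vessel voxels inside targets are part
    of the reference, as in lung masks that keep small vessels).  Seed
    contours are discs of ``seed_radius`` at each target's center slice
    and at 60% of its axial extent on both sides.
    """
    return _generate(spec or PhantomSpec(), check=True)


def suggested_range(spec: PhantomSpec, spacing_m: int = 2) -> SliceRangeSpec:
    """Mode-A slice range spanning the targets' axial extent.

    Anchored at the central seed slice with the radius that keeps the seed
    disc inside every processed slice's target cross-section.
    """
    nz = spec.shape[0]
    semi_z = 0.36 * nz
    n_s = nz // 2
    # keep in-plane cross-section large enough to hold the seed disc
    semi_x = _target_geometry(spec)[0][1][2]
    frac = math.sqrt(max(1.0 - ((spec.seed_radius + 2.0) / semi_x) ** 2, 0.0))
    r = int(semi_z * frac)
    return SliceRangeSpec(mode="A", n_s=n_s, r=r, spacing_m=spacing_m)


def degrade_phantom(volume: Volume, lesion: LesionSpec) -> Volume:
    """Return a copy with a spherical lesion burned into the volume.

    The lesion replaces the local texture with a background-like grating
    at an elevated intensity; the companion ground-truth mask is not
    touched, so segmentation quality is expected to degrade gracefully.
    """
    if lesion.radius <= 0:
        return Volume(volume.data.copy(), volume.spacing, volume.origin)
    data = np.array(volume.data, dtype=np.float64, copy=True)
    z, y, x = np.ogrid[: data.shape[0], : data.shape[1], : data.shape[2]]
    cz, cy, cx = lesion.center
    sphere = (z - cz) ** 2 + (y - cy) ** 2 + (x - cx) ** 2 <= lesion.radius**2
    tex = TextureSpec(
        lesion.wavelength,
        lesion.orientation_deg,
        lesion.amplitude,
        lesion.base_intensity,
        speckle=0.0,
    )
    filled = np.broadcast_to(tex.render(data.shape[1:]), data.shape)
    data[sphere] = filled[sphere]
    return Volume(data, volume.spacing, volume.origin)
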