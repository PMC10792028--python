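"""Segmentation-quality metrics between a result mask R and a reference G.

Overlap measures (from voxel counts)::

    DC  = 2 |G & R| / (|G| + |R|)
    VOE = 100 (1 - |G & R| / |G | R|)
    RVD = 100 (|R| - |G|) / |G|

Surface measures use the sets of surface voxels (object voxels with at
least one background 6-neighbour, the volume border counting as
background) and Euclidean center-to-center distances in millimetres.  MSD
is the symmetric mean of both directed nearest-surface distance lists;
HD95 is the 95th percentile (linear interpolation) of the pooled multiset
of both lists, a robust variant of the Hausdorff distance.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .volume_io import MaskVolume

__all__ = [
    "MetricsReport",
    "overlap_metrics",
    "surface_voxels",
    "surface_distances",
    "evaluate_masks",
]


@dataclass
class MetricsReport:
    """The five quality measures plus the raw voxel counts behind them."""

    dc: float
    voe: float
    rvd: float
    msd: float
    hd95: float
    n_reference: int
    n_result: int
    n_intersection: int

    def as_dict(self) -> dict:
        return asdict(self)


def _as_bool(mask: MaskVolume | np.ndarray) -> np.ndarray:
    if isinstance(mask, MaskVolume):
        return mask.as_bool()
    return np.asarray(mask).astype(bool)


def overlap_metrics(G: MaskVolume | np.ndarray, R: MaskVolume | np.ndarray) -> tuple[float, float, float]:
    """Dice coefficient, volume overlap error (%) and relative volume
    difference (%) from exact integer voxel counts."""
    g = _as_bool(G)
    r = _as_bool(R)
    if g.shape != r.shape:
        raise ValueError("masks must share a shape")
    n_g = int(g.sum())
    if n_g == 0:
        raise ValueError("empty reference")
    n_r = int(r.sum())
    n_i = int((g & r).sum())
    n_u = n_g + n_r - n_i
    dc = 2.0 * n_i / (n_g + n_r)
    voe = 100.0 * (1.0 - n_i / n_u)
    rvd = 100.0 * (n_r - n_g) / n_g
    return dc, voe, rvd


def surface_voxels(mask: MaskVolume | np.ndarray) -> np.ndarray:
    """Boolean map of object voxels with >= 1 background 6-neighbour.

    The volume border counts as background, so objects touching the edge
    still contribute surface voxels there.
    """
    m = _as_bool(mask)
    structure = ndimage.generate_binary_structure(m.ndim, 1)
    eroded = ndimage.binary_erosion(m, structure=structure, border_value=0)
    return m & ~eroded


def surface_distances(
    G: MaskVolume | np.ndarray,
    R: MaskVolume | np.ndarray,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> tuple[float, float]:
    """Symmetric mean surface distance and 95th-percentile Hausdorff (mm)."""
    g = _as_bool(G)
    r = _as_bool(R)
    if g.shape != r.shape:
        raise ValueError("masks must share a shape")
    if not g.any() or not r.any():
        raise ValueError("empty mask")
    sp = np.asarray(spacing, dtype=float)
    coords_g = np.argwhere(surface_voxels(g)) * sp
    coords_r = np.argwhere(surface_voxels(r)) * sp
    d_gr, _ = cKDTree(coords_r).query(coords_g)
    d_rg, _ = cKDTree(coords_g).query(coords_r)
    pooled = np.concatenate([d_gr, d_rg])
    msd = float(pooled.sum() / (len(d_gr) + len(d_rg)))
    hd95 = float(np.percentile(pooled, 95))
    return msd, hd95


def evaluate_masks(
    G: MaskVolume,
    R: MaskVolume,
    spacing: tuple[float, float, float] | None = None,
) -> MetricsReport:
    """Full metrics report for a (reference, result) mask pair."""
    if spacing is None:
        spacing = G.spacing if isinstance(G, MaskVolume) else (1.0, 1.0, 1.0)
    dc, voe, rvd = overlap_metrics(G, R)
    msd, hd95 = surface_distances(G, R, spacing)
    g = _as_bool(G)
    r = _as_bool(R)
    return MetricsReport(
        dc=dc,
        voe=voe,
        rvd=rvd,
        msd=msd,
        hd95=hd95,
        n_reference=int(g.sum()),
        n_result=int(r.sum()),
        n_intersection=int((g & r).sum()),
    )
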