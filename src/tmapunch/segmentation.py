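"""Colour segmentation of H&E tiles and nuclei-mask extraction.

Each tile is partitioned by 3-class k-means in RGB space into the three
stain classes of an H&E scene -- white (mucus / empty), pink (cytoplasm,
basic) and blue (nuclei, acid).  Cluster labels are arbitrary, so clusters
are ranked by the luminance of their centroid: brightest -> white,
middle -> pink, darkest -> blue.  The nuclei mask keeps (a configurable dark
fraction of) the blue class and is then cleaned by a disk dilation followed
by hole filling, which turns rings of touching nuclei into solid
agglomerates suitable for ellipse fitting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import dilation, disk
from sklearn.cluster import KMeans

from ._util import LUMA_WEIGHTS, as_rgb_u8, luminance, round_half_up
from .errors import DegenerateImageError

__all__ = [
    "SegmentationResult",
    "NucleiMask",
    "segment_kmeans3",
    "nuclei_mask",
    "clean_mask",
    "default_element_radius",
]


@dataclass(frozen=True)
class SegmentationResult:
    """Disjoint white / pink / blue masks covering every tile pixel."""

    white_mask: np.ndarray
    pink_mask: np.ndarray
    blue_mask: np.ndarray


@dataclass(frozen=True)
class NucleiMask:
    """Binary nuclei mask plus the cleaning element radius (0 = raw)."""

    mask: np.ndarray
    element_radius: int = 0


def segment_kmeans3(tile: np.ndarray, seed: int = 0) -> SegmentationResult:
    """Cluster tile pixels into white / pink / blue stain classes.

    k-means (k=3, Euclidean distance in RGB, 10 restarts, fixed seed) runs
    on the distinct colours weighted by their pixel counts, which is exact
    and much faster than clustering every pixel.

    Raises
    ------
    DegenerateImageError
        If the tile holds fewer than three distinct colours.
    """
    img = as_rgb_u8(tile)
    pixels = img.reshape(-1, 3)
    colors, inverse, counts = np.unique(
        pixels, axis=0, return_inverse=True, return_counts=True
    )
    if colors.shape[0] < 3:
        raise DegenerateImageError(
            f"tile holds only {colors.shape[0]} distinct colour(s)"
        )
    km = KMeans(n_clusters=3, n_init=10, random_state=seed)
    color_labels = km.fit_predict(
        colors.astype(np.float64), sample_weight=counts.astype(np.float64)
    )
    center_lum = km.cluster_centers_ @ np.asarray(LUMA_WEIGHTS)
    order = np.argsort(center_lum)[::-1]  # bright -> dark
    labels = color_labels[inverse].reshape(img.shape[:2])
    white, pink, blue = (labels == order[i] for i in range(3))
    return SegmentationResult(white_mask=white, pink_mask=pink, blue_mask=blue)


def nuclei_mask(
    tile: np.ndarray, seg: SegmentationResult, dark_fraction: float = 1.0
) -> NucleiMask:
    """Binary mask of the darkest ``dark_fraction`` of blue-class pixels.

    The default fraction 1.0 keeps the whole blue cluster; lower values
    keep only the most intensely stained (most acid) pixels, ranked by
    luminance.  An empty blue cluster yields an empty mask.
    """
    if not 0.0 <= dark_fraction <= 1.0:
        raise ValueError("dark_fraction must lie in [0, 1]")
    blue = np.asarray(seg.blue_mask, dtype=bool)
    if dark_fraction >= 1.0 or not blue.any():
        return NucleiMask(mask=blue.copy())
    lum = luminance(tile)
    vals = lum[blue]
    k = int(round_half_up(dark_fraction * vals.size))
    if k <= 0:
        return NucleiMask(mask=np.zeros_like(blue))
    cutoff = np.partition(vals, k - 1)[k - 1]
    return NucleiMask(mask=blue & (lum <= cutoff))


def default_element_radius(r_ref: float) -> int:
    """Disk radius (px) spanning about one micrometre at resolution r_ref."""
    return max(1, int(round_half_up(1.0 / r_ref)))


def clean_mask(nm: NucleiMask, radius: Optional[int] = None, r_ref: float = 0.46) -> NucleiMask:
    """Dilate by a disk element, then fill enclosed holes.

    Dilation bridges gaps between touching nuclei; hole filling (background
    4-connectivity, the dual of the 8-connected foreground) solidifies the
    resulting agglomerates.  The output is always a superset of the input.
    """
    r = default_element_radius(r_ref) if radius is None else int(radius)
    mask = np.asarray(nm.mask, dtype=bool)
    if r > 0 and mask.any():
        mask = dilation(mask, footprint=disk(r))
    mask = ndi.binary_fill_holes(mask)
    return NucleiMask(mask=mask, element_radius=r)
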