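"""Model-independent local thickness of the nuclei mask.

The local thickness at a foreground point ``p`` is the diameter of the
largest disk that contains ``p`` and fits entirely inside the structure:

    tau(p) = 2 * max{ r : p in disk(x, r), disk(x, r) subset of mask }

It is a model-independent thickness estimator: no assumption about the
shape of the object is required, which matters because gland cross-sections
come in unknown geometries.  Double cell layers around a lumen produce
thick walls (large tau), single pathological layers thin ones.

Computation follows the classic distance-map / distance-ridge route:

1. the exact Euclidean distance transform gives, for every foreground
   pixel, the radius of the largest disk centred there;
2. the distance ridge keeps only the maximal (non-redundant) disks;
3. tau is the diameter of the largest disk covering each pixel.

Everything outside the image border counts as background.  Disks are open
(pixel ``y`` belongs to ``disk(x, r)`` iff ``|y - x| < r``), which makes the
maximal radius at ``x`` exactly the distance-transform value ``d(x)``.  All
containment tests run on squared integer distances, so the result is exact.

The thickness map is rendered to an 8-bit image on a fixed absolute scale
(``tau_display_max`` micrometres map to 255) so that tiles are comparable,
and a tile shows a double cell layer when the number of bright pixels
(intensity >= 1.3 * P_REF) exceeds ``530 / r_ref**2``.
"""

from __future__ import annotations

import math
from typing import List, Tuple

import numpy as np
from scipy import ndimage as ndi

from ._util import round_half_up
from .calibration import ReferenceProfile

__all__ = [
    "SINGLE_LAYER",
    "DOUBLE_LAYER",
    "euclidean_distance_map",
    "distance_ridge",
    "local_thickness",
    "render_thickness_image",
    "count_bright",
    "classify_layering",
    "bright_count_cutoff",
]

SINGLE_LAYER = "single_layer"
DOUBLE_LAYER = "double_layer"

#: um**2-denominated constant of the bright-pixel count threshold.
BRIGHT_COUNT_CONST = 530.0
#: factor on P_REF defining "bright" rendered intensities.
BRIGHT_FACTOR = 1.3
#: default absolute rendering scale: thickness mapped linearly to [0, 255]
#: with this value (in micrometres) at full intensity.
TAU_DISPLAY_MAX_UM = 20.0


def _squared_edt(mask: np.ndarray) -> np.ndarray:
    """Exact squared Euclidean distance to the nearest background pixel.

    The image border is treated as background, so a mask touching the edge
    is still bounded by it.
    """
    padded = np.pad(np.asarray(mask, dtype=bool), 1, constant_values=False)
    d = ndi.distance_transform_edt(padded)
    # EDT values are square roots of integers; squaring and rounding
    # recovers the integer exactly.
    return np.rint(d * d).astype(np.int64)[1:-1, 1:-1]


def euclidean_distance_map(mask: np.ndarray) -> np.ndarray:
    """Exact Euclidean distance map of a binary mask (0 on background)."""
    return np.sqrt(_squared_edt(mask).astype(np.float64))


def _contained(s2: np.ndarray, a2: int, b2: np.ndarray) -> np.ndarray:
    """Exact test ``sqrt(s2) + sqrt(a2) <= sqrt(b2)`` on integers.

    Equivalent to disk(p, d_p) being inside disk(q, d_q) with s2 = |p-q|**2,
    a2 = d_p**2, b2 = d_q**2.
    """
    rhs = b2 - s2 - a2
    return (rhs >= 0) & (4 * s2 * a2 <= rhs * rhs)


def distance_ridge(dist: np.ndarray) -> List[Tuple[Tuple[int, int], float]]:
    """Maximal inscribed disks ``((y, x), radius)`` of a distance map.

    A disk ``(p, d(p))`` is redundant when another centre ``q`` satisfies
    ``|p - q| + d(p) <= d(q)``; only non-redundant disks are returned.
    Every foreground pixel is covered by at least one returned disk.
    Quadratic in the number of foreground pixels; intended for masks of
    moderate size (the thickness computation itself does not need it).
    """
    d = np.asarray(dist, dtype=np.float64)
    d2 = np.rint(d * d).astype(np.int64)
    ys, xs = np.nonzero(d2 > 0)
    if ys.size == 0:
        return []
    v = d2[ys, xs]
    order = np.argsort(-v, kind="stable")
    ys, xs, v = ys[order], xs[order], v[order]
    out: List[Tuple[Tuple[int, int], float]] = []
    for i in range(ys.size):
        # only strictly larger disks can strictly contain disk i
        k = np.searchsorted(-v, -v[i], side="left")
        if k > 0:
            s2 = (ys[:k] - ys[i]) ** 2 + (xs[:k] - xs[i]) ** 2
            if _contained(s2, int(v[i]), v[:k]).any():
                continue
        out.append(((int(ys[i]), int(xs[i])), float(math.sqrt(v[i]))))
    return out


def _disk_offsets(v: int, width: int) -> np.ndarray:
    """Flat-index offsets of pixels with squared norm <= v - 1."""
    r = math.isqrt(max(v - 1, 0))
    oy, ox = np.mgrid[-r : r + 1, -r : r + 1]
    keep = oy * oy + ox * ox <= v - 1
    return (oy[keep] * width + ox[keep]).astype(np.int64)


def local_thickness(mask: np.ndarray) -> np.ndarray:
    """Per-pixel local thickness tau (px) of a binary mask.

    tau(p) is twice the largest distance-transform value d(x) over centres
    x whose open disk of radius d(x) contains p.  Painting every maximal
    disk, largest first, realises the ridge definition exactly: redundant
    disks never raise the maximum because their containing disk has a
    radius at least as large.
    """
    m = np.asarray(mask, dtype=bool)
    tau = np.zeros(m.shape, dtype=np.float64)
    if not m.any():
        return tau
    d2 = _squared_edt(m)
    ys, xs = np.nonzero(m)
    v = d2[ys, xs]
    rmax = math.isqrt(int(v.max()))
    h, w = m.shape
    pw = w + 2 * rmax
    t2 = np.zeros((h + 2 * rmax) * pw, dtype=np.int64)
    base = (ys + rmax).astype(np.int64) * pw + (xs + rmax)
    order = np.argsort(-v, kind="stable")
    v = v[order]
    base = base[order]
    # process one distinct squared radius at a time; within a group every
    # centre paints the same value, so scattered duplicates are harmless
    boundaries = np.flatnonzero(np.diff(v)) + 1
    start = 0
    for stop in list(boundaries) + [v.size]:
        val = int(v[start])
        off = _disk_offsets(val, pw)
        centres = base[start:stop]
        chunk = max(1, 4_000_000 // max(off.size, 1))
        for c0 in range(0, centres.size, chunk):
            idx = (centres[c0 : c0 + chunk, None] + off[None, :]).ravel()
            # duplicate indices all receive the same value, so a plain
            # gather / max / scatter is race-free and faster than ufunc.at
            sub = t2[idx]
            np.maximum(sub, val, out=sub)
            t2[idx] = sub
        start = stop
    t2 = t2.reshape(h + 2 * rmax, pw)[rmax : rmax + h, rmax : rmax + w]
    tau[m] = 2.0 * np.sqrt(t2[m].astype(np.float64))
    return tau


def render_thickness_image(
    tmap: np.ndarray,
    r_ref: float,
    tau_display_max: float = TAU_DISPLAY_MAX_UM,
) -> np.ndarray:
    """Render thickness (px) as 8-bit gray on an absolute physical scale.

    ``intensity = clamp(round(255 * tau_um / tau_display_max))`` where
    ``tau_um = tau * r_ref``.  The mapping is not per-image normalised, so
    rendered tiles are mutually comparable and the bright-pixel threshold
    corresponds to a fixed physical thickness.
    """
    if tau_display_max <= 0:
        raise ValueError("tau_display_max must be positive")
    t_um = np.asarray(tmap, dtype=np.float64) * float(r_ref)
    return np.clip(round_half_up(255.0 * t_um / tau_display_max), 0, 255).astype(
        np.uint8
    )


def count_bright(
    img: np.ndarray,
    profile: ReferenceProfile,
    bright_factor: float = BRIGHT_FACTOR,
) -> int:
    """Number of rendered pixels with intensity >= bright_factor * P_REF."""
    thr = math.ceil(bright_factor * profile.p_ref - 1e-9)
    return int((np.asarray(img) >= thr).sum())


def bright_count_cutoff(
    r_ref: float, count_const: float = BRIGHT_COUNT_CONST
) -> float:
    """Bright-pixel count above which a tile shows thick (double) layers."""
    return count_const / (r_ref * r_ref)


def classify_layering(
    bright_count: int, r_ref: float, count_const: float = BRIGHT_COUNT_CONST
) -> str:
    """Layering verdict: double layer iff strictly more bright pixels than
    ``count_const / r_ref**2``."""
    if bright_count < 0:
        raise ValueError("bright_count cannot be negative")
    if bright_count > bright_count_cutoff(r_ref, count_const):
        return DOUBLE_LAYER
    return SINGLE_LAYER
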