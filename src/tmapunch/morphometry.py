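"""Ellipse morphometry of nuclear agglomerates and randomness decision.

In tubular carcinoma the glandular architecture decays into many small,
similarly sized tubules scattered at random, whereas normal breast tissue
shows fewer, larger and size-heterogeneous lobular agglomerates.  The tile
statistic capturing this is the population standard deviation of the areas
of moment-equivalent ellipses fitted to the connected components of the
cleaned nuclei mask, after discarding lymphocyte-sized objects.

Both thresholds are micrometre-denominated constants converted to px**2 by
dividing by the squared resolution: objects below ``64 / r_ref**2`` px**2
(a typical ~8 um lymphocyte) are ignored, and an area standard deviation
below ``95 / r_ref**2`` px**2 marks the tile as randomly organised
(pathological).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from skimage.measure import label, regionprops

from .errors import UndefinedStatisticError

__all__ = [
    "RANDOM",
    "STRUCTURED",
    "ObjectEllipse",
    "fit_ellipses",
    "filter_lymphocyte_sized",
    "area_std",
    "classify_distribution",
    "size_cutoff_px2",
    "std_cutoff_px2",
]

RANDOM = "random"
STRUCTURED = "structured"

#: um**2-denominated constants of the size filter and randomness threshold.
SIZE_CONST = 64.0
STD_CONST = 95.0


@dataclass(frozen=True)
class ObjectEllipse:
    """Moment-equivalent ellipse of one nuclear agglomerate.

    ``area`` is pi * semimajor * semiminor (the ellipse area, not the pixel
    count); ``n_pixels`` keeps the raw component size as a diagnostic.
    """

    centroid: Tuple[float, float]
    semimajor: float
    semiminor: float
    area: float
    n_pixels: int


def fit_ellipses(mask: np.ndarray) -> List[ObjectEllipse]:
    """Fit one ellipse per 8-connected component, in scan order.

    Semi-axes come from the second central moments of the component
    (the moment-equivalent ellipse).  An empty mask yields an empty list.
    """
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return []
    lab = label(m, connectivity=2)
    out: List[ObjectEllipse] = []
    for p in regionprops(lab):
        a = p.axis_major_length / 2.0
        b = p.axis_minor_length / 2.0
        out.append(
            ObjectEllipse(
                centroid=(float(p.centroid[0]), float(p.centroid[1])),
                semimajor=float(a),
                semiminor=float(b),
                area=float(math.pi * a * b),
                n_pixels=int(p.num_pixels),
            )
        )
    return out


def size_cutoff_px2(r_ref: float, size_const: float = SIZE_CONST) -> float:
    """Lymphocyte size filter in px**2 at resolution ``r_ref``."""
    return size_const / (r_ref * r_ref)


def std_cutoff_px2(r_ref: float, std_const: float = STD_CONST) -> float:
    """Randomness threshold on the area standard deviation, in px**2."""
    return std_const / (r_ref * r_ref)


def filter_lymphocyte_sized(
    ellipses: Sequence[ObjectEllipse],
    r_ref: float,
    size_const: float = SIZE_CONST,
) -> List[ObjectEllipse]:
    """Drop objects smaller than the lymphocyte cutoff ``size_const/r_ref**2``."""
    cutoff = size_cutoff_px2(r_ref, size_const)
    return [e for e in ellipses if e.area >= cutoff]


def area_std(ellipses: Sequence[ObjectEllipse]) -> float:
    """Population standard deviation of the ellipse areas (px**2)."""
    if len(ellipses) == 0:
        raise UndefinedStatisticError("area_std of an empty object list")
    return float(np.std([e.area for e in ellipses]))


def classify_distribution(
    std: float, r_ref: float, std_const: float = STD_CONST
) -> str:
    """Randomness verdict: ``random`` iff std is strictly below the cutoff."""
    if std < 0:
        raise ValueError("standard deviation cannot be negative")
    return RANDOM if std < std_cutoff_px2(r_ref, std_const) else STRUCTURED
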