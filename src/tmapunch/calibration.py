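"""Reference calibration of whole-slide H&E images.

Slides digitised at different times or on different scanners vary in
brightness and in physical resolution.  Before any tiling or
classification, every slide is normalised onto a common reference frame:

* **Intensity** -- the three characteristic gray levels of an H&E scene
  (background ``B``, nuclei ``N``, cytoplasm ``C``) are estimated from the
  slide itself and mapped exactly onto reference anchors
  ``(B_R, N_R, C_R)`` by the unique quadratic transfer
  ``y = A*x**2 + B*x + C`` through the three anchor pairs.
* **Resolution** -- the image is resampled bilinearly so that one pixel
  spans ``R_REF`` micrometres.

The default reference profile uses ``B_R=235, C_R=175, N_R=100`` whose mean
is the reference mean intensity ``P_REF=170`` at ``R_REF=0.46`` um/px.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize
from sklearn.cluster import KMeans

from ._util import as_rgb_u8, luminance, round_half_up
from .errors import DegenerateImageError, InvalidResolutionError, SingularSystemError

__all__ = [
    "ReferenceProfile",
    "ColorLevels",
    "CalibrationCoefficients",
    "default_profile",
    "estimate_color_levels",
    "solve_transfer",
    "apply_transfer",
    "rescale_to_resolution",
    "derive_profile",
]


@dataclass(frozen=True)
class ReferenceProfile:
    """Reference anchors a slide is calibrated onto.

    ``b_r``, ``n_r``, ``c_r`` are the 8-bit reference intensities of
    background, nuclei and cytoplasm; ``p_ref`` is their (rounded) mean and
    ``r_ref`` the reference resolution in um/px.
    """

    b_r: int = 235
    n_r: int = 100
    c_r: int = 175
    p_ref: int = 170
    r_ref: float = 0.46

    def __post_init__(self) -> None:
        if not (self.b_r > self.c_r > self.n_r):
            raise ValueError("profile must satisfy B_R > C_R > N_R")
        for v in (self.b_r, self.n_r, self.c_r, self.p_ref):
            if not 0 <= v <= 255:
                raise ValueError("profile intensities must lie in [0, 255]")
        if self.r_ref <= 0:
            raise InvalidResolutionError("r_ref must be positive")
        mean = (self.b_r + self.n_r + self.c_r) / 3.0
        # rounding the three anchors independently can shift the mean by
        # strictly less than one gray level, so allow +-1 around p_ref
        if abs(self.p_ref - mean) > 1.0:
            raise ValueError(
                f"p_ref={self.p_ref} inconsistent with anchor mean {mean:.2f}"
            )

    def to_json(self) -> str:
        return json.dumps(
            {
                "b_r": self.b_r,
                "n_r": self.n_r,
                "c_r": self.c_r,
                "p_ref": self.p_ref,
                "r_ref": self.r_ref,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ReferenceProfile":
        d = json.loads(text)
        return cls(
            b_r=int(d["b_r"]),
            n_r=int(d["n_r"]),
            c_r=int(d["c_r"]),
            p_ref=int(d["p_ref"]),
            r_ref=float(d["r_ref"]),
        )


def default_profile() -> ReferenceProfile:
    """The package default reference profile (mean intensity 170, 0.46 um/px)."""
    return ReferenceProfile()


@dataclass(frozen=True)
class ColorLevels:
    """Observed mean gray levels of a slide: background, nuclei, cytoplasm."""

    b: float
    n: float
    c: float

    def __post_init__(self) -> None:
        if not (self.b > self.c > self.n):
            raise ValueError("levels must satisfy B > C > N")


@dataclass(frozen=True)
class CalibrationCoefficients:
    """Quadratic transfer ``y = a*x**2 + b*x + c`` acting on 8-bit gray."""

    a: float
    b: float
    c: float

    def __call__(self, x):
        x = np.asarray(x, dtype=np.float64)
        return self.a * x * x + self.b * x + self.c


def estimate_color_levels(image: np.ndarray, seed: int = 0) -> ColorLevels:
    """Estimate the slide's background / nuclei / cytoplasm gray levels.

    The luminance histogram is partitioned by 3-class k-means; the cluster
    means, ranked bright to dark, are reported as (B, C, N).

    Raises
    ------
    DegenerateImageError
        If the image shows fewer than three distinct gray levels.
    """
    lum = luminance(image).ravel()
    bins = np.rint(lum).astype(np.intp)
    counts = np.bincount(bins, minlength=256).astype(np.float64)
    sums = np.bincount(bins, weights=lum, minlength=256)
    present = np.flatnonzero(counts)
    if present.size < 3:
        raise DegenerateImageError(
            f"image shows only {present.size} distinct gray level(s)"
        )
    km = KMeans(n_clusters=3, n_init=10, random_state=seed)
    assign = km.fit_predict(
        present.reshape(-1, 1).astype(np.float64), sample_weight=counts[present]
    )
    means = np.array(
        [
            sums[present[assign == k]].sum() / counts[present[assign == k]].sum()
            for k in range(3)
        ]
    )
    hi, mid, lo = np.argsort(means)[::-1]
    return ColorLevels(b=float(means[hi]), c=float(means[mid]), n=float(means[lo]))


def solve_transfer(
    observed: ColorLevels, reference: ReferenceProfile
) -> CalibrationCoefficients:
    """Fit the unique quadratic through (B,B_R), (N,N_R), (C,C_R).

    Raises
    ------
    SingularSystemError
        If any two observed anchors coincide.
    """
    x = np.array([observed.b, observed.n, observed.c], dtype=np.float64)
    y = np.array(
        [reference.b_r, reference.n_r, reference.c_r], dtype=np.float64
    )
    if len({observed.b, observed.n, observed.c}) < 3:
        raise SingularSystemError("observed anchors must be pairwise distinct")
    m = np.stack([x * x, x, np.ones(3)], axis=1)
    a, b, c = np.linalg.solve(m, y)
    return CalibrationCoefficients(a=float(a), b=float(b), c=float(c))


def apply_transfer(
    image: np.ndarray, coeffs: CalibrationCoefficients
) -> np.ndarray:
    """Map every channel value through the quadratic transfer.

    Values are rounded half-up and clamped to [0, 255]; a 256-entry lookup
    table makes the operation exact and fast.
    """
    img = as_rgb_u8(image)
    lut = np.clip(round_half_up(coeffs(np.arange(256))), 0, 255).astype(np.uint8)
    return lut[img]


def rescale_to_resolution(
    image: np.ndarray, r_in: float, profile: ReferenceProfile
) -> np.ndarray:
    """Resample the image from ``r_in`` um/px onto the reference resolution.

    Output side lengths are ``round(side * r_in / r_ref)`` (half-up);
    resampling is bilinear.
    """
    if r_in is None or r_in <= 0:
        raise InvalidResolutionError(f"invalid input resolution {r_in!r}")
    img = as_rgb_u8(image)
    scale = r_in / profile.r_ref
    h, w = img.shape[:2]
    out_h = max(1, int(round_half_up(h * scale)))
    out_w = max(1, int(round_half_up(w * scale)))
    if (out_h, out_w) == (h, w):
        return img.copy()
    res = resize(
        img.astype(np.float64),
        (out_h, out_w, 3),
        order=1,
        anti_aliasing=False,
        preserve_range=True,
    )
    return np.clip(round_half_up(res), 0, 255).astype(np.uint8)


def derive_profile(p_new: int, base: ReferenceProfile) -> ReferenceProfile:
    """Rescale the reference anchors to a new mean intensity ``p_new``.

    The anchors keep their original proportions: each is multiplied by
    ``p_new / base.p_ref``, rounded half-up, and capped at 255.
    """
    if not 0 < p_new <= 255:
        raise ValueError(f"p_new must lie in (0, 255], got {p_new}")
    factor = p_new / base.p_ref
    scale = lambda v: int(min(255, round_half_up(v * factor)))  # noqa: E731
    return ReferenceProfile(
        b_r=scale(base.b_r),
        n_r=scale(base.n_r),
        c_r=scale(base.c_r),
        p_ref=int(p_new),
        r_ref=base.r_ref,
    )
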