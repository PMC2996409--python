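"""Small numeric helpers shared across modules."""

from __future__ import annotations

import numpy as np

#: ITU-R BT.601 luma weights, the stated gray-conversion convention.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


def round_half_up(x):
    """Round with ties going up (0.5 -> 1), elementwise for arrays."""
    return np.floor(np.asarray(x, dtype=np.float64) + 0.5)


def luminance(image: np.ndarray) -> np.ndarray:
    """Float luminance of an 8-bit RGB image (or pass gray through)."""
    img = np.asarray(image)
    if img.ndim == 2:
        return img.astype(np.float64)
    if img.ndim == 3 and img.shape[2] == 3:
        r, g, b = LUMA_WEIGHTS
        return (
            r * img[..., 0].astype(np.float64)
            + g * img[..., 1].astype(np.float64)
            + b * img[..., 2].astype(np.float64)
        )
    raise ValueError(f"expected HxW or HxWx3 image, got shape {img.shape}")


def as_rgb_u8(image: np.ndarray) -> np.ndarray:
    """Validate and return a contiguous uint8 RGB array."""
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3 or img.dtype != np.uint8:
        raise ValueError("expected an 8-bit HxWx3 RGB image")
    return np.ascontiguousarray(img)
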