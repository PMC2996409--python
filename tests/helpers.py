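"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the thickness oracle is
a brute-force search over every candidate disk, and the tone classifier is
a nearest-colour rule with known tone centres.
"""

from __future__ import annotations

import numpy as np


def brute_force_local_thickness(mask: np.ndarray) -> np.ndarray:
    """Exhaustive largest-inscribed-disk thickness.

    For every foreground pixel p, tau(p) = 2 * max over all centres x of the
    radius of the largest disk at x (its brute-force distance to the nearest
    background pixel, image border included) whose open disk contains p.
    Squared integer arithmetic throughout.
    """
    m = np.asarray(mask, dtype=bool)
    h, w = m.shape
    tau = np.zeros((h, w), dtype=np.float64)
    pts = np.argwhere(m)
    if pts.size == 0:
        return tau
    padded = np.pad(m, 1, constant_values=False)
    bg = np.argwhere(~padded) - 1  # background incl. the border ring
    # squared distance of every foreground pixel to its nearest background
    d2 = ((pts[:, None, :] - bg[None, :, :]) ** 2).sum(-1).min(1)
    # containment: p in open disk(x, d(x))  <=>  |p-x|^2 <= d(x)^2 - 1
    pp = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    covered = pp <= (d2[None, :] - 1)
    best = np.where(covered, d2[None, :], 0).max(1)
    tau[pts[:, 0], pts[:, 1]] = 2.0 * np.sqrt(best)
    return tau


def brute_force_ridge(mask: np.ndarray) -> set:
    """Maximal-disk centres by direct pairwise containment testing.

    Disk (p, d(p)) is redundant iff some other q satisfies
    |p-q| + d(p) <= d(q); tested exactly on squared integers.
    """
    m = np.asarray(mask, dtype=bool)
    pts = np.argwhere(m)
    if pts.size == 0:
        return set()
    padded = np.pad(m, 1, constant_values=False)
    bg = np.argwhere(~padded) - 1
    d2 = ((pts[:, None, :] - bg[None, :, :]) ** 2).sum(-1).min(1)
    out = set()
    for i, (y, x) in enumerate(pts):
        redundant = False
        for j in range(len(pts)):
            if j == i:
                continue
            s2 = int(((pts[i] - pts[j]) ** 2).sum())
            rhs = int(d2[j]) - s2 - int(d2[i])
            if rhs >= 0 and 4 * s2 * int(d2[i]) <= rhs * rhs:
                redundant = True
                break
        if not redundant:
            out.add((int(y), int(x)))
    return out


def random_mask(rng: np.random.Generator, max_side: int = 32) -> np.ndarray:
    """Random binary mask with random size and density."""
    h = int(rng.integers(3, max_side + 1))
    w = int(rng.integers(3, max_side + 1))
    return rng.random((h, w)) < rng.uniform(0.2, 0.85)


def nearest_tone_labels(tile: np.ndarray, tones: np.ndarray) -> np.ndarray:
    """Assign each pixel to the nearest of the given RGB tones."""
    px = tile.reshape(-1, 1, 3).astype(np.float64)
    t = np.asarray(tones, dtype=np.float64).reshape(1, -1, 3)
    return ((px - t) ** 2).sum(-1).argmin(1).reshape(tile.shape[:2])
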