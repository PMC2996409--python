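"""Synthetic H&E scene generator with per-tile ground truth.

Emulates the three tile morphologies the classifier must tell apart, so the
whole pipeline can be exercised without glass slides:

* **normal** -- a lobule-like cluster of acini: white lumens ringed by two
  concentric nuclei layers, deliberately size-heterogeneous (lumen radii
  are drawn from staggered strata so the agglomerate-area spread always
  reads as structured tissue);
* **pathological** -- many small tubules at random positions, each a white
  lumen ringed by a single thin nuclei layer, nearly constant in size
  (tubular-carcinoma morphology: numerous, small, homogeneous);
* **fat** -- bright, nearly empty tiles with thin adipocyte outlines, whose
  mean intensity exceeds the informative-filter cutoff by construction.

Geometry is parameterised in micrometres and anchored on an 8 um epithelial
cell: one nuclei layer spans ~4.5-5 um (the nucleus of one cell layer), a
double layer ~10 um.  Colours approximate an H&E palette -- background
235 gray, cytoplasm pink, nuclei blue-violet -- with clamped Gaussian noise.
Scenes are deterministic per seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .tiling import AFFECTED, NON_INFORMATIVE, UNAFFECTED

__all__ = [
    "NORMAL",
    "PATHOLOGICAL",
    "FAT",
    "TILE_CLASSES",
    "CLASS_TO_LABEL",
    "SceneSpec",
    "SlideSample",
    "generate_scene",
    "generate_labeled_dataset",
]

NORMAL = "normal"
PATHOLOGICAL = "pathological"
FAT = "fat"
TILE_CLASSES = (NORMAL, PATHOLOGICAL, FAT)

#: ground-truth diagnosis implied by each generated tile class
CLASS_TO_LABEL = {
    NORMAL: UNAFFECTED,
    PATHOLOGICAL: AFFECTED,
    FAT: NON_INFORMATIVE,
}


@dataclass(frozen=True)
class SceneSpec:
    """Layout, geometry and palette of one synthetic slide."""

    rows: int = 8
    cols: int = 9
    tile_px: int = 224
    resolution: float = 0.46  # um/px
    #: per-tile class plan (row-major, rows*cols entries); random if None
    plan: Optional[Tuple[str, ...]] = None
    mix: Tuple[float, float, float] = (0.45, 0.35, 0.20)  # normal, path, fat
    cell_diameter_um: float = 8.0
    #: normal acini: lumen radius strata (um) sampled one-per-acinus
    normal_lumen_strata_um: Tuple[Tuple[float, float], ...] = (
        (2.5, 3.5),
        (4.5, 5.5),
        (6.5, 7.5),
        (8.5, 9.5),
    )
    normal_wall_um: float = 10.0  # two nuclei layers
    path_lumen_um: Tuple[float, float] = (1.7, 2.3)
    path_wall_um: float = 4.5  # one nuclei layer
    tubules_per_tile: Tuple[int, int] = (10, 16)
    background_gray: int = 235
    cytoplasm_rgb: Tuple[int, int, int] = (230, 180, 200)
    nuclei_rgb: Tuple[int, int, int] = (90, 90, 160)
    noise_sigma: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows <= 0 or self.cols <= 0 or self.tile_px <= 0:
            raise ValueError("rows, cols and tile_px must be positive")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.cell_diameter_um <= 0:
            raise ValueError("cell_diameter_um must be positive")
        if self.plan is not None:
            if len(self.plan) != self.rows * self.cols:
                raise ValueError(
                    f"plan has {len(self.plan)} entries, grid needs "
                    f"{self.rows * self.cols}"
                )
            bad = set(self.plan) - set(TILE_CLASSES)
            if bad:
                raise ValueError(f"unknown tile classes in plan: {bad}")
        if not math.isclose(sum(self.mix), 1.0, abs_tol=1e-9) or min(self.mix) < 0:
            raise ValueError("mix must be three non-negative proportions summing to 1")

    @property
    def width(self) -> int:
        return self.cols * self.tile_px

    @property
    def height(self) -> int:
        return self.rows * self.tile_px


@dataclass
class SlideSample:
    """One generated slide: image, per-tile classes and scoring metadata."""

    image: np.ndarray
    tile_classes: List[str]
    truth: List[str]  # affected / unaffected / non_informative
    scorable: List[bool]  # False for discordant (dropped) tiles


# ---------------------------------------------------------------- drawing

def _draw_disk(tile: np.ndarray, cy: float, cx: float, r: float, color) -> None:
    """Paint the open disk |p - c| < r with the given colour."""
    h, w = tile.shape[:2]
    y0, y1 = max(0, int(cy - r) - 1), min(h, int(cy + r) + 2)
    x0, x1 = max(0, int(cx - r) - 1), min(w, int(cx + r) + 2)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    m = (yy - cy) ** 2 + (xx - cx) ** 2 < r * r
    tile[y0:y1, x0:x1][m] = color


def _draw_ring(
    tile: np.ndarray, cy: float, cx: float, r: float, half_width: float, color
) -> None:
    """Paint a thin circle outline of the given radius."""
    h, w = tile.shape[:2]
    rr = r + half_width
    y0, y1 = max(0, int(cy - rr) - 1), min(h, int(cy + rr) + 2)
    x0, x1 = max(0, int(cx - rr) - 1), min(w, int(cx + rr) + 2)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    m = np.abs(d - r) < half_width
    tile[y0:y1, x0:x1][m] = color


def _place(
    rng: np.random.Generator,
    taken: List[Tuple[float, float, float]],
    extent: float,
    lo: float,
    hi_y: float,
    hi_x: float,
    gap: float,
    tries: int = 300,
) -> Optional[Tuple[float, float]]:
    """Uniform rejection sampling with a pairwise-separation constraint."""
    if lo + extent >= hi_y - extent or lo + extent >= hi_x - extent:
        return None  # structure does not fit in the tile
    for _ in range(tries):
        cy = rng.uniform(lo + extent, hi_y - extent)
        cx = rng.uniform(lo + extent, hi_x - extent)
        if all(
            math.hypot(cy - ty, cx - tx) >= extent + te + gap
            for ty, tx, te in taken
        ):
            taken.append((cy, cx, extent))
            return cy, cx
    return None


# ------------------------------------------------------------- tile paint

def _paint_fat(tile: np.ndarray, spec: SceneSpec, rng: np.random.Generator) -> None:
    tile[:] = spec.background_gray
    px = 1.0 / spec.resolution
    for _ in range(int(rng.integers(4, 9))):
        r = min(rng.uniform(10.0, 22.0) * px, min(tile.shape[:2]) / 2 - 2)
        if r <= 2:
            continue
        cy = rng.uniform(r, tile.shape[0] - r)
        cx = rng.uniform(r, tile.shape[1] - r)
        _draw_ring(tile, cy, cx, r, 0.7, (225, 195, 210))


def _paint_mucus_and_lymphocytes(
    tile: np.ndarray,
    spec: SceneSpec,
    rng: np.random.Generator,
    taken: List[Tuple[float, float, float]],
) -> None:
    px = 1.0 / spec.resolution
    h, w = tile.shape[:2]
    # mucus patches: drawn before structures, so they never breach a lumen
    for _ in range(int(rng.integers(1, 3))):
        r = min(rng.uniform(3.0, 6.0) * px, min(h, w) / 2 - 1)
        if r <= 1:
            continue
        _draw_disk(
            tile,
            rng.uniform(r, h - r),
            rng.uniform(r, w - r),
            r,
            (spec.background_gray,) * 3,
        )
    # stray lymphocytes: below the size filter once fitted
    for _ in range(int(rng.integers(0, 4))):
        r = rng.uniform(2.0, 3.0) * px
        pos = _place(rng, taken, r, 2.0, h - 2.0, w - 2.0, gap=2.6 * px)
        if pos is not None:
            _draw_disk(tile, pos[0], pos[1], r, spec.nuclei_rgb)


def _paint_normal(tile: np.ndarray, spec: SceneSpec, rng: np.random.Generator) -> None:
    """Lobule cluster: one acinus per lumen stratum, on a jittered lattice."""
    tile[:] = spec.cytoplasm_rgb
    px = 1.0 / spec.resolution
    h, w = tile.shape[:2]
    taken: List[Tuple[float, float, float]] = []
    lumens = [rng.uniform(lo, hi) for lo, hi in spec.normal_lumen_strata_um]
    rng.shuffle(lumens)
    # 2x2 jittered lattice keeps the cluster compact (lobule-like) while
    # guaranteeing the acini stay disjoint after mask dilation
    cells = [(0.25, 0.25), (0.25, 0.75), (0.75, 0.25), (0.75, 0.75)]
    for (fy, fx), lumen in zip(cells, lumens):
        outer = (lumen + spec.normal_wall_um) * px
        if 2 * outer + 4 >= min(h, w):
            continue  # acinus does not fit in the tile
        jit = 4.0 * px
        cy = np.clip(fy * h + rng.uniform(-jit, jit), outer + 2, h - outer - 2)
        cx = np.clip(fx * w + rng.uniform(-jit, jit), outer + 2, w - outer - 2)
        _draw_disk(tile, cy, cx, outer, spec.nuclei_rgb)
        _draw_disk(tile, cy, cx, lumen * px, (spec.background_gray,) * 3)
        taken.append((float(cy), float(cx), outer))
    _paint_mucus_and_lymphocytes(tile, spec, rng, taken)


def _paint_pathological(
    tile: np.ndarray, spec: SceneSpec, rng: np.random.Generator
) -> None:
    """Many small uniform single-layer tubules at random positions."""
    tile[:] = spec.cytoplasm_rgb
    px = 1.0 / spec.resolution
    h, w = tile.shape[:2]
    taken: List[Tuple[float, float, float]] = []
    n = int(rng.integers(spec.tubules_per_tile[0], spec.tubules_per_tile[1] + 1))
    for _ in range(n):
        lumen = rng.uniform(*spec.path_lumen_um)
        outer = (lumen + spec.path_wall_um) * px
        pos = _place(rng, taken, outer, 2.0, h - 2.0, w - 2.0, gap=2.6 * px)
        if pos is None:
            continue
        _draw_disk(tile, pos[0], pos[1], outer, spec.nuclei_rgb)
        _draw_disk(tile, pos[0], pos[1], lumen * px, (spec.background_gray,) * 3)
    _paint_mucus_and_lymphocytes(tile, spec, rng, taken)


# ------------------------------------------------------------------ scene

def generate_scene(spec: SceneSpec) -> Tuple[np.ndarray, List[str]]:
    """Render one slide and return (RGB image, per-tile class list).

    Tiles follow ``spec.plan`` when given, otherwise a random plan drawn
    from ``spec.mix``.  Deterministic per ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.plan is not None:
        plan = list(spec.plan)
    else:
        plan = list(
            rng.choice(TILE_CLASSES, size=spec.rows * spec.cols, p=spec.mix)
        )
    img = np.zeros((spec.height, spec.width, 3), dtype=np.float64)
    painters = {FAT: _paint_fat, NORMAL: _paint_normal, PATHOLOGICAL: _paint_pathological}
    for i, cls in enumerate(plan):
        r, c = divmod(i, spec.cols)
        view = img[
            r * spec.tile_px : (r + 1) * spec.tile_px,
            c * spec.tile_px : (c + 1) * spec.tile_px,
        ]
        painters[cls](view, spec, rng)
    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8), plan


def generate_labeled_dataset(
    n_slides: int,
    mix: Tuple[float, float, float] = (0.45, 0.35, 0.20),
    seed: int = 0,
    dropout: float = 0.0,
    rows: int = 8,
    cols: int = 9,
    tile_px: int = 224,
    resolution: float = 0.46,
) -> List[SlideSample]:
    """Generate ``n_slides`` labelled slides at the given class mix.

    ``dropout`` marks exactly ``round(dropout * n_tiles)`` tiles (chosen
    uniformly across the dataset) as discordant: their ``scorable`` flag is
    cleared, emulating tiles on which expert reviewers disagreed and which
    are removed from scoring.
    """
    if n_slides <= 0:
        raise ValueError("n_slides must be positive")
    if not 0.0 <= dropout < 1.0:
        raise ValueError("dropout must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    slide_seeds = rng.integers(0, 2**31 - 1, size=n_slides)
    samples: List[SlideSample] = []
    for s in range(n_slides):
        spec = SceneSpec(
            rows=rows,
            cols=cols,
            tile_px=tile_px,
            resolution=resolution,
            mix=mix,
            seed=int(slide_seeds[s]),
        )
        image, classes = generate_scene(spec)
        samples.append(
            SlideSample(
                image=image,
                tile_classes=classes,
                truth=[CLASS_TO_LABEL[c] for c in classes],
                scorable=[True] * len(classes),
            )
        )
    n_tiles = n_slides * rows * cols
    n_drop = int(round(dropout * n_tiles))
    if n_drop:
        dropped = rng.choice(n_tiles, size=n_drop, replace=False)
        per_slide = rows * cols
        for idx in dropped:
            samples[idx // per_slide].scorable[idx % per_slide] = False
    return samples
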