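"""Per-tile decision workflow and whole-slide processing.

Every tile runs through three short-circuiting stages:

1. **Informative filter** -- tiles whose mean luminance exceeds
   ``1.2 * P_REF`` hold no tissue (empty glass or fat) and are labelled
   ``non_informative``.
2. **Cell-distribution evaluation** -- the nuclei mask is segmented,
   cleaned, and summarised by the standard deviation of agglomerate ellipse
   areas; a randomly organised tile (std below ``95 / r_ref**2``) is
   ``affected``.
3. **Layer-thickness investigation** -- local thickness of the nuclei mask
   is rendered and the bright-pixel count decides single layer
   (``affected``) versus double layer (``unaffected``).

A whole slide is calibrated once, rescaled to the reference resolution,
cut into the punching grid, classified tile by tile, and reassembled into
an annotated overview.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import List, Optional, Tuple

import numpy as np

from ._util import luminance
from . import morphometry, segmentation, thickness
from .calibration import (
    ReferenceProfile,
    apply_transfer,
    estimate_color_levels,
    rescale_to_resolution,
    solve_transfer,
)
from .errors import DegenerateImageError
from .tiling import (
    AFFECTED,
    NON_INFORMATIVE,
    UNAFFECTED,
    annotate_and_reassemble,
    cut_tiles,
    make_grid,
)

__all__ = [
    "INFORMATIVE",
    "RunConfig",
    "TileDiagnosis",
    "informative_filter",
    "classify_tile",
    "process_slide",
]

INFORMATIVE = "informative"

#: factor on P_REF above which a tile's mean intensity marks it as empty/fat.
INFORMATIVE_FACTOR = 1.2


@dataclass(frozen=True)
class RunConfig:
    """All tunable parameters of the pipeline, with their default values.

    The threshold constants are deliberately exposed so that users can
    fine-tune them for scanners or stains that differ from the reference
    material.
    """

    profile: ReferenceProfile = field(default_factory=ReferenceProfile)
    informative_factor: float = INFORMATIVE_FACTOR
    size_const: float = morphometry.SIZE_CONST
    std_const: float = morphometry.STD_CONST
    bright_factor: float = thickness.BRIGHT_FACTOR
    bright_count_const: float = thickness.BRIGHT_COUNT_CONST
    tau_display_max: float = thickness.TAU_DISPLAY_MAX_UM
    dark_fraction: float = 1.0
    element_radius: Optional[int] = None  # None -> ~1 um disk at r_ref
    rows: int = 8
    cols: int = 9
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "informative_factor",
            "size_const",
            "std_const",
            "bright_factor",
            "bright_count_const",
            "tau_display_max",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_json(self) -> str:
        d = {
            "b_r": self.profile.b_r,
            "n_r": self.profile.n_r,
            "c_r": self.profile.c_r,
            "p_ref": self.profile.p_ref,
            "r_ref": self.profile.r_ref,
            "informative_factor": self.informative_factor,
            "size_const": self.size_const,
            "std_const": self.std_const,
            "bright_factor": self.bright_factor,
            "bright_count_const": self.bright_count_const,
            "tau_display_max": self.tau_display_max,
            "dark_fraction": self.dark_fraction,
            "element_radius": self.element_radius,
            "rows": self.rows,
            "cols": self.cols,
            "seed": self.seed,
        }
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        profile = ReferenceProfile(
            b_r=int(d.pop("b_r", 235)),
            n_r=int(d.pop("n_r", 100)),
            c_r=int(d.pop("c_r", 175)),
            p_ref=int(d.pop("p_ref", 170)),
            r_ref=float(d.pop("r_ref", 0.46)),
        )
        er = d.pop("element_radius", None)
        return cls(
            profile=profile,
            element_radius=None if er is None else int(er),
            **d,
        )


@dataclass
class TileDiagnosis:
    """Verdict for one tile plus the intermediate diagnostics.

    Fields that a short-circuited stage never computed stay ``None``;
    ``decision_stage`` records which stage produced the label.
    """

    row: int
    col: int
    label: str
    decision_stage: str
    mean_intensity: float
    n_objects: Optional[int] = None
    n_after_filter: Optional[int] = None
    area_std: Optional[float] = None
    distribution: Optional[str] = None
    bright_count: Optional[int] = None
    layering: Optional[str] = None
    warning: Optional[str] = None

    def to_dict(self) -> dict:
        return asdict(self)


def informative_filter(
    tile: np.ndarray,
    profile: ReferenceProfile,
    informative_factor: float = INFORMATIVE_FACTOR,
) -> str:
    """'non_informative' iff mean tile luminance strictly exceeds
    ``informative_factor * P_REF`` (brighter tiles are glass or fat)."""
    mean = float(luminance(tile).mean())
    thr = round(informative_factor * profile.p_ref, 6)
    return NON_INFORMATIVE if mean > thr else INFORMATIVE


def classify_tile(
    tile: np.ndarray,
    config: RunConfig,
    seed: Optional[int] = None,
    row: int = 0,
    col: int = 0,
) -> TileDiagnosis:
    """Run the three-stage workflow on one calibrated, rescaled tile."""
    seed = config.seed if seed is None else seed
    profile = config.profile
    mean = float(luminance(tile).mean())

    # stage 1: informative filter
    if informative_filter(tile, profile, config.informative_factor) == NON_INFORMATIVE:
        return TileDiagnosis(
            row=row,
            col=col,
            label=NON_INFORMATIVE,
            decision_stage="informative_filter",
            mean_intensity=mean,
        )

    # stage 2: nuclei segmentation and cell-distribution evaluation
    try:
        seg = segmentation.segment_kmeans3(tile, seed=seed)
    except DegenerateImageError:
        # a dark but colour-degenerate tile cannot be segmented; fold it
        # into non_informative rather than aborting the slide run
        return TileDiagnosis(
            row=row,
            col=col,
            label=NON_INFORMATIVE,
            decision_stage="informative_filter",
            mean_intensity=mean,
            warning="degenerate_segmentation",
        )
    nm = segmentation.nuclei_mask(tile, seg, dark_fraction=config.dark_fraction)
    nm = segmentation.clean_mask(
        nm, radius=config.element_radius, r_ref=profile.r_ref
    )
    ellipses = morphometry.fit_ellipses(nm.mask)
    kept = morphometry.filter_lymphocyte_sized(
        ellipses, profile.r_ref, config.size_const
    )
    # with no agglomerates of gland size left, area spread is degenerate
    # (zero): such tiles read as randomly organised
    std = morphometry.area_std(kept) if kept else 0.0
    dist = morphometry.classify_distribution(std, profile.r_ref, config.std_const)
    diag = TileDiagnosis(
        row=row,
        col=col,
        label=AFFECTED,
        decision_stage="distribution",
        mean_intensity=mean,
        n_objects=len(ellipses),
        n_after_filter=len(kept),
        area_std=std,
        distribution=dist,
    )
    if dist == morphometry.RANDOM:
        return diag

    # stage 3: layer-thickness investigation
    tau = thickness.local_thickness(nm.mask)
    rendered = thickness.render_thickness_image(
        tau, profile.r_ref, config.tau_display_max
    )
    bright = thickness.count_bright(rendered, profile, config.bright_factor)
    layering = thickness.classify_layering(
        bright, profile.r_ref, config.bright_count_const
    )
    diag.decision_stage = "thickness"
    diag.bright_count = bright
    diag.layering = layering
    diag.label = UNAFFECTED if layering == thickness.DOUBLE_LAYER else AFFECTED
    return diag


def process_slide(
    image: np.ndarray,
    r_in: float,
    config: Optional[RunConfig] = None,
) -> Tuple[List[TileDiagnosis], np.ndarray]:
    """Calibrate, rescale, tile and classify a whole slide.

    Returns the row-major tile diagnoses (1-based row/column indices) and
    the annotated overview image.  Deterministic for a fixed config.
    """
    config = config or RunConfig()
    profile = config.profile
    try:
        levels = estimate_color_levels(image, seed=config.seed)
        coeffs = solve_transfer(levels, profile)
        calibrated = apply_transfer(image, coeffs)
    except DegenerateImageError:
        # an (almost) uniform slide offers no anchors; leave it unscaled --
        # its tiles will fall out at the informative filter
        calibrated = np.asarray(image)
    scaled = rescale_to_resolution(calibrated, r_in, profile)
    grid = make_grid(scaled.shape[1], scaled.shape[0], config.rows, config.cols)
    tiles = cut_tiles(scaled, grid)
    diagnoses: List[TileDiagnosis] = []
    for i, tile in enumerate(tiles):
        r, c = divmod(i, grid.cols)
        diagnoses.append(
            classify_tile(tile, config, seed=config.seed, row=r + 1, col=c + 1)
        )
    annotated = annotate_and_reassemble(
        tiles, [d.label for d in diagnoses], grid
    )
    return diagnoses, annotated
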