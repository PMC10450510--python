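"""Automated counting of stained cell bodies in brightfield micrographs.

Pipeline: pick the highest-contrast RGB channel, resize, denoise,
adaptive (local) threshold, Gaussian blur, morphological opening and
dilation, Canny edge extraction, contour extraction, then keep contours
whose area lies within mean +- 2 SD of the per-image contour-area
distribution.  Counts are converted to volumetric density using the net
tissue area (measured externally, in physical units) times the 60-μm
section thickness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import feature, filters, measure, morphology, transform, util


@dataclass
class CountingConfig:
    resize_factor: float = 0.5
    denoise_sigma: float = 1.0
    block_size: int = 51  # adaptive-threshold neighbourhood, must be odd
    # a pixel must sit this far below the local mean to count as stained;
    # keeps background texture and shot noise out of the mask
    threshold_offset: float = 0.1
    blur_sigma: float = 1.0
    morph_radius: int = 1
    open_iterations: int = 1
    dilate_iterations: int = 1
    canny_sigma: float = 1.0
    size_sd_band: float = 2.0
    section_thickness_um: float = 60.0
    density_unit_um3: float = 1.0e6  # report cells per this many μm³

    def __post_init__(self) -> None:
        if self.block_size % 2 == 0:
            raise ValueError("adaptive-threshold block size must be odd")
        if self.section_thickness_um <= 0:
            raise ValueError("section thickness must be positive")


@dataclass
class CountResult:
    image_id: str
    n_cells: int
    contours: list[np.ndarray] = field(default_factory=list)  # pixel coords
    tissue_area_um2: float | None = None
    density: float | None = None  # cells per density_unit_um3


def select_channel(image: np.ndarray) -> np.ndarray:
    """Return the RGB channel with maximal intensity SD (ties: first)."""
    img = np.asarray(image)
    if img.ndim == 2:
        return img
    if img.ndim != 3 or img.shape[2] < 2:
        raise ValueError("expected an RGB or grayscale image")
    sds = [float(img[..., c].astype(float).std()) for c in range(img.shape[2])]
    return img[..., int(np.argmax(sds))]


def _shoelace_area(contour: np.ndarray) -> float:
    x, y = contour[:, 1], contour[:, 0]
    return 0.5 * abs(float(np.dot(x, np.roll(y, 1)) - np.dot(y, np.roll(x, 1))))


def count_cells(gray: np.ndarray, cfg: CountingConfig | None = None,
                image_id: str = "") -> CountResult:
    """Count dark cell bodies on a bright background; deterministic."""
    cfg = cfg or CountingConfig()
    img = util.img_as_float(np.asarray(gray))
    if img.size == 0:
        raise ValueError("empty image")

    if cfg.resize_factor != 1.0:
        img = transform.rescale(img, cfg.resize_factor, anti_aliasing=True)
    if cfg.denoise_sigma > 0:
        img = filters.gaussian(img, cfg.denoise_sigma)

    local = filters.threshold_local(img, cfg.block_size,
                                    offset=cfg.threshold_offset)
    mask = img < local  # stained somata are darker than tissue

    if cfg.blur_sigma > 0:
        mask = filters.gaussian(mask.astype(float), cfg.blur_sigma) > 0.5

    footprint = morphology.disk(cfg.morph_radius)
    for _ in range(cfg.open_iterations):
        mask = morphology.opening(mask, footprint)
    for _ in range(cfg.dilate_iterations):
        mask = morphology.dilation(mask, footprint)

    edges = feature.canny(img, sigma=cfg.canny_sigma)  # outline extraction
    mask = mask | (edges & morphology.dilation(mask, footprint))

    padded = np.pad(mask.astype(float), 1)
    contours = [c - 1.0 for c in measure.find_contours(padded, 0.5)]
    areas = np.array([_shoelace_area(c) for c in contours])
    keep = np.ones(areas.size, dtype=bool)
    if areas.size:
        mean, sd = areas.mean(), areas.std(ddof=1) if areas.size > 1 else 0.0
        keep = np.abs(areas - mean) <= cfg.size_sd_band * sd

    kept = [c / cfg.resize_factor for c, k in zip(contours, keep) if k]
    return CountResult(image_id, int(keep.sum()), kept)


def density(n_cells: int, tissue_area_um2: float,
            thickness_um: float = 60.0, unit_um3: float = 1.0e6) -> float:
    """Cells per ``unit_um3`` μm³ of tissue (area x section thickness).

    Invariant to image resizing because the area is supplied in physical
    units, not pixels.
    """
    if tissue_area_um2 <= 0:
        raise ValueError("tissue area must be positive")
    return n_cells / (tissue_area_um2 * thickness_um) * unit_um3
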