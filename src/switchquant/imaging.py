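"""Per-cell fluorescence from a grayscale image plus a label mask.

Segmentation is an input (mask labels 1..n over background 0).  Each
cell's mean gray value is corrected by one shared per-image background
level, estimated from random cell-sized regions placed entirely outside
all labels.  For integer images the corrected value is computed with
exact integer arithmetic, so adding a constant offset to the whole image
leaves every corrected intensity bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "LabeledImage",
    "CellIntensityRecord",
    "BackgroundEstimate",
    "BackgroundPlacementError",
    "cell_mean_fluorescence",
    "background_level",
    "corrected_intensities",
    "read_labeled_image",
]


@dataclass
class LabeledImage:
    """2-D grayscale image with an integer segmentation mask."""

    image: np.ndarray
    mask: np.ndarray
    bit_depth: Optional[int] = None

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        self.mask = np.asarray(self.mask)
        if self.image.ndim != 2:
            raise ValueError("image must be 2-D")
        if self.image.shape != self.mask.shape:
            raise ValueError(
                f"image shape {self.image.shape} != mask shape {self.mask.shape}"
            )
        if not np.issubdtype(self.mask.dtype, np.integer):
            raise ValueError("mask must be integer-typed")
        if self.mask.min() < 0:
            raise ValueError("mask labels must be >= 0")

    @property
    def labels(self) -> np.ndarray:
        """Sorted positive labels present in the mask."""
        lab = np.unique(self.mask)
        return lab[lab > 0]


@dataclass
class CellIntensityRecord:
    label: int
    area: int
    mean_intensity: float
    background: float
    corrected_intensity: float  # may be negative under noise; never clipped


@dataclass
class BackgroundEstimate:
    """Pooled-pixel background mean plus the sampled region mask."""

    value: float
    region_mask: np.ndarray
    n_regions: int
    n_pixels: int
    pixel_sum: float  # exact for integer images

    def __float__(self) -> float:
        return self.value


class BackgroundPlacementError(RuntimeError):
    pass


def _label_sums(li: LabeledImage) -> tuple[np.ndarray, np.ndarray]:
    """(sum, area) of pixel values per label index 0..max_label."""
    flat_mask = li.mask.ravel()
    sums = np.bincount(flat_mask, weights=li.image.ravel().astype(np.float64))
    areas = np.bincount(flat_mask)
    return sums, areas


def cell_mean_fluorescence(li: LabeledImage) -> list[tuple[int, int, float]]:
    """(label, area, mean gray value) for every segmented cell."""
    sums, areas = _label_sums(li)
    return [
        (int(lab), int(areas[lab]), float(sums[lab] / areas[lab])) for lab in li.labels
    ]


def background_level(
    li: LabeledImage,
    n_regions: int = 8,
    region_area: Optional[int] = None,
    seed: int = 0,
    max_retries: int = 5000,
) -> BackgroundEstimate:
    """Mean gray value over random cell-sized regions outside all cells.

    ``n_regions`` disk-shaped regions (area defaulting to the median cell
    area) are rejection-sampled so that each lies fully outside every
    label and none overlap; their pixels are pooled into one mean.
    Deterministic for a given seed.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    if region_area is None:
        areas = [a for _, a, _ in cell_mean_fluorescence(li)]
        if not areas:
            raise ValueError("region_area required when the mask has no cells")
        region_area = int(np.median(areas))
    if region_area < 1:
        raise ValueError("region_area must be >= 1")

    radius = max(1, int(round(math.sqrt(region_area / math.pi))))
    h, w = li.image.shape
    dy, dx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    disk = dy**2 + dx**2 <= radius**2
    dys, dxs = dy[disk], dx[disk]

    forbidden = li.mask > 0
    region_mask = np.zeros_like(forbidden)
    rng = np.random.default_rng(seed)
    placed = 0
    tries = 0
    while placed < n_regions:
        tries += 1
        if tries > max_retries:
            raise BackgroundPlacementError(
                f"placed {placed} of {n_regions} regions after {max_retries} tries; "
                f"{int((~forbidden).sum())} background pixels available"
            )
        cy = int(rng.integers(radius, h - radius))
        cx = int(rng.integers(radius, w - radius))
        ys, xs = cy + dys, cx + dxs
        if forbidden[ys, xs].any() or region_mask[ys, xs].any():
            continue
        region_mask[ys, xs] = True
        placed += 1

    pix = li.image[region_mask]
    pixel_sum = float(np.sum(pix, dtype=np.float64))
    return BackgroundEstimate(
        value=pixel_sum / pix.size,
        region_mask=region_mask,
        n_regions=n_regions,
        n_pixels=int(pix.size),
        pixel_sum=pixel_sum,
    )


def corrected_intensities(
    li: LabeledImage,
    n_regions: int = 8,
    region_area: Optional[int] = None,
    seed: int = 0,
) -> list[CellIntensityRecord]:
    """Background-subtracted mean intensity per cell (one shared background).

    For integer images the subtraction is carried out as the exact
    rational ``(S_cell * A_bg - S_bg * A_cell) / (A_cell * A_bg)`` so the
    result is invariant, bit for bit, under a constant offset added to
    the whole image.
    """
    bg = background_level(li, n_regions=n_regions, region_area=region_area, seed=seed)
    sums, areas = _label_sums(li)
    integer_image = np.issubdtype(li.image.dtype, np.integer)

    records = []
    s_bg, a_bg = bg.pixel_sum, bg.n_pixels
    for lab in li.labels:
        s_c, a_c = float(sums[lab]), int(areas[lab])
        mean_c = s_c / a_c
        if integer_image:
            corrected = (int(s_c) * a_bg - int(s_bg) * a_c) / (a_c * a_bg)
        else:
            corrected = mean_c - bg.value
        records.append(
            CellIntensityRecord(
                label=int(lab),
                area=a_c,
                mean_intensity=mean_c,
                background=bg.value,
                corrected_intensity=float(corrected),
            )
        )
    return records


def read_labeled_image(image_path, mask_path) -> LabeledImage:
    """Load an image/mask pair from TIFF or PNG files."""
    from imageio import v3 as iio

    image = np.asarray(iio.imread(image_path))
    mask = np.asarray(iio.imread(mask_path))
    if not np.issubdtype(mask.dtype, np.integer):
        mask = mask.astype(np.int64)
    return LabeledImage(image=image, mask=mask)
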