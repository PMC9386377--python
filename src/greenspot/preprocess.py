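"""Vegetation segmentation: excess-green index, smoothing, thresholding, morphology.

Turns an RGB field image into a cleaned binary vegetation mask and a list of
connected plant blobs. The pipeline order is fixed: pyramid downsampling to the
working resolution, excess-green (ExG = 2G − R − B) response, mean filtering,
Otsu thresholding, then a morphological open/close to drop specks and fill
pinholes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import closing, opening
from skimage.transform import resize

__all__ = [
    "Blob",
    "downsample",
    "excess_green",
    "mean_filter",
    "binarize",
    "morph_clean",
    "extract_blobs",
    "segment",
]


@dataclass
class Blob:
    """A connected foreground component.

    ``mask`` is the blob's own footprint cropped to its bounding box;
    ``bbox`` is (top, left, bottom, right), half-open, in full-image
    coordinates; ``centroid`` is the (row, col) pixel-coordinate mean.
    """

    mask: np.ndarray
    bbox: tuple[int, int, int, int]
    area: int = field(init=False)
    centroid: tuple[float, float] = field(init=False)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.area = int(self.mask.sum())
        if self.area == 0:
            raise ValueError("empty blob")
        rows, cols = np.nonzero(self.mask)
        self.centroid = (
            float(rows.mean()) + self.bbox[0],
            float(cols.mean()) + self.bbox[1],
        )

    @property
    def pixels(self) -> np.ndarray:
        """(n, 2) array of (row, col) coordinates in full-image frame."""
        rows, cols = np.nonzero(self.mask)
        return np.column_stack([rows + self.bbox[0], cols + self.bbox[1]])


def _check_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 RGB array, got shape {image.shape}")
    return image


def downsample(image: np.ndarray, target_w: int = 640, target_h: int = 480) -> np.ndarray:
    """Pyramid-downsample an RGB image to exactly (target_w, target_h).

    Each pyramid level Gaussian-smooths the image and then discards the even
    rows and even columns (keeping odd indices). Halving repeats while both
    dimensions remain at least twice the target; a final bilinear resize
    lands on the exact target size (e.g. 2592x1944 halves to 648x486, then
    resizes to 640x480).
    """
    image = _check_rgb(image)
    h, w = image.shape[:2]
    if target_w > w or target_h > h:
        raise ValueError(f"target {target_w}x{target_h} exceeds source {w}x{h}")
    if (w, h) == (target_w, target_h):
        return image

    out = image.astype(np.float64)
    while out.shape[0] >= 2 * target_h and out.shape[1] >= 2 * target_w:
        smoothed = np.empty_like(out)
        for c in range(3):
            smoothed[:, :, c] = ndi.gaussian_filter(out[:, :, c], sigma=1.0, mode="nearest")
        out = smoothed[1::2, 1::2]
    if out.shape[:2] != (target_h, target_w):
        out = resize(out, (target_h, target_w), order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def excess_green(image: np.ndarray) -> np.ndarray:
    """Per-pixel excess-green index 2G − R − B, clamped to [0, 255].

    Soil is roughly achromatic to reddish, so ExG suppresses the background
    while green plant material saturates toward high values.
    """
    image = _check_rgb(image).astype(np.int32)
    r, g, b = image[:, :, 0], image[:, :, 1], image[:, :, 2]
    return np.clip(2 * g - r - b, 0, 255).astype(np.uint8)


def mean_filter(gray: np.ndarray, kernel: int = 5) -> np.ndarray:
    """Box-average the gray response with a kernel x kernel window.

    Borders are handled by edge replication; kernel must be odd (kernel 1 is
    the identity). Output is rounded back to uint8.
    """
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError(f"kernel must be odd and >= 1, got {kernel}")
    gray = np.asarray(gray, dtype=np.float64)
    out = ndi.uniform_filter(gray, size=kernel, mode="nearest")
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def binarize(gray: np.ndarray) -> np.ndarray:
    """Otsu-threshold the ExG response; pixels strictly above are foreground.

    A constant image has no between-class variance to maximize and yields an
    empty mask by convention.
    """
    gray = np.asarray(gray)
    if gray.size == 0:
        raise ValueError("empty image")
    if gray.min() == gray.max():
        return np.zeros(gray.shape, dtype=bool)
    thr = threshold_otsu(gray, nbins=256)
    return gray > thr


def morph_clean(mask: np.ndarray, se: int = 3) -> np.ndarray:
    """Morphological opening then closing with a square se x se element."""
    if se < 1 or se % 2 == 0:
        raise ValueError(f"structuring element must be odd and >= 1, got {se}")
    mask = np.asarray(mask, dtype=bool)
    footprint = np.ones((se, se), dtype=bool)
    out = opening(mask, footprint)
    return closing(out, footprint)


def extract_blobs(mask: np.ndarray, min_area: int = 50) -> list[Blob]:
    """8-connected components with area >= min_area, largest first."""
    mask = np.asarray(mask, dtype=bool)
    labeled = label(mask, connectivity=2)
    blobs = []
    for region in regionprops(labeled):
        if region.area < min_area:
            continue
        top, left, bottom, right = region.bbox
        blobs.append(Blob(mask=region.image, bbox=(top, left, bottom, right)))
    blobs.sort(key=lambda b: (-b.area, b.bbox[0], b.bbox[1]))
    return blobs


def segment(image: np.ndarray, *, kernel: int = 5, se: int = 3,
            min_area: int = 50, target_size: tuple[int, int] | None = None,
            ) -> tuple[np.ndarray, list[Blob]]:
    """Full pipeline: optional downsample -> ExG -> mean filter -> Otsu -> open/close.

    Returns the cleaned mask and its blobs.
    """
    image = _check_rgb(image)
    if target_size is not None:
        image = downsample(image, target_size[0], target_size[1])
    exg = excess_green(image)
    smoothed = mean_filter(exg, kernel=kernel)
    mask = morph_clean(binarize(smoothed), se=se)
    return mask, extract_blobs(mask, min_area=min_area)
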