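"""Region-of-interest segmentation of section pixels.

The section is separated from the slide background on the sum-of-intensity
image: Otsu thresholding, hole filling (cell lumina and vessels are darker
than the surrounding walls and must be kept inside the ROI), then a
morphological opening and closing with large disk structuring elements to
remove debris and smooth the outline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import closing, disk, opening, reconstruction

from .image import MultispectralImage, sum_intensity_image


@dataclass
class RoiMask:
    """Boolean section mask plus bookkeeping from the segmentation."""

    mask: np.ndarray
    threshold: float | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def n_roi(self) -> int:
        return int(self.mask.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


def otsu_threshold(counts: np.ndarray, levels: np.ndarray | None = None) -> float:
    """Otsu threshold of an intensity histogram.

    Returns the level maximising the between-class variance of the two-class
    split; pixels with value <= threshold form the low class.  Ties are broken
    towards the lowest such level, making the result deterministic.

    Parameters
    ----------
    counts
        Histogram counts per level (or per bin).
    levels
        Level value of each bin; defaults to 0..len(counts)-1.
    """
    counts = np.asarray(counts, dtype=np.float64)
    if levels is None:
        levels = np.arange(counts.size, dtype=np.float64)
    else:
        levels = np.asarray(levels, dtype=np.float64)
    if np.count_nonzero(counts) < 2:
        raise ValueError("histogram must have at least two nonzero bins to split")

    # Between-class variance w0*w1*(mu0-mu1)^2 for every candidate cut after
    # bin t (low class = bins 0..t).
    w0 = np.cumsum(counts)
    total = w0[-1]
    m0 = np.cumsum(counts * levels)
    mtot = m0[-1]
    w1 = total - w0
    valid = (w0 > 0) & (w1 > 0)
    bcv = np.zeros_like(w0)
    bcv[valid] = (
        (m0[valid] / w0[valid] - (mtot - m0[valid]) / w1[valid]) ** 2
        * w0[valid] * w1[valid]
    )
    t = int(np.argmax(bcv))  # argmax returns the first (lowest) maximiser
    return float(levels[t])


def _binarize(sum_img: np.ndarray, threshold_override: float | None, n_bins: int) -> tuple[np.ndarray, float]:
    lo, hi = float(sum_img.min()), float(sum_img.max())
    if threshold_override is not None:
        return sum_img > threshold_override, float(threshold_override)
    if hi == lo:
        raise ValueError("sum-of-intensity image is constant; no threshold exists")
    centers = lo + (np.arange(n_bins) + 0.5) * (hi - lo) / n_bins
    counts, _ = np.histogram(sum_img, bins=n_bins, range=(lo, hi))
    thr = otsu_threshold(counts, centers)
    return sum_img > thr, thr


def segment_roi(
    msi: MultispectralImage,
    opening_radius: int = 50,
    closing_radius: int = 25,
    threshold_override: float | None = None,
    fill_order: str = "post",
    n_bins: int = 256,
    decomposition: str | None = "sequence",
) -> RoiMask:
    """Segment the section ROI on the sum-of-intensity image.

    Pipeline: sum of the 11 channels → Otsu threshold on a 256-bin histogram
    (or a user override) → hole filling → binary opening with a disk of
    radius ``opening_radius`` (default diameter 101) → binary closing with a
    disk of radius ``closing_radius`` (default diameter 51).

    ``fill_order`` selects when holes are filled: ``"post"`` (default) fills
    the binary mask after thresholding; ``"pre"`` fills grey-level holes on
    the sum image by morphological reconstruction before thresholding.
    Either way the contract is a solid section mask with lumina included.

    ``decomposition`` is forwarded to :func:`skimage.morphology.disk`;
    the default ``"sequence"`` uses a fast decomposed footprint, ``None``
    the exact disk.
    """
    if opening_radius < 0 or closing_radius < 0:
        raise ValueError("structuring-element radii must be >= 0")
    sum_img = sum_intensity_image(msi)

    if fill_order == "pre":
        # Grey-level hole filling: reconstruct from a seed equal to the image
        # on the border and +inf inside, then threshold.
        seed = sum_img.copy()
        seed[1:-1, 1:-1] = sum_img.max()
        filled = reconstruction(seed, sum_img, method="erosion")
        binary, thr = _binarize(filled, threshold_override, n_bins)
    elif fill_order == "post":
        binary, thr = _binarize(sum_img, threshold_override, n_bins)
        binary = ndimage.binary_fill_holes(binary)
    else:
        raise ValueError(f"fill_order must be 'pre' or 'post', got {fill_order!r}")

    mask = binary
    if opening_radius > 0:
        mask = opening(mask, disk(opening_radius, decomposition=decomposition))
    if closing_radius > 0:
        mask = closing(mask, disk(closing_radius, decomposition=decomposition))

    if not mask.any():
        raise ValueError(
            "segmentation produced an empty mask "
            f"(threshold={thr:.6g}, intensity range=[{sum_img.min():.6g}, {sum_img.max():.6g}])"
        )
    return RoiMask(mask=mask, threshold=thr)
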