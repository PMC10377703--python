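"""Visual representation of multispectral image series.

Multispectral stacks cannot be displayed directly; an RGB composite of
macrofluorescence averages the red, green and blue channels of the stack
into a colour quick-view.  To compare intensities across a series, every
image is rendered with a common min/max/gamma greyscale, zoom windows are
selected automatically at the centre and border of each section, and the
whole series is tiled into montages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .image import MultispectralImage
from .roi import RoiMask

#: Channel groups averaged into the composite colour planes.
COMPOSITE_CHANNELS = {
    "red": ("U2r", "BLr", "GRr"),
    "green": ("U1g", "U2g", "BLg"),
    "blue": ("U1b", "U2b"),
}


@dataclass(frozen=True)
class RenderScale:
    """Common greyscale: intensities in [min_level, max_level] mapped to 8 bit
    with a gamma exponent (gamma < 1 lifts low fluorescence intensities)."""

    min_level: float = 0.0
    max_level: float = 11000.0
    gamma: float = 0.65

    def __post_init__(self) -> None:
        if not self.max_level > self.min_level:
            raise ValueError("max_level must exceed min_level")
        if not self.gamma > 0:
            raise ValueError("gamma must be positive")


@dataclass(frozen=True)
class ZoomSpec:
    """Square zoom window, given by its centre (x, y) and side length."""

    centre_xy: tuple[int, int]
    side: int

    def slices(self, shape: tuple[int, int]) -> tuple[slice, slice]:
        """Row/column slices of the window, clamped inside ``shape``."""
        cx, cy = self.centre_xy
        half = self.side // 2
        r0 = min(max(cy - half, 0), max(shape[0] - self.side, 0))
        c0 = min(max(cx - half, 0), max(shape[1] - self.side, 0))
        return slice(r0, r0 + self.side), slice(c0, c0 + self.side)


def rgb_composite(msi: MultispectralImage) -> np.ndarray:
    """RGB composite of macrofluorescence (H×W×3 float64).

    red = mean(U2r, BLr, GRr); green = mean(U1g, U2g, BLg);
    blue = mean(U1b, U2b).
    """
    planes = []
    for colour in ("red", "green", "blue"):
        chans = COMPOSITE_CHANNELS[colour]
        planes.append(
            np.mean([msi.channel(c).astype(np.float64) for c in chans], axis=0)
        )
    return np.stack(planes, axis=-1)


def rescale_to_8bit(img: np.ndarray, scale: RenderScale) -> np.ndarray:
    """Clip to [min, max], normalise, apply gamma, code to 8 bit.

    out = round(255 * ((clip(in) - min)/(max - min))**gamma), round half up.
    """
    x = np.clip(np.asarray(img, dtype=np.float64), scale.min_level, scale.max_level)
    x = (x - scale.min_level) / (scale.max_level - scale.min_level)
    x = 255.0 * x ** scale.gamma
    return np.floor(x + 0.5).astype(np.uint8)


def nearest_rank_percentile(values: np.ndarray, q: float) -> float:
    """Nearest-rank percentile: the ceil(q/100 * n)-th smallest value."""
    v = np.sort(np.asarray(values).ravel())
    if v.size == 0:
        raise ValueError("empty input")
    rank = max(int(np.ceil(q / 100.0 * v.size)), 1)
    return float(v[rank - 1])


def suggest_common_scale(
    images: Sequence[np.ndarray], gamma: float = 0.65
) -> tuple[list[dict], RenderScale]:
    """Per-image min/max/1st/99th percentiles and a suggested common scale.

    The suggested scale spans 0 to the largest per-image 99th percentile; the
    caller may override it.  Percentiles use the nearest-rank definition.
    """
    if len(images) == 0:
        raise ValueError("need at least one image")
    stats = []
    for img in images:
        arr = np.asarray(img, dtype=np.float64)
        stats.append(
            {
                "min": float(arr.min()),
                "max": float(arr.max()),
                "p1": nearest_rank_percentile(arr, 1),
                "p99": nearest_rank_percentile(arr, 99),
            }
        )
    max_p99 = max(s["p99"] for s in stats)
    if max_p99 <= 0:
        max_p99 = max(max(s["max"] for s in stats), 1.0)
    return stats, RenderScale(min_level=0.0, max_level=max_p99, gamma=gamma)


def roi_centroid(roi: RoiMask) -> tuple[float, float]:
    """Centroid (x, y) of the ROI pixels."""
    rows, cols = np.nonzero(roi.mask)
    if rows.size == 0:
        raise ValueError("ROI is empty")
    return float(cols.mean()), float(rows.mean())


def select_zoom_regions(
    roi: RoiMask, side: int = 1500, direction: tuple[int, int] = (1, 0)
) -> dict[str, ZoomSpec]:
    """Automatic centre and border zoom windows for one section.

    The centre window is centred on the ROI centroid.  The border window is
    centred on the boundary crossing found by walking from the centroid along
    ``direction`` (default: increasing x, i.e. eastwards) until the ray
    leaves the ROI; both windows are clamped inside the image by
    :meth:`ZoomSpec.slices`.
    """
    if side > min(roi.shape):
        raise ValueError(f"zoom side {side} exceeds image extent {roi.shape}")
    cx, cy = roi_centroid(roi)
    centre = ZoomSpec(centre_xy=(int(round(cx)), int(round(cy))), side=side)

    dx, dy = direction
    if dx == 0 and dy == 0:
        raise ValueError("direction must be non-zero")
    x, y = int(round(cx)), int(round(cy))
    H, W = roi.shape
    last_inside = (x, y)
    while 0 <= x < W and 0 <= y < H:
        if roi.mask[y, x]:
            last_inside = (x, y)
        elif roi.mask[last_inside[1], last_inside[0]]:
            break  # first ROI→background crossing after having been inside
        x, y = x + dx, y + dy
    border = ZoomSpec(centre_xy=last_inside, side=side)
    return {"centre": centre, "border": border}


def build_montage(
    images: Sequence[np.ndarray],
    row_keys: Sequence,
    col_keys: Sequence | None = None,
    pad: int = 8,
    pad_value: int = 0,
) -> np.ndarray:
    """Tile a series of equally scaled 8-bit images into one grid image.

    Rows group images by ``row_keys`` (e.g. inbred line); within a row,
    images are ordered by ``col_keys`` (e.g. internode/section id) or by
    input order.  Cells are padded to the largest cell size with
    ``pad_value``; rows shorter than the widest row get blank cells.
    """
    if len(images) == 0:
        raise ValueError("montage needs at least one image")
    if col_keys is None:
        col_keys = list(range(len(images)))
    order = sorted(range(len(images)), key=lambda i: (row_keys[i], col_keys[i]))
    groups: dict = {}
    for i in order:
        groups.setdefault(row_keys[i], []).append(images[i])

    cell_h = max(img.shape[0] for img in images)
    cell_w = max(img.shape[1] for img in images)
    n_rows = len(groups)
    n_cols = max(len(v) for v in groups.values())
    extra = images[0].shape[2:]  # allow H×W or H×W×3 cells
    out = np.full(
        (n_rows * cell_h + (n_rows + 1) * pad,
         n_cols * cell_w + (n_cols + 1) * pad, *extra),
        pad_value,
        dtype=images[0].dtype,
    )
    for r, key in enumerate(sorted(groups)):
        for c, img in enumerate(groups[key]):
            r0 = pad + r * (cell_h + pad)
            c0 = pad + c * (cell_w + pad)
            out[r0 : r0 + img.shape[0], c0 : c0 + img.shape[1]] = img
    return out
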