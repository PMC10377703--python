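"""Multispectral image data model.

A multispectral macrofluorescence image is assembled from four RGB images
acquired through the filter cubes U1, U2 (UV excitation) and BL, GR
(visible excitation).  Within each filter the colour planes are ordered
blue, green, red; the U1 red plane is discarded because it carries the
Rayleigh reflection of the excitation band, leaving 11 channels.  The
vector of 11 intensities recorded for a single pixel is called its
pseudospectrum and is the observation unit for all multivariate analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

#: Fixed channel order of an assembled stack.  Channels acquired with a
#: visible filter at wavelengths at or below the excitation band (BLb, GRb,
#: GRg) carry no fluorescence but are retained as a baseline reference.
CHANNEL_NAMES = (
    "U1b", "U1g",
    "U2b", "U2g", "U2r",
    "BLb", "BLg", "BLr",
    "GRb", "GRg", "GRr",
)

#: Cameras used for this kind of acquisition are 14-bit.
INTENSITY_MAX = 16383


@dataclass(frozen=True)
class ChannelLayout:
    """Ordered channel identifiers of a multispectral stack."""

    names: tuple[str, ...] = CHANNEL_NAMES

    def __post_init__(self) -> None:
        if len(self.names) != 11:
            raise ValueError(f"expected 11 channels, got {len(self.names)}")
        if "U1r" in self.names:
            raise ValueError("channel U1r must not be present (excitation reflection)")
        if len(set(self.names)) != len(self.names):
            raise ValueError("channel names must be unique")

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown channel {name!r}") from None

    def __len__(self) -> int:
        return len(self.names)


DEFAULT_LAYOUT = ChannelLayout()


@dataclass
class MultispectralImage:
    """H×W×C stack of fluorescence intensities plus acquisition metadata.

    Parameters
    ----------
    pixels
        Intensity array of shape (H, W, C).  Stored as acquired (typically
        unsigned 16-bit); all statistics promote to float64.
    layout
        Channel identifiers, one per plane of ``pixels``.
    pixel_size
        Edge length of one pixel in micrometres.
    meta
        Mapping with at least ``group_id``, ``internode_id``, ``section_id``.
    """

    pixels: np.ndarray
    layout: ChannelLayout = DEFAULT_LAYOUT
    pixel_size: float = 2.78
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3:
            raise ValueError("pixels must be a H×W×C array")
        if self.pixels.shape[2] != len(self.layout):
            raise ValueError(
                f"channel count {self.pixels.shape[2]} does not match layout "
                f"length {len(self.layout)}"
            )
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must have at least one pixel")
        if np.issubdtype(self.pixels.dtype, np.floating) and np.nanmin(self.pixels) < 0:
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[2]

    def channel(self, name: str) -> np.ndarray:
        """Return one channel plane by name (a view, not a copy)."""
        return self.pixels[:, :, self.layout.index(name)]

    def unfold(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Unfold to a pixels × channels data table (float64).

        If ``mask`` is given only the masked pixels are returned, in row-major
        order.  This is the data-table view used by the streaming PCA.
        """
        if mask is None:
            return self.pixels.reshape(-1, self.n_channels).astype(np.float64)
        return self.pixels[np.asarray(mask, dtype=bool)].astype(np.float64)


def assemble_multispectral(
    u1_rgb: np.ndarray,
    u2_rgb: np.ndarray,
    bl_rgb: np.ndarray,
    gr_rgb: np.ndarray,
    meta: Mapping | None = None,
    pixel_size: float = 2.78,
) -> MultispectralImage:
    """Merge the four filter-cube RGB images into an 11-channel stack.

    Each input is H×W×3 with planes ordered (r, g, b).  The red plane of the
    U1 image is dropped; every retained plane is copied unmodified.  All four
    inputs must share the same height and width.
    """
    inputs = {"U1": u1_rgb, "U2": u2_rgb, "BL": bl_rgb, "GR": gr_rgb}
    shape = None
    for code, img in inputs.items():
        img = np.asarray(img)
        if img.ndim != 3 or img.shape[2] != 3:
            raise ValueError(f"filter {code}: expected an H×W×3 RGB image, got shape {img.shape}")
        if shape is None:
            shape = img.shape[:2]
        elif img.shape[:2] != shape:
            raise ValueError(
                f"filter {code}: shape {img.shape[:2]} does not match U1 shape {shape}"
            )
        inputs[code] = img

    R, G, B = 0, 1, 2
    planes = [
        inputs["U1"][:, :, B], inputs["U1"][:, :, G],          # U1r dropped
        inputs["U2"][:, :, B], inputs["U2"][:, :, G], inputs["U2"][:, :, R],
        inputs["BL"][:, :, B], inputs["BL"][:, :, G], inputs["BL"][:, :, R],
        inputs["GR"][:, :, B], inputs["GR"][:, :, G], inputs["GR"][:, :, R],
    ]
    stack = np.stack(planes, axis=-1)
    return MultispectralImage(
        pixels=stack,
        layout=DEFAULT_LAYOUT,
        pixel_size=pixel_size,
        meta=dict(meta or {}),
    )


def split_multispectral(msi: MultispectralImage) -> dict[str, np.ndarray]:
    """Inverse view of :func:`assemble_multispectral`: name → channel plane."""
    return {name: msi.channel(name) for name in msi.layout.names}


def sum_intensity_image(msi: MultispectralImage) -> np.ndarray:
    """Per-pixel sum over the 11 channels (float64, overflow-safe)."""
    return msi.pixels.astype(np.float64).sum(axis=2)


def mean_pseudospectrum(msi: MultispectralImage, mask: np.ndarray) -> np.ndarray:
    """Channel-wise mean pseudospectrum over the masked pixels."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != msi.shape:
        raise ValueError(f"mask shape {mask.shape} does not match image shape {msi.shape}")
    if not mask.any():
        raise ValueError("mask selects no pixels")
    return msi.pixels[mask].astype(np.float64).mean(axis=0)
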