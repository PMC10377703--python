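"""Readers and writers: multi-page TIFF stacks, sidecar JSON, manifests.

Stacks are stored as multi-page TIFF, one page per channel in layout order,
with the channel names in the image-description tag.  Per-image metadata
(group / internode / section ids, pixel size) lives in a sidecar JSON next
to the TIFF, since TIFF tag dialects are unreliable across tools.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .image import DEFAULT_LAYOUT, ChannelLayout, MultispectralImage
from .roi import RoiMask


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_stack(msi: MultispectralImage, path: str | Path) -> None:
    """Write an 11-channel stack as multi-page TIFF + sidecar JSON."""
    path = Path(path)
    pixels = msi.pixels
    if np.issubdtype(pixels.dtype, np.floating):
        pixels = np.clip(np.round(pixels), 0, 65535).astype(np.uint16)
    pages = np.moveaxis(pixels, -1, 0)
    tifffile.imwrite(
        path,
        pages,
        photometric="minisblack",
        description=json.dumps({"channels": list(msi.layout.names)}),
    )
    _sidecar(path).write_text(
        json.dumps({"pixel_size_um": msi.pixel_size, "meta": msi.meta}, indent=1)
    )


def read_stack(path: str | Path) -> MultispectralImage:
    """Read a multi-page TIFF stack written by :func:`write_stack`.

    Pre-assembled stacks from other tools are accepted as long as pages are
    in layout order; channel names in the description tag are checked when
    present.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        pages = tif.asarray()
        desc = tif.pages[0].description
    layout = DEFAULT_LAYOUT
    if desc:
        try:
            names = json.loads(desc).get("channels")
            if names:
                layout = ChannelLayout(names=tuple(names))
        except (json.JSONDecodeError, ValueError, AttributeError):
            pass
    pixels = np.moveaxis(pages, 0, -1)
    pixel_size, meta = 2.78, {}
    sc = _sidecar(path)
    if sc.exists():
        d = json.loads(sc.read_text())
        pixel_size = d.get("pixel_size_um", pixel_size)
        meta = d.get("meta", {})
    return MultispectralImage(pixels=pixels, layout=layout, pixel_size=pixel_size, meta=meta)


def write_mask(roi: RoiMask, path: str | Path) -> None:
    """Write the ROI as 0/255 single-page TIFF + JSON with threshold, n_roi."""
    path = Path(path)
    tifffile.imwrite(path, roi.mask.astype(np.uint8) * 255)
    _sidecar(path).write_text(
        json.dumps({"threshold": roi.threshold, "n_roi": roi.n_roi}, indent=1)
    )


def read_mask(path: str | Path) -> RoiMask:
    path = Path(path)
    mask = tifffile.imread(path) > 0
    threshold = None
    sc = _sidecar(path)
    if sc.exists():
        threshold = json.loads(sc.read_text()).get("threshold")
    return RoiMask(mask=mask, threshold=threshold)


def write_label_map(labels: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(Path(path), np.asarray(labels, dtype=np.uint8))


def write_score_stack(scores: np.ndarray, path: str | Path) -> None:
    """Score image as multi-page 32-bit float TIFF (one page per component)."""
    tifffile.imwrite(
        Path(path),
        np.moveaxis(scores.astype(np.float32), -1, 0),
        photometric="minisblack",
    )


def write_png(img: np.ndarray, path: str | Path) -> None:
    iio.imwrite(Path(path), np.asarray(img, dtype=np.uint8))


def read_rgb(path: str | Path) -> np.ndarray:
    """Read a filter-cube RGB image (TIFF or PNG) as an H×W×3 array."""
    arr = iio.imread(Path(path))
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise ValueError(f"{path}: expected an RGB image, got shape {arr.shape}")
    return arr[:, :, :3]


MANIFEST_COLUMNS = ["image", "mask", "group_id", "internode_id", "section_id"]


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Manifest CSV: image path, optional mask path, group/internode/section.

    Paths are resolved relative to the manifest's directory.  The
    (group, internode, section) triple must be unique per row.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns and c != "mask"]
    if missing:
        raise ValueError(f"manifest is missing columns: {missing}")
    if "mask" not in df.columns:
        df["mask"] = ""
    keys = df[["group_id", "internode_id", "section_id"]].apply(tuple, axis=1)
    if keys.duplicated().any():
        raise ValueError("manifest has duplicate (group, internode, section) rows")
    root = path.parent
    for col in ("image", "mask"):
        df[col] = df[col].map(lambda p: str(root / p) if p else "")
    return df[MANIFEST_COLUMNS]


def write_manifest(rows: list[dict], path: str | Path) -> None:
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(Path(path), index=False)
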