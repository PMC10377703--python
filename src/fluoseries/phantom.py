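"""Synthetic internode-section simulator.

Generates series of multispectral "section" images with known ground truth,
emulating the anatomy of a grass-stem internode cross-section: an elliptical
section on a dark background, an outer epidermis ring, a rind annulus dense
in vascular bundles, and an inner pith parenchyma with scattered bundles.
Each vascular bundle is a disk (bundle interior, weakly fluorescent lumen
and thin walls) wrapped in a strongly lignified sclerenchyma sheath ring.

Every tissue class has an 11-channel pseudospectrum: parenchyma and
epidermis dominated by UV-induced blue emission (hydroxycinnamic acids),
sheaths by strong visible-induced emission (lignin).  Pixel intensities are
the class spectrum times per-image factors plus Gaussian channel noise,
clipped to the 14-bit acquisition range.

A series nests three variance levels, largest to smallest: a group (inbred
line) effect as per-class spectral multipliers, an internode-level lognormal
intensity factor (emulating section-thickness variation), and per-pixel
noise.  Seeds are derived per section from the base seed so a series is
bit-reproducible and each section independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np

from .image import CHANNEL_NAMES, INTENSITY_MAX, DEFAULT_LAYOUT, MultispectralImage

CLASS_NAMES = (
    "background",
    "epidermis",
    "rind_parenchyma",
    "pith_parenchyma",
    "bundle_sheath",
    "bundle_interior",
)

#: Channels that carry real signal under visible (BL/GR) excitation; used to
#: inject lignin-like group effects.
VISIBLE_SIGNAL_CHANNELS = ("BLg", "BLr", "GRr")

# Default class pseudospectra (rows = CLASS_NAMES, columns = CHANNEL_NAMES).
# UV channels (U1b, U1g, U2b, U2g, U2r) carry the blue hydroxycinnamic-acid
# emission of parenchyma walls; BLg/BLr/GRr carry the visible-excited lignin
# emission that singles out sheaths and epidermis; BLb, GRb, GRg are the
# signal-free baseline channels and sit near the background level.
DEFAULT_CLASS_SPECTRA = np.array(
    # U1b   U1g   U2b   U2g   U2r   BLb   BLg   BLr   GRb   GRg   GRr
    [
        [  30,   30,   30,   30,   30,   30,   30,   30,   30,   30,   30],  # background
        [ 900,  450, 1000,  550,  350,   40, 1600, 2600,   40,   40, 2100],  # epidermis
        [3000,  900, 3500, 1000,  450,   40,  750, 1200,   40,   40,  850],  # rind_parenchyma
        [3500, 1000, 4000, 1100,  350,   40,  320,  480,   40,   40,  280],  # pith_parenchyma
        [2500, 1200, 3000, 1500, 1500,   40, 3000, 5500,   40,   40, 4500],  # bundle_sheath
        [ 600,  260,  700,  310,  160,   40,  260,  360,   40,   40,  260],  # bundle_interior
    ],
    dtype=np.float64,
)


@dataclass
class TissueLabelMap:
    """Integer tissue labels with a legend; label 0 is always background."""

    labels: np.ndarray
    legend: dict[int, str] = field(
        default_factory=lambda: dict(enumerate(CLASS_NAMES))
    )

    def mask(self, class_name: str) -> np.ndarray:
        code = {v: k for k, v in self.legend.items()}[class_name]
        return self.labels == code

    def section_mask(self) -> np.ndarray:
        """Ground-truth ROI: every non-background pixel."""
        return self.labels != 0


@dataclass
class PhantomConfig:
    """Geometry, spectra and noise of one synthetic section."""

    height: int = 256
    width: int = 256
    semi_axis_x: float = 100.0
    semi_axis_y: float = 80.0
    epidermis_thickness: float = 4.0
    rind_thickness: float = 18.0
    n_rind_bundles: int = 10
    n_pith_bundles: int = 6
    bundle_radius: float = 4.0
    sheath_thickness: float = 2.5
    class_spectra: np.ndarray = field(
        default_factory=lambda: DEFAULT_CLASS_SPECTRA.copy()
    )
    noise_fraction: float = 0.10      # per-channel sd as fraction of class mean
    cell_lattice: bool = False        # dark lumen grid inside parenchyma
    cell_pitch: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        self.class_spectra = np.asarray(self.class_spectra, dtype=np.float64)
        if self.class_spectra.shape != (len(CLASS_NAMES), len(CHANNEL_NAMES)):
            raise ValueError("class_spectra must be 6×11")
        if np.any(self.class_spectra < 0):
            raise ValueError("class spectra must be non-negative")
        for name in ("semi_axis_x", "semi_axis_y", "epidermis_thickness",
                     "rind_thickness", "bundle_radius", "sheath_thickness"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.epidermis_thickness + self.rind_thickness >= min(
            self.semi_axis_x, self.semi_axis_y
        ):
            raise ValueError("epidermis + rind must be thinner than the minor semi-axis")
        if self.noise_fraction < 0:
            raise ValueError("noise_fraction must be >= 0")


def _ellipse_rho(shape: tuple[int, int], a: float, b: float) -> np.ndarray:
    """Normalised elliptical radius of every pixel (1.0 on the ellipse)."""
    H, W = shape
    yy, xx = np.mgrid[0:H, 0:W]
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    return np.sqrt(((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2)


def _place_bundles(
    cfg: PhantomConfig, rng: np.random.Generator, max_attempts: int = 2000
) -> list[tuple[float, float]]:
    """Seeded rejection sampling of non-overlapping bundle centres."""
    H, W = cfg.height, cfg.width
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    a, b = cfg.semi_axis_x, cfg.semi_axis_y
    outer = cfg.bundle_radius + cfg.sheath_thickness
    min_sep = 2.0 * outer + 1.0
    centres: list[tuple[float, float]] = []

    def ok(x: float, y: float) -> bool:
        return all((x - u) ** 2 + (y - v) ** 2 >= min_sep**2 for u, v in centres)

    # rind bundles: on the mid-rind ellipse at random angles
    ar = a - cfg.epidermis_thickness - cfg.rind_thickness / 2.0
    br = b - cfg.epidermis_thickness - cfg.rind_thickness / 2.0
    placed = 0
    attempts = 0
    while placed < cfg.n_rind_bundles:
        if attempts >= max_attempts:
            raise ValueError("could not place rind bundles without overlap")
        theta = rng.uniform(0.0, 2.0 * np.pi)
        x, y = cx + ar * np.cos(theta), cy + br * np.sin(theta)
        attempts += 1
        if ok(x, y):
            centres.append((x, y))
            placed += 1

    # pith bundles: uniform inside the pith, margin away from the rind
    ap = a - cfg.epidermis_thickness - cfg.rind_thickness - outer - 1.0
    bp = b - cfg.epidermis_thickness - cfg.rind_thickness - outer - 1.0
    placed = 0
    attempts = 0
    while placed < cfg.n_pith_bundles:
        if attempts >= max_attempts:
            raise ValueError("could not place pith bundles without overlap")
        u, v = rng.uniform(-1.0, 1.0, size=2)
        attempts += 1
        if u * u + v * v > 1.0:
            continue
        x, y = cx + u * ap, cy + v * bp
        if ok(x, y):
            centres.append((x, y))
            placed += 1
    return centres


def generate_label_map(cfg: PhantomConfig, rng: np.random.Generator) -> TissueLabelMap:
    """Tissue geometry only (no intensities)."""
    shape = (cfg.height, cfg.width)
    a, b = cfg.semi_axis_x, cfg.semi_axis_y
    rho_outer = _ellipse_rho(shape, a, b)
    rho_epid = _ellipse_rho(shape, a - cfg.epidermis_thickness, b - cfg.epidermis_thickness)
    t = cfg.epidermis_thickness + cfg.rind_thickness
    rho_rind = _ellipse_rho(shape, a - t, b - t)

    labels = np.zeros(shape, dtype=np.uint8)
    labels[rho_outer <= 1.0] = 3                     # pith by default
    labels[(rho_outer <= 1.0) & (rho_rind > 1.0)] = 2   # rind annulus
    labels[(rho_outer <= 1.0) & (rho_epid > 1.0)] = 1   # epidermis shell

    yy, xx = np.mgrid[0 : cfg.height, 0 : cfg.width]
    for x0, y0 in _place_bundles(cfg, rng):
        d2 = (xx - x0) ** 2 + (yy - y0) ** 2
        outer = (cfg.bundle_radius + cfg.sheath_thickness) ** 2
        inner = cfg.bundle_radius**2
        sheath = (d2 <= outer) & (labels > 0)
        labels[sheath] = 4
        labels[(d2 <= inner) & (labels > 0)] = 5
    return TissueLabelMap(labels=labels)


def generate_phantom_section(
    cfg: PhantomConfig,
    intensity_factor: float = 1.0,
    meta: Mapping | None = None,
) -> tuple[MultispectralImage, TissueLabelMap]:
    """One synthetic section: 11-channel image plus ground-truth labels.

    Deterministic for a given config/seed.  ``intensity_factor`` scales all
    non-background class spectra multiplicatively (thickness variation).
    """
    rng = np.random.default_rng(cfg.seed)
    label_map = generate_label_map(cfg, rng)

    spectra = cfg.class_spectra.copy()
    spectra[1:] *= intensity_factor
    base = spectra[label_map.labels]                 # (H, W, 11)
    if cfg.cell_lattice:
        # dark lumen grid in parenchyma: emulates the cell-wall / lumen
        # bimodality of real tissue
        yy, xx = np.mgrid[0 : cfg.height, 0 : cfg.width]
        lumen = ((yy % cfg.cell_pitch) > 1) & ((xx % cfg.cell_pitch) > 1)
        paren = np.isin(label_map.labels, (2, 3)) & lumen
        base[paren] *= 0.25
    if cfg.noise_fraction > 0:
        sd = cfg.noise_fraction * spectra[label_map.labels]
        base = base + rng.standard_normal(base.shape) * sd
    pixels = np.clip(base, 0.0, INTENSITY_MAX)
    msi = MultispectralImage(
        pixels=pixels, layout=DEFAULT_LAYOUT, meta=dict(meta or {})
    )
    return msi, label_map


@dataclass
class SeriesConfig:
    """Study design of a synthetic series with nested variance components."""

    groups: tuple = ("g1", "g2", "g3", "g4")
    internodes_per_group: int = 5
    sections_per_internode: int = 2
    #: group id → 6×11 multiplicative effect on the class spectra
    group_multipliers: dict = field(default_factory=dict)
    #: sd of the internode-level lognormal intensity factor
    internode_sd: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.internodes_per_group < 1 or self.sections_per_internode < 1:
            raise ValueError("counts must be >= 1")
        if self.internode_sd < 0:
            raise ValueError("internode_sd must be >= 0")
        for g, mult in self.group_multipliers.items():
            m = np.asarray(mult, dtype=np.float64)
            if m.shape != (len(CLASS_NAMES), len(CHANNEL_NAMES)) or np.any(m <= 0):
                raise ValueError(f"multipliers for group {g!r} must be positive 6×11")


def sheath_effect_multipliers(factor: float = 1.5) -> np.ndarray:
    """6×11 multiplier matrix boosting the bundle-sheath visible channels."""
    m = np.ones((len(CLASS_NAMES), len(CHANNEL_NAMES)))
    row = CLASS_NAMES.index("bundle_sheath")
    for ch in VISIBLE_SIGNAL_CHANNELS:
        m[row, CHANNEL_NAMES.index(ch)] = factor
    return m


def small_phantom_config(size: int = 64, **overrides) -> PhantomConfig:
    """Geometry scaled to small fast images (simulation/test scale).

    Keeps the same anatomy — epidermis shell, rind annulus with bundles,
    pith with bundles — at a fraction of the tutorial-scale pixel counts.
    """
    base = dict(
        height=size,
        width=size,
        semi_axis_x=0.42 * size,
        semi_axis_y=0.34 * size,
        epidermis_thickness=max(0.02 * size, 1.5),
        rind_thickness=max(0.10 * size, 3.0),
        n_rind_bundles=6,
        n_pith_bundles=3,
        bundle_radius=max(0.035 * size, 1.5),
        sheath_thickness=max(0.02 * size, 1.0),
    )
    base.update(overrides)
    return PhantomConfig(**base)


def generate_series(
    series_cfg: SeriesConfig, phantom_cfg: PhantomConfig
) -> list[tuple[MultispectralImage, TissueLabelMap, dict]]:
    """Generate every section of the design; returns (image, labels, meta).

    Section seeds derive from the base seed and the (group, internode,
    section) indices, so any section is reproducible in isolation and the
    series is invariant to generation order.
    """
    out = []
    for gi, group in enumerate(series_cfg.groups):
        mult = np.asarray(
            series_cfg.group_multipliers.get(group, np.ones_like(phantom_cfg.class_spectra)),
            dtype=np.float64,
        )
        for ii in range(series_cfg.internodes_per_group):
            node_rng = np.random.default_rng(
                np.random.SeedSequence(series_cfg.seed, spawn_key=(gi, ii))
            )
            factor = float(
                np.exp(node_rng.standard_normal() * series_cfg.internode_sd)
            )
            for si in range(series_cfg.sections_per_internode):
                sec_seed = np.random.SeedSequence(
                    series_cfg.seed, spawn_key=(gi, ii, si)
                ).generate_state(1)[0]
                cfg = replace(
                    phantom_cfg,
                    class_spectra=phantom_cfg.class_spectra * mult,
                    seed=int(sec_seed),
                )
                meta = {
                    "group_id": group,
                    "internode_id": f"{group}_i{ii + 1}",
                    "section_id": f"{group}_i{ii + 1}_s{si + 1}",
                }
                msi, labels = generate_phantom_section(
                    cfg, intensity_factor=factor, meta=meta
                )
                out.append((msi, labels, meta))
    return out
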