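"""End-to-end orchestration: segment → fit → score → distributions → compare.

`analyze_series` is the in-memory engine used by tests and simulations;
`run_pipeline` is the file-based workflow behind the CLI, consuming a
manifest CSV and writing every artefact (model JSON, score stacks, 8-bit
renderings, histogram/distribution CSVs, the group-effect report and a
provenance JSON) into a run directory.  Images are always streamed in
manifest order so floating-point accumulation is reproducible bit-exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compare import line_effect_report
from .distributions import (
    RebinnedDistributionSet,
    ScoreHistogramSet,
    accumulate_score_histogram,
    init_histogram_edges,
    rebin_distribution_set,
)
from .image import MultispectralImage, mean_pseudospectrum
from .io import (
    read_manifest,
    read_mask,
    read_stack,
    write_mask,
    write_png,
    write_score_stack,
)
from .pca import (
    PcaModel,
    accumulate_local_stats,
    encode_score_image,
    fit_large_pca,
    project_scores,
)
from .rendering import RenderScale, build_montage, rescale_to_8bit, rgb_composite
from .roi import RoiMask, segment_roi


@dataclass
class RunConfig:
    """All pipeline parameters; defaults follow the reference acquisition
    and analysis settings (14-bit intensities rendered with min 0 / max
    11,000 / gamma 0.65, structuring-element diameters 101 and 51, score
    coding at ±5σ, histograms of 10,000 bins at ±25σ, 1% percentile steps).
    """

    # rendering
    render_min: float = 0.0
    render_max: float = 11000.0
    render_gamma: float = 0.65
    # segmentation
    opening_radius: int = 50
    closing_radius: int = 25
    fill_order: str = "post"
    threshold_override: float | None = None
    # large PCA
    n_components: int = 8
    ddof: int = 0
    # score coding and distributions
    scale_stat: str = "sqrt_eigenvalue"
    score_factor: float = 5.0
    hist_factor: float = 25.0
    n_bins: int = 10_000
    step_pct: float = 1.0
    normalise: bool = True
    # comparison
    n_distribution_pcs: int = 5
    #: components whose distributions are analysed (default: first 4)
    analysis_components: tuple = (0, 1, 2, 3)

    def __post_init__(self) -> None:
        if not self.render_max > self.render_min:
            raise ValueError("render_max must exceed render_min")
        if self.render_gamma <= 0:
            raise ValueError("render_gamma must be positive")
        if self.opening_radius < 0 or self.closing_radius < 0:
            raise ValueError("structuring-element radii must be >= 0")
        if self.fill_order not in ("pre", "post"):
            raise ValueError("fill_order must be 'pre' or 'post'")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.ddof not in (0, 1):
            raise ValueError("ddof must be 0 or 1")
        if self.scale_stat not in ("sqrt_eigenvalue", "eigenvalue"):
            raise ValueError("scale_stat must be 'sqrt_eigenvalue' or 'eigenvalue'")
        if self.score_factor <= 0 or self.hist_factor <= 0:
            raise ValueError("scale factors must be positive")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if not 0 < self.step_pct <= 50:
            raise ValueError("step_pct must be in (0, 50]")
        if self.n_distribution_pcs < 1:
            raise ValueError("n_distribution_pcs must be >= 1")
        self.analysis_components = tuple(int(c) for c in self.analysis_components)
        if any(c < 0 for c in self.analysis_components):
            raise ValueError("analysis_components must be non-negative indices")

    @property
    def render_scale(self) -> RenderScale:
        return RenderScale(self.render_min, self.render_max, self.render_gamma)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["analysis_components"] = list(self.analysis_components)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    def hash(self) -> str:
        d = dataclasses.asdict(self)
        d["analysis_components"] = list(self.analysis_components)
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class SeriesResult:
    """Everything the in-memory pipeline computes for one series."""

    model: PcaModel
    histograms: dict[int, ScoreHistogramSet]
    rebinned: dict[int, RebinnedDistributionSet]
    report: pd.DataFrame
    groups: list
    image_ids: list
    n_roi: list


def analyze_series(
    images: Sequence[MultispectralImage],
    masks: Sequence[RoiMask],
    groups: Sequence,
    config: RunConfig | None = None,
) -> SeriesResult:
    """Run the statistical pipeline on an in-memory series.

    Fits one PCA from the per-image sufficient statistics, projects every
    image, accumulates the per-image score histograms on common ±25σ edges,
    rebins them at the pooled percentile edges and tests the group effect on
    the distribution principal components.
    """
    cfg = config or RunConfig()
    if not (len(images) == len(masks) == len(groups)):
        raise ValueError("images, masks and groups must have equal length")
    if len(images) < 2:
        raise ValueError("need at least two images")

    stats = [accumulate_local_stats(img, m) for img, m in zip(images, masks)]
    model = fit_large_pca(stats, n_components=cfg.n_components, ddof=cfg.ddof)

    comps = [c for c in cfg.analysis_components if c < model.n_components]
    comps = [c for c in comps if model.eigenvalues[c] > 0] or comps[:1]
    edges = {
        c: init_histogram_edges(model, c, cfg.hist_factor, cfg.n_bins, cfg.scale_stat)
        for c in comps
    }
    counts: dict[int, list[np.ndarray]] = {c: [] for c in comps}
    n_roi = []
    image_ids = []
    for i, (img, m) in enumerate(zip(images, masks)):
        score_img = project_scores(img, m, model)
        n_roi.append(m.n_roi)
        image_ids.append(img.meta.get("section_id", i))
        for c in comps:
            cnt, _ = accumulate_score_histogram(score_img, c, edges[c])
            counts[c].append(cnt)

    histograms = {
        c: ScoreHistogramSet(edges=edges[c], counts=np.stack(counts[c]), image_ids=image_ids)
        for c in comps
    }
    rebinned = {
        c: rebin_distribution_set(histograms[c], cfg.step_pct, cfg.normalise)
        for c in comps
    }
    report = line_effect_report(rebinned, groups, n_pcs=cfg.n_distribution_pcs)
    return SeriesResult(
        model=model,
        histograms=histograms,
        rebinned=rebinned,
        report=report,
        groups=list(groups),
        image_ids=image_ids,
        n_roi=n_roi,
    )


class StageError(RuntimeError):
    """Pipeline failure annotated with the stage and offending image."""

    def __init__(self, stage: str, image_id: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on image {image_id!r}: {cause}")
        self.stage = stage
        self.image_id = image_id


def run_pipeline(
    manifest_path: str | Path,
    out_dir: str | Path,
    config: RunConfig | None = None,
) -> SeriesResult:
    """File-based pipeline over a manifest CSV; writes a run directory.

    Per image: ROI mask (segmented if the manifest gives none), score stack
    (float32 TIFF), 8-bit score renderings and the RGB composite rendering.
    Per series: model JSON, histogram and rebinned-distribution CSVs with
    edge JSONs, the group-effect report CSV/JSON, score montages and a
    provenance JSON.  Re-running on the same inputs reproduces the numeric
    artefacts bit-exactly (fixed streaming order).
    """
    cfg = config or RunConfig()
    out = Path(out_dir)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    (out / "scores").mkdir(exist_ok=True)
    (out / "render").mkdir(exist_ok=True)
    manifest = read_manifest(manifest_path)

    images, masks, groups = [], [], []
    for _, row in manifest.iterrows():
        sid = row["section_id"]
        try:
            msi = read_stack(row["image"])
        except Exception as e:  # noqa: BLE001 - abort contract names the image
            raise StageError("read", f"{sid} ({row['image']})", e) from e
        try:
            if row["mask"]:
                roi = read_mask(row["mask"])
            else:
                roi = segment_roi(
                    msi,
                    opening_radius=cfg.opening_radius,
                    closing_radius=cfg.closing_radius,
                    threshold_override=cfg.threshold_override,
                    fill_order=cfg.fill_order,
                )
                write_mask(roi, out / "masks" / f"{sid}_mask.tif")
        except StageError:
            raise
        except Exception as e:  # noqa: BLE001
            raise StageError("roi", sid, e) from e
        images.append(msi)
        masks.append(roi)
        groups.append(row["group_id"])

    try:
        result = analyze_series(images, masks, groups, cfg)
    except Exception as e:  # noqa: BLE001
        raise StageError("fit", "<series>", e) from e

    result.model.to_json(out / "model.json")

    encoded: dict[int, list[np.ndarray]] = {c: [] for c in result.histograms}
    for msi, roi, sid in zip(images, masks, result.image_ids):
        try:
            score_img = project_scores(msi, roi, result.model)
            write_score_stack(score_img.scores, out / "scores" / f"{sid}_scores.tif")
            for c in result.histograms:
                img8 = encode_score_image(
                    score_img, c, cfg.scale_stat, cfg.score_factor
                )
                write_png(img8, out / "render" / f"{sid}_pc{c + 1}.png")
                encoded[c].append(img8)
            composite = rescale_to_8bit(rgb_composite(msi), cfg.render_scale)
            write_png(composite, out / "render" / f"{sid}_composite.png")
        except Exception as e:  # noqa: BLE001
            raise StageError("score", str(sid), e) from e

    for c, hist in result.histograms.items():
        pd.DataFrame(hist.counts, index=hist.image_ids).to_csv(
            out / f"histogram_pc{c + 1}.csv"
        )
        (out / f"histogram_pc{c + 1}_edges.json").write_text(
            json.dumps(hist.edges.tolist())
        )
        reb = result.rebinned[c]
        pd.DataFrame(reb.rows, index=reb.image_ids).to_csv(
            out / f"distribution_pc{c + 1}.csv"
        )
        (out / f"distribution_pc{c + 1}_edges.json").write_text(
            json.dumps(reb.pct_edges.tolist())
        )
        montage = build_montage(encoded[c], row_keys=groups, col_keys=result.image_ids)
        write_png(montage, out / "render" / f"montage_pc{c + 1}.png")

    result.report.to_csv(out / "report.csv", index=False)
    result.report.to_json(out / "report.json", orient="records", indent=1)

    provenance = {
        "package_version": __version__,
        "config_hash": cfg.hash(),
        "config": json.loads(json.dumps(dataclasses.asdict(cfg), default=list)),
        "images": [
            {"section_id": sid, "group_id": g, "n_roi": n}
            for sid, g, n in zip(result.image_ids, result.groups, result.n_roi)
        ],
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=1))
    return result
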