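"""Streaming ("large") PCA over all ROI pixels of an image series.

A series of large multispectral images cannot be pooled into one in-memory
data table.  PCA only needs the pooled mean and covariance, and both are
sums of per-image sufficient statistics: for image i with unfolded ROI data
table X_i (n_i pixels × 11 channels),

    n_i,    s_i = Σ_j x_ij,    V_i = X_iᵀ X_i.

Merging the statistics over the series gives

    n = Σ n_i,   mean = Σ s_i / n,   cov = (Σ V_i − n · mean meanᵀ) / n,

and the 11×11 covariance is eigen-decomposed to obtain the eigenvalues λ and
orthonormal loadings L shared by the whole series.  Each image is then
centred by the global mean and projected, C_i = (X_i − 1 meanᵀ) L, and the
scores are refolded to score images.  The result is identical to a PCA of
all pixels concatenated, but only one image is ever held in memory.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .image import MultispectralImage
from .roi import RoiMask


@dataclass
class LocalStats:
    """Per-image sufficient statistics (count, channel sums, cross-products)."""

    n: int
    s: np.ndarray          # (C,) channel sums
    V: np.ndarray          # (C, C) cross-product matrix XᵀX

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=np.float64)
        self.V = np.asarray(self.V, dtype=np.float64)
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.V.shape != (self.s.size, self.s.size):
            raise ValueError("V must be C×C with C = len(s)")

    def merge(self, other: "LocalStats") -> "LocalStats":
        return LocalStats(self.n + other.n, self.s + other.s, self.V + other.V)


@dataclass
class PcaModel:
    """Global PCA model shared by every image of the series."""

    n: int
    mean: np.ndarray
    cov: np.ndarray
    eigenvalues: np.ndarray      # descending
    loadings: np.ndarray         # (C, K), orthonormal columns
    variance_pct: np.ndarray
    ddof: int = 0
    degenerate: bool = False     # True when total variance is zero

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n": int(self.n),
            "ddof": int(self.ddof),
            "degenerate": bool(self.degenerate),
            "mean": self.mean.tolist(),
            "cov": self.cov.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "loadings": self.loadings.tolist(),
            "variance_pct": self.variance_pct.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PcaModel":
        d = json.loads(Path(path).read_text())
        return cls(
            n=d["n"],
            mean=np.array(d["mean"]),
            cov=np.array(d["cov"]),
            eigenvalues=np.array(d["eigenvalues"]),
            loadings=np.array(d["loadings"]),
            variance_pct=np.array(d["variance_pct"]),
            ddof=d.get("ddof", 0),
            degenerate=d.get("degenerate", False),
        )


@dataclass
class ScoreImage:
    """Refolded per-pixel scores of one image; NaN outside the ROI."""

    scores: np.ndarray           # (H, W, K) float32, NaN = no data
    mask: RoiMask
    eigenvalues: np.ndarray

    def component(self, k: int) -> np.ndarray:
        return self.scores[:, :, k]

    def roi_scores(self, k: int) -> np.ndarray:
        """1-D array of component-k scores over the ROI pixels (float64)."""
        return self.scores[self.mask.mask, k].astype(np.float64)


def accumulate_local_stats(msi: MultispectralImage, roi: RoiMask) -> LocalStats:
    """Sufficient statistics of one image's ROI pixels, in double precision."""
    if roi.shape != msi.shape:
        raise ValueError("ROI shape does not match image shape")
    if roi.n_roi == 0:
        raise ValueError("ROI is empty")
    X = msi.unfold(roi.mask)                 # float64
    return LocalStats(n=X.shape[0], s=X.sum(axis=0), V=X.T @ X)


def _sign_fix(loadings: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive."""
    idx = np.argmax(np.abs(loadings), axis=0)
    signs = np.sign(loadings[idx, np.arange(loadings.shape[1])])
    signs[signs == 0] = 1.0
    return loadings * signs


def fit_large_pca(
    stats: Iterable[LocalStats],
    n_components: int | None = None,
    ddof: int = 0,
) -> PcaModel:
    """Merge per-image statistics and eigen-decompose the global covariance.

    ``ddof=0`` (default) divides the centred cross-products by n (population
    covariance); ``ddof=1`` divides by n−1.  Loadings are unaffected by the
    choice.  Columns are sign-fixed so the largest-magnitude entry of each
    loading is positive.
    """
    stats = list(stats)
    if not stats:
        raise ValueError("need at least one LocalStats")
    total = stats[0]
    for st in stats[1:]:
        total = total.merge(st)
    if total.n < 2:
        raise ValueError("need at least two pixels in total")

    n = total.n
    mean = total.s / n
    cov = (total.V - n * np.outer(mean, mean)) / (n - ddof)
    cov = (cov + cov.T) / 2.0                 # enforce symmetry

    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    # covariance is PSD; zero out the tiny negative eigenvalues of fp noise
    tol = 1e-12 * max(float(np.abs(evals).max()), 1.0)
    evals[(evals < 0) & (evals > -tol)] = 0.0

    K = evecs.shape[1] if n_components is None else min(n_components, evecs.shape[1])
    loadings = _sign_fix(evecs[:, :K])
    eigenvalues = evals[:K]

    trace = evals.sum()
    degenerate = not trace > 0
    if degenerate:
        warnings.warn("zero total variance: all eigenvalues are 0", RuntimeWarning)
        variance_pct = np.zeros(K)
    else:
        variance_pct = 100.0 * eigenvalues / trace

    return PcaModel(
        n=n,
        mean=mean,
        cov=cov,
        eigenvalues=eigenvalues,
        loadings=loadings,
        variance_pct=variance_pct,
        ddof=ddof,
        degenerate=degenerate,
    )


def project_scores(msi: MultispectralImage, roi: RoiMask, model: PcaModel) -> ScoreImage:
    """Centre by the global mean and project onto the common loadings."""
    if msi.n_channels != model.mean.size:
        raise ValueError(
            f"image has {msi.n_channels} channels, model expects {model.mean.size}"
        )
    if roi.shape != msi.shape:
        raise ValueError("ROI shape does not match image shape")
    X = msi.unfold(roi.mask)
    C = (X - model.mean) @ model.loadings
    H, W = msi.shape
    out = np.full((H, W, model.n_components), np.nan, dtype=np.float32)
    out[roi.mask] = C.astype(np.float32)
    return ScoreImage(scores=out, mask=roi, eigenvalues=model.eigenvalues)


def score_scale_sigma(
    eigenvalue: float, scale_stat: str = "sqrt_eigenvalue"
) -> float:
    """Spread statistic σ used to scale score renderings and histogram spans.

    ``"sqrt_eigenvalue"`` (default) takes σ = √λ, the standard deviation of
    the component's scores; ``"eigenvalue"`` takes σ = λ literally.
    """
    if eigenvalue <= 0:
        raise ValueError("component eigenvalue must be positive")
    if scale_stat == "sqrt_eigenvalue":
        return float(np.sqrt(eigenvalue))
    if scale_stat == "eigenvalue":
        return float(eigenvalue)
    raise ValueError(f"unknown scale_stat {scale_stat!r}")


def encode_score_image(
    score_img: ScoreImage,
    component: int,
    scale_stat: str = "sqrt_eigenvalue",
    factor: float = 5.0,
    out_max: int = 255,
) -> np.ndarray:
    """Code one score component to 8 bit on a series-common scale.

    The interval [−factor·σ, +factor·σ] is mapped linearly onto
    [0, out_max], values outside are clipped, rounding is half-up, and
    non-ROI pixels are set to 0.
    """
    sigma = score_scale_sigma(float(score_img.eigenvalues[component]), scale_stat)
    lo, hi = -factor * sigma, factor * sigma
    x = score_img.component(component).astype(np.float64)
    with np.errstate(invalid="ignore"):
        y = np.clip((x - lo) / (hi - lo), 0.0, 1.0) * out_max
        y = np.floor(y + 0.5)
    y[~score_img.mask.mask] = 0
    return y.astype(np.uint8 if out_max <= 255 else np.uint16)
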