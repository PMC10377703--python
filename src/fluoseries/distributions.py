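"""Score distributions with percentile rebinning.

For each principal component, per-image score histograms are accumulated on
a common a-priori grid of 10,000 equal bins spanning ±25σ (σ from the
component eigenvalue) during the scoring pass, so the series is read only
once.  In a post-processing step the histograms are summed into a total
distribution, the 0..100% percentiles (1% steps) of its cumulative curve
define 100 variable-width bins each holding 1% of all pixels series-wide,
and each image's cumulative distribution is interpolated at those percentile
edges.  The resulting 100-value rows are the per-image quantitative features
compared across groups: a flat row (0.01 everywhere, normalised) means the
image is indistinguishable from the pooled series, and deviations localise
where in the score range the image over- or under-represents pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .pca import PcaModel, ScoreImage, score_scale_sigma


def init_histogram_edges(
    model: PcaModel,
    component: int,
    factor: float = 25.0,
    n_bins: int = 10_000,
    scale_stat: str = "sqrt_eigenvalue",
) -> np.ndarray:
    """Equal-width bin edges spanning [−factor·σ, +factor·σ] for a component.

    The factor (default 25) is chosen large enough that scores beyond the
    span are rare; such scores are clamped into the terminal bins by
    :func:`accumulate_score_histogram` and reported.
    """
    sigma = score_scale_sigma(float(model.eigenvalues[component]), scale_stat)
    return np.linspace(-factor * sigma, factor * sigma, n_bins + 1)


def accumulate_score_histogram(
    score_img: ScoreImage, component: int, edges: np.ndarray
) -> tuple[np.ndarray, dict]:
    """Histogram of one image's ROI scores on common edges.

    Bins are left-closed/right-open with the last bin closed.  Scores outside
    the span are counted into the terminal bins so that the counts always sum
    to the ROI pixel count; the overflow report says how many were clamped.
    """
    edges = np.asarray(edges, dtype=np.float64)
    scores = score_img.roi_scores(component)
    n_bins = edges.size - 1
    idx = np.searchsorted(edges, scores, side="right") - 1
    # score exactly on the top edge belongs to the last bin (closed)
    idx[scores == edges[-1]] = n_bins - 1
    below = int((idx < 0).sum())
    above = int((idx > n_bins - 1).sum())
    counts = np.bincount(np.clip(idx, 0, n_bins - 1), minlength=n_bins)
    report = {
        "n_below": below,
        "n_above": above,
        "min_score": float(scores.min()) if scores.size else np.nan,
        "max_score": float(scores.max()) if scores.size else np.nan,
    }
    return counts, report


@dataclass
class ScoreHistogramSet:
    """Per-image fixed-edge score histograms for one component."""

    edges: np.ndarray               # (B+1,) strictly ascending
    counts: np.ndarray              # (n_images, B) integer counts
    image_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=np.float64)
        self.counts = np.atleast_2d(np.asarray(self.counts))
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("edges must be strictly ascending")
        if self.counts.shape[1] != self.edges.size - 1:
            raise ValueError("counts width must equal number of bins")
        if not self.image_ids:
            self.image_ids = list(range(self.counts.shape[0]))

    @property
    def n_images(self) -> int:
        return self.counts.shape[0]


def pool_total_distribution(hist: ScoreHistogramSet) -> tuple[np.ndarray, np.ndarray]:
    """Total score distribution (sum over images) and its cumulative curve."""
    total = hist.counts.sum(axis=0)
    return total, np.cumsum(total)


def percentile_edges(
    total_cumulative: np.ndarray, edges: np.ndarray, step_pct: float = 1.0
) -> np.ndarray:
    """Percentile edges of the pooled score distribution.

    The cumulative curve is treated as piecewise linear between the raw
    edges (mass spread uniformly inside each raw bin); for each q in
    0, step, …, 100 the score at which it reaches q% of the total mass is
    returned.  Where several percentiles fall in an empty score range the
    leftmost attainment is kept, producing repeated (zero-width) edges.
    """
    cum = np.concatenate(([0.0], np.asarray(total_cumulative, dtype=np.float64)))
    total = cum[-1]
    if not total > 0:
        raise ValueError("total distribution has no mass")
    qs = np.arange(0.0, 100.0 + step_pct / 2, step_pct)
    targets = qs / 100.0 * total
    out = np.empty_like(targets)
    # first index where cum >= target  → leftmost attainment
    hi = np.searchsorted(cum, targets, side="left")
    hi = np.clip(hi, 1, cum.size - 1)
    lo = hi - 1
    seg = cum[hi] - cum[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(seg > 0, (targets - cum[lo]) / seg, 0.0)
    out = edges[lo] + frac * (edges[hi] - edges[lo])
    out = np.maximum.accumulate(out)     # guard against fp non-monotonicity
    return out


def rebin_image_distribution(
    counts: np.ndarray,
    raw_edges: np.ndarray,
    pct_edges: np.ndarray,
    normalise: bool = True,
) -> np.ndarray:
    """Rebin one image's histogram onto the pooled percentile edges.

    The image's cumulative distribution is interpolated (piecewise linear)
    at the percentile edges; successive differences give the mass per
    percentile bin.  With ``normalise`` the row is divided by the image
    total so it sums to 1.
    """
    counts = np.asarray(counts, dtype=np.float64)
    cum = np.concatenate(([0.0], np.cumsum(counts)))
    vals = np.interp(pct_edges, raw_edges, cum)
    masses = np.diff(vals)
    if np.any(masses < -1e-9 * max(cum[-1], 1.0)):
        raise ValueError("negative rebinned mass beyond numerical tolerance")
    masses = np.clip(masses, 0.0, None)
    if normalise:
        if not cum[-1] > 0:
            raise ValueError("image histogram has no mass")
        masses = masses / cum[-1]
    return masses


@dataclass
class RebinnedDistributionSet:
    """Per-image percentile-rebinned score distributions for one component."""

    pct_edges: np.ndarray           # (n_steps+1,) non-decreasing
    rows: np.ndarray                # (n_images, n_steps)
    image_ids: list
    normalised: bool = True

    @property
    def n_images(self) -> int:
        return self.rows.shape[0]


def rebin_distribution_set(
    hist: ScoreHistogramSet, step_pct: float = 1.0, normalise: bool = True
) -> RebinnedDistributionSet:
    """Full step-2 post-processing: pool, percentile edges, per-image rebin."""
    _, cum = pool_total_distribution(hist)
    pct = percentile_edges(cum, hist.edges, step_pct)
    rows = np.stack(
        [
            rebin_image_distribution(hist.counts[i], hist.edges, pct, normalise)
            for i in range(hist.n_images)
        ]
    )
    return RebinnedDistributionSet(
        pct_edges=pct, rows=rows, image_ids=list(hist.image_ids), normalised=normalise
    )
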