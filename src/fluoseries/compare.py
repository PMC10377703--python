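"""Group comparison of percentile-rebinned score distributions.

Each image is summarised, per large-PCA component, by its 100-bin rebinned
score distribution.  The rows are compared by a second, ordinary PCA
("score distribution principal components"), and the group (inbred line)
effect on each distribution PC is tested with a one-way ANOVA F-test.  The
result is a table with one row per large-PCA component and one column per
distribution PC, each cell holding the percent variance the PC describes
and the p-value of the group effect.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .distributions import RebinnedDistributionSet


@dataclass
class DistributionPcaResult:
    """PCA of the images × bins distribution matrix (columns centred)."""

    loadings: np.ndarray        # (n_bins, K) orthonormal
    scores: np.ndarray          # (n_images, K)
    eigenvalues: np.ndarray     # (K,) descending
    variance_pct: np.ndarray    # (K,) percent of total variance


@dataclass
class AnovaResult:
    """One-way ANOVA of a scalar response against a grouping factor."""

    F: float
    df_between: int
    df_within: int
    p_value: float
    ss_between: float
    ss_within: float
    group_means: dict


def distribution_pca(dist_matrix: np.ndarray, n_components: int | None = None) -> DistributionPcaResult:
    """Column-centred covariance PCA of per-image distributions.

    Implemented through the SVD of the centred matrix, which is equivalent
    to eigen-decomposing the bins×bins covariance; columns are centred but
    not scaled, and loadings follow the largest-magnitude-entry-positive
    sign convention.  Eigenvalues use the divide-by-n convention so the sum
    equals the total (population) variance of the matrix.
    """
    X = np.asarray(dist_matrix, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two images (rows)")
    if not np.all(np.isfinite(X)):
        raise ValueError("distribution matrix must be finite")
    n = X.shape[0]
    Xc = X - X.mean(axis=0, keepdims=True)
    U, svals, Vt = np.linalg.svd(Xc, full_matrices=False)
    evals = svals**2 / n
    K = evals.size if n_components is None else min(n_components, evals.size)
    loadings = Vt.T[:, :K]
    signs = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(K)])
    signs[signs == 0] = 1.0
    loadings = loadings * signs
    scores = Xc @ loadings
    total = evals.sum()
    variance_pct = 100.0 * evals[:K] / total if total > 0 else np.zeros(K)
    return DistributionPcaResult(
        loadings=loadings,
        scores=scores,
        eigenvalues=evals[:K],
        variance_pct=variance_pct,
    )


def one_way_anova(values: Sequence[float], groups: Sequence) -> AnovaResult:
    """One-way fixed-effect ANOVA: F = (SS_b/df_b) / (SS_w/df_w).

    The p-value is the upper tail of the F(df_between, df_within)
    distribution.  If both the between- and within-group sums of squares
    are zero, F is undefined and reported as NaN with p = NaN.
    """
    values = np.asarray(values, dtype=np.float64)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must have the same length")
    labels = pd.unique(groups)
    if labels.size < 2:
        raise ValueError("need at least two groups")
    grand = values.mean()
    ss_b = 0.0
    ss_w = 0.0
    means = {}
    for g in labels:
        v = values[groups == g]
        means[g] = float(v.mean())
        ss_b += v.size * (v.mean() - grand) ** 2
        ss_w += float(((v - v.mean()) ** 2).sum())
    df_b = labels.size - 1
    df_w = values.size - labels.size
    if df_w < 1:
        raise ValueError("need at least one group with two or more observations")
    if ss_w == 0.0 and ss_b == 0.0:
        return AnovaResult(np.nan, df_b, df_w, np.nan, ss_b, ss_w, means)
    ms_b = ss_b / df_b
    ms_w = ss_w / df_w
    if ms_w == 0.0:
        return AnovaResult(np.inf, df_b, df_w, 0.0, ss_b, ss_w, means)
    F = ms_b / ms_w
    p = float(sps.f.sf(F, df_b, df_w))
    return AnovaResult(float(F), df_b, df_w, p, float(ss_b), float(ss_w), means)


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (step-up FDR); NaNs are passed through."""
    p = np.asarray(p_values, dtype=np.float64)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv)
    ranked = pv[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    out[ok] = adj
    return out


def line_effect_report(
    rebinned: Mapping[int, RebinnedDistributionSet],
    groups: Sequence,
    n_pcs: int = 5,
) -> pd.DataFrame:
    """Group-effect table over large-PCA components × distribution PCs.

    For every large-PCA component, a PCA of the rebinned distributions is
    fitted and the first ``n_pcs`` distribution-PC scores are each tested
    for a group effect with one-way ANOVA.  The returned frame has one row
    per (component, distribution PC) with the percent variance, F, raw
    p-value and, as a labelled extension, a Benjamini–Hochberg adjusted
    p-value across the whole table.
    """
    groups = np.asarray(groups)
    records = []
    for comp in sorted(rebinned):
        dset = rebinned[comp]
        if dset.rows.shape[0] != groups.size:
            raise ValueError("group labels do not match number of images")
        pca = distribution_pca(dset.rows, n_components=n_pcs)
        for k in range(pca.scores.shape[1]):
            res = one_way_anova(pca.scores[:, k], groups)
            records.append(
                {
                    "component": comp + 1,
                    "distribution_pc": k + 1,
                    "variance_pct": float(pca.variance_pct[k]),
                    "F": res.F,
                    "df_between": res.df_between,
                    "df_within": res.df_within,
                    "p_value": res.p_value,
                }
            )
    table = pd.DataFrame.from_records(records)
    table["p_bh_extension"] = benjamini_hochberg(table["p_value"].to_numpy())
    return table
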