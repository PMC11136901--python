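"""Suitability projection, binarization and range-comparison analytics.

Suitability maps are posterior-mean presence probabilities over a
projection domain (all models are projected onto the largest calibration
buffer).  Maps are binarized with a 10 %-omission threshold (the 10th
percentile of suitability at the training presences) and compared with
the Jaccard similarity index, range expansion/contraction percentages
under an unlimited-dispersal assumption, southern range limits, and
paired Wilcoxon signed-rank contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata, wilcoxon

__all__ = ["BinaryMap", "project_map", "binarize", "jaccard",
           "pairwise_jaccard", "range_change", "southern_limit",
           "paired_wilcoxon"]


@dataclass
class BinaryMap:
    """0/1 cells over the projection domain, plus provenance."""

    cells: np.ndarray            # bool array over the grid
    threshold: float
    grid: object = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.cells = np.asarray(self.cells, dtype=bool)

    @property
    def n_suitable(self):
        return int(self.cells.sum())


def project_map(results, env_norm, domain_mask, predictors=None, thin_to=400):
    """Posterior-mean suitability over the projection domain.

    Returns a 2-D array with NaN outside ``domain_mask``; cells inside the
    domain with any missing predictor also stay NaN.
    """
    names = predictors or results.names
    if list(names) != list(results.names):
        raise ValueError("predictor names do not match the fitted model")
    domain_mask = np.asarray(domain_mask, dtype=bool)
    X, m = env_norm.sea_values(names, mask=domain_mask)
    complete = np.isfinite(X).all(axis=1)
    out = np.full(env_norm.grid.shape, np.nan)
    rows, cols = np.nonzero(m)
    mean = results.predict_mean(X[complete], thin_to=thin_to)
    out[rows[complete], cols[complete]] = mean
    return out


def binarize(suit, presence_suit, omission=0.10, grid=None, meta=None) -> BinaryMap:
    """Threshold a suitability map at the ``omission`` quantile (linear
    interpolation) of the training-presence suitabilities; a cell is
    suitable iff its value is >= the threshold."""
    presence_suit = np.asarray(presence_suit, dtype=float)
    if presence_suit.size == 0:
        raise ValueError("presence suitability sample is empty")
    thr = float(np.quantile(presence_suit, omission, method="linear"))
    suit = np.asarray(suit, dtype=float)
    cells = np.isfinite(suit) & (suit >= thr)
    return BinaryMap(cells, thr, grid, meta or {})


def jaccard(a: BinaryMap, b: BinaryMap):
    """|A n B| / |A u B| over suitable cells; 1.0 when both maps are empty."""
    if a.cells.shape != b.cells.shape:
        raise ValueError("binary maps are on different grids")
    union = np.sum(a.cells | b.cells)
    if union == 0:
        return 1.0  # both empty; flagged as trivially identical
    return float(np.sum(a.cells & b.cells) / union)


def pairwise_jaccard(set_a, set_b):
    """Full |set_a| x |set_b| cross-product Jaccard matrix plus summary.

    Returns (matrix, {"mean": ..., "se": ..., "n_pairs": ...}).
    """
    if not set_a or not set_b:
        raise ValueError("binary map lists must be non-empty")
    shape = set_a[0].cells.shape
    for m in list(set_a) + list(set_b):
        if m.cells.shape != shape:
            raise ValueError("mixed grids in binary map lists")
    mat = np.array([[jaccard(a, b) for b in set_b] for a in set_a])
    flat = mat.ravel()
    summary = {"mean": float(flat.mean()),
               "se": float(flat.std(ddof=1) / np.sqrt(flat.size))
               if flat.size > 1 else 0.0,
               "n_pairs": int(flat.size)}
    return mat, summary


def range_change(current: BinaryMap, future: BinaryMap):
    """(expansion %, contraction %) relative to the current range size,
    under unlimited dispersal (no reachability mask)."""
    if current.cells.shape != future.cells.shape:
        raise ValueError("binary maps are on different grids")
    n_cur = current.n_suitable
    if n_cur == 0:
        raise ValueError("current range is empty")
    gained = np.sum(future.cells & ~current.cells)
    lost = np.sum(current.cells & ~future.cells)
    return 100.0 * gained / n_cur, 100.0 * lost / n_cur


def southern_limit(bmap: BinaryMap, lats=None):
    """Minimum cell-center latitude among suitable cells."""
    if bmap.n_suitable == 0:
        raise ValueError("binary map has no suitable cells")
    if lats is None:
        if bmap.grid is None:
            raise ValueError("need grid latitudes")
        lats = bmap.grid.lats
    rows = np.nonzero(bmap.cells.any(axis=1))[0]
    return float(np.asarray(lats)[rows].min())


def _exact_signrank_p(ranks, v, alternative):
    """Exact null distribution of the positive-rank sum by convolution
    over all 2^n sign patterns (mid-ranks handled by doubling)."""
    r2 = np.rint(2.0 * np.asarray(ranks)).astype(int)
    total = int(r2.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[:total + 1 - r]
        pmf = 0.5 * (pmf + shifted)
    v2 = int(round(2.0 * v))
    cdf = pmf[:v2 + 1].sum()
    sf = pmf[v2:].sum()
    if alternative == "greater":
        return min(1.0, sf)
    if alternative == "less":
        return min(1.0, cdf)
    return min(1.0, 2.0 * min(cdf, sf))


def paired_wilcoxon(x, y, alternative="two-sided"):
    """Paired Wilcoxon signed-rank test.

    Returns (V, p) where V is the positive-rank sum (zero differences
    dropped, mid-ranks for ties).  The p-value is exact (full sign-pattern
    null distribution) for n <= 25 and a normal approximation with
    continuity correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples of equal length >= 3")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all paired differences are zero")
    ranks = rankdata(np.abs(d))
    v = float(ranks[d > 0].sum())
    if d.size <= 25:
        return v, _exact_signrank_p(ranks, v, alternative)
    res = wilcoxon(x, y, zero_method="wilcox", correction=True,
                   alternative=alternative, method="approx")
    return v, float(res.pvalue)
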