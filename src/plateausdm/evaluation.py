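"""Model evaluation: spatial block cross-validation, the continuous Boyce
index, permutation variable importance, and marginal response curves.

The Boyce index is the presence-only performance metric used throughout:
Spearman rank correlation between predicted-to-expected presence ratios
(P/E) computed in a moving window over the suitability range and the
window centers.  Defaults follow the usual continuous implementation:
window width = one tenth of the background suitability range, 100 evenly
spaced evaluation points, windows with zero expected share dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

from .model import MCMCConfig, PlateauModel

__all__ = ["FoldAssignment", "spatial_block_folds", "cross_validate",
           "boyce_index", "permutation_importance", "response_curve"]


@dataclass
class FoldAssignment:
    """Per-record fold ids from a block grid over the point bounding box."""

    fold: np.ndarray           # fold id (1..k) per record
    block: np.ndarray          # block id per record
    k: int
    grid_shape: tuple
    seed: int = 0

    def __post_init__(self):
        self.fold = np.asarray(self.fold, dtype=int)
        self.block = np.asarray(self.block, dtype=int)
        if self.fold.min(initial=1) < 1 or self.fold.max(initial=1) > self.k:
            raise ValueError("fold ids must lie in 1..k")


def spatial_block_folds(lons, lats, labels=None, n_rows=10, n_cols=10, k=5,
                        seed=0, max_retries=20) -> FoldAssignment:
    """Split the point bounding box into ``n_rows x n_cols`` lat/lon blocks
    and randomly allocate the non-empty blocks to ``k`` folds, balancing
    per-fold presence counts (greedy, random tie-breaks).

    Records in the same block always share a fold.  If after bounded
    retries some fold holds zero presences, an error is raised.
    """
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    if lons.size == 0:
        raise ValueError("no points to assign")
    if np.ptp(lons) == 0 or np.ptp(lats) == 0:
        raise ValueError("points span a degenerate bounding box")
    pres = np.ones(lons.size, dtype=bool) if labels is None \
        else (np.asarray(labels) == "presence")
    eps = 1e-9
    ci = np.minimum(((lons - lons.min()) / (np.ptp(lons) + eps) * n_cols)
                    .astype(int), n_cols - 1)
    ri = np.minimum(((lats - lats.min()) / (np.ptp(lats) + eps) * n_rows)
                    .astype(int), n_rows - 1)
    block = ri * n_cols + ci
    uniq = np.unique(block)
    pres_per_block = np.array([np.sum(pres[block == b]) for b in uniq])
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        order = rng.permutation(uniq.size)
        order = order[np.argsort(-pres_per_block[order], kind="stable")]
        fold_of_block = np.zeros(uniq.size, dtype=int)
        fold_pres = np.zeros(k)
        for idx in order:
            f = int(np.argmin(fold_pres))
            fold_of_block[idx] = f + 1
            fold_pres[f] += pres_per_block[idx]
        if np.all(fold_pres > 0):
            lookup = dict(zip(uniq.tolist(), fold_of_block.tolist()))
            fold = np.array([lookup[b] for b in block])
            return FoldAssignment(fold, block, k, (n_rows, n_cols), seed)
    raise RuntimeError(f"could not allocate blocks to {k} folds with "
                       "at least one presence each")


def boyce_index(pres_suit, bg_suit, window_frac=0.1, res=100,
                rm_duplicate=True):
    """Continuous Boyce index in [-1, 1].

    ``pres_suit`` are suitability values at (withheld) presences;
    ``bg_suit`` over the background (calibration-area) cells.  For each of
    ``res`` window centers spanning the background range, P is the share
    of presences and E the share of background inside a window of width
    ``window_frac`` x range; windows with E = 0 are dropped and the result
    is the Spearman correlation of P/E with the window center.  Following
    the standard continuous implementation, runs of duplicated P/E values
    are collapsed to their first window (``rm_duplicate``) so that long
    stretches of empty windows do not drown the correlation in ties.
    """
    pres = np.asarray(pres_suit, dtype=float)
    bg = np.asarray(bg_suit, dtype=float)
    pres = pres[np.isfinite(pres)]
    bg = bg[np.isfinite(bg)]
    if pres.size == 0 or bg.size == 0:
        raise ValueError("empty presence or background suitability input")
    lo, hi = bg.min(), bg.max()
    if hi - lo <= 0:
        raise ValueError("background suitability is constant; "
                         "Boyce index undefined")
    half = 0.5 * window_frac * (hi - lo)
    centers = np.linspace(lo, hi, res)
    ratios, kept = [], []
    for c in centers:
        inside_bg = np.mean((bg >= c - half) & (bg <= c + half))
        if inside_bg == 0:
            continue
        inside_p = np.mean((pres >= c - half) & (pres <= c + half))
        ratios.append(inside_p / inside_bg)
        kept.append(c)
    if not kept:
        raise ValueError("all Boyce windows empty; index undefined")
    ratios = np.asarray(ratios)
    kept = np.asarray(kept)
    if rm_duplicate and ratios.size > 1:
        _, first = np.unique(ratios, return_index=True)
        first = np.sort(first)  # keep the first window of each distinct P/E
        ratios, kept = ratios[first], kept[first]
    if np.ptp(ratios) == 0:  # constant P/E: no association
        return 0.0
    rho, _ = spearmanr(ratios, kept)
    return float(rho)


def cross_validate(occ, env_norm, area, prior, mcmc_cfg: MCMCConfig,
                   folds: FoldAssignment, predictors=None, thin_to=400):
    """Fivefold (or k-fold) spatially blocked cross-validation.

    For each fold: fit on the remaining folds, predict over the
    calibration-area background, and score the withheld presences with the
    Boyce index.  Returns the list of per-fold Boyce values.
    """
    if folds.k < 2:
        raise ValueError("need k >= 2 folds")
    names = predictors or env_norm.layer_names
    t = occ.table
    if len(t) != folds.fold.size:
        raise ValueError("fold assignment does not match the occurrence set")
    X = env_norm.values_at(t["row"].to_numpy(), t["col"].to_numpy(), names)
    y = (t["label"] == "presence").to_numpy(dtype=float)
    Xbg, _ = env_norm.sea_values(names, mask=area.mask)
    Xbg = Xbg[np.isfinite(Xbg).all(axis=1)]
    scores = []
    for f in range(1, folds.k + 1):
        train = folds.fold != f
        test_pres = (~train) & (y == 1)
        if y[train].min(initial=1) == 1 or y[train].max(initial=0) == 0:
            raise ValueError(f"training split for fold {f} lacks both labels")
        res = PlateauModel(y[train], X[train], names, prior).fit(mcmc_cfg)
        bg_suit = res.predict_mean(Xbg, thin_to=thin_to)
        pres_suit = res.predict_mean(X[test_pres], thin_to=thin_to)
        scores.append(boyce_index(pres_suit, bg_suit))
    return scores


def permutation_importance(results, X, n_perm=5, seed=0):
    """Permutation importance per predictor.

    importance_j = mean over ``n_perm`` permutations of
    1 - Pearson(prediction on intact data, prediction with column j
    permuted), clipped to [0, 1].  Constant predictions yield 0 with a
    warning.
    """
    X = np.asarray(X, dtype=float)
    rng = np.random.default_rng(seed)
    base = results.predict_mean(X)
    out = {}
    if np.ptp(base) < 1e-12:
        warnings.warn("constant predictions; importances undefined, "
                      "reported as 0", UserWarning)
        return pd.Series({n: 0.0 for n in results.names}, name="importance")
    for j, name in enumerate(results.names):
        vals = []
        for _ in range(n_perm):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            pred = results.predict_mean(Xp)
            if np.ptp(pred) < 1e-12:
                r = 0.0
            else:
                r, _ = pearsonr(base, pred)
            vals.append(1.0 - r)
        out[name] = float(np.clip(np.mean(vals), 0.0, 1.0))
    return pd.Series(out, name="importance")


def response_curve(results, predictor, X_ref, n_grid=100, transform=None,
                   extend_to=None, ci=0.95, thin_to=400):
    """Marginal posterior response curve for one predictor.

    The predictor is varied over [observed min, max(observed max,
    ``extend_to``)] (both on the normalized scale) while all other
    predictors are held at their median over ``X_ref`` (typically the
    calibration-area cells).  Returns a table with the normalized grid,
    the physical-unit grid when a transform is given, and the posterior
    mean and central credible band.
    """
    if predictor not in results.names:
        raise KeyError(f"unknown predictor {predictor!r}")
    X_ref = np.asarray(X_ref, dtype=float)
    j = results.names.index(predictor)
    lo = np.nanmin(X_ref[:, j])
    hi = np.nanmax(X_ref[:, j])
    if extend_to is not None:
        hi = max(hi, extend_to)
    grid = np.linspace(lo, hi, n_grid)
    med = np.nanmedian(X_ref, axis=0)
    X = np.tile(med, (n_grid, 1))
    X[:, j] = grid
    mean, lower, upper = results.predict(X, ci=ci, thin_to=thin_to)
    table = pd.DataFrame({"normalized": grid, "mean": mean,
                          "lower": lower, "upper": upper})
    table["value"] = (transform.denormalize_value(predictor, grid)
                      if transform is not None else grid)
    return table[["value", "normalized", "mean", "lower", "upper"]]
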