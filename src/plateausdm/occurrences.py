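"""Occurrence cleaning, spatial thinning, calibration areas,
pseudo-absences, predictor normalization and collinearity screening.

This is the data-preparation stage of the analysis: raw presence points
are snapped to the predictor grid, records on land or duplicated within a
grid cell are dropped, the remainder is spatially thinned to a minimum
pairwise great-circle distance (20 km by default), calibration areas are
built as distance buffers around the retained presences intersected with
the domain mask, and pseudo-absences are drawn uniformly within them.
Predictors are min-max normalized to 0-1 over the largest calibration
area so that physical constraint constants (26 degC, 200 m, ...) and
future layers map through one shared affine transform.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import EnvStack, cross_distance_km, pairwise_distance_km

__all__ = ["OccurrenceSet", "CalibrationArea", "NormalizationTransform",
           "clean_records", "thin_records", "buffer_area",
           "draw_pseudo_absences", "normalize_predictors", "vif_check"]


@dataclass
class OccurrenceSet:
    """Point records (lon, lat, presence/pseudo_absence) snapped to a grid.

    ``table`` has columns lon, lat, label, row, col; row/col of -1 marks a
    record outside the grid (removed by cleaning).
    """

    table: pd.DataFrame
    meta: dict = field(default_factory=dict)

    REQUIRED = ("lon", "lat", "label", "row", "col")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"occurrence table missing columns {missing}")
        self.table = self.table.reset_index(drop=True)

    @classmethod
    def from_points(cls, lons, lats, grid, label="presence", meta=None):
        lons = np.atleast_1d(np.asarray(lons, dtype=float))
        lats = np.atleast_1d(np.asarray(lats, dtype=float))
        row, col = grid.snap(lons, lats)
        table = pd.DataFrame({"lon": lons, "lat": lats, "label": label,
                              "row": row, "col": col})
        return cls(table, meta or {})

    def __len__(self):
        return len(self.table)

    @property
    def presences(self):
        return self.table[self.table["label"] == "presence"]

    @property
    def pseudo_absences(self):
        return self.table[self.table["label"] == "pseudo_absence"]

    def concat(self, other):
        return OccurrenceSet(pd.concat([self.table, other.table],
                                       ignore_index=True),
                             {**self.meta, **other.meta})

    def to_csv(self, path):
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(path, index=False, float_format="%.10g")
        if self.meta:
            Path(str(path) + ".json").write_text(
                json.dumps(self.meta, indent=1, sort_keys=True, default=str))

    @classmethod
    def from_csv(cls, path, grid=None):
        table = pd.read_csv(path)
        if "row" not in table.columns:
            if grid is None:
                raise ValueError("need a grid to snap a bare lon/lat CSV")
            row, col = grid.snap(table["lon"].to_numpy(),
                                 table["lat"].to_numpy())
            table["row"], table["col"] = row, col
        if "label" not in table.columns:
            table["label"] = "presence"
        metafile = Path(str(path) + ".json")
        meta = json.loads(metafile.read_text()) if metafile.exists() else {}
        return cls(table, meta)


@dataclass
class CalibrationArea:
    """Boolean cell mask = buffer around presences (cell-center membership)
    intersected with the domain mask."""

    mask: np.ndarray
    buffer_radius_km: float
    n_presences: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_cells(self):
        return int(self.mask.sum())


def clean_records(raw: OccurrenceSet, env: EnvStack) -> OccurrenceSet:
    """Drop records on land (or off-grid) and keep one presence per cell.

    The first record in each occupied cell (input order) is retained; the
    counts of each removal class are reported in ``meta['cleaning_log']``.
    """
    if len(raw) == 0:
        raise ValueError("raw occurrence set is empty")
    t = raw.table.copy()
    n_in = len(t)
    on_grid = (t["row"] >= 0) & (t["col"] >= 0)
    at_sea = np.zeros(len(t), dtype=bool)
    at_sea[on_grid] = env.sea[t.loc[on_grid, "row"], t.loc[on_grid, "col"]]
    t = t[at_sea]
    n_land = n_in - len(t)
    t = t.drop_duplicates(subset=["row", "col"], keep="first")
    n_dup = n_in - n_land - len(t)
    if len(t) == 0:
        raise ValueError("all records were removed by cleaning")
    log = {"input": n_in, "removed_land_or_offgrid": int(n_land),
           "removed_duplicate_cell": int(n_dup), "retained": len(t)}
    return OccurrenceSet(t, {**raw.meta, "cleaning_log": log})


def thin_records(occ: OccurrenceSet, min_dist_km=20.0, n_rep=10,
                 seed=0) -> OccurrenceSet:
    """Randomized spatial thinning to a minimum pairwise distance.

    Repeats ``n_rep`` randomized runs of: while any pair is closer than
    ``min_dist_km``, remove one record chosen uniformly among those with
    the most too-close neighbours.  The run retaining the most records
    wins (ties broken by run order), reproducing the usual randomized
    max-retention thinning behaviour.
    """
    if min_dist_km <= 0:
        raise ValueError("min_dist_km must be > 0")
    t = occ.table
    n = len(t)
    if n <= 1:
        return OccurrenceSet(t.copy(), {**occ.meta,
                                        "thinning": {"min_dist_km": min_dist_km,
                                                     "retained": n}})
    D = pairwise_distance_km(t["lat"].to_numpy(), t["lon"].to_numpy())
    close = D < min_dist_km
    np.fill_diagonal(close, False)
    best = None
    for rep in range(n_rep):
        rng = np.random.default_rng([int(seed) % (2**31), rep])
        keep = np.ones(n, dtype=bool)
        counts = close.sum(axis=1).astype(int)
        while True:
            live = np.nonzero(keep)[0]
            c = counts[live]
            if c.max(initial=0) == 0:
                break
            cands = live[c == c.max()]
            drop = rng.choice(cands)
            keep[drop] = False
            counts[close[drop]] -= 1
        if best is None or keep.sum() > best.sum():
            best = keep.copy()
    out = t[best]
    return OccurrenceSet(out, {**occ.meta,
                               "thinning": {"min_dist_km": min_dist_km,
                                            "n_rep": n_rep, "seed": int(seed),
                                            "retained": int(best.sum())}})


def buffer_area(presences: OccurrenceSet, radius_km, domain_mask,
                grid=None, env: EnvStack = None) -> CalibrationArea:
    """Cells whose centers lie within ``radius_km`` (great-circle) of at
    least one presence, intersected with the domain mask."""
    if radius_km <= 0:
        raise ValueError("buffer radius must be > 0")
    pres = presences.presences
    if len(pres) == 0:
        raise ValueError("need at least one presence to buffer")
    if grid is None:
        grid = env.grid
    domain_mask = np.asarray(domain_mask, dtype=bool)
    lat2d, lon2d = grid.mesh()
    rows, cols = np.nonzero(domain_mask)
    d = cross_distance_km(lat2d[rows, cols], lon2d[rows, cols],
                          pres["lat"].to_numpy(), pres["lon"].to_numpy())
    within = d.min(axis=1) <= radius_km
    mask = np.zeros(grid.shape, dtype=bool)
    mask[rows[within], cols[within]] = True
    return CalibrationArea(mask, float(radius_km), len(pres),
                           {"seed": presences.meta.get("seed")})


def draw_pseudo_absences(area: CalibrationArea, n, seed, exclude: OccurrenceSet,
                         env: EnvStack = None) -> OccurrenceSet:
    """Uniform sample (without replacement) of ``n`` pseudo-absence cells
    from the calibration area, excluding presence cells and cells with any
    missing predictor value."""
    eligible = area.mask.copy()
    pres = exclude.presences
    eligible[pres["row"].to_numpy(), pres["col"].to_numpy()] = False
    if env is not None:
        complete = np.ones(eligible.shape, dtype=bool)
        for name in env.layer_names:
            complete &= np.isfinite(env.layer(name))
        eligible &= complete
    rows, cols = np.nonzero(eligible)
    if n > rows.size:
        raise ValueError(f"requested {n} pseudo-absences but only "
                         f"{rows.size} eligible cells")
    rng = np.random.default_rng(seed)
    pick = rng.choice(rows.size, size=n, replace=False)
    r, c = rows[pick], cols[pick]
    grid = env.grid if env is not None else None
    if grid is not None:
        lon, lat = grid.lons[c], grid.lats[r]
    else:
        lon = lat = np.full(n, np.nan)
    table = pd.DataFrame({"lon": lon, "lat": lat, "label": "pseudo_absence",
                          "row": r, "col": c})
    return OccurrenceSet(table, {"seed": int(seed),
                                 "buffer_radius_km": area.buffer_radius_km})


@dataclass
class NormalizationTransform:
    """Shared affine min-max transform: x_norm = (x - offset) / scale.

    Computed once over the largest calibration area and reused for every
    model variant, for constraint constants in physical units, and for
    future layers (values outside [0, 1] are deliberately not clipped).
    """

    offsets: dict
    scales: dict

    @property
    def layers(self):
        return list(self.offsets)

    def normalize_value(self, name, value):
        if name not in self.offsets:
            raise KeyError(f"no transform for layer {name!r}")
        return (np.asarray(value, dtype=float) - self.offsets[name]) / self.scales[name]

    def denormalize_value(self, name, value):
        return np.asarray(value, dtype=float) * self.scales[name] + self.offsets[name]

    def apply(self, env: EnvStack) -> EnvStack:
        """Normalized copy of a stack (layers without a transform pass
        through untouched; no clipping)."""
        out = env.copy()
        for name in env.layer_names:
            if name in self.offsets:
                out.layers[name] = self.normalize_value(name, env.layer(name))
                out.units[name] = "normalized"
        return out

    def to_json(self, path):
        Path(path).write_text(json.dumps(
            {"offsets": self.offsets, "scales": self.scales},
            indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path):
        d = json.loads(Path(path).read_text())
        return cls(d["offsets"], d["scales"])


def normalize_predictors(env: EnvStack, area: CalibrationArea):
    """Min-max normalize every predictor over the calibration-area cells.

    Returns (normalized stack over the full grid, NormalizationTransform).
    A constant layer (zero range over the area) is an error.
    """
    if area.n_cells == 0:
        raise ValueError("calibration area is empty")
    offsets, scales = {}, {}
    for name in env.layer_names:
        vals = env.layer(name)[area.mask]
        vals = vals[np.isfinite(vals)]
        lo, hi = float(vals.min()), float(vals.max())
        if hi - lo < 1e-12:
            raise ValueError(f"layer {name!r} is constant over the "
                             "calibration area; cannot normalize")
        offsets[name], scales[name] = lo, hi - lo
    transform = NormalizationTransform(offsets, scales)
    return transform.apply(env), transform


def vif_check(env: EnvStack, area: CalibrationArea, threshold=10.0):
    """Variance inflation factors over calibration-area cells.

    VIF_j = 1 / (1 - R^2_j) from an OLS (with intercept) of predictor j on
    all others; a perfectly collinear predictor reports infinity and
    fails.  Returns (DataFrame with vif and pass flags, overall pass bool).
    """
    import statsmodels.api as sm
    names = env.layer_names
    if len(names) < 2:
        raise ValueError("VIF needs at least two predictors")
    X, _ = env.sea_values(names, mask=area.mask)
    X = X[np.isfinite(X).all(axis=1)]
    if X.shape[0] <= len(names):
        raise ValueError("need more cells than predictors for VIF")
    rows = []
    for j, name in enumerate(names):
        others = np.delete(X, j, axis=1)
        fit = sm.OLS(X[:, j], sm.add_constant(others)).fit()
        r2 = min(fit.rsquared, 1.0)
        vif = np.inf if 1.0 - r2 < 1e-12 else 1.0 / (1.0 - r2)
        rows.append({"predictor": name, "vif": vif, "pass": vif < threshold})
    report = pd.DataFrame(rows).set_index("predictor")
    ok = bool(report["pass"].all())
    if not ok:
        warnings.warn("predictors with VIF >= %.3g: %s"
                      % (threshold, ", ".join(report.index[~report["pass"]])),
                      UserWarning)
    return report, ok
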