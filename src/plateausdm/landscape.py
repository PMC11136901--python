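"""Seeded synthetic coastal landscapes with known plateau ground truth.

The generator emulates the statistical structure a coastal SDM assumes:
a regular lon/lat grid split by a connected north-south coastline into
land (west) and sea (east); six predictor layers -- water depth, distance
to shore, annual mean benthic temperature, annual temperature range,
salinity and current velocity -- with a latitudinal thermal gradient and
offshore-deepening bathymetry; presence records sampled from a known
trapezoidal suitability surface (optionally with spatial sampling bias);
and a warmed "future" stack in which only the temperature layers change.

Default physical ranges mimic a temperate coastal study region
(temperature 2-28 degC, depth 0-3000 m, salinity 29-35) so that the sea
cucumber tolerance constants (optimum 15-18 degC, limit 26 degC, depth
optimum 0-40 m, limit 200 m) are meaningful on the synthetic landscape.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import expit, logit

from .grids import EnvStack, RasterGrid, cross_distance_km
from .model import PlateauParams, plateau_response

PREDICTORS = ["depth", "dist_shore", "temp_mean", "temp_range",
              "salinity", "velocity"]

#: nominal physical ranges used by the generator (and by the default
#: ground-truth normalization)
NOMINAL_RANGES = {
    "depth": (0.0, 3000.0),
    "dist_shore": (0.0, 800.0),
    "temp_mean": (2.0, 28.0),
    "temp_range": (2.0, 12.0),
    "salinity": (29.0, 35.0),
    "velocity": (0.0, 1.5),
}

UNITS = {"depth": "m", "dist_shore": "km", "temp_mean": "degC",
         "temp_range": "degC", "salinity": "psu", "velocity": "m/s"}


@dataclass
class LandscapeConfig:
    """Geometry and noise configuration for one synthetic landscape."""

    n_rows: int = 60
    n_cols: int = 80
    lat_range: tuple = (25.0, 45.0)
    lon_range: tuple = (115.0, 140.0)
    coast_complexity: float = 1.0
    coast_frac: float = 0.3          # mean coastline position across the grid
    shelf_south_km: float = 650.0    # bathymetric e-folding scale, south edge
    shelf_north_km: float = 250.0    # ... north edge (narrow northern shelf)
    noise_sd: dict = field(default_factory=lambda: {
        "temp_mean": 0.5, "depth": 100.0})
    smooth_sigma: float = 3.0        # cells; width of the smoothing kernel
    seed: int = 0

    def __post_init__(self):
        if self.n_rows < 10 or self.n_cols < 10:
            raise ValueError("n_rows and n_cols must be >= 10")
        if self.lat_range[0] >= self.lat_range[1]:
            raise ValueError("lat_range is degenerate")
        if self.lon_range[0] >= self.lon_range[1]:
            raise ValueError("lon_range is degenerate")
        if self.coast_complexity < 0:
            raise ValueError("coast_complexity must be >= 0")
        if any(v < 0 for v in self.noise_sd.values()):
            raise ValueError("noise SDs must be >= 0")

    def to_dict(self):
        return asdict(self)


def _smooth_unit_field(shape, rng, sigma):
    """Gaussian-kernel-smoothed white noise rescaled to [0, 1]."""
    f = gaussian_filter(rng.standard_normal(shape), sigma, mode="nearest")
    lo, hi = f.min(), f.max()
    if hi - lo < 1e-12:
        return np.full(shape, 0.5)
    return (f - lo) / (hi - lo)


def _smooth_noise(shape, rng, sigma):
    """Smoothed white noise standardized to zero mean, unit sd."""
    f = gaussian_filter(rng.standard_normal(shape), sigma, mode="nearest")
    sd = f.std()
    return (f - f.mean()) / sd if sd > 1e-12 else np.zeros(shape)


def make_domain(cfg: LandscapeConfig) -> EnvStack:
    """Generate the grid and sea/land mask.

    Land occupies the western side of a connected coastline whose
    east-west excursion is controlled by ``coast_complexity``
    (0 = straight north-south coastline).
    """
    grid = RasterGrid.regular(cfg.n_rows, cfg.n_cols, cfg.lat_range,
                              cfg.lon_range)
    rng = np.random.default_rng(cfg.seed)
    base = cfg.coast_frac * cfg.n_cols
    wiggle = cfg.coast_complexity * (cfg.n_cols / 10.0) * _smooth_noise(
        (cfg.n_rows,), rng, cfg.smooth_sigma)
    coast_col = base + wiggle
    cols = np.arange(cfg.n_cols)[None, :]
    sea = cols >= coast_col[:, None]
    if not sea.any():
        raise ValueError("degenerate grid: all land "
                         "(coast_frac/coast_complexity too large)")
    if sea.all():
        raise ValueError("degenerate grid: all sea "
                         "(coast_frac too small for this grid)")
    stack = EnvStack(grid, sea)
    stack.meta = {"landscape_config": cfg.to_dict()}
    return stack


def make_predictors(domain: EnvStack, cfg: LandscapeConfig) -> EnvStack:
    """Populate the six predictor layers on the sea cells of ``domain``."""
    env = domain.copy()
    grid = env.grid
    rng = np.random.default_rng(cfg.seed + 1)
    lat2d, lon2d = grid.mesh()
    sea = env.sea
    land = ~sea
    nsd = cfg.noise_sd

    # distance to shore: great-circle distance to the nearest land cell center
    dist = np.full(grid.shape, np.nan)
    d = cross_distance_km(lat2d[sea], lon2d[sea], lat2d[land], lon2d[land])
    dist[sea] = d.min(axis=1)
    env.add_layer("dist_shore", dist, UNITS["dist_shore"])

    # bathymetry deepens monotonically offshore: a gently sloping shelf
    # (a few tens of metres within the first cells off the coast) dropping
    # to abyssal depth a few hundred km out.  The shelf is broad in the
    # south and narrow in the north (as in temperate western-Pacific
    # margins) and varies smoothly in space, so depth is not a
    # deterministic function of distance to shore (keeps their
    # collinearity realistic, VIF < 10).
    depth_max = NOMINAL_RANGES["depth"][1]
    latfrac = (lat2d - cfg.lat_range[0]) / (cfg.lat_range[1] - cfg.lat_range[0])
    shelf_base = cfg.shelf_south_km + (cfg.shelf_north_km
                                       - cfg.shelf_south_km) * latfrac
    shelf = shelf_base * (0.7 + 0.6 * _smooth_unit_field(
        grid.shape, rng, 2.0 * cfg.smooth_sigma))
    depth = depth_max * np.minimum(1.0, (dist / shelf) ** 2)
    depth += nsd.get("depth", 0.0) * _smooth_noise(grid.shape, rng,
                                                   cfg.smooth_sigma)
    env.add_layer("depth", np.clip(depth, 0.0, None), UNITS["depth"])

    # mean temperature: linear latitudinal gradient, warm south -> cold north
    t_lo, t_hi = NOMINAL_RANGES["temp_mean"]
    frac = (lat2d - cfg.lat_range[0]) / (cfg.lat_range[1] - cfg.lat_range[0])
    temp = t_hi - (t_hi - t_lo) * frac
    temp += nsd.get("temp_mean", 0.0) * _smooth_noise(grid.shape, rng,
                                                      cfg.smooth_sigma)
    env.add_layer("temp_mean", temp, UNITS["temp_mean"])

    # annual temperature range: small over thermally stable warm southern
    # waters, rising to a broad plateau in the seasonally mixed north --
    # i.e. spatially confounded with mean temperature at the warm end, as
    # in real marginal seas
    lo, hi = NOMINAL_RANGES["temp_range"]
    saturating = np.clip((latfrac - 0.30) / 0.15, 0.0, 1.0)
    trange = lo + (hi - lo) * (0.7 * saturating
                               + 0.3 * _smooth_unit_field(grid.shape, rng,
                                                          cfg.smooth_sigma))
    env.add_layer("temp_range", trange, UNITS["temp_range"])

    # salinity and current velocity: smoothed random fields in bounds
    for name in ("salinity", "velocity"):
        lo, hi = NOMINAL_RANGES[name]
        field_ = lo + (hi - lo) * _smooth_unit_field(grid.shape, rng,
                                                     cfg.smooth_sigma)
        env.add_layer(name, field_, UNITS[name])
    return env


def make_landscape(cfg: LandscapeConfig) -> EnvStack:
    """Convenience: domain plus predictors in one call."""
    return make_predictors(make_domain(cfg), cfg)


def eez_mask(env: EnvStack, max_dist_km=370.0):
    """EEZ-analogue domain mask: sea cells within ``max_dist_km`` of shore
    (200 nautical miles by default)."""
    return env.sea & (np.nan_to_num(env.layer("dist_shore"), nan=np.inf)
                      <= max_dist_km)


# --------------------------------------------------------------------------
# ground truth
# --------------------------------------------------------------------------

@dataclass
class TrueResponse:
    """Known generating plateau response, on a fixed normalization.

    ``params`` maps predictor name -> (c1, c2, b1, b2) on the normalized
    scale implied by ``ranges`` (physical min/max per predictor); ``beta0``
    is the apex log-odds.
    """

    beta0: float
    params: dict
    ranges: dict = field(default_factory=lambda: dict(NOMINAL_RANGES))

    def __post_init__(self):
        for name, (c1, c2, b1, b2) in self.params.items():
            if c1 > c2:
                raise ValueError(f"{name}: c1 > c2 in true response")
            if b1 < 0 or b2 < 0:
                raise ValueError(f"{name}: negative slope in true response")

    @property
    def names(self):
        return list(self.params)

    def normalize(self, name, values):
        lo, hi = self.ranges[name]
        return (np.asarray(values, dtype=float) - lo) / (hi - lo)

    def as_plateau_params(self):
        arr = np.array([self.params[n] for n in self.names], dtype=float)
        return PlateauParams(self.beta0, arr[:, 0], arr[:, 1],
                             arr[:, 2], arr[:, 3])

    def to_json(self, path):
        Path(path).write_text(json.dumps(
            {"beta0": self.beta0,
             "params": {k: list(v) for k, v in self.params.items()},
             "ranges": {k: list(v) for k, v in self.ranges.items()}},
            indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path):
        d = json.loads(Path(path).read_text())
        return cls(d["beta0"], {k: tuple(v) for k, v in d["params"].items()},
                   {k: tuple(v) for k, v in d["ranges"].items()})


def default_true_response(beta0=2.5, absent_floor=0.01):
    """Ground truth consistent with the sea cucumber's tolerance table:
    optimal temperature band 15-18 degC declining to "effectively absent"
    at the 26 degC upper thermal limit (and below ~8 degC on the cold
    side), optimal depth 0-40 m vanishing at the 200 m limit, no effect of
    the other predictors."""
    ranges = dict(NOMINAL_RANGES)
    L = float(logit(absent_floor))

    def norm(name, v):
        lo, hi = ranges[name]
        return (v - lo) / (hi - lo)

    drop = beta0 - L  # log-odds drop from apex to "effectively absent"
    t1, t2 = norm("temp_mean", 15.0), norm("temp_mean", 18.0)
    params = {
        "depth": (0.0, norm("depth", 40.0), 0.0,
                  drop / (norm("depth", 200.0) - norm("depth", 40.0))),
        "dist_shore": (0.0, 1.0, 0.0, 0.0),
        "temp_mean": (t1, t2,
                      drop / (t1 - norm("temp_mean", 8.0)),
                      drop / (norm("temp_mean", 26.0) - t2)),
        "temp_range": (0.0, 1.0, 0.0, 0.0),
        "salinity": (0.0, 1.0, 0.0, 0.0),
        "velocity": (0.0, 1.0, 0.0, 0.0),
    }
    return TrueResponse(beta0, params, ranges)


def true_suitability(env: EnvStack, truth: TrueResponse):
    """Exact forward evaluation of the true response on every sea cell.

    Returns a 2-D probability map (NaN over land).
    """
    for name in truth.names:
        if name not in env.layers:
            raise KeyError(f"true response references layer {name!r} "
                           "missing from the stack")
    lp = np.full(env.grid.shape, truth.beta0)
    for name in truth.names:
        c1, c2, b1, b2 = truth.params[name]
        x = truth.normalize(name, env.layer(name))
        lp += plateau_response(x, c1, c2, b1, b2)
    out = expit(lp)
    out[~env.sea] = np.nan
    return out


# --------------------------------------------------------------------------
# sampling and futures
# --------------------------------------------------------------------------

def sample_occurrences(suit, env: EnvStack, n_target, bias_strength=0.0,
                       seed=0, region_mask=None):
    """Sample presence cells with probability proportional to suitability
    times a smooth spatial bias field (``bias_strength = 0`` is unbiased).

    At most one presence per cell.  ``region_mask`` optionally restricts
    the sampled region (e.g. to emulate geographically truncated surveys).
    Returns an :class:`~plateausdm.occurrences.OccurrenceSet`.  A uniformly
    zero suitability yields an empty set; a positive but insufficient
    number of candidate cells is an error reporting the achievable count.
    """
    import pandas as pd

    from .occurrences import OccurrenceSet
    if n_target < 1:
        raise ValueError("n_target must be >= 1")
    suit = np.asarray(suit, dtype=float)
    ok = env.sea & np.isfinite(suit)
    if region_mask is not None:
        ok &= np.asarray(region_mask, dtype=bool)
    rng = np.random.default_rng(seed)
    weights = np.where(ok, np.nan_to_num(suit, nan=0.0), 0.0)
    if bias_strength != 0.0:
        bias = _smooth_noise(env.grid.shape, rng, 3.0)
        weights = weights * np.exp(bias_strength * bias)
    rows, cols = np.nonzero(weights > 0)
    meta = {"seed": int(seed), "bias_strength": float(bias_strength)}
    empty = pd.DataFrame({"lon": [], "lat": [], "label": [],
                          "row": [], "col": []})
    if rows.size == 0:
        return OccurrenceSet(empty, meta)
    if rows.size < n_target:
        raise ValueError(f"cannot place {n_target} presences: only "
                         f"{rows.size} cells have positive sampling weight")
    w = weights[rows, cols]
    pick = rng.choice(rows.size, size=n_target, replace=False, p=w / w.sum())
    r, c = rows[pick], cols[pick]
    order = np.lexsort((c, r))
    r, c = r[order], c[order]
    table = pd.DataFrame({"lon": env.grid.lons[c], "lat": env.grid.lats[r],
                          "label": "presence", "row": r, "col": c})
    return OccurrenceSet(table, meta)


def make_future(env: EnvStack, delta_temp, delta_range=0.0, seed=0,
                warming_sd=0.3, smooth_sigma=4.0):
    """Warmed future stack: temperature layers shifted by spatially smooth
    fields with the requested mean deltas; all other layers (in particular
    depth and distance to shore) copied unchanged."""
    fut = env.copy()
    rng = np.random.default_rng(seed)
    for name, delta in (("temp_mean", delta_temp), ("temp_range", delta_range)):
        if delta == 0.0 and warming_sd == 0.0:
            continue
        fieldn = warming_sd * _smooth_noise(env.grid.shape, rng, smooth_sigma) \
            if warming_sd > 0 else 0.0
        shift = delta + fieldn
        fut.layers[name] = env.layer(name) + np.where(env.sea, shift, np.nan)
    fut.meta = dict(env.meta)
    fut.meta.update({"future": {"delta_temp": delta_temp,
                                "delta_range": delta_range, "seed": seed}})
    return fut
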