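"""Raster grids, great-circle geometry and plain-text raster IO.

All grids are regular in degrees (equidistant cylindrical / plate carrée),
row index 0 at the southern edge, with cell-center coordinates.  Distances
are great-circle (haversine) on a spherical Earth of radius 6371 km.
Rasters are written as ESRI ASCII grids (`.asc`, north-up on disk) with a
JSON sidecar describing layers and units, so stacks round-trip without any
binary formats.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

EARTH_RADIUS_KM = 6371.0
NODATA = -9999.0


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km between points given in decimal degrees.

    Inputs broadcast like numpy arrays.
    """
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(a)))


def cross_distance_km(lats_a, lons_a, lats_b, lons_b):
    """(len(a), len(b)) matrix of great-circle distances."""
    lats_a = np.asarray(lats_a, dtype=float)[:, None]
    lons_a = np.asarray(lons_a, dtype=float)[:, None]
    return haversine_km(lats_a, lons_a,
                        np.asarray(lats_b, dtype=float)[None, :],
                        np.asarray(lons_b, dtype=float)[None, :])


def pairwise_distance_km(lats, lons):
    return cross_distance_km(lats, lons, lats, lons)


@dataclass(frozen=True)
class RasterGrid:
    """Regular lon/lat grid; ``lats``/``lons`` are ascending cell centers."""

    lats: np.ndarray
    lons: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "lats", np.asarray(self.lats, dtype=float))
        object.__setattr__(self, "lons", np.asarray(self.lons, dtype=float))
        if self.lats.ndim != 1 or self.lons.ndim != 1:
            raise ValueError("grid axes must be 1-D")
        for name, ax in (("lats", self.lats), ("lons", self.lons)):
            if ax.size < 2 or np.any(np.diff(ax) <= 0):
                raise ValueError(f"{name} must be ascending with >= 2 values")

    @classmethod
    def regular(cls, n_rows, n_cols, lat_range, lon_range):
        lat0, lat1 = lat_range
        lon0, lon1 = lon_range
        dlat = (lat1 - lat0) / n_rows
        dlon = (lon1 - lon0) / n_cols
        lats = lat0 + dlat * (np.arange(n_rows) + 0.5)
        lons = lon0 + dlon * (np.arange(n_cols) + 0.5)
        return cls(lats, lons)

    @property
    def shape(self):
        return (self.lats.size, self.lons.size)

    @property
    def dlat(self):
        return float(self.lats[1] - self.lats[0])

    @property
    def dlon(self):
        return float(self.lons[1] - self.lons[0])

    def mesh(self):
        """(lat2d, lon2d) cell-center coordinate arrays."""
        return np.meshgrid(self.lats, self.lons, indexing="ij")

    def snap(self, lons, lats):
        """Map point coordinates to (row, col); -1 where outside the grid."""
        lons = np.atleast_1d(np.asarray(lons, dtype=float))
        lats = np.atleast_1d(np.asarray(lats, dtype=float))
        row = np.floor((lats - (self.lats[0] - self.dlat / 2)) / self.dlat).astype(int)
        col = np.floor((lons - (self.lons[0] - self.dlon / 2)) / self.dlon).astype(int)
        bad = (row < 0) | (row >= self.shape[0]) | (col < 0) | (col >= self.shape[1])
        row[bad] = -1
        col[bad] = -1
        return row, col

    def same_geometry(self, other, tol=1e-9):
        return (self.shape == other.shape
                and np.allclose(self.lats, other.lats, atol=tol)
                and np.allclose(self.lons, other.lons, atol=tol))

    def to_dict(self):
        return {
            "n_rows": self.shape[0], "n_cols": self.shape[1],
            "lat_min_edge": float(self.lats[0] - self.dlat / 2),
            "lon_min_edge": float(self.lons[0] - self.dlon / 2),
            "dlat": self.dlat, "dlon": self.dlon,
        }

    @classmethod
    def from_dict(cls, d):
        lats = d["lat_min_edge"] + d["dlat"] * (np.arange(d["n_rows"]) + 0.5)
        lons = d["lon_min_edge"] + d["dlon"] * (np.arange(d["n_cols"]) + 0.5)
        return cls(lats, lons)


def write_ascii_grid(path, grid: RasterGrid, values: np.ndarray, nodata=NODATA):
    """Write one layer as an ESRI ASCII grid (north-up; DX/DY header when
    cells are not square in degrees)."""
    arr = np.asarray(values, dtype=float)
    if arr.shape != grid.shape:
        raise ValueError("layer shape does not match grid")
    out = np.where(np.isnan(arr), nodata, arr)[::-1]  # row 0 = north on disk
    header = [f"NCOLS {grid.shape[1]}", f"NROWS {grid.shape[0]}",
              f"XLLCORNER {grid.lons[0] - grid.dlon / 2:.10g}",
              f"YLLCORNER {grid.lats[0] - grid.dlat / 2:.10g}"]
    if abs(grid.dlat - grid.dlon) < 1e-12:
        header.append(f"CELLSIZE {grid.dlon:.10g}")
    else:
        header.append(f"DX {grid.dlon:.10g}")
        header.append(f"DY {grid.dlat:.10g}")
    header.append(f"NODATA_VALUE {nodata:.10g}")
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        for row in out:
            fh.write(" ".join(f"{v:.8g}" for v in row) + "\n")


def read_ascii_grid(path):
    """Read an ESRI ASCII grid -> (RasterGrid, values with NaN nodata)."""
    with open(path) as fh:
        tokens = {}
        pos = fh.tell()
        rows = []
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0].isalpha() or parts[0].upper() in (
                    "NCOLS", "NROWS", "XLLCORNER", "YLLCORNER",
                    "CELLSIZE", "DX", "DY", "NODATA_VALUE"):
                tokens[parts[0].upper()] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    n_cols = int(tokens["NCOLS"])
    n_rows = int(tokens["NROWS"])
    dlon = tokens.get("DX", tokens.get("CELLSIZE"))
    dlat = tokens.get("DY", tokens.get("CELLSIZE"))
    nodata = tokens.get("NODATA_VALUE", NODATA)
    arr = np.array(rows, dtype=float)[::-1]  # back to south-up
    if arr.shape != (n_rows, n_cols):
        raise ValueError(f"grid body shape {arr.shape} != header ({n_rows},{n_cols})")
    arr[arr == nodata] = np.nan
    lats = tokens["YLLCORNER"] + dlat * (np.arange(n_rows) + 0.5)
    lons = tokens["XLLCORNER"] + dlon * (np.arange(n_cols) + 0.5)
    return RasterGrid(lats, lons), arr


@dataclass
class EnvStack:
    """Named, co-registered 2-D predictor layers with a sea/land mask.

    Layers are float arrays on ``grid`` with NaN over land (the no-data
    convention); ``sea`` is True for water cells.
    """

    grid: RasterGrid
    sea: np.ndarray
    layers: dict = field(default_factory=dict)
    units: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.sea = np.asarray(self.sea, dtype=bool)
        if self.sea.shape != self.grid.shape:
            raise ValueError("sea mask shape does not match grid")
        for name, arr in self.layers.items():
            self._check_layer(name, arr)

    def _check_layer(self, name, arr):
        arr = np.asarray(arr, dtype=float)
        if arr.shape != self.grid.shape:
            raise ValueError(f"layer {name!r} shape does not match grid")
        return arr

    def add_layer(self, name, values, units=""):
        arr = self._check_layer(name, values).copy()
        arr[~self.sea] = np.nan
        self.layers[name] = arr
        if units:
            self.units[name] = units

    def layer(self, name):
        if name not in self.layers:
            raise KeyError(f"layer {name!r} not in stack "
                           f"(have {sorted(self.layers)})")
        return self.layers[name]

    @property
    def layer_names(self):
        return list(self.layers)

    def copy(self):
        return EnvStack(self.grid, self.sea.copy(),
                        {k: v.copy() for k, v in self.layers.items()},
                        dict(self.units), dict(self.meta))

    def sea_values(self, names=None, mask=None):
        """Matrix of layer values over sea cells (or a boolean ``mask``)."""
        names = names or self.layer_names
        m = self.sea if mask is None else (np.asarray(mask, bool) & self.sea)
        return np.column_stack([self.layer(n)[m] for n in names]), m

    def values_at(self, rows, cols, names=None):
        names = names or self.layer_names
        return np.column_stack([self.layer(n)[rows, cols] for n in names])

    # ------------------------------------------------------------------ IO
    def write_dir(self, path):
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        write_ascii_grid(path / "sea_mask.asc", self.grid,
                         self.sea.astype(float))
        for name in self.layers:
            write_ascii_grid(path / f"{name}.asc", self.grid, self.layers[name])
        sidecar = {"grid": self.grid.to_dict(), "layers": self.layer_names,
                   "units": self.units, "meta": self.meta}
        (path / "stack.json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))

    @classmethod
    def read_dir(cls, path):
        path = Path(path)
        sidecar = json.loads((path / "stack.json").read_text())
        grid = RasterGrid.from_dict(sidecar["grid"])
        _, mask = read_ascii_grid(path / "sea_mask.asc")
        stack = cls(grid, mask > 0.5, units=sidecar.get("units", {}),
                    meta=sidecar.get("meta", {}))
        for name in sidecar["layers"]:
            _, arr = read_ascii_grid(path / f"{name}.asc")
            stack.layers[name] = arr
        return stack


def regrid_bilinear(src_grid: RasterGrid, values: np.ndarray, dst_grid: RasterGrid):
    """Bilinear interpolation between regular lon/lat grids.

    Each destination cell center is interpolated from the four enclosing
    source cell centers; a no-data (NaN) corner makes the result no-data,
    as do destination centers outside the source center envelope.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != src_grid.shape:
        raise ValueError("values shape does not match source grid")
    if (dst_grid.lats[-1] < src_grid.lats[0] or dst_grid.lats[0] > src_grid.lats[-1]
            or dst_grid.lons[-1] < src_grid.lons[0] or dst_grid.lons[0] > src_grid.lons[-1]):
        raise ValueError("source and target grids do not overlap")
    out = np.full(dst_grid.shape, np.nan)

    def locate(axis, targets):
        idx = np.searchsorted(axis, targets) - 1
        inside = (targets >= axis[0]) & (targets <= axis[-1])
        idx = np.clip(idx, 0, axis.size - 2)
        frac = (targets - axis[idx]) / (axis[idx + 1] - axis[idx])
        return idx, frac, inside

    ri, rf, rin = locate(src_grid.lats, dst_grid.lats)
    ci, cf, cin = locate(src_grid.lons, dst_grid.lons)
    RF = rf[:, None]
    CF = cf[None, :]
    v00 = values[np.ix_(ri, ci)]
    v01 = values[np.ix_(ri, ci + 1)]
    v10 = values[np.ix_(ri + 1, ci)]
    v11 = values[np.ix_(ri + 1, ci + 1)]
    interp = (v00 * (1 - RF) * (1 - CF) + v01 * (1 - RF) * CF
              + v10 * RF * (1 - CF) + v11 * RF * CF)
    ok = rin[:, None] & cin[None, :]
    out[ok] = interp[ok]
    return out
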