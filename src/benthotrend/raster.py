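"""Regular lat/lon seafloor-temperature grid.

Holds, per cell, the decadal mean seafloor temperature at the cell's mean
depth plus the temperatures at the cell's minimum and maximum depth (the
within-cell range drives one of the occurrence filters). Backed by an
xarray Dataset on cell-centre coordinates; serialized as NetCDF (classic
format via the scipy backend). Cells with no data (land) are NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr

VAR_MEAN = "t_mean_depth"
VAR_MIN = "t_at_min_depth"
VAR_MAX = "t_at_max_depth"


@dataclass
class TemperatureRaster:
    data: xr.Dataset

    @classmethod
    def from_arrays(
        cls,
        lat_centers: np.ndarray,
        lon_centers: np.ndarray,
        t_mean: np.ndarray,
        t_at_min_depth: np.ndarray,
        t_at_max_depth: np.ndarray,
        cell_deg: float,
    ) -> "TemperatureRaster":
        if cell_deg <= 0:
            raise ValueError("raster cell size must be positive")
        ds = xr.Dataset(
            {
                VAR_MEAN: (("lat", "lon"), np.asarray(t_mean, dtype=float)),
                VAR_MIN: (("lat", "lon"), np.asarray(t_at_min_depth, dtype=float)),
                VAR_MAX: (("lat", "lon"), np.asarray(t_at_max_depth, dtype=float)),
            },
            coords={"lat": np.asarray(lat_centers, float), "lon": np.asarray(lon_centers, float)},
            attrs={"cell_deg": float(cell_deg)},
        )
        return cls(ds)

    @property
    def cell_deg(self) -> float:
        return float(self.data.attrs["cell_deg"])

    def _index(self, lats, lons) -> tuple[np.ndarray, np.ndarray]:
        """Row/col cell indices for points; -1 where outside the grid."""
        lats = np.asarray(lats, dtype=float)
        lons = np.asarray(lons, dtype=float)
        lat_c = self.data["lat"].to_numpy()
        lon_c = self.data["lon"].to_numpy()
        half = self.cell_deg / 2.0
        rows = np.searchsorted(lat_c + half, lats, side="left")
        cols = np.searchsorted(lon_c + half, lons, side="left")
        rows_ok = (rows < lat_c.size) & (np.abs(lats - lat_c[np.clip(rows, 0, lat_c.size - 1)]) <= half)
        cols_ok = (cols < lon_c.size) & (np.abs(lons - lon_c[np.clip(cols, 0, lon_c.size - 1)]) <= half)
        ok = rows_ok & cols_ok
        return np.where(ok, rows, -1), np.where(ok, cols, -1)

    def lookup(self, lats, lons, var: str = VAR_MEAN) -> np.ndarray:
        """Cell values at point coordinates; NaN outside the grid."""
        rows, cols = self._index(lats, lons)
        arr = self.data[var].to_numpy()
        out = np.full(rows.shape, np.nan)
        inside = rows >= 0
        out[inside] = arr[rows[inside], cols[inside]]
        return out

    def cell_temperature_range(self, lats, lons) -> np.ndarray:
        """|T(min depth) - T(max depth)| of the cell under each point."""
        return np.abs(
            self.lookup(lats, lons, VAR_MIN) - self.lookup(lats, lons, VAR_MAX)
        )

    def to_netcdf(self, path) -> None:
        self.data.to_netcdf(path, engine="scipy")

    @classmethod
    def open(cls, path) -> "TemperatureRaster":
        ds = xr.open_dataset(path, engine="scipy").load()
        missing = [v for v in (VAR_MEAN, VAR_MIN, VAR_MAX) if v not in ds]
        if missing:
            raise ValueError(f"raster file missing variables: {missing}")
        if "cell_deg" not in ds.attrs:
            lat = ds["lat"].to_numpy()
            ds.attrs["cell_deg"] = float(np.diff(lat).mean())
        return cls(ds)
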