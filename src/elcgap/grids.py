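"""Regular lat/lon raster grids and environmental raster stacks.

A grid is a regular WGS84 lat/lon lattice. Cells are half-open intervals
``[west, east) x [south, north)`` measured from the grid origin, so every
point inside the extent belongs to exactly one cell. Nodata cells (the "sea")
are represented as NaN in memory and as a nodata value on disk.

Rasters are stored on disk as single-band ESRI ASCII grids (a plain-text
format readable by any GIS), one file per variable, plus a CSV manifest that
records each variable's ecogeographical component.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

COMPONENTS = ("bioclimatic", "edaphic", "geophysic")

#: Conventional names for the coordinate layers appended to the geophysic set.
LATITUDE_VAR = "latitude"
LONGITUDE_VAR = "longitude"

ASCII_NODATA = -9999.0


@dataclass(frozen=True)
class GridGeometry:
    """Geometry of a regular lat/lon raster: origin, cell size and shape."""

    west: float
    north: float
    cell_size: float
    n_rows: int
    n_cols: int

    @property
    def south(self) -> float:
        return self.north - self.n_rows * self.cell_size

    @property
    def east(self) -> float:
        return self.west + self.n_cols * self.cell_size

    def cell_index(self, lat: float, lon: float) -> tuple[int, int] | None:
        """Row/col of the cell containing (lat, lon), or None if outside.

        Cells are half-open: a point on the shared edge of two cells belongs
        to the cell whose [west, east) x [south, north) interval contains it.
        """
        col = math.floor((lon - self.west) / self.cell_size)
        row_from_south = math.floor((lat - self.south) / self.cell_size)
        row = self.n_rows - 1 - row_from_south
        if 0 <= row < self.n_rows and 0 <= col < self.n_cols:
            return row, col
        return None

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(lat, lon) of the center of cell (row, col)."""
        lat = self.north - (row + 0.5) * self.cell_size
        lon = self.west + (col + 0.5) * self.cell_size
        return lat, lon

    def center_grids(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-cell center latitude and longitude arrays (n_rows x n_cols)."""
        lats = self.north - (np.arange(self.n_rows) + 0.5) * self.cell_size
        lons = self.west + (np.arange(self.n_cols) + 0.5) * self.cell_size
        lat_grid, lon_grid = np.meshgrid(lats, lons, indexing="ij")
        return lat_grid, lon_grid


@dataclass
class EcoRasterStack:
    """A set of gridded environmental variables sharing one grid geometry.

    Each layer is a float array with NaN on nodata cells; ``components`` tags
    every variable as bioclimatic, edaphic or geophysic.
    """

    geometry: GridGeometry
    layers: dict[str, np.ndarray] = field(default_factory=dict)
    components: dict[str, str] = field(default_factory=dict)

    def add_layer(self, name: str, data: np.ndarray, component: str) -> None:
        if component not in COMPONENTS:
            raise ValueError(f"unknown component {component!r}")
        if data.shape != (self.geometry.n_rows, self.geometry.n_cols):
            raise ValueError(f"layer {name!r} shape {data.shape} does not match grid")
        self.layers[name] = np.asarray(data, dtype=float)
        self.components[name] = component

    def variables(self, component: str | None = None) -> list[str]:
        if component is None:
            return list(self.layers)
        return [v for v, c in self.components.items() if c == component]

    @property
    def land_mask(self) -> np.ndarray:
        """Cells where every layer has data."""
        mask = np.ones((self.geometry.n_rows, self.geometry.n_cols), dtype=bool)
        for arr in self.layers.values():
            mask &= ~np.isnan(arr)
        return mask

    def coordinate_layer(self, name: str) -> np.ndarray:
        """Latitude or longitude of cell centers, masked to land cells."""
        lat_grid, lon_grid = self.geometry.center_grids()
        arr = lat_grid if name == LATITUDE_VAR else lon_grid
        out = arr.astype(float).copy()
        out[~self.land_mask] = np.nan
        return out

    def get_layer(self, name: str) -> np.ndarray:
        """A named layer, resolving the synthetic latitude/longitude layers."""
        if name in self.layers:
            return self.layers[name]
        if name in (LATITUDE_VAR, LONGITUDE_VAR):
            return self.coordinate_layer(name)
        raise KeyError(name)


def write_ascii_grid(path: str | Path, geometry: GridGeometry, data: np.ndarray,
                     nodata: float = ASCII_NODATA) -> None:
    """Write one layer as an ESRI ASCII grid (rows north to south)."""
    out = np.asarray(data, dtype=float).copy()
    out[np.isnan(out)] = nodata
    header = (
        f"ncols {geometry.n_cols}\n"
        f"nrows {geometry.n_rows}\n"
        f"xllcorner {geometry.west!r}\n"
        f"yllcorner {geometry.south!r}\n"
        f"cellsize {geometry.cell_size!r}\n"
        f"NODATA_value {nodata!r}\n"
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header)
        for row in out:
            fh.write(" ".join(repr(float(v)) for v in row))
            fh.write("\n")


def read_ascii_grid(path: str | Path) -> tuple[GridGeometry, np.ndarray]:
    """Read an ESRI ASCII grid; nodata cells become NaN."""
    with open(path, encoding="utf-8") as fh:
        header: dict[str, float] = {}
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        data = np.loadtxt(fh)
    n_rows = int(header["nrows"])
    n_cols = int(header["ncols"])
    data = data.reshape(n_rows, n_cols)
    nodata = header.get("nodata_value", ASCII_NODATA)
    data[data == nodata] = np.nan
    geometry = GridGeometry(
        west=header["xllcorner"],
        north=header["yllcorner"] + n_rows * header["cellsize"],
        cell_size=header["cellsize"],
        n_rows=n_rows,
        n_cols=n_cols,
    )
    return geometry, data


def write_stack(stack: EcoRasterStack, directory: str | Path) -> Path:
    """Write every layer of a stack as ASCII grids plus a manifest CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for name, arr in stack.layers.items():
        fname = f"{name}.asc"
        write_ascii_grid(directory / fname, stack.geometry, arr)
        rows.append({"variable": name, "component": stack.components[name], "file": fname})
    manifest = directory / "layers.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_stack(directory: str | Path) -> EcoRasterStack:
    """Read a stack previously written by :func:`write_stack`."""
    directory = Path(directory)
    manifest = pd.read_csv(directory / "layers.csv")
    stack: EcoRasterStack | None = None
    for row in manifest.itertuples():
        geometry, data = read_ascii_grid(directory / row.file)
        if stack is None:
            stack = EcoRasterStack(geometry=geometry)
        stack.add_layer(row.variable, data, row.component)
    if stack is None:
        raise ValueError(f"empty layer manifest in {directory}")
    return stack
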