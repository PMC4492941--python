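"""Core spatial containers: grids, raster stacks and occurrence matrices.

Rasters are plain ``numpy`` arrays on a regular WGS84 lon/lat grid with
cell-center registration and row 0 at the northern edge (north-up).
Missing cells (land, for marine layers) are ``NaN``.  Raster I/O uses the
ESRI ASCII grid format (plain text, one ``cellsize``), which requires
square cells in degrees.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GridSpec",
    "PredictorStack",
    "OccurrenceMatrix",
    "PREDICTOR_NAMES",
    "read_ascii_grid",
    "write_ascii_grid",
]

#: canonical order of the nine environmental predictor layers
PREDICTOR_NAMES = (
    "sst_mean",
    "sst_range",
    "sss_mean",
    "sss_range",
    "bathymetry",
    "slope",
    "eastness",
    "northness",
    "dist_shore",
)


@dataclass(frozen=True)
class GridSpec:
    """Regular lon/lat grid, cell-center registration, row 0 northernmost.

    ``lon_min``/``lon_max``/``lat_min``/``lat_max`` are the *outer edges*
    of the grid; cell centers sit half a cell inside them.
    """

    n_rows: int
    n_cols: int
    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float

    def __post_init__(self) -> None:
        if self.n_rows < 2 or self.n_cols < 2:
            raise ValueError("grid must have at least 2 rows and 2 columns")
        if not (self.lon_max > self.lon_min and self.lat_max > self.lat_min):
            raise ValueError("grid bounds must satisfy lon_max > lon_min and lat_max > lat_min")

    @property
    def dlon(self) -> float:
        return (self.lon_max - self.lon_min) / self.n_cols

    @property
    def dlat(self) -> float:
        return (self.lat_max - self.lat_min) / self.n_rows

    @property
    def lon_centers(self) -> np.ndarray:
        """Cell-center longitudes, west to east (length n_cols)."""
        return self.lon_min + (np.arange(self.n_cols) + 0.5) * self.dlon

    @property
    def lat_centers(self) -> np.ndarray:
        """Cell-center latitudes, north to south (length n_rows, row order)."""
        return self.lat_max - (np.arange(self.n_rows) + 0.5) * self.dlat

    def cell_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) 2-D arrays of every cell center, shape (n_rows, n_cols)."""
        lon, lat = np.meshgrid(self.lon_centers, self.lat_centers)
        return lon, lat

    def nearest_cell(self, lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of the cell whose center is nearest to each point.

        Points must lie within the grid's outer bounds.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        if np.any((lon < self.lon_min) | (lon > self.lon_max)):
            raise ValueError("longitude outside grid bounds")
        if np.any((lat < self.lat_min) | (lat > self.lat_max)):
            raise ValueError("latitude outside grid bounds")
        col = np.clip(((lon - self.lon_min) / self.dlon).astype(int), 0, self.n_cols - 1)
        row = np.clip(((self.lat_max - lat) / self.dlat).astype(int), 0, self.n_rows - 1)
        return row, col


@dataclass
class PredictorStack:
    """Co-registered named raster layers sharing one grid and one sea mask."""

    grid: GridSpec
    layers: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        shape = (self.grid.n_rows, self.grid.n_cols)
        masks = []
        for name, arr in self.layers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != shape:
                raise ValueError(f"layer {name!r} has shape {arr.shape}, expected {shape}")
            self.layers[name] = arr
            masks.append(np.isfinite(arr))
        if masks:
            first = masks[0]
            for name, m in zip(list(self.layers)[1:], masks[1:]):
                if not np.array_equal(first, m):
                    raise ValueError(f"layer {name!r} does not share the stack's missing-value mask")

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def sea_mask(self) -> np.ndarray:
        """Boolean mask of valid (sea) cells."""
        if not self.layers:
            return np.ones((self.grid.n_rows, self.grid.n_cols), dtype=bool)
        return np.isfinite(next(iter(self.layers.values())))

    def __getitem__(self, name: str) -> np.ndarray:
        return self.layers[name]

    def cell_table(self) -> pd.DataFrame:
        """One row per sea cell: row, col, lon, lat and every layer value."""
        lon, lat = self.grid.cell_coords()
        mask = self.sea_mask
        rows, cols = np.nonzero(mask)
        data = {
            "row": rows,
            "col": cols,
            "lon": lon[mask],
            "lat": lat[mask],
        }
        for name, arr in self.layers.items():
            data[name] = arr[mask]
        return pd.DataFrame(data)


@dataclass
class OccurrenceMatrix:
    """Binary site-by-species table with site coordinates attached."""

    site_id: np.ndarray          # (n_sites,) str or int labels
    lon: np.ndarray              # (n_sites,) degrees
    lat: np.ndarray              # (n_sites,) degrees
    species: list[str]           # (n_species,) column names
    values: np.ndarray = field(repr=False)  # (n_sites, n_species) strictly 0/1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("occurrence values must be strictly 0/1")
        self.values = self.values.astype(np.uint8)
        n = len(self.site_id)
        if not (len(self.lon) == len(self.lat) == n == self.values.shape[0]):
            raise ValueError("site_id, lon, lat and value rows must align")
        if self.values.shape[1] != len(self.species):
            raise ValueError("species names must match value columns")

    @property
    def n_sites(self) -> int:
        return self.values.shape[0]

    @property
    def n_species(self) -> int:
        return self.values.shape[1]

    def prevalence(self) -> np.ndarray:
        """Fraction of sites occupied, per species."""
        return self.values.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.species)
        df.insert(0, "lat", self.lat)
        df.insert(0, "lon", self.lon)
        df.insert(0, "site_id", self.site_id)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "OccurrenceMatrix":
        df = pd.read_csv(path)
        required = ["site_id", "lon", "lat"]
        for col in required:
            if col not in df.columns:
                raise ValueError(f"occurrence CSV missing required column {col!r}")
        species = [c for c in df.columns if c not in required]
        vals = df[species].to_numpy()
        bad = ~np.isin(vals, (0, 1))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"non-binary occurrence value {vals[r, c]!r} at row {r} "
                f"(species {species[c]!r})"
            )
        return cls(
            site_id=df["site_id"].to_numpy(),
            lon=df["lon"].to_numpy(dtype=float),
            lat=df["lat"].to_numpy(dtype=float),
            species=species,
            values=vals,
        )


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O (plain-text raster format)

_NODATA = -9999.0


def write_ascii_grid(path, grid: GridSpec, array: np.ndarray, nodata: float = _NODATA) -> None:
    """Write one raster layer as an ESRI ASCII grid (.asc).

    The format carries a single ``cellsize``, so the grid must have (near)
    square cells in degrees.
    """
    if abs(grid.dlon - grid.dlat) > 1e-9 * max(grid.dlon, grid.dlat):
        raise ValueError("ESRI ASCII grid requires square cells (dlon == dlat)")
    array = np.asarray(array, dtype=float)
    if array.shape != (grid.n_rows, grid.n_cols):
        raise ValueError("array shape does not match grid")
    out = np.where(np.isfinite(array), array, nodata)
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.lon_min!r}\n"
        f"yllcorner {grid.lat_min!r}\n"
        f"cellsize {grid.dlon!r}\n"
        f"NODATA_value {nodata!r}\n"
    )
    buf = io.StringIO()
    np.savetxt(buf, out, fmt="%.10g")
    with open(path, "w") as fh:
        fh.write(header)
        fh.write(buf.getvalue())


def read_ascii_grid(path) -> tuple[GridSpec, np.ndarray]:
    """Read an ESRI ASCII grid; nodata cells come back as NaN."""
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        m = re.match(r"^\s*([A-Za-z_]+)\s+(\S+)\s*$", line)
        if m and m.group(1).lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        ):
            header[m.group(1).lower()] = float(m.group(2))
            n_header += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"ASCII grid missing header field {key!r}")
    n_cols = int(header["ncols"])
    n_rows = int(header["nrows"])
    cs = header["cellsize"]
    arr = np.loadtxt(io.StringIO("".join(lines[n_header:]))).reshape(n_rows, n_cols)
    nodata = header.get("nodata_value", _NODATA)
    arr = np.where(arr == nodata, np.nan, arr)
    grid = GridSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        lon_min=header["xllcorner"],
        lon_max=header["xllcorner"] + n_cols * cs,
        lat_min=header["yllcorner"],
        lat_max=header["yllcorner"] + n_rows * cs,
    )
    return grid, arr
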