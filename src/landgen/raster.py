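"""ESRI ASCII grid rasters and terrain derivatives.

Rasters carry the landscape variables (elevation, aspect, slope,
topographic complexity, vegetation, rivers, roads, disturbance), the
resistance surfaces built from them, and circuit current maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "Raster",
    "read_ascii_grid",
    "write_ascii_grid",
    "derive_terrain",
]

log = logging.getLogger(__name__)

DEFAULT_NODATA = -9999.0


@dataclass
class Raster:
    """A rectangular grid with lower-left origin and square cells.

    ``values`` is an (nrows, ncols) float array in map orientation: row 0
    is the *top* (northernmost) row, as in the ESRI ASCII dialect.
    """

    values: np.ndarray
    xll: float = 0.0
    yll: float = 0.0
    cellsize: float = 1.0
    nodata: float = DEFAULT_NODATA

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be > 0")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    def valid(self) -> np.ndarray:
        """Boolean mask of non-nodata, finite cells."""
        return np.isfinite(self.values) & (self.values != self.nodata)

    def like(self, values: np.ndarray, nodata: float | None = None) -> "Raster":
        """A new raster on this grid with the given values."""
        return Raster(values, self.xll, self.yll, self.cellsize,
                      self.nodata if nodata is None else nodata)

    def aligned_with(self, other: "Raster") -> bool:
        return (
            self.values.shape == other.values.shape
            and abs(self.xll - other.xll) < 1e-6
            and abs(self.yll - other.yll) < 1e-6
            and abs(self.cellsize - other.cellsize) < 1e-9
        )

    # ------------------------------------------------------------------
    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the cell containing map point (x, y)."""
        col = int(np.floor((x - self.xll) / self.cellsize))
        row = self.nrows - 1 - int(np.floor((y - self.yll) / self.cellsize))
        if not (0 <= row < self.nrows and 0 <= col < self.ncols):
            raise ValueError(f"point ({x}, {y}) outside raster extent")
        return row, col

    def center_of(self, row: int, col: int) -> tuple[float, float]:
        """Map coordinates of a cell centre."""
        x = self.xll + (col + 0.5) * self.cellsize
        y = self.yll + (self.nrows - 1 - row + 0.5) * self.cellsize
        return x, y


def check_aligned(*rasters: Raster) -> None:
    for r in rasters[1:]:
        if not rasters[0].aligned_with(r):
            raise ValueError("rasters are not aligned (shape/origin/cellsize differ)")


# ----------------------------------------------------------------------
def read_ascii_grid(path) -> Raster:
    """Read an ESRI ASCII grid (.asc)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            pos = fh.tell()
            line = fh.readline()
            if not line:
                raise ValueError("empty or truncated ASCII grid")
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "xllcenter",
                "yllcenter", "cellsize", "nodata_value",
            ):
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        data = np.loadtxt(fh, dtype=float, ndmin=2)

    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"ASCII grid header missing {key}")
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if data.shape != (nrows, ncols):
        raise ValueError(
            f"grid body shape {data.shape} does not match header ({nrows}, {ncols})"
        )
    if "nodata_value" not in header:
        log.warning("NODATA_value missing; defaulting to %s", DEFAULT_NODATA)
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    cellsize = header["cellsize"]
    xll = header.get("xllcorner", header.get("xllcenter", 0.0) - cellsize / 2)
    yll = header.get("yllcorner", header.get("yllcenter", 0.0) - cellsize / 2)
    return Raster(data, xll, yll, cellsize, nodata)


def write_ascii_grid(raster: Raster, path, fmt: str = "%.8g") -> None:
    """Write an ESRI ASCII grid; round-trips losslessly at ``fmt`` precision."""
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.ncols}\n")
        fh.write(f"nrows {raster.nrows}\n")
        fh.write(f"xllcorner {raster.xll:.8g}\n")
        fh.write(f"yllcorner {raster.yll:.8g}\n")
        fh.write(f"cellsize {raster.cellsize:.8g}\n")
        fh.write(f"NODATA_value {raster.nodata:.8g}\n")
        np.savetxt(fh, raster.values, fmt=fmt)


# ----------------------------------------------------------------------
def _horn_gradients(dem: Raster) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Horn third-order finite differences on the 3x3 neighbourhood.

    Returns (dz/dx eastward, dz/dy northward, valid-mask). Edge cells use
    the available neighbours via edge replication; cells whose 3x3
    neighbourhood touches nodata are invalid.
    """
    v = dem.valid()
    z = np.where(v, dem.values, np.nan)
    zp = np.pad(z, 1, mode="edge")
    a = zp[:-2, :-2]; b = zp[:-2, 1:-1]; c = zp[:-2, 2:]
    d = zp[1:-1, :-2];                   f = zp[1:-1, 2:]
    g = zp[2:, :-2];  h = zp[2:, 1:-1];  i = zp[2:, 2:]
    cs = dem.cellsize
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * cs)
    # row index grows southward, so the northward derivative flips sign
    dzdy = ((a + 2 * b + c) - (g + 2 * h + i)) / (8 * cs)
    ok = np.isfinite(dzdx) & np.isfinite(dzdy)
    return dzdx, dzdy, ok


def derive_terrain(dem: Raster, tc_window: int = 3) -> dict[str, Raster]:
    """Slope, aspect and topographic complexity from a DEM.

    slope
        Degrees, from the Horn gradient magnitude.
    aspect
        Compass bearing (degrees, 0 = north, clockwise) of the steepest
        *ascent* direction; flat cells (zero gradient) are nodata.
    tc
        Topographic complexity: standard deviation of elevation within the
        ``tc_window`` x ``tc_window`` neighbourhood (edge cells use the
        available in-grid neighbours).
    """
    if tc_window < 1 or tc_window % 2 == 0:
        raise ValueError("tc_window must be a positive odd integer")
    v = dem.valid()
    if v.sum() < 9:
        raise ValueError("DEM needs at least a 3x3 block of valid cells")

    dzdx, dzdy, ok = _horn_gradients(dem)
    nod = dem.nodata

    grad = np.hypot(dzdx, dzdy)
    slope = np.degrees(np.arctan(grad))
    slope = np.where(ok & v, slope, nod)

    flat = grad == 0
    aspect = np.degrees(np.arctan2(dzdx, dzdy)) % 360.0
    aspect = np.where(ok & v & ~flat, aspect, nod)

    # windowed SD over available (valid, in-grid) cells
    z = np.where(v, dem.values, 0.0)
    w = float(tc_window)
    boxsum = lambda x: ndimage.uniform_filter(x, size=tc_window, mode="constant") * w * w
    cnt = np.round(boxsum(v.astype(float)))  # integer counts, de-noised
    s1 = boxsum(z)
    s2 = boxsum(z * z)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = s1 / cnt
        var = s2 / cnt - mean * mean
    tc = np.sqrt(np.clip(var, 0.0, None))
    tc = np.where(v & (cnt > 0), tc, nod)

    mk = lambda x: dem.like(x, nodata=nod)
    return {"slope": mk(slope), "aspect": mk(aspect), "tc": mk(tc)}
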