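"""Minimal ESRI ASCII grid (.asc) reader/writer.

The format is a six-line text header (ncols, nrows, xllcorner, yllcorner,
cellsize, NODATA_value) followed by rows of values, northernmost row first.
Arrays here follow the same convention: ``data[0]`` is the top (north) row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AsciiGrid", "read_ascii_grid", "write_ascii_grid"]


@dataclass
class AsciiGrid:
    data: np.ndarray  # 2D, row 0 = north
    xllcorner: float
    yllcorner: float
    cellsize: float
    nodata: float = -9999.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("AsciiGrid data must be 2D")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    @property
    def nrows(self) -> int:
        return self.data.shape[0]

    @property
    def ncols(self) -> int:
        return self.data.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(lon_min, lat_min, lon_max, lat_max)."""
        return (
            self.xllcorner,
            self.yllcorner,
            self.xllcorner + self.ncols * self.cellsize,
            self.yllcorner + self.nrows * self.cellsize,
        )

    def aligned_with(self, other: "AsciiGrid", tol: float = 1e-9) -> bool:
        return (
            self.data.shape == other.data.shape
            and abs(self.xllcorner - other.xllcorner) <= tol
            and abs(self.yllcorner - other.yllcorner) <= tol
            and abs(self.cellsize - other.cellsize) <= tol
        )

    def like(self, data: np.ndarray) -> "AsciiGrid":
        """A new grid with the same geotransform and different data."""
        if data.shape != self.data.shape:
            raise ValueError("shape mismatch")
        return AsciiGrid(data, self.xllcorner, self.yllcorner, self.cellsize, self.nodata)


def read_ascii_grid(path) -> AsciiGrid:
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            parts = line.split()
            if len(parts) != 2 or not parts[0].replace("_", "").isalpha():
                break
            header[parts[0].lower()] = float(parts[1])
            pos = fh.tell()
        fh.seek(0)
        for _ in range(len(header)):
            fh.readline()
        data = np.loadtxt(fh, dtype=float, ndmin=2)
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"missing header field {key!r} in {path}")
    if data.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(
            f"data shape {data.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])}) in {path}"
        )
    return AsciiGrid(
        data,
        header["xllcorner"],
        header["yllcorner"],
        header["cellsize"],
        header.get("nodata_value", -9999.0),
    )


def write_ascii_grid(grid: AsciiGrid, path, fmt: str = "%.6g") -> None:
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {grid.xllcorner:.10g}\n")
        fh.write(f"yllcorner {grid.yllcorner:.10g}\n")
        fh.write(f"cellsize {grid.cellsize:.10g}\n")
        fh.write(f"NODATA_value {grid.nodata:.10g}\n")
        np.savetxt(fh, grid.data, fmt=fmt)
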