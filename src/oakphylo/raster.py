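"""Minimal georeferenced float grid with ESRI ASCII I/O.

Row 0 is the north edge; indices are 0-based; cell centers carry the
values.  This is deliberately lightweight: the connectivity stage only
needs aligned grids, a cell size, and a nodata sentinel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Raster", "read_ascii_grid", "write_ascii_grid"]


@dataclass
class Raster:
    values: np.ndarray  # (rows, cols) float
    cell_size: float = 1.0
    x_origin: float = 0.0  # west edge
    y_origin: float = 0.0  # south edge
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or 0 in self.values.shape:
            raise ValueError("raster values must be a non-empty 2-D array")
        finite = np.isfinite(self.values) | (self.values == self.nodata)
        if not finite.all():
            raise ValueError("raster values must be finite or nodata")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def mask(self) -> np.ndarray:
        """True where the cell holds data."""
        return self.values != self.nodata

    def masked(self) -> np.ndarray:
        """Values with nodata replaced by NaN."""
        out = self.values.copy()
        out[~self.mask()] = np.nan
        return out

    def aligned_with(self, other: "Raster") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.isclose(self.x_origin, other.x_origin)
            and np.isclose(self.y_origin, other.y_origin)
        )

    def like(self, values: np.ndarray) -> "Raster":
        return Raster(values, self.cell_size, self.x_origin, self.y_origin, self.nodata)

    def cell_area(self) -> float:
        """Area of one cell in km^2 when cell_size is in km (or km-equivalents)."""
        return self.cell_size**2


def read_ascii_grid(path: str) -> Raster:
    """Read an ESRI ASCII grid (.asc)."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
            ):
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(x) for x in parts])
    values = np.array(rows)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError("ASCII grid body does not match header dimensions")
    return Raster(
        values,
        cell_size=header.get("cellsize", 1.0),
        x_origin=header.get("xllcorner", 0.0),
        y_origin=header.get("yllcorner", 0.0),
        nodata=header.get("nodata_value", -9999.0),
    )


def write_ascii_grid(raster: Raster, path: str) -> None:
    rows, cols = raster.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {cols}\n")
        fh.write(f"nrows {rows}\n")
        fh.write(f"xllcorner {raster.x_origin}\n")
        fh.write(f"yllcorner {raster.y_origin}\n")
        fh.write(f"cellsize {raster.cell_size}\n")
        fh.write(f"NODATA_value {raster.nodata}\n")
        for r in range(rows):
            fh.write(" ".join(f"{v:.6g}" for v in raster.values[r]) + "\n")
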