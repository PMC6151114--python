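"""Raster containers and plain-text grid I/O.

The package works on co-registered single-band rasters stacked into an
:class:`EnvGrid`. Grids follow the usual north-up raster convention:
row 0 is the northernmost row, ``origin_x``/``origin_y`` locate the
upper-left corner of the upper-left cell, and a point ``(x, y)`` falls in
column ``floor((x - origin_x) / cell_size)`` and row
``floor((origin_y - y) / cell_size)``. Cell centers sit at half-cell
offsets from the origin.

Layers are exchanged on disk as ESRI ASCII grids (one layer per ``.asc``
file), the plain-text format whose six-line header gives ``ncols``,
``nrows``, ``xllcorner``, ``yllcorner``, ``cellsize`` and
``NODATA_value``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

__all__ = ["EnvGrid", "read_ascii_grid", "write_ascii_grid"]

DEFAULT_NODATA = -9999.0


@dataclass
class EnvGrid:
    """A stack of named, co-registered environmental raster layers.

    Parameters
    ----------
    layers
        Mapping from layer name to a 2-D float array of shape
        ``(n_rows, n_cols)``. Units are per layer (°C for temperature-like
        layers, mm for precipitation-like layers, dimensionless indices
        otherwise).
    origin_x, origin_y
        Map coordinates of the grid's upper-left corner.
    cell_size
        Cell edge length in map units; must be positive.
    nodata_mask
        Boolean array, ``True`` where a cell carries no data. All layers
        share this support.
    crs_label
        Free-text identifier of the coordinate reference system.
    """

    layers: dict[str, np.ndarray]
    origin_x: float = 0.0
    origin_y: float = 0.0
    cell_size: float = 1.0
    nodata_mask: np.ndarray | None = None
    crs_label: str = "synthetic"
    _shape: tuple[int, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("EnvGrid requires at least one layer")
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")
        shapes = {name: np.asarray(a).shape for name, a in self.layers.items()}
        first = next(iter(shapes.values()))
        if len(first) != 2:
            raise ValueError("layers must be 2-D arrays")
        for name, shp in shapes.items():
            if shp != first:
                raise ValueError(
                    f"layer {name!r} has shape {shp}, expected {first}"
                )
        self.layers = {n: np.asarray(a, dtype=float) for n, a in self.layers.items()}
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(first, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != first:
                raise ValueError("nodata_mask shape does not match layers")
        self._shape = first

    # -- geometry ----------------------------------------------------------

    @property
    def n_rows(self) -> int:
        return self._shape[0]

    @property
    def n_cols(self) -> int:
        return self._shape[1]

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    @property
    def valid_mask(self) -> np.ndarray:
        return ~self.nodata_mask

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid footprint."""
        return (
            self.origin_x,
            self.origin_y - self.n_rows * self.cell_size,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y,
        )

    def point_to_cell(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates to (row, col) under the north-up convention."""
        col = np.floor((np.asarray(x, dtype=float) - self.origin_x) / self.cell_size)
        row = np.floor((self.origin_y - np.asarray(y, dtype=float)) / self.cell_size)
        return row.astype(int), col.astype(int)

    def cell_center(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        x = self.origin_x + (np.asarray(col) + 0.5) * self.cell_size
        y = self.origin_y - (np.asarray(row) + 0.5) * self.cell_size
        return x, y

    def in_bounds(self, row, col) -> np.ndarray:
        row = np.asarray(row)
        col = np.asarray(col)
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)

    # -- persistence -------------------------------------------------------

    def to_dir(self, path: str, nodata_value: float = DEFAULT_NODATA) -> None:
        """Write one ASCII grid per layer into a directory."""
        os.makedirs(path, exist_ok=True)
        for name, arr in self.layers.items():
            write_ascii_grid(
                os.path.join(path, f"{name}.asc"),
                arr,
                origin_x=self.origin_x,
                origin_y=self.origin_y,
                cell_size=self.cell_size,
                nodata_mask=self.nodata_mask,
                nodata_value=nodata_value,
            )

    @classmethod
    def from_dir(cls, path: str, crs_label: str = "unknown") -> "EnvGrid":
        """Load every ``.asc`` file in a directory as one co-registered stack."""
        files = sorted(f for f in os.listdir(path) if f.endswith(".asc"))
        if not files:
            raise FileNotFoundError(f"no .asc layers found in {path!r}")
        layers: dict[str, np.ndarray] = {}
        meta = None
        mask = None
        for fname in files:
            arr, m, this_meta = read_ascii_grid(os.path.join(path, fname))
            if meta is None:
                meta, mask = this_meta, m
            elif this_meta != meta:
                raise ValueError(f"layer {fname!r} is not co-registered with the stack")
            else:
                mask = mask | m
            layers[fname[:-4]] = arr
        return cls(
            layers=layers,
            origin_x=meta["origin_x"],
            origin_y=meta["origin_y"],
            cell_size=meta["cell_size"],
            nodata_mask=mask,
            crs_label=crs_label,
        )


def write_ascii_grid(
    path: str,
    array: np.ndarray,
    *,
    origin_x: float,
    origin_y: float,
    cell_size: float,
    nodata_mask: np.ndarray | None = None,
    nodata_value: float = DEFAULT_NODATA,
) -> None:
    array = np.asarray(array, dtype=float)
    n_rows, n_cols = array.shape
    out = array.copy()
    if nodata_mask is not None:
        out[np.asarray(nodata_mask, dtype=bool)] = nodata_value
    # repr of Python floats round-trips exactly through the text format
    header = (
        f"ncols {n_cols}\n"
        f"nrows {n_rows}\n"
        f"xllcorner {float(origin_x)!r}\n"
        f"yllcorner {float(origin_y - n_rows * cell_size)!r}\n"
        f"cellsize {float(cell_size)!r}\n"
        f"NODATA_value {float(nodata_value)!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for row in out:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_ascii_grid(path: str):
    """Read an ESRI ASCII grid.

    Returns ``(array, nodata_mask, meta)`` where meta holds
    ``origin_x``, ``origin_y`` (upper-left corner) and ``cell_size``.
    """
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, _, value = line.partition(" ")
            key = key.strip().lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                       "nodata_value"}:
                header[key] = float(value)
                pos = fh.tell()
            else:  # optional NODATA_value line absent
                break
        fh.seek(pos)
        data = np.loadtxt(fh, dtype=float, ndmin=2)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    if data.shape != (n_rows, n_cols):
        raise ValueError(f"{path!r}: data shape {data.shape} does not match header")
    nodata_value = header.get("nodata_value", DEFAULT_NODATA)
    mask = data == nodata_value
    meta = {
        "origin_x": header["xllcorner"],
        "origin_y": header["yllcorner"] + n_rows * header["cellsize"],
        "cell_size": header["cellsize"],
    }
    return data, mask, meta
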