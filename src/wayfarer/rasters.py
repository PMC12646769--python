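"""Planar raster grids and the aligned landscape layer stack.

Conventions (fixed for bit-reproducible point lookups):

* coordinates are planar metres (projected); no geographic CRS handling,
* row 0 is the top (north) edge; column 0 the left (west) edge,
* a point (x, y) falls in column ``floor((x - x0) / res)`` and row
  ``floor((y_top - y) / res)``: cells are half-open, ``[x0, x1)`` in x and
  ``(y1, y_top]`` in y.

Rasters are serialised as ESRI ASCII grids (plain text) so that a full
landscape stack survives text-only storage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DataError, FormatError

#: Cover classes, in code order.  Code 0 is the reference habitat used by
#: the selection models.
COVER_CLASSES = ("scrub", "glade", "riverine", "bare_soil", "black_cotton")
COVER_CODES = {name: code for code, name in enumerate(COVER_CLASSES)}


@dataclass
class Raster:
    """A single-band raster on a regular planar grid.

    Parameters
    ----------
    data:
        2-D array, row 0 at the top (north).
    x0:
        x coordinate of the left (west) edge, metres.
    y_top:
        y coordinate of the top (north) edge, metres.
    res:
        Cell size in metres (square cells).
    """

    data: np.ndarray
    x0: float
    y_top: float
    res: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise DataError("raster data must be 2-D")
        if self.res <= 0:
            raise DataError("raster resolution must be > 0")

    # -- geometry -----------------------------------------------------------
    @property
    def nrows(self) -> int:
        return self.data.shape[0]

    @property
    def ncols(self) -> int:
        return self.data.shape[1]

    @property
    def x_max(self) -> float:
        return self.x0 + self.ncols * self.res

    @property
    def y_min(self) -> float:
        return self.y_top - self.nrows * self.res

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, Y) arrays of cell-centre coordinates, shaped like data."""
        cols = self.x0 + (np.arange(self.ncols) + 0.5) * self.res
        rows = self.y_top - (np.arange(self.nrows) + 0.5) * self.res
        return np.meshgrid(cols, rows)

    def index_of(self, x, y) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Map point coordinates to (row, col, inside) arrays.

        Points outside the extent get clipped indices with ``inside`` False.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x0) / self.res).astype(int)
        row = np.floor((self.y_top - y) / self.res).astype(int)
        # the top edge itself belongs to row 0
        row = np.where(np.asarray(y) == self.y_top, 0, row)
        inside = (col >= 0) & (col < self.ncols) & (row >= 0) & (row < self.nrows)
        return (
            np.clip(row, 0, self.nrows - 1),
            np.clip(col, 0, self.ncols - 1),
            inside,
        )

    def values_at(self, x, y, fill=np.nan) -> np.ndarray:
        """Sample the containing cell for each point, no interpolation."""
        row, col, inside = self.index_of(x, y)
        vals = self.data[row, col].astype(float)
        return np.where(inside, vals, fill)

    def contains(self, x, y) -> np.ndarray:
        return self.index_of(x, y)[2]

    def aligned_with(self, other: "Raster") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.x0, other.x0)
            and np.isclose(self.y_top, other.y_top)
            and np.isclose(self.res, other.res)
        )

    # -- I/O ----------------------------------------------------------------
    def write_ascii(self, path: str | Path, fmt: str = "%.6g") -> None:
        """Write as an ESRI ASCII grid (text)."""
        path = Path(path)
        header = (
            f"ncols {self.ncols}\n"
            f"nrows {self.nrows}\n"
            f"xllcorner {self.x0!r}\n"
            f"yllcorner {self.y_min!r}\n"
            f"cellsize {self.res!r}\n"
            "NODATA_value -9999\n"
        )
        body = np.where(np.isfinite(self.data.astype(float)), self.data, -9999)
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, body, fmt=fmt)

    @classmethod
    def read_ascii(cls, path: str | Path) -> "Raster":
        path = Path(path)
        header: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                header[key.lower()] = float(val)
            data = np.loadtxt(fh)
        try:
            nrows = int(header["nrows"])
            ncols = int(header["ncols"])
            res = header["cellsize"]
            x0 = header["xllcorner"]
            y_top = header["yllcorner"] + nrows * res
        except KeyError as exc:  # pragma: no cover - malformed file
            raise FormatError(f"missing ESRI ASCII header field: {exc}") from exc
        data = np.atleast_2d(data)
        if data.shape != (nrows, ncols):
            raise FormatError(
                f"grid body {data.shape} does not match header ({nrows}, {ncols})"
            )
        nodata = header.get("nodata_value", -9999)
        data = np.where(data == nodata, np.nan, data)
        return cls(data=data, x0=x0, y_top=y_top, res=res)


@dataclass
class LandscapeStack:
    """Aligned rasters describing one study landscape.

    ``cover`` holds integer codes from :data:`COVER_CODES`; ``road`` and
    ``water`` are 0/1; ``elevation`` is metres.  Terrain derivatives
    (``slope``, ``aspect``, ``tri``) are attached by :mod:`wayfarer.terrain`.
    """

    cover: Raster
    road: Raster
    water: Raster
    elevation: Raster
    slope: Raster | None = None
    aspect: Raster | None = None
    tri: Raster | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("road", "water", "elevation"):
            if not self.cover.aligned_with(getattr(self, name)):
                raise DataError(f"layer '{name}' is not aligned with 'cover'")

    @property
    def grid(self) -> Raster:
        return self.cover

    def has_terrain(self) -> bool:
        return self.slope is not None and self.aspect is not None and self.tri is not None

    def cover_names_at(self, x, y) -> np.ndarray:
        codes = self.cover.values_at(x, y)
        names = np.empty(codes.shape, dtype=object)
        valid = np.isfinite(codes)
        names[~valid] = None
        idx = codes[valid].astype(int)
        names[valid] = np.asarray(COVER_CLASSES, dtype=object)[idx]
        return names

    # -- I/O ----------------------------------------------------------------
    _LAYER_FMTS = {
        "cover": "%d",
        "road": "%d",
        "water": "%d",
        "elevation": "%.6f",
        "slope": "%.6f",
        "aspect": "%.6f",
        "tri": "%.6f",
    }

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, fmt in self._LAYER_FMTS.items():
            layer: Raster | None = getattr(self, name)
            if layer is not None:
                layer.write_ascii(out_dir / f"{name}.asc", fmt=fmt)
        meta = dict(self.meta)
        meta["cover_classes"] = list(COVER_CLASSES)
        (out_dir / "landscape_meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, in_dir: str | Path) -> "LandscapeStack":
        in_dir = Path(in_dir)
        layers = {}
        for name in cls._LAYER_FMTS:
            p = in_dir / f"{name}.asc"
            if p.exists():
                r = Raster.read_ascii(p)
                if name in ("cover", "road", "water"):
                    r.data = r.data.astype(int)
                layers[name] = r
            elif name in ("cover", "road", "water", "elevation"):
                raise FormatError(f"missing required layer file: {p}")
        meta_path = in_dir / "landscape_meta.json"
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        meta.pop("cover_classes", None)
        return cls(meta=meta, **layers)
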