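"""Raster and table input/output.

Two raster formats are supported, both single-band integer grids:

* ESRI ASCII grid (``.asc`` / ``.txt``): the plain-text interchange format
  with an ``ncols/nrows/xllcorner/yllcorner/cellsize/NODATA_value`` header.
* TIFF (``.tif`` / ``.tiff``) via :mod:`tifffile`.  The cell size is carried
  in the ImageDescription tag as a small JSON blob; no CRS handling is
  attempted (reprojection and multi-band imagery are out of scope).

Row 0 is the top (north) row of the map and cells are addressed (row, col).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .landscape import ALL_LABELS, BinaryLandscape, ClassCodeScheme

log = logging.getLogger(__name__)

_ASCII_SUFFIXES = {".asc", ".txt", ".grd"}
_TIFF_SUFFIXES = {".tif", ".tiff"}


class RasterFormatError(ValueError):
    """Raised when a raster file cannot be parsed or is unsupported."""


@dataclass
class LandcoverRaster:
    """A categorical land-cover grid as read from disk."""

    grid: np.ndarray  # 2-D integer codes
    cell_size: float | None
    nodata: int | None = None

    @property
    def n_nodata(self) -> int:
        if self.nodata is None:
            return 0
        return int((self.grid == self.nodata).sum())


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower()
    if suffix in _ASCII_SUFFIXES:
        return "ascii-grid"
    if suffix in _TIFF_SUFFIXES:
        return "geotiff"
    raise RasterFormatError(f"cannot infer raster format from suffix {suffix!r}")


def read_landcover(
    path: str | Path,
    format: str | None = None,
    cell_size: float | None = None,
) -> LandcoverRaster:
    """Read a single-band integer raster.

    Parameters
    ----------
    path
        File to read.
    format
        ``"ascii-grid"`` or ``"geotiff"``; inferred from the suffix when None.
    cell_size
        Optional override.  When it disagrees with file metadata a warning is
        issued and the override wins.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "ascii-grid":
        raster = _read_ascii_grid(path)
    elif fmt == "geotiff":
        raster = _read_tiff(path)
    else:
        raise RasterFormatError(f"unsupported format {fmt!r}")

    if cell_size is not None:
        if raster.cell_size is not None and not np.isclose(raster.cell_size, cell_size):
            warnings.warn(
                f"cell size override {cell_size} disagrees with file metadata "
                f"{raster.cell_size}; using the override",
                stacklevel=2,
            )
        raster.cell_size = cell_size
    if raster.cell_size is None:
        raise RasterFormatError(
            f"{path} carries no cell size; pass cell_size= explicitly"
        )
    if raster.n_nodata:
        log.info("%s: %d NODATA cells", path, raster.n_nodata)
    return raster


def _read_ascii_grid(path: Path) -> LandcoverRaster:
    header: dict[str, float] = {}
    data_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if not data_lines and key in {
                "ncols",
                "nrows",
                "xllcorner",
                "yllcorner",
                "xllcenter",
                "yllcenter",
                "cellsize",
                "nodata_value",
            }:
                header[key] = float(parts[1])
            else:
                data_lines.append(line)
    for required in ("ncols", "nrows", "cellsize"):
        if required not in header:
            raise RasterFormatError(f"{path}: missing ASCII grid header key {required}")
    try:
        values = np.loadtxt(data_lines, ndmin=2)
    except ValueError as exc:
        raise RasterFormatError(f"{path}: cannot parse grid body: {exc}") from exc
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if values.shape != (nrows, ncols):
        raise RasterFormatError(
            f"{path}: body shape {values.shape} does not match header "
            f"({nrows}, {ncols})"
        )
    if not np.all(values == np.round(values)):
        raise RasterFormatError(f"{path}: non-integer cell values")
    nodata = header.get("nodata_value")
    return LandcoverRaster(
        grid=values.astype(np.int64),
        cell_size=float(header["cellsize"]),
        nodata=None if nodata is None else int(nodata),
    )


def _read_tiff(path: Path) -> LandcoverRaster:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        arr = page.asarray()
        description = page.description or ""
    if arr.ndim == 3:
        if arr.shape[2] == 1:
            arr = arr[:, :, 0]
        else:
            raise RasterFormatError(f"{path}: multi-band rasters are unsupported")
    if arr.ndim != 2:
        raise RasterFormatError(f"{path}: expected a single-band 2-D raster")
    if not np.issubdtype(arr.dtype, np.integer):
        raise RasterFormatError(f"{path}: expected an integer raster, got {arr.dtype}")
    cell_size = None
    nodata = None
    if description:
        try:
            meta = json.loads(description)
            cell_size = meta.get("cell_size")
            nodata = meta.get("nodata")
        except (json.JSONDecodeError, AttributeError):
            pass
    return LandcoverRaster(grid=arr.astype(np.int64), cell_size=cell_size, nodata=nodata)


def write_landcover(
    grid: np.ndarray,
    path: str | Path,
    cell_size: float,
    format: str | None = None,
    nodata: int | None = None,
) -> Path:
    """Write an integer grid to ASCII grid or TIFF (inferred from suffix)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    grid = np.asarray(grid)
    if grid.ndim != 2:
        raise ValueError("grid must be 2-D")
    if fmt == "ascii-grid":
        nrows, ncols = grid.shape
        with open(path, "w") as fh:
            fh.write(f"ncols {ncols}\n")
            fh.write(f"nrows {nrows}\n")
            fh.write("xllcorner 0.0\n")
            fh.write("yllcorner 0.0\n")
            fh.write(f"cellsize {cell_size}\n")
            if nodata is not None:
                fh.write(f"NODATA_value {nodata}\n")
            np.savetxt(fh, grid.astype(np.int64), fmt="%d")
    else:
        import tifffile

        meta = {"cell_size": cell_size}
        if nodata is not None:
            meta["nodata"] = nodata
        dtype = np.int32 if grid.min() < 0 or grid.max() > 255 else np.uint8
        tifffile.imwrite(path, grid.astype(dtype), description=json.dumps(meta))
    return path


def binarize(
    raster: LandcoverRaster | np.ndarray,
    foreground_codes: set[int] | frozenset[int],
    nodata_policy: str = "background",
    nodata: int | None = None,
    cell_size: float | None = None,
) -> BinaryLandscape:
    """Binarize a categorical grid: cell is foreground iff its code is in
    ``foreground_codes``.

    NODATA cells are treated as background (default, with a logged count) or
    raise, per ``nodata_policy`` in {"background", "error"}.
    """
    if not foreground_codes:
        raise ValueError("foreground_codes must be non-empty")
    if nodata_policy not in {"background", "error"}:
        raise ValueError(f"unknown nodata_policy {nodata_policy!r}")
    if isinstance(raster, LandcoverRaster):
        grid = raster.grid
        nodata = raster.nodata if nodata is None else nodata
        cell_size = raster.cell_size if cell_size is None else cell_size
    else:
        grid = np.asarray(raster)
    if cell_size is None:
        cell_size = 30.0
    if nodata is not None:
        n_nodata = int((grid == nodata).sum())
        if n_nodata:
            if nodata_policy == "error":
                raise ValueError(f"{n_nodata} NODATA cells present with nodata_policy='error'")
            log.info("binarize: %d NODATA cells treated as background", n_nodata)
            if nodata in foreground_codes:
                raise ValueError("nodata code cannot also be a foreground code")
    fg = np.isin(grid, list(foreground_codes))
    return BinaryLandscape(fg, cell_size=cell_size)


def write_class_map(
    labels: np.ndarray,
    path: str | Path,
    scheme: ClassCodeScheme | None = None,
    cell_size: float = 30.0,
    format: str | None = None,
) -> Path:
    """Encode a structural-class label grid with a code scheme and write it.

    ``labels`` may be a grid of label strings or of default integer codes
    (index into :data:`~fragscape.landscape.ALL_LABELS`).
    """
    scheme = scheme or ClassCodeScheme()
    labels = np.asarray(labels)
    if labels.dtype.kind in "iu":
        if labels.min() < 0 or labels.max() >= len(ALL_LABELS):
            raise ValueError("integer label grid contains codes outside 0..7")
        name_grid = np.array(ALL_LABELS, dtype=object)[labels]
    else:
        name_grid = labels.astype(object)
        unknown = set(np.unique(name_grid)) - set(ALL_LABELS)
        if unknown:
            raise ValueError(f"labels not covered by the scheme: {sorted(unknown)}")
    encode = np.vectorize(scheme.encode, otypes=[np.int64])
    coded = encode(name_grid)
    return write_landcover(coded, path, cell_size=cell_size, format=format)


def read_class_map(
    path: str | Path,
    scheme: ClassCodeScheme | None = None,
    format: str | None = None,
    cell_size: float | None = None,
) -> tuple[np.ndarray, float]:
    """Read a class-map raster back to default label codes (0..7).

    Returns ``(label_codes, cell_size)`` where ``label_codes[i, j]`` indexes
    :data:`~fragscape.landscape.ALL_LABELS`.
    """
    scheme = scheme or ClassCodeScheme()
    raster = read_landcover(path, format=format, cell_size=cell_size)
    inverse = scheme.inverse
    unknown = set(np.unique(raster.grid)) - set(inverse)
    if unknown:
        raise ValueError(f"file contains codes not in scheme: {sorted(unknown)}")
    lut = np.zeros(max(inverse) + 1, dtype=np.uint8)
    for code, label in inverse.items():
        lut[code] = ALL_LABELS.index(label)
    return lut[raster.grid], raster.cell_size
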