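"""Four-band raster composites and per-plot pixel extraction.

A :class:`BandComposite` holds the four aligned Sentinel-2 style bands
(B02 blue, B03 green, B04 red, B08 NIR) as unsigned 16-bit digital numbers
(L2A convention: surface reflectance x 10000).  Plots are extracted from a
composite as masked pixel windows (:class:`PlotPixels`) carrying a
phenological-stage label, and named ``{date}_{plot}_{stage}``.

Coordinate convention: 0-based row/col indices, half-open windows
``(row0, row1, col0, col1)``.  Polygon footprints include a pixel when the
pixel *centre* falls inside the polygon.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from shapely import contains_xy
from shapely.geometry import Polygon
from shapely import wkt as shapely_wkt

from .exceptions import ExtractionError, FormatError, NamingError, WindowError

BAND_NAMES = ("blue", "green", "red", "nir")

#: half-open pixel window (row0, row1, col0, col1)
Window = tuple[int, int, int, int]


@dataclass
class BandComposite:
    """Aligned 4-band raster grid in digital numbers (uint16)."""

    blue: np.ndarray
    green: np.ndarray
    red: np.ndarray
    nir: np.ndarray
    transform: tuple[float, float, float, float, float, float] | None = None

    def __post_init__(self) -> None:
        shapes = {b.shape for b in self.bands}
        if len(shapes) != 1:
            raise FormatError(f"bands have mismatched shapes: {shapes}")
        for b in self.bands:
            if not np.issubdtype(b.dtype, np.integer):
                raise FormatError(f"band dtype {b.dtype} is not integer")
            if b.min(initial=0) < 0:
                raise FormatError("negative digital numbers")

    @property
    def bands(self) -> tuple[np.ndarray, ...]:
        return (self.blue, self.green, self.red, self.nir)

    @property
    def height(self) -> int:
        return self.blue.shape[0]

    @property
    def width(self) -> int:
        return self.blue.shape[1]

    def stack(self) -> np.ndarray:
        """Bands stacked to shape (4, height, width)."""
        return np.stack(self.bands)


@dataclass
class PlotPixels:
    """Masked per-band pixel set for one plot/date with its stage label.

    ``mask`` and the band grids cover the plot's bounding window; ``window``
    records where that window sits in the source composite.
    """

    plot_id: str
    date: str
    stage: int
    mask: np.ndarray
    blue: np.ndarray
    green: np.ndarray
    red: np.ndarray
    nir: np.ndarray
    window: Window | None = None

    def __post_init__(self) -> None:
        if not self.mask.any():
            raise ExtractionError("plot mask has no pixels")
        if self.stage not in range(1, 7):
            raise ExtractionError(f"stage {self.stage} not in 1..6")
        for b in self.bands:
            if b.shape != self.mask.shape:
                raise ExtractionError("band grid does not match mask shape")

    @property
    def bands(self) -> tuple[np.ndarray, ...]:
        return (self.blue, self.green, self.red, self.nir)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def write_composite(path: str | Path, comp: BandComposite) -> None:
    """Write a composite as a 4-band uint16 TIFF (band-sequential)."""
    tifffile.imwrite(str(path), comp.stack().astype(np.uint16),
                     photometric="minisblack")


def read_composite(path: str | Path) -> BandComposite:
    """Read a 4-band integer raster; bands mapped to (B02,B03,B04,B08) by index."""
    arr = tifffile.imread(str(path))
    if arr.ndim == 3 and arr.shape[-1] == 4 and arr.shape[0] != 4:
        arr = np.moveaxis(arr, -1, 0)  # pixel-interleaved layout
    if arr.ndim != 3 or arr.shape[0] != 4:
        raise FormatError(f"expected 4 bands, got array of shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        raise FormatError(f"expected integer raster, got dtype {arr.dtype}")
    return BandComposite(*[arr[i] for i in range(4)])


def crop_to_window(comp: BandComposite, window: Window) -> BandComposite:
    """Crop all four bands to the half-open window (row0,row1,col0,col1)."""
    r0, r1, c0, c1 = window
    if not (0 <= r0 < r1 <= comp.height and 0 <= c0 < c1 <= comp.width):
        raise WindowError(
            f"window {window} outside raster {comp.height}x{comp.width}"
        )
    return BandComposite(*[b[r0:r1, c0:c1].copy() for b in comp.bands])


def footprint_mask(
    footprint: Window | Polygon | str | Sequence[Window],
    shape: tuple[int, int],
) -> np.ndarray:
    """Rasterize a footprint to a boolean mask over a raster of ``shape``.

    Footprints may be a half-open pixel rectangle, a list of rectangles
    (union), a shapely polygon in pixel coordinates (x=col, y=row), or a WKT
    string of such a polygon.  Polygons include pixels whose centre lies
    inside.
    """
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    if isinstance(footprint, str):
        footprint = shapely_wkt.loads(footprint)
    if isinstance(footprint, Polygon):
        c0, r0, c1, r1 = footprint.bounds
        rows = np.arange(max(int(np.floor(r0)), 0), min(int(np.ceil(r1)) + 1, h))
        cols = np.arange(max(int(np.floor(c0)), 0), min(int(np.ceil(c1)) + 1, w))
        if rows.size and cols.size:
            cc, rr = np.meshgrid(cols + 0.5, rows + 0.5)
            inside = contains_xy(footprint, cc, rr)
            mask[np.ix_(rows, cols)] = inside
        return mask
    rects = [footprint] if _is_rect(footprint) else list(footprint)
    for r0, r1, c0, c1 in rects:
        mask[max(r0, 0) : min(r1, h), max(c0, 0) : min(c1, w)] = True
    return mask


def _is_rect(obj) -> bool:
    return (
        isinstance(obj, (tuple, list))
        and len(obj) == 4
        and all(isinstance(v, (int, np.integer)) for v in obj)
    )


def extract_plot(
    comp: BandComposite,
    footprint,
    plot_id: str,
    date: str,
    stage: int,
) -> PlotPixels:
    """Extract the masked pixel set of one plot as a bounding-window crop.

    Pure selection: pixel values are copied unchanged from the composite.
    """
    mask = footprint_mask(footprint, (comp.height, comp.width))
    if not mask.any():
        raise ExtractionError(f"footprint of plot {plot_id!r} outside raster")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    win: Window = (int(rows[0]), int(rows[-1]) + 1, int(cols[0]), int(cols[-1]) + 1)
    r0, r1, c0, c1 = win
    return PlotPixels(
        plot_id=str(plot_id),
        date=date,
        stage=int(stage),
        mask=mask[r0:r1, c0:c1],
        blue=comp.blue[r0:r1, c0:c1].copy(),
        green=comp.green[r0:r1, c0:c1].copy(),
        red=comp.red[r0:r1, c0:c1].copy(),
        nir=comp.nir[r0:r1, c0:c1].copy(),
        window=win,
    )


_DATE_RE = re.compile(r"^\d{8}$")
_NAME_RE = re.compile(r"^(\d{8})_([^_]+)_([1-6])$")


def sample_filename(plot: PlotPixels) -> str:
    """Canonical sample name ``{date}_{plot_id}_{stage}`` (date as YYYYMMDD)."""
    date = plot.date.replace("-", "")
    if not _DATE_RE.match(date):
        raise NamingError(f"date {plot.date!r} is not YYYY-MM-DD or YYYYMMDD")
    if "_" in plot.plot_id:
        raise NamingError(f"plot_id {plot.plot_id!r} contains the separator '_'")
    return f"{date}_{plot.plot_id}_{plot.stage}"


def parse_sample_filename(name: str) -> tuple[str, str, int]:
    """Invert :func:`sample_filename` -> (date, plot_id, stage)."""
    m = _NAME_RE.match(name)
    if m is None:
        raise NamingError(f"unparseable sample name {name!r}")
    return m.group(1), m.group(2), int(m.group(3))


# -- plot tables -------------------------------------------------------------

def write_plot_table(path: str | Path, records) -> None:
    """Persist plot records as CSV (plot_id, date, stage, footprint bounds)."""
    rows = []
    for rec in records:
        r0, r1, c0, c1 = rec.footprint
        rows.append(
            dict(plot_id=rec.plot_id, date=rec.date, stage=rec.stage,
                 row0=r0, row1=r1, col0=c0, col1=c1)
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_plot_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"plot_id": str, "date": str})
    return df
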