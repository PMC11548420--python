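"""Raster and tabular I/O for dual-polarization GRD backscatter.

Backscatter is carried internally in linear power (sigma-nought, m²/m²):
ratios of sigma-nought are only physically meaningful on that scale. dB
inputs are converted on ingest. GeoTIFFs are written with the GDAL nodata
convention (ASCII tag 42113) plus ModelPixelScale / ModelTiepoint geo tags
when a georeference is present; the CRS is stored as a text tag and treated
as opaque by all of the math.
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

__all__ = [
    "GeoReference",
    "RadarScene",
    "RasterIOError",
    "db_to_linear",
    "linear_to_db",
    "read_dual_pol_scene",
    "read_grid",
    "write_grid",
    "read_campaign_manifest",
    "write_campaign_manifest",
]

# GDAL's private TIFF tags for nodata and georeferencing.
_TAG_GDAL_NODATA = 42113
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_CRS_TEXT = 42112  # GDAL metadata tag; we store a small JSON payload


class RasterIOError(ValueError):
    """Structured error for raster ingest/export problems."""


@dataclass(frozen=True)
class GeoReference:
    """Affine georeference: world = origin + pixel_size * (col, row).

    ``pixel_size`` is (x_size, y_size) with y_size conventionally negative
    for north-up rasters; ``origin`` is the world coordinate of the outer
    corner of pixel (0, 0). ``crs`` is a free-text CRS tag, opaque here.
    """

    origin: tuple[float, float] = (0.0, 0.0)
    pixel_size: tuple[float, float] = (1.0, -1.0)
    crs: str | None = None

    def pixel_centers(self, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        """World x/y coordinates of every pixel center, each shaped like the grid."""
        rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
        x = self.origin[0] + (cols + 0.5) * self.pixel_size[0]
        y = self.origin[1] + (rows + 0.5) * self.pixel_size[1]
        return x, y


@dataclass
class RadarScene:
    """One acquisition's VV/VH backscatter in linear power with validity mask.

    Invariants: vv, vh and mask share a shape; at mask-true pixels vv > 0,
    vh >= 0 and both are finite; doy lies in [1, 366].
    """

    vv: np.ndarray
    vh: np.ndarray
    mask: np.ndarray
    doy: int
    scene_id: str = ""
    geo: GeoReference | None = None

    def __post_init__(self) -> None:
        self.vv = np.asarray(self.vv, dtype=np.float64)
        self.vh = np.asarray(self.vh, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not (self.vv.shape == self.vh.shape == self.mask.shape):
            raise RasterIOError(
                f"scene '{self.scene_id}': vv {self.vv.shape}, vh {self.vh.shape} "
                f"and mask {self.mask.shape} must share a shape"
            )
        if not 1 <= int(self.doy) <= 366:
            raise RasterIOError(f"doy {self.doy} outside [1, 366]")
        self.doy = int(self.doy)
        # Demote non-finite / out-of-range pixels rather than fabricate values.
        bad = ~np.isfinite(self.vv) | ~np.isfinite(self.vh)
        bad |= (self.vv <= 0) | (self.vh < 0)
        self.mask &= ~bad

    @property
    def shape(self) -> tuple[int, int]:
        return self.vv.shape

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())


def db_to_linear(x: np.ndarray) -> np.ndarray:
    """Convert backscatter from dB to linear power: 10**(x/10)."""
    return np.power(10.0, np.asarray(x, dtype=np.float64) / 10.0)


def linear_to_db(x: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Convert linear power to dB (10*log10 x); valid pixels must be positive.

    Raises :class:`RasterIOError` naming the count and the first offending
    flat index when a mask-valid pixel is non-positive.
    """
    x = np.asarray(x, dtype=np.float64)
    valid = np.ones(x.shape, bool) if mask is None else np.asarray(mask, bool)
    bad = valid & ~(x > 0)
    if bad.any():
        idx = int(np.flatnonzero(bad)[0])
        raise RasterIOError(
            f"{int(bad.sum())} non-positive valid pixel(s); first at flat index {idx}"
        )
    out = np.full(x.shape, np.nan)
    np.multiply(10.0, np.log10(x, where=valid, out=np.full(x.shape, np.nan)), out=out)
    return out


def _load_band(source) -> tuple[np.ndarray, float | None, GeoReference | None]:
    """Load one band from a path or a (path, band_index) pair."""
    if isinstance(source, (tuple, list)):
        path, band = source
    else:
        path, band = source, None
    arr, nodata, geo = read_grid(path, return_raw=True)
    if arr.ndim == 3:
        if band is None:
            raise RasterIOError(f"{path}: multi-band raster needs a band index")
        axis0 = 0 if arr.shape[0] < min(arr.shape[1:]) else -1
        arr = arr[band] if axis0 == 0 else arr[..., band]
    elif band not in (None, 0):
        raise RasterIOError(f"{path}: single-band raster, band {band} requested")
    return np.asarray(arr, np.float64), nodata, geo


def read_dual_pol_scene(
    vv_source,
    vh_source,
    doy: int,
    units: str = "linear",
    scene_id: str = "",
) -> RadarScene:
    """Ingest a VV/VH pair (paths, or (path, band) pairs) into a RadarScene.

    ``units`` is "linear" or "dB"; dB inputs are converted so the scene is
    always in linear power. Declared-nodata and non-finite pixels become
    mask-false; ingest never fabricates valid pixels.
    """
    if units not in ("linear", "dB", "db"):
        raise RasterIOError(f"unknown units tag {units!r}; expected 'linear' or 'dB'")
    vv, nodata_vv, geo_vv = _load_band(vv_source)
    vh, nodata_vh, geo_vh = _load_band(vh_source)
    if vv.shape != vh.shape:
        raise RasterIOError(
            f"shape mismatch: vv {vv.shape} from {vv_source!r} vs "
            f"vh {vh.shape} from {vh_source!r}"
        )
    if geo_vv is not None and geo_vh is not None and geo_vv != geo_vh:
        raise RasterIOError(
            f"georeference mismatch between {vv_source!r} and {vh_source!r}"
        )
    mask = np.isfinite(vv) & np.isfinite(vh)
    if nodata_vv is not None:
        mask &= vv != nodata_vv
    if nodata_vh is not None:
        mask &= vh != nodata_vh
    if units != "linear":
        vv, vh = db_to_linear(vv), db_to_linear(vh)
    return RadarScene(vv=vv, vh=vh, mask=mask, doy=doy, scene_id=scene_id, geo=geo_vv or geo_vh)


def write_grid(
    grid: np.ndarray,
    mask: np.ndarray | None,
    path,
    geo: GeoReference | None = None,
    nodata: float | None = None,
    dtype=np.float32,
) -> None:
    """Write a 2-D grid as a (Geo)TIFF, encoding mask-false pixels as nodata.

    float32 payloads default to NaN nodata; integer payloads (zone labels)
    default to 0. Without a georeference a plain TIFF is written.
    """
    grid = np.asarray(grid)
    out = grid.astype(dtype, copy=True)
    if nodata is None:
        nodata = 0 if np.issubdtype(np.dtype(dtype), np.integer) else np.nan
    if mask is not None:
        out[~np.asarray(mask, bool)] = nodata
    extratags = [(_TAG_GDAL_NODATA, "s", 0, str(nodata), True)]
    if geo is not None:
        sx, sy = geo.pixel_size
        extratags.append((_TAG_MODEL_PIXEL_SCALE, "d", 3, (abs(sx), abs(sy), 0.0), True))
        extratags.append(
            (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, geo.origin[0], geo.origin[1], 0.0), True)
        )
        payload = json.dumps({"crs": geo.crs, "pixel_size": list(geo.pixel_size)})
        extratags.append((_TAG_CRS_TEXT, "s", 0, payload, True))
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".part")
    try:
        tifffile.imwrite(tmp, out, extratags=extratags)
        os.replace(tmp, path)
    except OSError as exc:
        tmp.unlink(missing_ok=True)
        raise RasterIOError(f"cannot write raster {path}: {exc}") from exc


def read_grid(path, return_raw: bool = False):
    """Read a (Geo)TIFF written by :func:`write_grid` (or any plain TIFF).

    Returns ``(grid, mask, geo)`` with nodata decoded into the mask, or with
    ``return_raw`` the undecoded array plus the declared nodata value.
    """
    path = Path(path)
    if not path.exists():
        raise RasterIOError(f"raster not found: {path}")
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        tags = tif.pages[0].tags
        nodata = None
        if _TAG_GDAL_NODATA in tags:
            txt = str(tags[_TAG_GDAL_NODATA].value).strip()
            nodata = float(txt) if txt not in ("", "nan") else np.nan
        geo = None
        if _TAG_MODEL_TIEPOINT in tags:
            tp = tags[_TAG_MODEL_TIEPOINT].value
            scale = tags[_TAG_MODEL_PIXEL_SCALE].value if _TAG_MODEL_PIXEL_SCALE in tags else (1, 1, 0)
            crs = None
            sy = -abs(scale[1])
            if _TAG_CRS_TEXT in tags:
                try:
                    payload = json.loads(str(tags[_TAG_CRS_TEXT].value))
                    crs = payload.get("crs")
                    sy = payload.get("pixel_size", [scale[0], sy])[1]
                except (json.JSONDecodeError, TypeError):
                    pass
            geo = GeoReference(origin=(tp[3], tp[4]), pixel_size=(scale[0], sy), crs=crs)
    if return_raw:
        return arr, nodata, geo
    mask = np.isfinite(arr) if np.issubdtype(arr.dtype, np.floating) else np.ones(arr.shape, bool)
    if nodata is not None and not (isinstance(nodata, float) and np.isnan(nodata)):
        mask &= arr != nodata
    return arr, mask, geo


_MANIFEST_COLUMNS = ("scene_id", "doy", "vv_path", "vh_path", "units")


def read_campaign_manifest(path) -> list[dict]:
    """Read a campaign manifest CSV (scene_id, doy, vv_path, vh_path, units).

    Relative raster paths are resolved against the manifest's directory.
    """
    path = Path(path)
    if not path.exists():
        raise RasterIOError(f"manifest not found: {path}")
    rows = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(_MANIFEST_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise RasterIOError(f"manifest {path} missing columns: {sorted(missing)}")
        for rec in reader:
            rec = {k: rec[k] for k in _MANIFEST_COLUMNS}
            rec["doy"] = int(rec["doy"])
            for key in ("vv_path", "vh_path"):
                p = Path(rec[key])
                rec[key] = str(p if p.is_absolute() else path.parent / p)
            rows.append(rec)
    if not rows:
        raise RasterIOError(f"manifest {path} lists no scenes")
    return rows


def write_campaign_manifest(rows: Sequence[dict], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(_MANIFEST_COLUMNS))
        writer.writeheader()
        for rec in rows:
            writer.writerow({k: rec[k] for k in _MANIFEST_COLUMNS})
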