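"""Reading and writing of field images, sidecar metadata and masks.

On-disk layout for one coupon: a directory of single-channel grayscale
TIFF or PNG images (8- or 16-bit), one per microscope field, plus a
plain-text comma-separated *sidecar* file. The sidecar starts with
``# key: value`` header lines carrying coupon-level metadata (coupon id,
material, chamber, tray slot, pixel scale, field size, acquisition grid
shape) followed by a CSV table with one row per tile::

    # coupon_id: C01
    # material: glass
    # pixel_scale_um: 0.486
    ...
    tile_index,grid_row,grid_col,filename,excluded,reason
    0,0,0,C01_t000.tif,,

Pixel coordinates and acquisition-grid coordinates are both row-major,
0-based, origin top-left. Images are kept in their native integer range
(no rescaling) so that thresholding sees raw intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .errors import DataError, ValidationError

#: Default physical field size (mm) of one microscope image.
DEFAULT_FIELD_WIDTH_MM = 0.622
DEFAULT_FIELD_HEIGHT_MM = 0.467
#: Default raster and pixel pitch. 400 px at 0.486 um/px is 94.48 um^2,
#: and 6 px is 1.4 um^2 — the size-filter bounds in physical units.
DEFAULT_RASTER = (960, 1280)  # rows, cols
DEFAULT_PIXEL_SCALE_UM = 0.486

_SIDECAR_META_KEYS = (
    "coupon_id",
    "material",
    "chamber_id",
    "tray_slot",
    "trial_id",
    "pixel_scale_um",
    "field_width_mm",
    "field_height_mm",
    "grid_rows",
    "grid_cols",
)


@dataclass
class FieldImage:
    """One grayscale microscope tile with its acquisition-grid position.

    ``pixels`` is a 2-D unsigned-integer array in the native range of
    ``bit_depth`` (8 or 16). ``tile_index`` is the 0-based acquisition
    order; ``grid_row``/``grid_col`` locate the tile in the acquisition
    grid, row-major from the top-left.
    """

    pixels: np.ndarray
    bit_depth: int
    tile_index: int
    grid_row: int = 0
    grid_col: int = 0
    field_width_mm: float = DEFAULT_FIELD_WIDTH_MM
    field_height_mm: float = DEFAULT_FIELD_HEIGHT_MM
    pixel_scale_um: float = DEFAULT_PIXEL_SCALE_UM

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def n_levels(self) -> int:
        return 1 << self.bit_depth

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_scale_um ** 2

    @property
    def field_area_mm2(self) -> float:
        return self.field_width_mm * self.field_height_mm

    def validate(self, square_pixel_tol: float = 0.02) -> None:
        """Check the basic geometric contract of the tile.

        Raises :class:`ValidationError` if the image is not a 2-D
        integer grid, the bit depth is unsupported, or the physical
        field size disagrees with the raster times the pixel pitch by
        more than ``square_pixel_tol`` (relative) along either axis.
        """
        if self.pixels.ndim != 2:
            raise ValidationError(
                f"tile {self.tile_index}: expected a single-channel 2-D image, "
                f"got shape {self.pixels.shape}"
            )
        if self.bit_depth not in (8, 16):
            raise ValidationError(
                f"tile {self.tile_index}: unsupported bit depth {self.bit_depth}"
            )
        if not np.issubdtype(self.pixels.dtype, np.integer):
            raise ValidationError(
                f"tile {self.tile_index}: pixels must be integer, got {self.pixels.dtype}"
            )
        nrows, ncols = self.pixels.shape
        scale_mm = self.pixel_scale_um * 1e-3
        for name, extent, n in (
            ("width", self.field_width_mm, ncols),
            ("height", self.field_height_mm, nrows),
        ):
            if extent <= 0:
                raise ValidationError(f"tile {self.tile_index}: non-positive field {name}")
            rel = abs(extent / n - scale_mm) / scale_mm
            if rel > square_pixel_tol:
                raise ValidationError(
                    f"tile {self.tile_index}: field {name} {extent} mm over {n} px "
                    f"disagrees with pixel scale {self.pixel_scale_um} um/px "
                    f"by {rel:.1%} (square-pixel check)"
                )


@dataclass
class CouponDataset:
    """All fields acquired from one material coupon, plus exclusions.

    ``excluded_tiles`` maps a tile index to the textual reason it was
    excluded by the operator (e.g. ``"blurred"``); excluded tiles stay
    in ``fields`` but are skipped by downstream aggregation.
    """

    coupon_id: str
    material: str = ""
    chamber_id: str = ""
    tray_slot: int = 1
    trial_id: str = ""
    fields: list[FieldImage] = dc_field(default_factory=list)
    excluded_tiles: dict[int, str] = dc_field(default_factory=dict)
    grid_shape: tuple[int, int] = (15, 7)

    def validate(self) -> None:
        indices = [f.tile_index for f in self.fields]
        if len(set(indices)) != len(indices):
            raise ValidationError(f"coupon {self.coupon_id}: duplicate tile_index")
        unknown = set(self.excluded_tiles) - set(indices)
        if unknown:
            raise ValidationError(
                f"coupon {self.coupon_id}: excluded tiles {sorted(unknown)} not present"
            )
        if not 1 <= self.tray_slot <= 8:
            raise ValidationError(
                f"coupon {self.coupon_id}: tray_slot {self.tray_slot} outside 1..8"
            )
        for f in self.fields:
            f.validate()

    @property
    def valid_fields(self) -> list[FieldImage]:
        return [f for f in self.fields if f.tile_index not in self.excluded_tiles]


@dataclass
class ChamberLayout:
    """Geometry of the flow-chamber specimen tray.

    Four chambers each hold a 153 x 29 mm tray with room for eight
    37 x 14 mm coupons, for a system capacity of 32 specimens.
    """

    n_chambers: int = 4
    coupons_per_chamber: int = 8
    tray_width_mm: float = 153.0
    tray_height_mm: float = 29.0
    coupon_width_mm: float = 37.0
    coupon_height_mm: float = 14.0
    flow_inlet_side: str = "left"

    def validate(self) -> None:
        for name in ("n_chambers", "coupons_per_chamber"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive")
        for name in ("tray_width_mm", "tray_height_mm", "coupon_width_mm", "coupon_height_mm"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.flow_inlet_side not in ("left", "right", "top", "bottom"):
            raise ValidationError(f"unknown flow_inlet_side {self.flow_inlet_side!r}")
        footprint = self.coupons_per_chamber * self.coupon_width_mm * self.coupon_height_mm
        if footprint > self.tray_width_mm * self.tray_height_mm:
            raise ValidationError(
                f"{self.coupons_per_chamber} coupons of "
                f"{self.coupon_width_mm}x{self.coupon_height_mm} mm do not fit on a "
                f"{self.tray_width_mm}x{self.tray_height_mm} mm tray"
            )

    @property
    def capacity(self) -> int:
        return self.n_chambers * self.coupons_per_chamber


# ---------------------------------------------------------------------------
# image file IO

_IMAGE_SUFFIXES = (".tif", ".tiff", ".png")


def read_image(path: str | Path) -> tuple[np.ndarray, int]:
    """Read a single-channel grayscale image; return (pixels, bit_depth).

    RGB or multichannel input is rejected: the pipeline contract is one
    intensity channel (the DNA-stain channel) per file.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:
        raise DataError(
            f"{path.name}: image has {arr.shape[-1]} channels; expected a "
            "single-channel grayscale image (split channels upstream)"
        )
    if arr.ndim != 2:
        raise DataError(f"{path.name}: expected a 2-D image, got shape {arr.shape}")
    if arr.dtype == np.uint8:
        depth = 8
    elif arr.dtype == np.uint16:
        depth = 16
    else:
        raise DataError(f"{path.name}: unsupported dtype {arr.dtype} (need uint8/uint16)")
    return arr, depth


def write_image(path: str | Path, pixels: np.ndarray) -> Path:
    """Write a grayscale uint8/uint16 array losslessly (TIFF or PNG)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if pixels.dtype not in (np.dtype(np.uint8), np.dtype(np.uint16)):
        raise ValidationError(f"cannot write dtype {pixels.dtype}; use uint8/uint16")
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, pixels)
    elif path.suffix.lower() == ".png":
        iio.imwrite(path, pixels)
    else:
        raise ValidationError(f"unsupported image suffix {path.suffix!r}")
    return path


# ---------------------------------------------------------------------------
# sidecar IO

def write_sidecar(path: str | Path, coupon: CouponDataset, filenames: Mapping[int, str]) -> Path:
    """Serialize coupon metadata + per-tile table to the sidecar dialect."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    proto = coupon.fields[0] if coupon.fields else None
    meta = {
        "coupon_id": coupon.coupon_id,
        "material": coupon.material,
        "chamber_id": coupon.chamber_id,
        "tray_slot": coupon.tray_slot,
        "trial_id": coupon.trial_id,
        "pixel_scale_um": proto.pixel_scale_um if proto else DEFAULT_PIXEL_SCALE_UM,
        "field_width_mm": proto.field_width_mm if proto else DEFAULT_FIELD_WIDTH_MM,
        "field_height_mm": proto.field_height_mm if proto else DEFAULT_FIELD_HEIGHT_MM,
        "grid_rows": coupon.grid_shape[0],
        "grid_cols": coupon.grid_shape[1],
    }
    rows = []
    for f in sorted(coupon.fields, key=lambda f: f.tile_index):
        rows.append(
            {
                "tile_index": f.tile_index,
                "grid_row": f.grid_row,
                "grid_col": f.grid_col,
                "filename": filenames[f.tile_index],
                "excluded": int(f.tile_index in coupon.excluded_tiles),
                "reason": coupon.excluded_tiles.get(f.tile_index, ""),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["tile_index", "grid_row", "grid_col", "filename", "excluded", "reason"],
    )
    with open(path, "w") as fh:
        for key in _SIDECAR_META_KEYS:
            fh.write(f"# {key}: {meta[key]}\n")
        table.to_csv(fh, index=False)
    return path


def read_sidecar(path: str | Path) -> tuple[dict, pd.DataFrame]:
    """Parse a sidecar file into (metadata dict, per-tile table)."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"sidecar file not found: {path}")
    meta: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
    table = pd.read_csv(path, comment="#", dtype={"filename": str, "reason": str})
    for key in ("pixel_scale_um", "field_width_mm", "field_height_mm"):
        if key in meta:
            meta[key] = float(meta[key])
    for key in ("tray_slot", "grid_rows", "grid_cols"):
        if key in meta:
            meta[key] = int(meta[key])
    if "pixel_scale_um" not in meta and "field_width_mm" not in meta:
        raise ValidationError(
            f"{path.name}: sidecar must declare pixel_scale_um or field size"
        )
    return meta, table


def read_coupon(directory_path: str | Path, sidecar_path: str | Path | None = None) -> CouponDataset:
    """Read one coupon directory plus its sidecar into a CouponDataset.

    Fields come back ordered by tile index and validated against the
    square-pixel and uniqueness invariants. Missing sidecar, an empty
    directory, RGB images and inconsistent geometry all raise with an
    explicit message naming the offender.
    """
    directory = Path(directory_path)
    if not directory.is_dir():
        raise DataError(f"coupon directory not found: {directory}")
    if sidecar_path is None:
        candidates = sorted(directory.glob("*sidecar*.csv")) or sorted(directory.glob("*.sidecar"))
        if not candidates:
            raise ValidationError(
                f"{directory}: no sidecar given and none found (expected *sidecar*.csv)"
            )
        sidecar_path = candidates[0]
    meta, table = read_sidecar(sidecar_path)

    scale = float(meta.get("pixel_scale_um", DEFAULT_PIXEL_SCALE_UM))
    width = float(meta.get("field_width_mm", DEFAULT_FIELD_WIDTH_MM))
    height = float(meta.get("field_height_mm", DEFAULT_FIELD_HEIGHT_MM))

    fields: list[FieldImage] = []
    excluded: dict[int, str] = {}
    for row in table.itertuples(index=False):
        fpath = directory / str(row.filename)
        if not fpath.exists():
            raise DataError(f"listed image missing on disk: {fpath}")
        pixels, depth = read_image(fpath)
        fields.append(
            FieldImage(
                pixels=pixels,
                bit_depth=depth,
                tile_index=int(row.tile_index),
                grid_row=int(row.grid_row),
                grid_col=int(row.grid_col),
                field_width_mm=width,
                field_height_mm=height,
                pixel_scale_um=scale,
            )
        )
        if int(getattr(row, "excluded", 0) or 0):
            reason = str(getattr(row, "reason", "") or "manual")
            excluded[int(row.tile_index)] = reason if reason not in ("", "nan") else "manual"
    if not fields:
        raise DataError(f"{directory}: no fields found")
    fields.sort(key=lambda f: f.tile_index)
    coupon = CouponDataset(
        coupon_id=str(meta.get("coupon_id", directory.name)),
        material=str(meta.get("material", "")),
        chamber_id=str(meta.get("chamber_id", "")),
        tray_slot=int(meta.get("tray_slot", 1)),
        trial_id=str(meta.get("trial_id", "")),
        fields=fields,
        excluded_tiles=excluded,
        grid_shape=(int(meta.get("grid_rows", 15)), int(meta.get("grid_cols", 7))),
    )
    coupon.validate()
    return coupon


# ---------------------------------------------------------------------------
# masks

def write_masks(coupon: CouponDataset, results: Mapping[int, "object"], out_dir: str | Path) -> list[Path]:
    """Write one 0/255 PNG mask per non-excluded field.

    ``results`` maps tile_index to an object with a boolean ``kept_mask``
    attribute of the same shape as the source field. File naming is
    deterministic: ``<coupon_id>_t<tile_index:03d>_mask.png``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for f in coupon.valid_fields:
        if f.tile_index not in results:
            raise ValidationError(
                f"coupon {coupon.coupon_id}: no segmentation result for tile {f.tile_index}"
            )
        mask = np.asarray(results[f.tile_index].kept_mask)
        if mask.shape != f.pixels.shape:
            raise ValidationError(
                f"tile {f.tile_index}: mask shape {mask.shape} != field shape {f.pixels.shape}"
            )
        path = out / f"{coupon.coupon_id}_t{f.tile_index:03d}_mask.png"
        iio.imwrite(path, (mask.astype(np.uint8) * 255))
        paths.append(path)
    return paths


def read_mask(path: str | Path) -> np.ndarray:
    """Read a mask PNG back to a boolean grid."""
    arr = iio.imread(Path(path))
    return np.asarray(arr) > 0


# ---------------------------------------------------------------------------
# geometry report

def derive_geometry(
    layout: ChamberLayout,
    field_prototype: FieldImage | None = None,
    n_images_per_coupon: int = 105,
    size_bounds_px: tuple[int, int] = (6, 400),
) -> dict:
    """Derive the printed geometry numbers from first principles.

    Pure function of its inputs: tray area (cm^2), system capacity,
    per-field area (mm^2), total imaged area per coupon (mm^2), pixel
    area (um^2) and the um^2 equivalents of the object-size filter
    bounds.
    """
    layout.validate()
    if n_images_per_coupon < 1:
        raise ValidationError("n_images_per_coupon must be positive")
    if field_prototype is None:
        field_width, field_height = DEFAULT_FIELD_WIDTH_MM, DEFAULT_FIELD_HEIGHT_MM
        pixel_scale = DEFAULT_PIXEL_SCALE_UM
    else:
        field_width = field_prototype.field_width_mm
        field_height = field_prototype.field_height_mm
        pixel_scale = field_prototype.pixel_scale_um
    if field_width <= 0 or field_height <= 0 or pixel_scale <= 0:
        raise ValidationError("field geometry must be positive")
    field_area_mm2 = field_width * field_height
    pixel_area_um2 = pixel_scale ** 2
    lo, hi = size_bounds_px
    return {
        "tray_area_cm2": round(layout.tray_width_mm * layout.tray_height_mm / 100.0, 1),
        "system_capacity": layout.capacity,
        "field_area_mm2": field_area_mm2,
        "total_imaged_area_mm2": round(n_images_per_coupon * field_area_mm2, 1),
        "pixel_area_um2": pixel_area_um2,
        "min_object_area_um2": round(lo * pixel_area_um2, 1),
        "max_object_area_um2": round(hi * pixel_area_um2, 2),
    }


def flow_metrics(
    injection_volume_ml: float = 4.0,
    injection_interval_min: float = 15.0,
    chamber_volume_ml: float = 140.0,
) -> dict:
    """Medium-supply rates of the flow chamber.

    4 mL injected every 15 min gives 16 mL/h; relative to a 140 mL
    chamber that exchanges roughly 270% of the medium per day.
    """
    if min(injection_volume_ml, injection_interval_min, chamber_volume_ml) <= 0:
        raise ValidationError("flow parameters must be positive")
    rate_ml_per_h = injection_volume_ml * 60.0 / injection_interval_min
    exchange_pct_per_day = rate_ml_per_h * 24.0 / chamber_volume_ml * 100.0
    return {
        "flow_rate_ml_per_h": rate_ml_per_h,
        "daily_exchange_pct": exchange_pct_per_day,
    }
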