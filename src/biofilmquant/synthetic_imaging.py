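"""Synthetic DAPI-like epifluorescence fields with ground truth.

The generator emulates the data regime the pipeline is built for:
sparse, non-overlapping rod-shaped *E. coli* cells rendered as randomly
oriented capsules, bright on a dark background whose intensity histogram
is unimodal (Gaussian read noise around a dark mean, with the cells
forming a thin bright tail). Optional ingredients stress individual
pipeline stages: a linear illumination gradient (per-field vs. pooled
thresholding), sub-size speck and super-size debris artefacts (the
object-size filter), and Gaussian defocus blur (the focus gate).

Cells are placed by rejection sampling with a 1-px exclusion margin so
that ground truth is a clean mono-cell layer: every ground-truth pixel
is attributable to exactly one cell and no two cells merge under
8-connected labeling. Placement stops once the requested coverage is
reached, so realized coverage overshoots the target by at most one cell
footprint.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from .errors import DataError, ValidationError
from .image_io import (
    DEFAULT_PIXEL_SCALE_UM,
    DEFAULT_RASTER,
    CouponDataset,
    FieldImage,
    write_image,
    write_sidecar,
)

COVERAGE_LAWS = ("constant", "gradient", "random")


@dataclass
class SyntheticFieldSpec:
    """Parameters of one synthetic field.

    Intensity units are native camera counts for the given bit depth.
    Artefact size ranges deliberately straddle the 6..400 px object
    filter window: specks stay below it, debris above it.
    """

    raster: tuple[int, int] = DEFAULT_RASTER  # rows, cols
    pixel_scale_um: float = DEFAULT_PIXEL_SCALE_UM
    bit_depth: int = 16
    target_coverage_pct: float = 2.0
    cell_length_um: tuple[float, float] = (1.5, 4.0)
    cell_width_um: tuple[float, float] = (0.7, 1.0)
    cell_intensity_mean: float = 9000.0
    cell_intensity_sd: float = 500.0
    background_mean: float = 900.0
    background_sd: float = 60.0
    illumination_gradient_amplitude: float = 0.0
    n_small_artefacts: int = 0
    n_large_artefacts: int = 0
    small_artefact_area_px: tuple[int, int] = (1, 5)
    large_artefact_area_px: tuple[int, int] = (401, 2000)
    blur_sigma_px: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if min(self.raster) < 8:
            raise ValidationError("raster must be at least 8x8 px")
        if not 0 <= self.target_coverage_pct <= 100:
            raise ValidationError("target coverage must be in [0, 100]")
        if self.cell_intensity_mean <= self.background_mean:
            raise ValidationError(
                "cell intensity mean must exceed background mean (bright-object contract)"
            )
        if self.small_artefact_area_px[1] >= 6:
            raise ValidationError("small artefacts must stay below 6 px")
        if self.large_artefact_area_px[0] <= 400:
            raise ValidationError("large artefacts must exceed 400 px")
        if self.blur_sigma_px < 0:
            raise ValidationError("blur sigma must be >= 0")
        if self.bit_depth not in (8, 16):
            raise ValidationError("bit_depth must be 8 or 16")


def _capsule_stamp(
    length_px: float, width_px: float, angle_rad: float
) -> np.ndarray:
    """Boolean stamp of a capsule (segment dilated to width/2)."""
    half = length_px / 2.0
    r = width_px / 2.0
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    # bounding box half-extents
    hx = abs(c) * half + r + 1
    hy = abs(s) * half + r + 1
    ny, nx = int(np.ceil(2 * hy)) + 1, int(np.ceil(2 * hx)) + 1
    yy, xx = np.mgrid[0:ny, 0:nx]
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    dx, dy = xx - cx, yy - cy
    # distance from pixel centre to the capsule's axis segment
    t = np.clip(dx * c + dy * s, -half, half)
    px, py = t * c, t * s
    dist2 = (dx - px) ** 2 + (dy - py) ** 2
    return dist2 <= r * r


def _blob_stamp(area_px: int, rng: np.random.Generator) -> np.ndarray:
    """Roughly elliptical debris blob of at least ``area_px`` pixels.

    Discretizing an ellipse of nominal area ``area_px`` can undershoot
    by a few pixels, which would let a nominally super-size blob slip
    under the size filter; the axes are therefore inflated until the
    realized pixel count reaches the request.
    """
    aspect = rng.uniform(1.0, 2.5)
    angle = rng.uniform(0, np.pi)
    c, s = np.cos(angle), np.sin(angle)
    a = np.sqrt(area_px * aspect / np.pi)
    for _ in range(100):
        b = a / aspect
        h = int(np.ceil(2 * max(a, b))) + 3
        yy, xx = np.mgrid[0:h, 0:h]
        dy, dx = yy - (h - 1) / 2.0, xx - (h - 1) / 2.0
        u = dx * c + dy * s
        v = -dx * s + dy * c
        stamp = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        if int(stamp.sum()) >= area_px:
            return stamp
        a *= 1.04
    return stamp


def _place_stamp(
    stamp: np.ndarray,
    forbidden: np.ndarray,
    rng: np.random.Generator,
    max_attempts: int,
    allow_border: bool = True,
) -> tuple[np.ndarray, np.ndarray] | None:
    """Try to place ``stamp`` without touching ``forbidden``; returns the
    placed pixel coordinates (rows, cols) or None after max_attempts."""
    h, w = stamp.shape
    H, W = forbidden.shape
    sy, sx = np.nonzero(stamp)
    for _ in range(max_attempts):
        if allow_border:
            top = rng.integers(-h + 1, H)
            left = rng.integers(-w + 1, W)
        else:
            if H <= h or W <= w:
                return None
            top = rng.integers(0, H - h)
            left = rng.integers(0, W - w)
        rows = sy + top
        cols = sx + left
        inside = (rows >= 0) & (rows < H) & (cols >= 0) & (cols < W)
        if not inside.any():
            continue
        rows, cols = rows[inside], cols[inside]
        if forbidden[rows, cols].any():
            continue
        return rows, cols
    return None


_NEIGH8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1), (0, 0)]


def _mark(forbidden: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> None:
    """Mark placed pixels plus their 8-neighbourhood as forbidden (1-px margin)."""
    H, W = forbidden.shape
    for dr, dc in _NEIGH8:
        r = rows + dr
        c = cols + dc
        ok = (r >= 0) & (r < H) & (c >= 0) & (c < W)
        forbidden[r[ok], c[ok]] = True


def generate_field(
    spec: SyntheticFieldSpec,
    tile_index: int = 0,
    grid_row: int = 0,
    grid_col: int = 0,
) -> tuple[FieldImage, np.ndarray, np.ndarray]:
    """Render one field; returns (FieldImage, cell mask, artefact mask).

    Deterministic given ``spec.seed``. The cell and artefact masks are
    disjoint ground truth; reported true coverage is the cell-mask pixel
    fraction only. Raises :class:`DataError` when the requested coverage
    cannot be placed without overlap within a bounded number of retries.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    H, W = spec.raster
    n_px = H * W
    scale = spec.pixel_scale_um

    cell_mask = np.zeros((H, W), dtype=bool)
    artefact_mask = np.zeros((H, W), dtype=bool)
    forbidden = np.zeros((H, W), dtype=bool)

    target_px = int(round(spec.target_coverage_pct / 100.0 * n_px))
    placed_px = 0
    mean_cell_px = (
        np.mean(spec.cell_length_um) * np.mean(spec.cell_width_um) / scale**2
    )
    budget = int(200 * (target_px / max(mean_cell_px, 1.0) + 10))
    attempts_left = budget
    while placed_px < target_px:
        if attempts_left <= 0:
            raise DataError(
                f"could not reach {spec.target_coverage_pct}% coverage without "
                "overlap; lower the target coverage or enlarge the raster"
            )
        length = rng.uniform(*spec.cell_length_um) / scale
        width = rng.uniform(*spec.cell_width_um) / scale
        angle = rng.uniform(0, np.pi)
        stamp = _capsule_stamp(length, width, angle)
        placed = _place_stamp(stamp, forbidden, rng, max_attempts=50)
        attempts_left -= 1
        if placed is None:
            continue
        rows, cols = placed
        cell_mask[rows, cols] = True
        _mark(forbidden, rows, cols)
        placed_px += rows.size

    for _ in range(spec.n_small_artefacts):
        area = int(rng.integers(spec.small_artefact_area_px[0], spec.small_artefact_area_px[1] + 1))
        stamp = np.zeros((3, 3), dtype=bool)
        order = rng.permutation(9)[:area]
        stamp.flat[np.sort(order)] = True
        # keep specks connected: fall back to a straight run of pixels
        if ndi.label(stamp, structure=np.ones((3, 3)))[1] != 1:
            stamp = np.zeros((1, 5), dtype=bool)
            stamp[0, :area] = True
        placed = _place_stamp(stamp, forbidden, rng, max_attempts=100)
        if placed is not None:
            rows, cols = placed
            artefact_mask[rows, cols] = True
            _mark(forbidden, rows, cols)

    for _ in range(spec.n_large_artefacts):
        area = int(rng.integers(spec.large_artefact_area_px[0], spec.large_artefact_area_px[1] + 1))
        stamp = _blob_stamp(area, rng)
        placed = _place_stamp(stamp, forbidden, rng, max_attempts=100, allow_border=False)
        if placed is not None:
            rows, cols = placed
            artefact_mask[rows, cols] = True
            _mark(forbidden, rows, cols)

    # intensities: dark unimodal background + bright objects
    img = rng.normal(spec.background_mean, spec.background_sd, size=(H, W))
    if spec.illumination_gradient_amplitude:
        ramp = np.linspace(
            -spec.illumination_gradient_amplitude / 2.0,
            spec.illumination_gradient_amplitude / 2.0,
            W,
        )
        img *= 1.0 + ramp[None, :]
    bright = cell_mask | artefact_mask
    n_bright = int(bright.sum())
    if n_bright:
        base = rng.normal(spec.cell_intensity_mean, spec.cell_intensity_sd, size=n_bright)
        # Poisson-like shot noise on object pixels
        base += rng.normal(0.0, np.sqrt(np.clip(base, 1.0, None)))
        img[bright] = base
    if spec.blur_sigma_px > 0:
        img = ndi.gaussian_filter(img, spec.blur_sigma_px)
    maxval = (1 << spec.bit_depth) - 1
    img = np.clip(np.rint(img), 0, maxval)
    pixels = img.astype(np.uint16 if spec.bit_depth == 16 else np.uint8)

    field = FieldImage(
        pixels=pixels,
        bit_depth=spec.bit_depth,
        tile_index=tile_index,
        grid_row=grid_row,
        grid_col=grid_col,
        field_width_mm=W * scale * 1e-3,
        field_height_mm=H * scale * 1e-3,
        pixel_scale_um=scale,
    )
    return field, cell_mask, artefact_mask


def generate_coupon(
    n_fields: int,
    spec: SyntheticFieldSpec,
    coverage_law: str = "constant",
    gradient_rel_slope: float = 1.0,
    random_rel_sd: float = 0.25,
    grid_shape: tuple[int, int] | None = None,
    coupon_id: str = "SYN01",
    material: str = "synthetic",
    chamber_id: str = "FC1",
    tray_slot: int = 1,
    trial_id: str = "T1",
    seed: int | None = None,
) -> tuple[CouponDataset, pd.DataFrame]:
    """Generate a whole coupon: ``n_fields`` tiles plus a truth table.

    The per-field target coverage follows one of three laws around
    ``spec.target_coverage_pct``:

    - ``constant``: every field gets the same target;
    - ``gradient``: a linear ramp along the acquisition-grid rows
      (the flow axis), spanning ``gradient_rel_slope`` of the mean from
      first to last row — emulates a wave-like colonization pattern;
    - ``random``: per-field lognormal variation with relative sd
      ``random_rel_sd`` — emulates patchy colonization.

    Grid positions are filled row-major. The truth table has one row per
    field with target and realized (pixel-counted) coverage percent.
    """
    if n_fields < 1:
        raise ValidationError("n_fields must be >= 1")
    if coverage_law not in COVERAGE_LAWS:
        raise ValidationError(f"unknown coverage law {coverage_law!r}; use one of {COVERAGE_LAWS}")
    if grid_shape is None:
        ncols = max(1, int(np.ceil(np.sqrt(n_fields / 2.0))))
        nrows = int(np.ceil(n_fields / ncols))
        grid_shape = (nrows, ncols)
    nrows, ncols = grid_shape
    if nrows * ncols < n_fields:
        raise ValidationError(f"grid {grid_shape} too small for {n_fields} fields")

    root_seed = spec.seed if seed is None else seed
    ss = np.random.SeedSequence(root_seed)
    field_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_fields + 1)]
    law_rng = np.random.default_rng(field_seeds[-1])

    base = spec.target_coverage_pct
    targets = np.full(n_fields, base, dtype=float)
    rows_of = np.arange(n_fields) // ncols
    if coverage_law == "gradient" and nrows > 1:
        frac = rows_of / (nrows - 1)
        targets = base * (1.0 + gradient_rel_slope * (frac - 0.5))
    elif coverage_law == "random":
        sigma = np.sqrt(np.log1p(random_rel_sd**2))
        targets = base * law_rng.lognormal(-sigma**2 / 2.0, sigma, size=n_fields)
    targets = np.clip(targets, 0.0, 50.0)

    fields: list[FieldImage] = []
    truth_rows = []
    n_px = spec.raster[0] * spec.raster[1]
    for i in range(n_fields):
        fspec = replace(spec, target_coverage_pct=float(targets[i]), seed=field_seeds[i])
        field, cell_mask, _ = generate_field(
            fspec, tile_index=i, grid_row=int(rows_of[i]), grid_col=int(i % ncols)
        )
        fields.append(field)
        truth_rows.append(
            {
                "coupon_id": coupon_id,
                "tile_index": i,
                "grid_row": int(rows_of[i]),
                "grid_col": int(i % ncols),
                "target_pct": float(targets[i]),
                "true_pct": cell_mask.sum() / n_px * 100.0,
            }
        )
    coupon = CouponDataset(
        coupon_id=coupon_id,
        material=material,
        chamber_id=chamber_id,
        tray_slot=tray_slot,
        trial_id=trial_id,
        fields=fields,
        excluded_tiles={},
        grid_shape=grid_shape,
    )
    return coupon, pd.DataFrame(truth_rows)


def write_coupon(
    coupon: CouponDataset,
    out_dir: str | Path,
    truth: pd.DataFrame | None = None,
    image_format: str = "tif",
) -> Path:
    """Write a coupon to the directory+sidecar layout ``read_coupon`` reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    filenames = {}
    for f in coupon.fields:
        name = f"{coupon.coupon_id}_t{f.tile_index:03d}.{image_format}"
        write_image(out / name, f.pixels)
        filenames[f.tile_index] = name
    write_sidecar(out / f"{coupon.coupon_id}_sidecar.csv", coupon, filenames)
    if truth is not None:
        truth.to_csv(out / "truth.csv", index=False)
    return out
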