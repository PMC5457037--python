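"""Overview mosaics, colonization fingerprints and the position-trend test.

An overview mosaic lays the original tiles of one coupon out on the
acquisition grid with the kept segmented objects outlined, so image
quality and segmentation can be judged at a glance; invalid tiles are
struck through rather than dropped. A fingerprint is the positional
matrix of per-field coverage percent for a coupon (blank where the field
is invalid); arranging the eight coupon matrices of a chamber side by
side with the flow-inlet arrow exposes any spatial colonization pattern.

Whether colonization depends on coupon position along the flow axis is
made assertable by a permutation test on the rank correlation between
tray slot and pooled coupon coverage.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats
from skimage import transform

from .errors import DataError, ValidationError
from .image_io import ChamberLayout, CouponDataset
from .quantification import CouponSummary, CoverageRecord
from .segmentation import SegmentationResult


@dataclass
class OverviewMosaic:
    pixels: np.ndarray          # RGB uint8, (rows*th + gutters) x (cols*tw + gutters)
    index: pd.DataFrame         # tile -> mosaic coordinates + labels
    grid_shape: tuple[int, int]
    thumb_shape: tuple[int, int]
    gutter_px: int


def mosaic_raster_shape(
    grid_shape: tuple[int, int], thumb_shape: tuple[int, int], gutter_px: int = 0
) -> tuple[int, int]:
    """Output raster of a mosaic: pure arithmetic on the layout."""
    gr, gc = grid_shape
    th, tw = thumb_shape
    return gr * th + (gr - 1) * gutter_px, gc * tw + (gc - 1) * gutter_px


def _outline(mask: np.ndarray) -> np.ndarray:
    """One-pixel outer edge of a boolean mask (4-neighbour difference)."""
    if not mask.any():
        return np.zeros_like(mask)
    core = mask.copy()
    core[1:, :] &= mask[:-1, :]
    core[:-1, :] &= mask[1:, :]
    core[:, 1:] &= mask[:, :-1]
    core[:, :-1] &= mask[:, 1:]
    return mask & ~core


def build_overview(
    coupon: CouponDataset,
    results: Mapping[int, SegmentationResult],
    records: Mapping[int, CoverageRecord],
    thumb_shape: tuple[int, int] = (96, 128),
    gutter_px: int = 0,
    outline_rgb: tuple[int, int, int] = (255, 64, 64),
) -> OverviewMosaic:
    """Assemble the per-coupon overview mosaic.

    Tiles are placed at their acquisition-grid position (row-major by
    tile index when grid positions are degenerate). Every tile of the
    coupon appears; invalid/excluded tiles get a diagonal strike-through
    instead of an overlay and carry no coverage label. A segmentation
    result must exist for every non-excluded field.
    """
    if not coupon.fields:
        raise DataError(f"coupon {coupon.coupon_id} has no fields")
    gr, gc = coupon.grid_shape
    if gr * gc < len(coupon.fields):
        raise ValidationError(
            f"grid {coupon.grid_shape} too small for {len(coupon.fields)} tiles"
        )
    th, tw = thumb_shape
    H, W = mosaic_raster_shape((gr, gc), (th, tw), gutter_px)
    canvas = np.zeros((H, W, 3), dtype=np.uint8)
    rows = []
    positions = {(f.grid_row, f.grid_col) for f in coupon.fields}
    use_grid = len(positions) == len(coupon.fields)
    for f in sorted(coupon.fields, key=lambda f: f.tile_index):
        if use_grid:
            r, c = f.grid_row, f.grid_col
        else:
            r, c = divmod(f.tile_index, gc)
        if not (0 <= r < gr and 0 <= c < gc):
            raise ValidationError(
                f"tile {f.tile_index}: grid position ({r}, {c}) outside {coupon.grid_shape}"
            )
        excluded = f.tile_index in coupon.excluded_tiles
        rec = records.get(f.tile_index)
        invalid = excluded or (rec is not None and not rec.valid)
        if not excluded and f.tile_index not in results:
            raise ValidationError(
                f"coupon {coupon.coupon_id}: missing segmentation result for "
                f"tile {f.tile_index}"
            )
        # stretch raw intensities for display only (quantification never sees this)
        img = f.pixels.astype(float)
        lo, hi = np.percentile(img, (1, 99.9))
        disp = np.clip((img - lo) / max(hi - lo, 1.0), 0, 1)
        thumb = transform.resize(disp, (th, tw), order=1, anti_aliasing=True)
        rgb = np.repeat((thumb * 255).astype(np.uint8)[..., None], 3, axis=2)
        if not invalid and f.tile_index in results:
            edge = _outline(results[f.tile_index].kept_mask)
            edge_small = transform.resize(edge.astype(float), (th, tw), order=0) > 0
            rgb[edge_small] = outline_rgb
        if invalid:  # diagonal strike-through marker
            npts = max(th, tw)
            rr = np.linspace(0, th - 1, npts).astype(int)
            cc = np.linspace(0, tw - 1, npts).astype(int)
            for off in (-1, 0, 1):
                rgb[rr, np.clip(cc + off, 0, tw - 1)] = (255, 255, 0)
        top, left = r * (th + gutter_px), c * (tw + gutter_px)
        canvas[top : top + th, left : left + tw] = rgb
        cov = rec.coverage_pct if (rec is not None and rec.valid) else None
        rows.append(
            {
                "tile_index": f.tile_index,
                "grid_row": r,
                "grid_col": c,
                "mosaic_top": top,
                "mosaic_left": left,
                "valid": not invalid,
                "coverage_pct": np.nan if cov is None else cov,
            }
        )
    return OverviewMosaic(
        pixels=canvas,
        index=pd.DataFrame(rows),
        grid_shape=(gr, gc),
        thumb_shape=(th, tw),
        gutter_px=gutter_px,
    )


def save_overview(mosaic: OverviewMosaic, png_path: str | Path, csv_path: str | Path | None = None) -> None:
    import imageio.v3 as iio

    png_path = Path(png_path)
    png_path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(png_path, mosaic.pixels)
    if csv_path is not None:
        mosaic.index.to_csv(csv_path, index=False)


# ---------------------------------------------------------------------------
# fingerprints

def build_fingerprint(
    records: Sequence[CoverageRecord],
    grid_shape: tuple[int, int],
    grid_positions: Mapping[int, tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Positional matrix of per-field coverage percent for one coupon.

    Cells of invalid fields are NaN (rendered blank). ``grid_positions``
    maps tile_index to (row, col); by default tiles fill the grid
    row-major by tile index.
    """
    gr, gc = grid_shape
    if gr * gc < len(records):
        raise ValidationError(f"grid {grid_shape} too small for {len(records)} fields")
    mat = np.full((gr, gc), np.nan)
    for rec in records:
        if grid_positions is not None:
            r, c = grid_positions[rec.tile_index]
        else:
            r, c = divmod(rec.tile_index, gc)
        if not (0 <= r < gr and 0 <= c < gc):
            raise ValidationError(f"tile {rec.tile_index}: position ({r}, {c}) off grid")
        if rec.valid:
            mat[r, c] = rec.coverage_pct
    return pd.DataFrame(mat, index=pd.RangeIndex(gr, name="grid_row"),
                        columns=pd.RangeIndex(gc, name="grid_col"))


def save_fingerprint_figure(
    fingerprints: Mapping[str, pd.DataFrame],
    png_path: str | Path,
    layout: ChamberLayout | None = None,
    vmin: float | None = None,
    vmax: float | None = None,
    cmap: str = "Blues",
    annotate: bool = True,
) -> None:
    """Render one or more coupon fingerprints with shared color limits.

    All coupons in one figure share vmin/vmax so their shading is
    comparable (the point of a fingerprint panel). Grid shapes must
    match across coupons. The flow-inlet arrow is drawn per the chamber
    layout.
    """
    if not fingerprints:
        raise DataError("no fingerprints to draw")
    shapes = {df.shape for df in fingerprints.values()}
    if len(shapes) > 1:
        raise ValidationError(f"mismatched fingerprint grids in one figure: {shapes}")
    stacked = np.concatenate([df.to_numpy().ravel() for df in fingerprints.values()])
    finite = stacked[np.isfinite(stacked)]
    if vmin is None:
        vmin = float(finite.min()) if finite.size else 0.0
    if vmax is None:
        vmax = float(finite.max()) if finite.size else 1.0
    n = len(fingerprints)
    fig, axes = plt.subplots(1, n, figsize=(2.2 * n + 1.5, 4.0), squeeze=False)
    for ax, (cid, df) in zip(axes[0], fingerprints.items()):
        im = ax.imshow(df.to_numpy(), cmap=cmap, vmin=vmin, vmax=vmax)
        ax.set_title(cid, fontsize=8)
        ax.set_xticks([])
        ax.set_yticks([])
        if annotate and df.size <= 200:
            for (r, c), v in np.ndenumerate(df.to_numpy()):
                if np.isfinite(v):
                    ax.text(c, r, f"{v:.1f}", ha="center", va="center", fontsize=5)
    side = layout.flow_inlet_side if layout is not None else "left"
    arrows = {"left": "inlet >", "right": "< inlet", "top": "inlet v", "bottom": "inlet ^"}
    fig.suptitle(f"flow {arrows.get(side, side)}", fontsize=9)
    fig.colorbar(im, ax=axes[0].tolist(), shrink=0.8, label="coverage %")
    png_path = Path(png_path)
    png_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(png_path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# position-independence

def position_trend_test(
    summaries: Sequence[CouponSummary],
    positions: Mapping[str, float] | None = None,
    n_permutations: int = 9999,
    seed: int = 0,
) -> dict:
    """Permutation test for a coverage trend along the flow axis.

    The statistic is the Spearman rank correlation between coupon
    position (tray slot along the flow axis by default) and pooled
    coupon coverage; the null distribution comes from permuting the
    position labels. Two-sided p with the add-one correction, so p is
    never exactly 0 and is exchangeable under relabeling.
    """
    if len(summaries) < 3:
        raise DataError("position trend test needs at least 3 coupons")
    if n_permutations < 1:
        raise ValidationError("n_permutations must be >= 1")
    cov = np.array([s.pooled_pct for s in summaries], dtype=float)
    if positions is None:
        pos = np.arange(len(summaries), dtype=float)
    else:
        pos = np.array([positions[s.coupon_id] for s in summaries], dtype=float)
    # Spearman rho = Pearson correlation of ranks; precompute ranks once so
    # the permutation loop is a single matrix product.
    rp = stats.rankdata(pos)
    rc = stats.rankdata(cov)
    zp = (rp - rp.mean())
    zc = (rc - rc.mean())
    denom = np.sqrt((zp**2).sum() * (zc**2).sum())
    if denom == 0:
        return {"statistic": 0.0, "p_value": 1.0, "n_coupons": len(summaries),
                "n_permutations": n_permutations}
    rho = float(zp @ zc / denom)
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(zp) for _ in range(n_permutations)])
    null = perms @ zc / denom
    hits = int(np.sum(np.abs(null) >= abs(rho) - 1e-12))
    p = (hits + 1) / (n_permutations + 1)
    return {"statistic": float(rho), "p_value": float(p), "n_coupons": len(summaries),
            "n_permutations": n_permutations}
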