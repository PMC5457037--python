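"""Per-field binarization and object-size filtering.

Each microscope field is thresholded independently with the triangle
algorithm: on the intensity histogram, a line is drawn from the global
peak (the dark background mode of a DAPI field) to the farthest occupied
intensity on the bright side, and the threshold is placed at the level
where the perpendicular distance between histogram and line is maximal.
The method assumes a unimodal histogram — a dominant background mode
with a sparse bright tail of stained cells — which is exactly the regime
of sparse mono-layer colonization.

Connected components of the thresholded mask are then filtered by area:
objects outside the configured window (default 6..400 px, i.e. roughly
1.4–94.5 um^2 at 0.486 um/px) are treated as artefacts (sub-cellular
specks, debris, aggregates) and removed. Both bounds are inclusive:
objects *smaller than* 6 px or *larger than* 400 px are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage import measure

from .errors import DegenerateHistogramError, ValidationError
from .image_io import FieldImage

DEFAULT_SIZE_BOUNDS = (6, 400)


@dataclass
class SegmentationResult:
    """Threshold, masks and the labeled-object table for one field.

    ``objects`` has one row per connected component of the raw mask with
    columns ``label, area_px, area_um2, centroid_row, centroid_col,
    bbox_min_row, bbox_min_col, bbox_max_row, bbox_max_col, kept``.
    ``kept_mask`` contains only objects inside the size window.
    """

    tile_index: int
    threshold: int
    raw_mask: np.ndarray
    kept_mask: np.ndarray
    objects: pd.DataFrame
    size_bounds: tuple[int, int] = DEFAULT_SIZE_BOUNDS
    connectivity: int = 8

    @property
    def kept_area_px(self) -> int:
        return int(self.kept_mask.sum())


def intensity_histogram(field: FieldImage) -> np.ndarray:
    """Histogram over the image's native intensity range (one bin/level)."""
    counts = np.bincount(field.pixels.ravel(), minlength=field.n_levels)
    if counts.size > field.n_levels:
        raise ValidationError(
            f"tile {field.tile_index}: intensities exceed {field.bit_depth}-bit range"
        )
    return counts


def triangle_threshold(counts: np.ndarray, polarity: str = "bright") -> int:
    """Triangle-algorithm threshold of an intensity histogram.

    The histogram is normalized to the unit square — intensity axis
    from the peak to the farthest occupied tail bin mapped to [0, 1],
    count axis divided by the peak count — so the result is invariant
    to bit depth and to uniform scaling of the counts. The line runs
    from the normalized peak (0, 1) to the tail end, and the threshold
    is the level of maximal perpendicular distance below that line.
    Ties are broken toward the peak (most conservative threshold).

    ``polarity`` selects which side of the peak holds the objects:
    "bright" (default, stained cells on dark background) or "dark"
    (computed by reflecting the histogram about the range midpoint).

    Returns the threshold as an intensity level; for bright polarity the
    object mask is ``pixels > t``, for dark polarity ``pixels < t``.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1 or counts.size < 2:
        raise ValidationError("histogram must be a 1-D array of >= 2 levels")
    if (counts < 0).any():
        raise ValidationError("histogram counts must be non-negative")
    nonzero = np.flatnonzero(counts)
    if nonzero.size < 2:
        raise DegenerateHistogramError(
            "histogram occupies fewer than two intensity levels; no threshold exists"
        )
    if polarity == "dark":
        flipped = triangle_threshold(counts[::-1], polarity="bright")
        return (counts.size - 1) - flipped
    if polarity != "bright":
        raise ValidationError(f"unknown polarity {polarity!r}")

    peak = int(np.argmax(counts))
    tail = int(nonzero[-1])
    if tail <= peak:
        # no occupied bins on the bright side of the peak
        raise DegenerateHistogramError(
            "histogram has no bright tail beyond its peak; cannot threshold "
            "bright objects"
        )
    span = tail - peak
    idx = np.arange(peak, tail + 1)
    x = (idx - peak) / span
    y = counts[peak : tail + 1] / counts[peak]
    y_tail = y[-1]
    # signed area-style distance: positive where the histogram dips below
    # the peak-to-tail chord; the common 1/|line| factor is constant and
    # does not move the argmax.
    d = (y_tail - 1.0) * x - (y - 1.0)
    best = int(np.flatnonzero(d == d.max())[0])  # first max = closest to peak
    return peak + best


def _to_skimage_connectivity(connectivity: int) -> int:
    if connectivity == 8:
        return 2
    if connectivity == 4:
        return 1
    raise ValidationError(f"connectivity must be 4 or 8, got {connectivity}")


def segment_field(
    field: FieldImage,
    size_bounds: tuple[int, int] = DEFAULT_SIZE_BOUNDS,
    polarity: str = "bright",
    connectivity: int = 8,
) -> SegmentationResult:
    """Threshold one field and size-filter its connected components.

    The threshold is computed from this field's own histogram — never
    pooled across fields — so illumination differences between tiles do
    not bleed into each other. Labeling uses 8-connectivity by default
    (diagonal pixels of a thin rod belong to one cell). Border-touching
    objects are kept, subject to the size window, because coverage is an
    area fraction rather than a count.
    """
    lo, hi = size_bounds
    if lo < 1 or hi < lo:
        raise ValidationError(f"invalid size bounds ({lo}, {hi}): need 1 <= min <= max")
    counts = intensity_histogram(field)
    t = triangle_threshold(counts, polarity=polarity)
    if polarity == "bright":
        raw_mask = field.pixels > t
    else:
        raw_mask = field.pixels < t

    labels, n_labels = measure.label(
        raw_mask, connectivity=_to_skimage_connectivity(connectivity), return_num=True
    )
    if n_labels:
        props = measure.regionprops_table(
            labels, properties=("label", "area", "centroid", "bbox")
        )
        objects = pd.DataFrame(props).rename(
            columns={
                "area": "area_px",
                "centroid-0": "centroid_row",
                "centroid-1": "centroid_col",
                "bbox-0": "bbox_min_row",
                "bbox-1": "bbox_min_col",
                "bbox-2": "bbox_max_row",
                "bbox-3": "bbox_max_col",
            }
        )
        objects["area_px"] = objects["area_px"].astype(int)
        objects["area_um2"] = objects["area_px"] * field.pixel_area_um2
        objects["kept"] = (objects["area_px"] >= lo) & (objects["area_px"] <= hi)
        lut = np.zeros(n_labels + 1, dtype=bool)
        lut[objects.loc[objects["kept"], "label"].to_numpy()] = True
        kept_mask = lut[labels]
    else:
        objects = pd.DataFrame(
            columns=[
                "label", "area_px", "centroid_row", "centroid_col",
                "bbox_min_row", "bbox_min_col", "bbox_max_row", "bbox_max_col",
                "area_um2", "kept",
            ]
        )
        kept_mask = np.zeros_like(raw_mask)

    return SegmentationResult(
        tile_index=field.tile_index,
        threshold=int(t),
        raw_mask=raw_mask,
        kept_mask=kept_mask,
        objects=objects,
        size_bounds=(lo, hi),
        connectivity=connectivity,
    )


def focus_metric(pixels: np.ndarray) -> float:
    """Relative high-frequency content: var(Laplacian) / var(image).

    Defocus suppresses the high-frequency response much faster than the
    overall contrast, so blurred fields score low. Dimensionless and
    invariant to affine intensity rescaling.
    """
    img = np.asarray(pixels, dtype=float)
    v = img.var()
    if v == 0:
        return 0.0
    return float(ndi.laplace(img).var() / v)


#: Default focus cut-off. A noisy in-focus DAPI field has a Laplacian
#: variance of the same order as the image variance (>~1); Gaussian
#: defocus of a few pixels pushes the ratio well below 0.1.
DEFAULT_BLUR_THRESHOLD = 0.1


def flag_invalid_field(
    field: FieldImage,
    result: SegmentationResult | None,
    blur_metric_threshold: float = DEFAULT_BLUR_THRESHOLD,
    excluded_tiles: dict[int, str] | None = None,
) -> tuple[bool, str | None]:
    """Decide whether a field enters downstream aggregation.

    Returns ``(valid, reason)``. A field is invalid if it was manually
    excluded, its histogram was degenerate (``result is None``), or its
    focus metric falls below the blur threshold. Invalid fields are kept
    in reports (rendered blank/struck) but never aggregated.
    """
    excluded_tiles = excluded_tiles or {}
    if field.tile_index in excluded_tiles:
        return False, f"manual: {excluded_tiles[field.tile_index]}"
    if result is None:
        return False, "degenerate histogram"
    if focus_metric(field.pixels) < blur_metric_threshold:
        return False, "blur"
    return True, None
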