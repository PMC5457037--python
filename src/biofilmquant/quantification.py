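"""Surface-coverage and sampling-effort statistics.

Coverage of one field is the kept (size-filtered) segmented area A over
the reference area Aref of the full raster, reported in percent,
A/Aref*100. Coupon-level coverage pools areas over valid fields,
sum(A)/sum(Aref)*100 — the area-true definition, which coincides with
the mean of per-field percentages when all fields share one raster.

To decide how many fields suffice for a stable estimate, the cumulative
coefficient of variation CV_k = sd(x_1..x_k)/mean(x_1..x_k)*100 is
tracked over the first k fields in acquisition order; the minimum image
number is the smallest k from which the curve stays at or below a target
CV (13% by default). Because acquisition order is arbitrary, an
order-permuted envelope of the curve is also available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, ValidationError
from .image_io import FieldImage
from .segmentation import SegmentationResult

DEFAULT_TARGET_CV_PCT = 13.0


@dataclass
class CoverageRecord:
    """Per-field coverage: kept area A, reference area Aref, percent."""

    coupon_id: str
    tile_index: int
    area_px: int
    aref_px: int
    pixel_area_um2: float
    valid: bool = True
    invalid_reason: str | None = None

    @property
    def area_um2(self) -> float:
        return self.area_px * self.pixel_area_um2

    @property
    def aref_um2(self) -> float:
        return self.aref_px * self.pixel_area_um2

    @property
    def coverage_pct(self) -> float | None:
        """A/Aref*100; None for invalid fields (no coverage value)."""
        if not self.valid:
            return None
        return self.area_px / self.aref_px * 100.0


@dataclass
class CouponSummary:
    coupon_id: str
    pooled_pct: float
    mean_pct: float
    sd_pct: float
    n_valid: int
    n_total: int


@dataclass
class CvCurve:
    """Cumulative CV (%) versus number of images, k = 2..n."""

    coupon_id: str
    k: np.ndarray        # image counts, 2..n
    cv_pct: np.ndarray   # CV_k in percent
    target_cv_pct: float = DEFAULT_TARGET_CV_PCT


def field_coverage(
    result: SegmentationResult | None,
    field: FieldImage,
    coupon_id: str = "",
    valid: bool = True,
    invalid_reason: str | None = None,
) -> CoverageRecord:
    """Coverage record for one field: A = kept-mask pixel sum, Aref = raster.

    Full precision is retained; rounding happens only at report time.
    """
    aref = int(np.prod(field.shape))
    if aref <= 0:
        raise ValidationError(f"tile {field.tile_index}: empty raster")
    if result is None or not valid:
        return CoverageRecord(
            coupon_id=coupon_id,
            tile_index=field.tile_index,
            area_px=0,
            aref_px=aref,
            pixel_area_um2=field.pixel_area_um2,
            valid=False,
            invalid_reason=invalid_reason or "invalid",
        )
    area = result.kept_area_px
    if not 0 <= area <= aref:
        raise DataError(f"tile {field.tile_index}: kept area {area} outside [0, {aref}]")
    return CoverageRecord(
        coupon_id=coupon_id,
        tile_index=field.tile_index,
        area_px=area,
        aref_px=aref,
        pixel_area_um2=field.pixel_area_um2,
        valid=True,
    )


def _valid_records(records: Iterable[CoverageRecord]) -> list[CoverageRecord]:
    return [r for r in records if r.valid]


def coupon_coverage(records: Sequence[CoverageRecord]) -> CouponSummary:
    """Pool coverage over the valid fields of one coupon.

    Pooled coverage sum(A)/sum(Aref)*100 is the primary summary; the
    mean/sd of per-field percentages are reported alongside (identical
    to the pooled value when all rasters are equal).
    """
    valid = _valid_records(records)
    if not valid:
        raise DataError("coupon has no valid images")
    coupon_id = valid[0].coupon_id
    total_a = sum(r.area_px for r in valid)
    total_ref = sum(r.aref_px for r in valid)
    pcts = np.array([r.coverage_pct for r in valid], dtype=float)
    return CouponSummary(
        coupon_id=coupon_id,
        pooled_pct=total_a / total_ref * 100.0,
        mean_pct=float(pcts.mean()),
        sd_pct=float(pcts.std(ddof=1)) if len(pcts) > 1 else 0.0,
        n_valid=len(valid),
        n_total=len(records),
    )


def _cumulative_cv_values(x: np.ndarray, ddof: int = 1) -> np.ndarray:
    """CV_k in percent for k = 2..n over a coverage series."""
    n = x.size
    ks = np.arange(2, n + 1)
    csum = np.cumsum(x)
    csum2 = np.cumsum(x * x)
    means = csum[1:] / ks
    if means[-1] <= 0:
        raise DataError("cumulative CV undefined: coverage series is all zero")
    # sample variance from running sums; clip tiny negative round-off
    var = (csum2[1:] - ks * means ** 2) / (ks - ddof)
    var = np.clip(var, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.sqrt(var) / means * 100.0
    cv[means <= 0] = np.nan  # undefined while the running mean is zero
    return cv


def cumulative_cv(
    records: Sequence[CoverageRecord],
    target_cv_pct: float = DEFAULT_TARGET_CV_PCT,
    ddof: int = 1,
) -> CvCurve:
    """Cumulative variation coefficient over valid fields in acquisition order.

    Uses the sample standard deviation (n-1 denominator) by default;
    ``ddof=0`` gives the population form.
    """
    valid = sorted(_valid_records(records), key=lambda r: r.tile_index)
    if len(valid) < 2:
        raise DataError("cumulative CV needs at least 2 valid fields")
    x = np.array([r.coverage_pct for r in valid], dtype=float)
    cv = _cumulative_cv_values(x, ddof=ddof)
    return CvCurve(
        coupon_id=valid[0].coupon_id,
        k=np.arange(2, len(valid) + 1),
        cv_pct=cv,
        target_cv_pct=target_cv_pct,
    )


def min_image_number(
    curve: CvCurve,
    target_cv_pct: float | None = None,
    mode: str = "sustained",
) -> int | None:
    """Smallest number of images achieving the target CV.

    In ``sustained`` mode (default) the smallest k such that CV_j <=
    target for every j >= k — the curve must *stay* at or below the
    target. ``first-crossing`` returns the first k with CV_k <= target,
    which can fire spuriously early on a noisy curve. Returns ``None``
    when the target is never reached.
    """
    if target_cv_pct is None:
        target_cv_pct = curve.target_cv_pct
    if target_cv_pct <= 0:
        raise ValidationError("target CV must be positive")
    if curve.cv_pct.size == 0:
        raise ValidationError("empty CV curve")
    below = curve.cv_pct <= target_cv_pct
    if mode == "first-crossing":
        hits = np.flatnonzero(below)
        return int(curve.k[hits[0]]) if hits.size else None
    if mode != "sustained":
        raise ValidationError(f"unknown mode {mode!r}")
    if not below[-1]:
        return None
    above = np.flatnonzero(~below)
    if above.size == 0:
        return int(curve.k[0])
    return int(curve.k[above[-1] + 1])


def bootstrap_cv_envelope(
    records: Sequence[CoverageRecord],
    n_permutations: int = 1000,
    seed: int = 0,
    quantiles: Sequence[float] = (5.0, 50.0, 95.0),
    ddof: int = 1,
) -> pd.DataFrame:
    """Order-permuted envelope of the cumulative-CV curve.

    Acquisition order is arbitrary, so the CV curve for any single order
    is one draw from a permutation distribution. Returns a DataFrame
    indexed by k with one column per requested percentile of CV_k over
    ``n_permutations`` random orderings. CV_n is order-invariant, so all
    quantiles coincide at k = n.
    """
    if n_permutations < 1:
        raise ValidationError("n_permutations must be >= 1")
    valid = sorted(_valid_records(records), key=lambda r: r.tile_index)
    if len(valid) < 2:
        raise DataError("cumulative CV needs at least 2 valid fields")
    x = np.array([r.coverage_pct for r in valid], dtype=float)
    rng = np.random.default_rng(seed)
    curves = np.empty((n_permutations, x.size - 1))
    for i in range(n_permutations):
        curves[i] = _cumulative_cv_values(rng.permutation(x), ddof=ddof)
    qs = np.percentile(curves, quantiles, axis=0)
    out = pd.DataFrame(
        {f"cv_p{q:g}": qs[j] for j, q in enumerate(quantiles)},
        index=pd.Index(np.arange(2, x.size + 1), name="k"),
    )
    return out


def records_to_frame(records: Sequence[CoverageRecord]) -> pd.DataFrame:
    """Flatten coverage records into the per-field coverage table."""
    rows = []
    for r in records:
        rows.append(
            {
                "coupon_id": r.coupon_id,
                "tile_index": r.tile_index,
                "area_px": r.area_px,
                "aref_px": r.aref_px,
                "area_um2": r.area_um2,
                "aref_um2": r.aref_um2,
                "coverage_pct": r.coverage_pct if r.valid else np.nan,
                "valid": r.valid,
                "invalid_reason": r.invalid_reason or "",
            }
        )
    return pd.DataFrame(rows)
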