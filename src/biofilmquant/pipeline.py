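"""End-to-end pipeline: ingest -> segment -> quantify -> report -> stats.

A run is driven by a :class:`PipelineConfig` that can round-trip through
YAML; every CSV the pipeline writes starts with a header comment line
carrying the package version and the config hash, so any result file
can be traced to the exact configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import DataError, DegenerateHistogramError, ValidationError
from .image_io import ChamberLayout, CouponDataset, read_coupon, write_masks
from .quantification import (
    CoverageRecord,
    bootstrap_cv_envelope,
    cumulative_cv,
    coupon_coverage,
    field_coverage,
    min_image_number,
    records_to_frame,
)
from .reporting import (
    build_fingerprint,
    build_overview,
    position_trend_test,
    save_fingerprint_figure,
    save_overview,
)
from .segmentation import (
    DEFAULT_BLUR_THRESHOLD,
    flag_invalid_field,
    segment_field,
)
from .group_stats import full_report, save_boxplot


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; round-trips losslessly through YAML."""

    data_dir: str = "."
    out_dir: str = "results"
    min_px: int = 6
    max_px: int = 400
    connectivity: int = 8
    polarity: str = "bright"
    target_cv_pct: float = 13.0
    alpha: float = 0.05
    blur_metric_threshold: float = DEFAULT_BLUR_THRESHOLD
    grid_rows: int = 15
    grid_cols: int = 7
    pixel_scale_um: float = 0.486
    group_by: str = "material"
    cv_envelope_permutations: int = 0  # 0 disables the envelope
    make_mosaics: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.min_px < 1 or self.max_px < self.min_px:
            raise ValidationError(
                f"size bounds ({self.min_px}, {self.max_px}): need 1 <= min_px <= max_px"
            )
        if self.connectivity not in (4, 8):
            raise ValidationError("connectivity must be 4 or 8")
        if self.polarity not in ("bright", "dark"):
            raise ValidationError("polarity must be 'bright' or 'dark'")
        if self.target_cv_pct <= 0:
            raise ValidationError("target_cv_pct must be positive")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValidationError("grid shape must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValidationError(f"config file {path} does not hold a mapping")
        return cls.from_dict(data)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def write_csv(df: pd.DataFrame, path: str | Path, config: PipelineConfig) -> Path:
    """Write a result CSV with the provenance header line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# biofilmquant {__version__} config={config.config_hash}\n")
        df.to_csv(fh, index=False)
    return path


def read_result_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def find_coupon_dirs(data_dir: str | Path) -> list[Path]:
    """Coupon directories = directories containing a ``*sidecar*.csv``."""
    root = Path(data_dir)
    if not root.exists():
        raise DataError(f"input directory not found: {root}")
    if list(root.glob("*sidecar*.csv")):
        return [root]
    dirs = sorted(d for d in root.iterdir() if d.is_dir() and list(d.glob("*sidecar*.csv")))
    if not dirs:
        raise DataError(f"{root}: no coupon directories (with sidecars) found")
    return dirs


def process_coupon(
    coupon: CouponDataset, config: PipelineConfig
) -> tuple[dict[int, object], list[CoverageRecord], list[str]]:
    """Segment every field of one coupon and build its coverage records.

    Returns (results-by-tile, coverage records, log lines). Fields with
    a degenerate histogram, a failing focus metric, or a manual
    exclusion are flagged invalid and carried through with no coverage
    value.
    """
    results: dict[int, object] = {}
    records: list[CoverageRecord] = []
    log: list[str] = []
    for f in coupon.fields:
        try:
            res = segment_field(
                f,
                size_bounds=(config.min_px, config.max_px),
                polarity=config.polarity,
                connectivity=config.connectivity,
            )
        except DegenerateHistogramError:
            res = None
        valid, reason = flag_invalid_field(
            f,
            res,
            blur_metric_threshold=config.blur_metric_threshold,
            excluded_tiles=coupon.excluded_tiles,
        )
        if res is not None:
            results[f.tile_index] = res
        rec = field_coverage(
            res, f, coupon_id=coupon.coupon_id, valid=valid, invalid_reason=reason
        )
        records.append(rec)
        n_obj = len(res.objects) if res is not None else 0
        n_kept = int(res.objects["kept"].sum()) if res is not None and n_obj else 0
        log.append(
            f"coupon={coupon.coupon_id} tile={f.tile_index} "
            f"threshold={res.threshold if res is not None else 'NA'} "
            f"objects={n_obj} kept={n_kept} valid={valid}"
            + (f" reason={reason}" if reason else "")
        )
    return results, records, log


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full pipeline on every coupon under ``config.data_dir``.

    Writes, under ``config.out_dir``: per-field ``coverage.csv``,
    ``coupon_summary.csv``, ``cv_curves.csv`` and ``min_images.csv``;
    kept masks and overview mosaics per coupon; fingerprint matrices and
    a shared-scale fingerprint figure; a position-trend test per chamber
    (3+ coupons); and a group-statistics report grouped by
    ``config.group_by``. A stage failure aborts with the stage name and
    the offending item in the message.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    log_lines = [f"biofilmquant {__version__} config={config.config_hash}"]

    coupon_dirs = find_coupon_dirs(config.data_dir)
    all_records: list[CoverageRecord] = []
    summaries = []
    summary_meta = {}
    cv_rows = []
    min_rows = []
    fingerprints: dict[str, pd.DataFrame] = {}
    chamber_members: dict[str, list] = {}

    for cdir in coupon_dirs:
        try:
            coupon = read_coupon(cdir)
        except (ValidationError, DataError) as exc:
            raise type(exc)(f"[ingest] {cdir.name}: {exc}") from exc
        try:
            results, records, clog = process_coupon(coupon, config)
        except (ValidationError, DataError) as exc:
            raise type(exc)(f"[segment] {coupon.coupon_id}: {exc}") from exc
        log_lines.extend(clog)
        all_records.extend(records)
        write_masks(coupon, results, out / "masks" / coupon.coupon_id)

        try:
            summary = coupon_coverage(records)
        except DataError as exc:
            raise DataError(f"[quantify] {coupon.coupon_id}: {exc}") from exc
        summaries.append(summary)
        summary_meta[summary.coupon_id] = {
            "material": coupon.material,
            "chamber_id": coupon.chamber_id,
            "tray_slot": coupon.tray_slot,
            "trial_id": coupon.trial_id,
        }
        chamber_members.setdefault(coupon.chamber_id, []).append(summary)

        n_valid = sum(r.valid for r in records)
        if n_valid >= 2:
            curve = cumulative_cv(records, target_cv_pct=config.target_cv_pct)
            for k, cv in zip(curve.k, curve.cv_pct):
                cv_rows.append({"coupon_id": coupon.coupon_id, "k": int(k), "cv_pct": cv})
            min_rows.append(
                {
                    "coupon_id": coupon.coupon_id,
                    "target_cv_pct": config.target_cv_pct,
                    "min_images": min_image_number(curve, config.target_cv_pct) or "not reached",
                }
            )
            if config.cv_envelope_permutations > 0:
                env = bootstrap_cv_envelope(
                    records, config.cv_envelope_permutations, seed=config.seed
                )
                write_csv(
                    env.reset_index().assign(coupon_id=coupon.coupon_id),
                    out / "cv_envelopes" / f"{coupon.coupon_id}_cv_envelope.csv",
                    config,
                )

        grid_positions = {f.tile_index: (f.grid_row, f.grid_col) for f in coupon.fields}
        fp = build_fingerprint(records, coupon.grid_shape, grid_positions)
        fingerprints[coupon.coupon_id] = fp
        write_csv(
            fp.reset_index(),
            out / "fingerprints" / f"{coupon.coupon_id}_fingerprint.csv",
            config,
        )
        if config.make_mosaics:
            try:
                mosaic = build_overview(coupon, results, {r.tile_index: r for r in records})
            except (ValidationError, DataError) as exc:
                raise type(exc)(f"[report] {coupon.coupon_id}: {exc}") from exc
            save_overview(
                mosaic,
                out / "overviews" / f"{coupon.coupon_id}_overview.png",
                out / "overviews" / f"{coupon.coupon_id}_overview_index.csv",
            )

    write_csv(records_to_frame(all_records), out / "coverage.csv", config)
    summary_df = pd.DataFrame(
        [
            {
                "coupon_id": s.coupon_id,
                **summary_meta[s.coupon_id],
                "pooled_pct": s.pooled_pct,
                "mean_pct": s.mean_pct,
                "sd_pct": s.sd_pct,
                "n_valid": s.n_valid,
                "n_total": s.n_total,
            }
            for s in summaries
        ]
    )
    write_csv(summary_df, out / "coupon_summary.csv", config)
    if cv_rows:
        write_csv(pd.DataFrame(cv_rows), out / "cv_curves.csv", config)
    if min_rows:
        write_csv(pd.DataFrame(min_rows), out / "min_images.csv", config)
    if fingerprints:
        shapes = {df.shape for df in fingerprints.values()}
        if len(shapes) == 1:
            save_fingerprint_figure(
                fingerprints, out / "fingerprints" / "fingerprints.png",
                layout=ChamberLayout(),
            )

    trend_rows = []
    for chamber_id, members in chamber_members.items():
        if len(members) < 3:
            continue
        positions = {
            s.coupon_id: float(summary_meta[s.coupon_id]["tray_slot"]) for s in members
        }
        res = position_trend_test(members, positions, seed=config.seed)
        trend_rows.append({"chamber_id": chamber_id, **res})
    if trend_rows:
        write_csv(pd.DataFrame(trend_rows), out / "position_trend.csv", config)

    groups: dict[str, list[float]] = {}
    for s in summaries:
        key = str(summary_meta[s.coupon_id].get(config.group_by, "") or "all")
        groups.setdefault(key, []).append(s.pooled_pct)
    groups = {k: v for k, v in groups.items() if len(v) >= 2}
    if len(groups) >= 2:
        try:
            report = full_report(groups, alpha=config.alpha, seed=config.seed)
        except (ValidationError, DataError) as exc:
            raise type(exc)(f"[stats] {exc}") from exc
        report["config_hash"] = config.config_hash
        report["version"] = __version__
        (out / "stats_report.json").write_text(json.dumps(report, indent=2))
        save_boxplot(groups, out / "coverage_boxplot.png")

    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out
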