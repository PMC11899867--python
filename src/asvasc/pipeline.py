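"""Run orchestration: quantify a manifest of images, then compare cohorts.

The pipeline has two stages.  ``run_quantify`` walks a manifest CSV — one
row per en-face image with its labels (subject, eye, region, layer) and
either an ROI mask file or a quadrant to construct — and writes a tidy
metrics CSV.  ``run_compare`` joins metrics to cohort covariates and emits
the three analysis tables: case-vs-control comparisons, active-vs-inactive
comparisons among diseased eyes, and CAS-association regressions.  Every
output carries the config hash so identical config + inputs give identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort_stats, metrics as vm
from .layers import load_enface, quadrant_roi, ROIMask
from .segmentation import EnhanceParams, segment_vessels

__all__ = ["RunConfig", "run_quantify", "run_compare"]

log = logging.getLogger("asvasc")


@dataclass
class RunConfig:
    """Single-YAML run configuration; round-trips losslessly."""

    manifest: str = "manifest.csv"
    output_dir: str = "out"
    clahe_clip: float | None = 2.0
    clahe_tiles: tuple[int, int] = (8, 8)
    median_kernel: int = 3
    threshold_enhanced: bool = True
    box_sizes: list[int] | None = None
    working_correlation: str = "exchangeable"
    sidak_m: int | None = None
    max_fail_fraction: float = 0.0
    seed: int = 0

    @property
    def enhance_params(self) -> EnhanceParams:
        return EnhanceParams(
            clahe_clip=self.clahe_clip,
            clahe_tiles=tuple(self.clahe_tiles),
            median_kernel=self.median_kernel,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["clahe_tiles"] = list(self.clahe_tiles)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.clahe_tiles = tuple(cfg.clahe_tiles)  # type: ignore[assignment]
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @property
    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _row_roi(row: pd.Series, img) -> ROIMask:
    roi_path = row.get("roi")
    if isinstance(roi_path, str) and roi_path:
        import imageio.v3 as iio

        arr = iio.imread(roi_path)
        if arr.ndim == 3:
            arr = arr[..., 0]
        return ROIMask(pixels=arr > 0, quadrant=str(row.get("region", "whole")))
    region = str(row["region"])
    return quadrant_roi(img, region, eye=str(row.get("eye", "OD")))


def run_quantify(cfg: RunConfig) -> pd.DataFrame:
    """Quantify every manifest row; write metrics.csv and a run manifest.

    Per-row failures are collected and logged; the run raises if the failed
    fraction exceeds ``max_fail_fraction``.
    """
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = pd.read_csv(cfg.manifest)

    rows, failures = [], []
    for idx, row in manifest.iterrows():
        try:
            img = load_enface(row["image"])
            roi = _row_roi(row, img)
            mask = segment_vessels(
                img, roi, cfg.enhance_params,
                threshold_enhanced=cfg.threshold_enhanced,
            )
            m = vm.compute_metrics(mask, roi, box_sizes=cfg.box_sizes)
            rows.append(
                {
                    "subject_id": row["subject_id"],
                    "eye": row["eye"],
                    "region": row["region"],
                    "layer": row["layer"],
                    **m.as_dict(),
                    "threshold": mask.source_threshold,
                    "config_hash": cfg.config_hash,
                }
            )
        except Exception as exc:
            failures.append({"row": int(idx), "image": row.get("image"), "error": str(exc)})
            log.error("row %d (%s) failed: %s", idx, row.get("image"), exc)

    result = pd.DataFrame(rows)
    result.to_csv(out_dir / "metrics.csv", index=False)
    run_log = {
        "config_hash": cfg.config_hash,
        "config": cfg.to_dict(),
        "n_rows": int(len(manifest)),
        "n_failed": len(failures),
        "failures": failures,
    }
    with open(out_dir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(run_log, fh, sort_keys=True)

    if len(manifest) and len(failures) / len(manifest) > cfg.max_fail_fraction:
        raise RuntimeError(
            f"{len(failures)}/{len(manifest)} manifest rows failed "
            f"(limit {cfg.max_fail_fraction:.0%}); see manifest.yaml"
        )
    return result


def _join(metrics_df: pd.DataFrame, cohort_df: pd.DataFrame) -> pd.DataFrame:
    """Join metrics to covariates on subject+eye (+region/layer if present)."""
    keys = [
        k for k in ("subject_id", "eye", "region", "layer")
        if k in cohort_df.columns
    ]
    covars = cohort_df[
        keys + [c for c in cohort_df.columns
                if c not in keys and c not in metrics_df.columns]
    ]
    merged = metrics_df.merge(covars, on=keys, how="left", indicator=True)
    orphans = merged[merged["_merge"] == "left_only"]
    if len(orphans):
        sample = orphans[keys].head(5).to_dict("records")
        log.warning(
            "%d metric rows lack cohort covariates, e.g. %s", len(orphans), sample
        )
    return merged[merged["_merge"] == "both"].drop(columns="_merge")


def run_compare(
    cfg: RunConfig,
    metrics_csv: str | Path,
    cohort_csv: str | Path,
) -> dict[str, pd.DataFrame]:
    """Produce the three analysis tables from metrics + cohort CSVs.

    Writes ``table_case_control.csv`` (all eyes, case vs control),
    ``table_activity.csv`` (diseased eyes, active vs inactive) and
    ``table_cas.csv`` (CAS-association slopes).
    """
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    metrics_df = pd.read_csv(metrics_csv)
    cohort_df = pd.read_csv(cohort_csv)
    table = _join(metrics_df, cohort_df)

    tables: dict[str, pd.DataFrame] = {}
    tables["case_control"] = cohort_stats.comparison_table(
        table, corr=cfg.working_correlation, sidak_m=cfg.sidak_m
    )
    ted = table[table["group"] == "case"]
    tables["activity"] = cohort_stats.comparison_table(
        ted, group_col="activity", case_label="active",
        corr=cfg.working_correlation, sidak_m=cfg.sidak_m,
    )
    tables["cas"] = cohort_stats.association_table(ted, corr=cfg.working_correlation)

    for name, df in tables.items():
        df = df.assign(config_hash=cfg.config_hash)
        df.to_csv(out_dir / f"table_{name}.csv", index=False)
        tables[name] = df
    return tables
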