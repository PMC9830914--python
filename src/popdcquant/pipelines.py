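"""End-to-end study pipelines and report serialization.

``run_biopsy_study`` mirrors the patient-vs-control biopsy analysis: every
image goes through fiber segmentation and compartment quantification, the
per-fiber SGCA-normalized sarcolemmal target levels are normalized to the
control-arm median, and the arms are compared with a Mann-Whitney test.
``compare_biopsies`` pools control-normalized per-fiber values across
biopsies and runs Kruskal-Wallis + Dunn on the fold changes.
``run_cotransfection_study`` does the same for per-cell localization ratios
with Kruskal-Wallis + Dunn against the wild-type pair.

Reports are plain dicts written as JSON (sorted keys) next to the per-object
CSVs; a copy of the configuration is embedded for provenance, and with a
fixed seed and inputs the bytes are reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import fibers, stats
from .cells import analyze_image as analyze_cell_image
from .stack import MEMBRANE_MARKER, TARGET, ChannelStack

logger = logging.getLogger(__name__)

CSV_FLOAT_FORMAT = "%.8g"


@dataclass
class RunConfig:
    """Serializable run configuration embedded in every report."""

    segmentation: fibers.SegmentationConfig = field(default_factory=fibers.SegmentationConfig)
    seed: int = 0
    out_dir: str | None = None
    log_level: str = "INFO"
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        seg = d.get("segmentation", {})
        if isinstance(seg, dict):
            seg = fibers.SegmentationConfig(**seg)
        return cls(
            segmentation=seg,
            seed=int(d.get("seed", 0)),
            out_dir=d.get("out_dir"),
            log_level=d.get("log_level", "INFO"),
            extra=d.get("extra", {}) or {},
        )


def _write_report(report: dict, tables: dict[str, pd.DataFrame], out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False, float_format=CSV_FLOAT_FORMAT)
    path = out / "report.json"
    with open(path, "w") as fh:
        json.dump(report, fh, sort_keys=True, indent=2, default=_json_default)
        fh.write("\n")
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def load_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _quantify_arm(images: list[ChannelStack], cfg: RunConfig) -> pd.DataFrame:
    frames = []
    for stack in images:
        df, masks = fibers.analyze_image(stack, cfg.segmentation)
        logger.info(
            "image %s: %d fibers (%d skipped)", stack.image_id, len(df), len(masks.skipped)
        )
        frames.append(df)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def run_biopsy_study(
    patient_images: list[ChannelStack],
    control_images: list[ChannelStack],
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Patient-vs-control biopsy comparison on one target protein.

    Quantifies every fiber in both arms, normalizes the per-fiber
    SGCA-normalized sarcolemmal target level to the control median, and
    reports normalized medians with 95% CIs plus a two-sided Mann-Whitney
    test. Aborts when an arm yields no usable fibers.
    """
    cfg = config or RunConfig()
    if not patient_images or not control_images:
        raise ValueError("both study arms need at least one image")
    patient_df = _quantify_arm(patient_images, cfg)
    control_df = _quantify_arm(control_images, cfg)

    def _usable(df: pd.DataFrame) -> np.ndarray:
        if len(df) == 0:
            return np.array([])
        ok = df["flags"].astype(str) == ""
        vals = df.loc[ok, "sgca_norm_sarcolemma"].to_numpy(dtype=float)
        return vals[np.isfinite(vals)]

    pat = _usable(patient_df)
    ctl = _usable(control_df)
    if pat.size == 0 or ctl.size == 0:
        raise RuntimeError(
            f"study arm without usable fibers (patient={pat.size}, control={ctl.size})"
        )

    ctl_norm = stats.normalize_to_control(ctl, ctl)
    pat_norm = stats.normalize_to_control(pat, ctl)
    ctl_sum = stats.summarize_group("control", ctl_norm)
    pat_sum = stats.summarize_group("patient", pat_norm)
    mw = stats.mann_whitney(pat, ctl)

    area_summary = {
        arm: stats.summarize_group(arm, df.loc[df["flags"] == "", "area_um2"])
        for arm, df in (("patient", patient_df), ("control", control_df))
    }

    report = {
        "analysis": "biopsy_study",
        "config": cfg.to_dict(),
        "groups": {
            "control": asdict(ctl_sum),
            "patient": asdict(pat_sum),
        },
        "mann_whitney": asdict(mw),
        "area_um2": {k: asdict(v) for k, v in area_summary.items()},
        "counts": {
            "patient": {
                "images": len(patient_images),
                "fibers": int(len(patient_df)),
                "usable_fibers": int(pat.size),
            },
            "control": {
                "images": len(control_images),
                "fibers": int(len(control_df)),
                "usable_fibers": int(ctl.size),
            },
        },
    }
    tables = {"fibers_patient": patient_df, "fibers_control": control_df}
    target_dir = out_dir or cfg.out_dir
    if target_dir is not None:
        report["report_path"] = str(_write_report(report, tables, target_dir))
    report["_tables"] = tables
    return report


def compare_biopsies(
    normalized_by_biopsy: dict[str, np.ndarray],
    comparisons: list[tuple[str, str]] | None = None,
) -> stats.ComparisonResult:
    """Cross-biopsy fold-change comparison.

    ``normalized_by_biopsy`` maps biopsy label to its per-fiber
    control-normalized values; pooled values are compared with
    Kruskal-Wallis followed by Dunn's test.
    """
    return stats.kruskal_dunn(
        {k: np.asarray(v, dtype=float) for k, v in normalized_by_biopsy.items()},
        comparisons=comparisons,
    )


def run_cotransfection_study(
    group_images: dict[str, list[ChannelStack]],
    wildtype_label: str,
    reporters: list[str] | None = None,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Co-transfection localization study across mutant groups.

    Quantifies per-cell membrane:cytoplasm ratios in every group, summarizes
    per-group medians with CIs (both raw and wild-type-normalized), and runs
    Kruskal-Wallis + Dunn against the wild-type pair when three or more
    groups are present (Mann-Whitney for two). Absolute membrane and
    cytoplasm means are summarized as well.
    """
    cfg = config or RunConfig()
    if wildtype_label not in group_images:
        raise ValueError(f"wild-type group {wildtype_label!r} missing")
    if any(len(v) == 0 for v in group_images.values()):
        empty = [k for k, v in group_images.items() if not v]
        raise ValueError(f"groups without images: {empty}")

    per_group_tables: dict[str, pd.DataFrame] = {}
    for label, images in group_images.items():
        frames = [analyze_cell_image(stack) for stack in images]
        df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
        df.insert(0, "group", label)
        per_group_tables[label] = df
        logger.info("group %s: %d cells", label, len(df))

    all_cells = pd.concat(per_group_tables.values(), ignore_index=True)
    if reporters is None:
        reporters = sorted(
            c[len("ratio_") :] for c in all_cells.columns if c.startswith("ratio_")
        )

    def _vals(df: pd.DataFrame, col: str) -> np.ndarray:
        v = df.loc[df["flags"] == "", col].to_numpy(dtype=float)
        return v[np.isfinite(v)]

    report: dict = {
        "analysis": "cotransfection_study",
        "config": cfg.to_dict(),
        "wildtype": wildtype_label,
        "reporters": {},
    }
    for rep in reporters:
        col = f"ratio_{rep}"
        groups = {g: _vals(df, col) for g, df in per_group_tables.items()}
        if any(v.size == 0 for v in groups.values()):
            empty = [g for g, v in groups.items() if v.size == 0]
            raise RuntimeError(f"groups without usable cells for {rep}: {empty}")
        wt = groups[wildtype_label]
        summaries = {
            g: asdict(stats.summarize_group(g, v, control_values=wt)) for g, v in groups.items()
        }
        if len(groups) >= 3:
            comparison = stats.kruskal_dunn(
                {wildtype_label: wt, **{g: v for g, v in groups.items() if g != wildtype_label}}
            )
        elif len(groups) == 2:
            other = next(g for g in groups if g != wildtype_label)
            comparison = stats.mann_whitney(groups[other], wt)
        else:
            comparison = None
        absolute = {
            g: {
                "membrane": asdict(stats.summarize_group(g, _vals(df, f"membrane_mean_{rep}"))),
                "cytoplasm": asdict(stats.summarize_group(g, _vals(df, f"cytoplasm_mean_{rep}"))),
            }
            for g, df in per_group_tables.items()
        }
        report["reporters"][rep] = {
            "groups": summaries,
            "comparison": asdict(comparison) if comparison else None,
            "absolute": absolute,
        }
    report["counts"] = {
        g: {"images": len(group_images[g]), "cells": int(len(df))}
        for g, df in per_group_tables.items()
    }
    tables = {"cells": all_cells}
    target_dir = out_dir or cfg.out_dir
    if target_dir is not None:
        report["report_path"] = str(_write_report(report, tables, target_dir))
    report["_tables"] = tables
    return report
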