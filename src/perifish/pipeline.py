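"""End-to-end orchestration: simulate/load → segment → spots → distances → PDFs.

A single validated config drives the whole run; outputs (label volume,
spot table, distance table, probability histogram, manifest) land in one
output directory, and every random choice derives from one seed so a rerun
with the same config is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import tifffile
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import __version__
from .distance import (
    DistanceRecord,
    default_bins,
    min_distance_3d,
    normalized_distance_map,
    normalized_position,
    pdf_histogram,
    plot_pdf,
    records_to_frame,
)
from .segmentation import SegmentationParams, segment_nuclei
from .simulate import SceneParams, generate_scene
from .spots import DoGParams, lamin_point_cloud, localize_spots
from .stack import load_ome_tiff

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, labelled with the stage that raised it."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    condition: str = "condition"
    #: either a path to an OME-TIFF stack ...
    input_stack: str | None = None
    channel_roles: tuple[str, str, str] = ("dna", "probe", "lamin")
    voxel_size_zyx: tuple[float, float, float] | None = None  # override for plain TIFF
    #: ... or parameters for a simulated scene
    simulate: SceneParams | None = None
    segmentation: SegmentationParams = Field(default_factory=SegmentationParams)
    probe_dog: DoGParams = Field(default_factory=DoGParams)
    lamin_dog: DoGParams = Field(default_factory=lambda: DoGParams(threshold_k=2.0))
    readout: Literal["distance_3d", "normalized_2d"] = "distance_3d"
    outdir: str = "perifish_out"
    seed: int = 0
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _check(self) -> "PipelineConfig":
        if (self.input_stack is None) == (self.simulate is None):
            raise ValueError("exactly one of input_stack or simulate must be given")
        if sorted(self.channel_roles) != ["dna", "lamin", "probe"]:
            raise ValueError(
                "channel_roles must be a permutation of ('dna', 'probe', 'lamin')"
            )
        return self


def validate_config(path: str | Path) -> PipelineConfig:
    """Load and fully validate a YAML config; schema violations are
    reported all at once, unknown keys rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return PipelineConfig.model_validate(raw)


@dataclass
class ConditionSummary:
    condition: str
    readout: str
    n_nuclei: int
    n_spots_detected: int
    n_spots_assigned: int
    n_records: int
    median: float
    mean: float
    sd: float
    histogram_path: str


def run_pipeline(config: PipelineConfig) -> ConditionSummary:
    """Run the full pipeline and write all artifacts to ``config.outdir``.

    Stages: acquire (load or simulate) → segment nuclei → localize probe
    spots → distance readout (3D µm shortest distance to the lamin cloud,
    or 2D normalized radial position on projected per-nucleus masks) →
    probability histogram. A manifest with the config hash, package
    version and per-stage counts is always written; stage errors are
    re-raised labelled with the stage name.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "perifish_version": __version__,
        "config_sha256": hashlib.sha256(
            config.model_dump_json().encode()
        ).hexdigest(),
        "config": json.loads(config.model_dump_json()),
        "stages": {},
        "complete": False,
    }

    def fail(stage: str, exc: Exception):
        manifest["stages"][stage] = {"error": str(exc)}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise PipelineError(stage, str(exc)) from exc

    # ---- acquire
    try:
        if config.simulate is not None:
            sim = config.simulate.model_copy(update={"seed": config.seed})
            stack, truth = generate_scene(sim)
            truth.to_csv(outdir / "ground_truth.csv")
        else:
            stack = load_ome_tiff(
                config.input_stack,
                channel_roles=config.channel_roles,
                voxel_size_zyx=config.voxel_size_zyx,
            )
        for role in ("dna", "probe", "lamin"):
            stack.channel(role)  # raises KeyError if a role is missing
    except Exception as exc:
        fail("acquire", exc)
    manifest["stages"]["acquire"] = {
        "shape_zyx": list(stack.shape_zyx),
        "voxel_size_zyx": list(stack.voxel_size_zyx),
    }

    # ---- segment
    try:
        labels = segment_nuclei(stack, config.segmentation)
        labels.table.to_csv(outdir / "nuclei.csv", index=False)
        tifffile.imwrite(outdir / "labels.tif", labels.label_volume.astype(np.uint16))
    except Exception as exc:
        fail("segment", exc)
    manifest["stages"]["segment"] = {
        "n_nuclei": labels.n_nuclei,
        "otsu_threshold": labels.threshold,
    }

    # ---- spots
    try:
        spots = localize_spots(stack, "probe", labels, config.probe_dog)
        _spots_frame(spots).to_csv(outdir / "spots.csv", index=False)
    except Exception as exc:
        fail("spots", exc)
    assigned = [s for s in spots if s.nucleus_label > 0]
    manifest["stages"]["spots"] = {
        "detected": len(spots),
        "assigned": len(assigned),
        "unassigned": len(spots) - len(assigned),
    }

    # ---- distances
    try:
        if config.readout == "distance_3d":
            records = _distance_3d_records(stack, labels, assigned, config)
            column, xlabel = "distance_3d_um", "distance to lamina (µm)"
        else:
            records = _normalized_2d_records(labels, assigned, config)
            column, xlabel = "normalized_position", "normalized distance to periphery"
        df = records_to_frame(records)
        df.to_csv(outdir / "distances.csv", index=False, float_format="%.6f")
    except Exception as exc:
        fail("distances", exc)
    manifest["stages"]["distances"] = {"n_records": len(records)}

    # ---- histogram
    try:
        values = df[column].to_numpy(dtype=float)
        if len(values) == 0:
            raise ValueError("no distance records to histogram")
        hist = pdf_histogram(values, default_bins(values, column), condition=config.condition)
        hist_path = outdir / "pdf.png"
        plot_pdf([hist], hist_path, xlabel=xlabel)
    except Exception as exc:
        fail("histogram", exc)
    manifest["stages"]["histogram"] = {"n_bins": len(hist.heights)}

    manifest["complete"] = True
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return ConditionSummary(
        condition=config.condition,
        readout=config.readout,
        n_nuclei=labels.n_nuclei,
        n_spots_detected=len(spots),
        n_spots_assigned=len(assigned),
        n_records=len(records),
        median=float(np.median(values)),
        mean=float(np.mean(values)),
        sd=float(np.std(values, ddof=1)) if len(values) > 1 else 0.0,
        histogram_path=str(hist_path),
    )


def _spots_frame(spots) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "channel": [s.channel for s in spots],
            "nucleus_label": [s.nucleus_label for s in spots],
            "voxel_z": [s.voxel_zyx[0] for s in spots],
            "voxel_y": [s.voxel_zyx[1] for s in spots],
            "voxel_x": [s.voxel_zyx[2] for s in spots],
            "refined_z": [s.refined_zyx[0] for s in spots],
            "refined_y": [s.refined_zyx[1] for s in spots],
            "refined_x": [s.refined_zyx[2] for s in spots],
            "z_um": [s.physical_zyx_um[0] for s in spots],
            "y_um": [s.physical_zyx_um[1] for s in spots],
            "x_um": [s.physical_zyx_um[2] for s in spots],
            "response": [s.response for s in spots],
        }
    )


def _distance_3d_records(stack, labels, assigned, config) -> list[DistanceRecord]:
    cloud = lamin_point_cloud(stack, labels, config.lamin_dog)
    records = []
    for i, spot in enumerate(assigned):
        pts = cloud.get(spot.nucleus_label)
        if pts is None or len(pts) == 0:
            continue  # nucleus without lamin sampling: excluded, logged by lamin_point_cloud
        records.append(
            DistanceRecord(
                nucleus_id=spot.nucleus_label,
                spot_id=i,
                distance_3d_um=min_distance_3d(np.asarray(spot.physical_zyx_um), pts),
                condition=config.condition,
            )
        )
    return records


def _normalized_2d_records(labels, assigned, config) -> list[DistanceRecord]:
    """2D readout from automatic masks: per-nucleus mask = z-projection of
    the 3D label restricted to the pre-dilation core (the dilated mask
    overshoots the nucleus boundary by design, which would inflate the
    normalization); spot coordinate = the refined (y, x)."""
    maps = {}
    records = []
    for i, spot in enumerate(assigned):
        lab = spot.nucleus_label
        if lab not in maps:
            vol = labels.label_volume == lab
            if labels.core_mask is not None:
                vol = vol & labels.core_mask
            mask2d = vol.any(axis=0)
            maps[lab] = normalized_distance_map(mask2d, nucleus_id=lab)
        try:
            pos = normalized_position(spot.refined_zyx[1:], maps[lab])
        except ValueError:
            logger.warning("spot %d outside projected mask of nucleus %d; skipped", i, lab)
            continue
        records.append(
            DistanceRecord(
                nucleus_id=lab, spot_id=i, normalized_position=pos, condition=config.condition
            )
        )
    return records
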