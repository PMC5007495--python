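"""File formats and configuration: TIFF stacks with modality sidecars,
CSV tables, manifest files and the YAML pipeline configuration."""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .ensemble import CVConfig
from .gp import GPConfig
from .rules import DEFAULT_IMAGE_COUNT_THRESHOLD, FinalAssignment
from .segmentation import CellContour, SegmentationParams
from .simulate import (
    DatasetManifest,
    FieldGeometry,
    GroundTruth,
    ManifestEntry,
    NoiseModel,
    TrueCell,
    TruePeak,
)
from .spots import Peak, SpotParams
from .types import AntibodyChannel, ImageStack, RhDLabel

__all__ = [
    "PipelineConfig",
    "write_image_stack",
    "read_image_stack",
    "write_ground_truth",
    "read_ground_truth",
    "write_manifest",
    "read_manifest",
    "write_contours",
    "peaks_to_frame",
    "assignments_to_frame",
    "load_config",
    "save_config",
    "config_hash",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def write_image_stack(path: str | Path, stack: ImageStack) -> None:
    """Write a multi-page 16-bit TIFF plus a JSON sidecar recording the
    frame-modality split and the pixel pitch."""
    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(np.uint16), photometric="minisblack")
    _sidecar_path(path).write_text(
        json.dumps(
            {
                "n_bright_field": stack.n_bright_field,
                "pixel_pitch_um": stack.pixel_pitch_um,
            }
        )
    )


def read_image_stack(path: str | Path) -> ImageStack:
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"missing modality sidecar {sidecar} for image stack {path}"
        )
    meta = json.loads(sidecar.read_text())
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    return ImageStack(
        frames=frames,
        n_bright_field=int(meta["n_bright_field"]),
        pixel_pitch_um=float(meta["pixel_pitch_um"]),
    )


def write_ground_truth(prefix: str | Path, truth: GroundTruth) -> None:
    """Write the cell and peak tables of one image's ground truth
    (``<prefix>.cells.csv`` / ``<prefix>.peaks.csv``; 0-based pixel coords)."""
    prefix = Path(prefix)
    pd.DataFrame(
        [dataclasses.asdict(c) for c in truth.cells]
    ).to_csv(prefix.with_name(prefix.name + ".cells.csv"), index=False)
    pd.DataFrame(
        [dataclasses.asdict(p) for p in truth.true_peaks]
    ).to_csv(prefix.with_name(prefix.name + ".peaks.csv"), index=False)


def read_ground_truth(prefix: str | Path) -> GroundTruth:
    prefix = Path(prefix)
    cells_df = pd.read_csv(prefix.with_name(prefix.name + ".cells.csv"))
    peaks_df = pd.read_csv(prefix.with_name(prefix.name + ".peaks.csv"))
    cells = [TrueCell(**row) for row in cells_df.to_dict("records")]
    peaks = [TruePeak(**row) for row in peaks_df.to_dict("records")]
    return GroundTruth(cells=cells, true_peaks=peaks)


def write_manifest(path: str | Path, manifest: DatasetManifest) -> None:
    rows = [
        {
            "sample_id": e.sample_id,
            "label": e.label.name,
            "channel": e.channel.name,
            "n_images": e.images_per_sample,
            "seed": e.seed,
        }
        for e in manifest.samples
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> DatasetManifest:
    df = pd.read_csv(path, sep="\t")
    return DatasetManifest(
        [
            ManifestEntry(
                sample_id=str(r["sample_id"]),
                label=RhDLabel.from_string(str(r["label"])),
                channel=AntibodyChannel.from_string(str(r["channel"])),
                images_per_sample=int(r["n_images"]),
                seed=int(r["seed"]),
            )
            for _, r in df.iterrows()
        ]
    )


def write_contours(prefix: str | Path, contours: list[CellContour]) -> None:
    """Node table plus per-cell summary table for one frame's contours."""
    prefix = Path(prefix)
    node_rows = [
        {"cell_id": c.cell_id, "node_index": i, "row": r, "col": col}
        for c in contours
        for i, (r, col) in enumerate(np.asarray(c.nodes))
    ]
    pd.DataFrame(node_rows).to_csv(
        prefix.with_name(prefix.name + ".nodes.csv"), index=False
    )
    summary_rows = [
        {
            "cell_id": c.cell_id,
            "area_px": c.area_px,
            "centroid_row": c.centroid[0],
            "centroid_col": c.centroid[1],
            "touches_edge": c.touches_edge,
        }
        for c in contours
    ]
    pd.DataFrame(summary_rows).to_csv(
        prefix.with_name(prefix.name + ".cells.csv"), index=False
    )


def peaks_to_frame(peaks: list[Peak], image_id: str = "") -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "image_id": image_id,
                "peak_id": i,
                "row": p.row,
                "col": p.col,
                "intensity_counts": p.intensity_counts,
                "cell_id": -1 if p.cell_id is None else p.cell_id,
                "excluded_flag": p.excluded_from_features,
            }
            for i, p in enumerate(peaks)
        ]
    )


def assignments_to_frame(assignments: list[FinalAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": a.sample_id,
                "m1": a.m1_label.name,
                "m2": a.m2_label.name,
                "n_images": a.n_images,
                "rule_fired": a.rule_fired.name,
                "final": a.label.name,
            }
            for a in assignments
        ]
    )


@dataclass
class PipelineConfig:
    """Full configuration of the synthetic pipeline; round-trips through YAML."""

    geometry: FieldGeometry = field(default_factory=FieldGeometry)
    noise: NoiseModel = field(default_factory=NoiseModel)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    spots: SpotParams = field(default_factory=SpotParams)
    cv: CVConfig = field(default_factory=CVConfig)
    image_count_threshold: int = DEFAULT_IMAGE_COUNT_THRESHOLD
    images_per_sample_range: tuple[int, int] = (11, 15)
    channel: AntibodyChannel = AntibodyChannel.H41

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["channel"] = self.channel.name
        d["images_per_sample_range"] = list(self.images_per_sample_range)
        d["cv"]["algorithms"] = list(self.cv.algorithms)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        cv = dict(d.get("cv", {}))
        gp = GPConfig(**cv.pop("gp", {}))
        if "algorithms" in cv:
            cv["algorithms"] = tuple(cv["algorithms"])
        return cls(
            geometry=FieldGeometry(**d.get("geometry", {})),
            noise=NoiseModel(**d.get("noise", {})),
            segmentation=SegmentationParams(**d.get("segmentation", {})),
            spots=SpotParams(**d.get("spots", {})),
            cv=CVConfig(gp=gp, **cv),
            image_count_threshold=int(
                d.get("image_count_threshold", DEFAULT_IMAGE_COUNT_THRESHOLD)
            ),
            images_per_sample_range=tuple(d.get("images_per_sample_range", (11, 15))),
            channel=AntibodyChannel.from_string(str(d.get("channel", "H41"))),
        )


def save_config(path: str | Path, config: PipelineConfig) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def load_config(path: str | Path) -> PipelineConfig:
    return PipelineConfig.from_dict(yaml.safe_load(Path(path).read_text()))


def config_hash(config: PipelineConfig) -> str:
    """Stable short hash of the configuration, stamped into output tables."""
    payload = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha1(payload.encode()).hexdigest()[:12]
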