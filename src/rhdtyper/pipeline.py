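"""End-to-end orchestration: simulate -> segment -> detect -> assign ->
features -> image/sample classification -> rule-based final assignment."""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd

from .features import (
    EmptyImageError,
    FEATURE_NAMES,
    image_features,
    sample_features,
)
from .io import PipelineConfig, assignments_to_frame, config_hash
from .rules import FinalAssignment, classify_cohort
from .segmentation import detect_cells
from .simulate import DatasetManifest, build_default_manifest, simulate_sample
from .spots import assign_peaks, detect_peaks
from .types import ImageStack

__all__ = ["CohortResult", "extract_image_row", "build_feature_tables", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class CohortResult:
    assignments: list[FinalAssignment]
    confusion_counts: pd.DataFrame
    confusion_percent: pd.DataFrame
    accuracy: float
    image_table: pd.DataFrame
    sample_table: pd.DataFrame


def extract_image_row(
    stack: ImageStack, config: PipelineConfig
) -> dict | None:
    """Segment, detect and featurise one image; None when no usable cell."""
    contours = detect_cells(stack.bright_field(0), config.segmentation)
    peaks = detect_peaks(stack.fluorescence(0), config.spots)
    peaks = assign_peaks(peaks, contours)
    try:
        vec = image_features(
            contours, peaks, stack.fluorescence(0), stack.pixel_pitch_um
        )
    except EmptyImageError:
        return None
    row = {name: getattr(vec, name) for name in FEATURE_NAMES}
    row.update(
        n_cells=vec.n_cells, has_signal=vec.has_signal, total_peaks=vec.total_peaks
    )
    return row


def build_feature_tables(
    manifest: DatasetManifest, config: PipelineConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate and featurise every manifest sample; returns the image-level
    and sample-level feature tables."""
    image_rows = []
    sample_rows = []
    for entry in manifest.samples:
        dataset = simulate_sample(
            entry, geometry=config.geometry, noise=config.noise
        )
        vectors = []
        for img_idx, (stack, _truth) in enumerate(dataset.images):
            row = extract_image_row(stack, config)
            if row is None:
                log.warning(
                    "sample %s image %d skipped: no usable cell",
                    entry.sample_id,
                    img_idx,
                )
                continue
            row.update(
                item_id=f"{entry.sample_id}/img{img_idx:03d}",
                sample_id=entry.sample_id,
                label=entry.label.name,
            )
            image_rows.append(row)
            vectors.append(row)
        if not vectors:
            log.warning("sample %s excluded: no usable images", entry.sample_id)
            continue
        sub = pd.DataFrame(vectors)
        sample_row = {name: float(sub[name].mean()) for name in FEATURE_NAMES}
        sample_row.update(
            item_id=entry.sample_id,
            sample_id=entry.sample_id,
            label=entry.label.name,
            n_images=len(vectors),
        )
        sample_rows.append(sample_row)
    return pd.DataFrame(image_rows), pd.DataFrame(sample_rows)


def run_pipeline(
    config: PipelineConfig,
    seed: int,
    out_dir: str | Path | None = None,
    manifest: DatasetManifest | None = None,
) -> CohortResult:
    """Run the whole synthetic cohort workflow reproducibly from one seed."""
    if manifest is None:
        manifest = build_default_manifest(
            seed, config.images_per_sample_range, config.channel
        )
    cfg = replace(config.cv, seed=seed)
    image_table, sample_table = build_feature_tables(manifest, config)
    if image_table.empty or sample_table.empty:
        raise RuntimeError("pipeline produced no usable images")
    assignments, counts, percent, accuracy = classify_cohort(
        image_table, sample_table, cfg, config.image_count_threshold
    )
    result = CohortResult(
        assignments=assignments,
        confusion_counts=counts,
        confusion_percent=percent,
        accuracy=accuracy,
        image_table=image_table,
        sample_table=sample_table,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        stamp = {"config_hash": config_hash(config), "seed": seed}
        for name, df in (
            ("image_features.csv", image_table),
            ("sample_features.csv", sample_table),
            ("final_assignments.csv", assignments_to_frame(assignments)),
        ):
            df = df.assign(**stamp)
            df.to_csv(out / name, index=False)
        counts.to_csv(out / "confusion_counts.csv")
        percent.to_csv(out / "confusion_percent.csv")
    return result
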