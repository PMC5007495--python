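"""Rule-based fusion of image-level and sample-level classification results
into the final per-sample RhD assignment."""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .ensemble import CVConfig, classify_method1, classify_method2
from .types import RhDLabel

__all__ = [
    "Rule",
    "FinalAssignment",
    "combine",
    "classify_cohort",
    "confusion_matrix",
]

DEFAULT_IMAGE_COUNT_THRESHOLD = 11


class Rule(Enum):
    CONCORDANT = "concordant"
    DNEG_DEL_IMAGES_GE_11 = "dneg_del_images_ge_threshold"
    DNEG_DEL_IMAGES_LT_11 = "dneg_del_images_lt_threshold"
    WEAKD_DEL_IMAGE_LEVEL = "weakd_del_image_level"
    DEFAULT_SAMPLE_LEVEL = "default_sample_level"


@dataclass
class FinalAssignment:
    sample_id: str
    label: RhDLabel
    m1_label: RhDLabel
    m2_label: RhDLabel
    n_images: int
    rule_fired: Rule


def combine(
    m1_label: RhDLabel,
    m2_label: RhDLabel,
    n_images: int,
    image_count_threshold: int = DEFAULT_IMAGE_COUNT_THRESHOLD,
    sample_id: str = "",
) -> FinalAssignment:
    """Fuse the two method labels into a final assignment.

    Decision order: (1) concordant labels win outright; (2) for the unordered
    pair {D-, DEL} the image-level result is trusted when at least
    ``image_count_threshold`` images back it, the sample-level result
    otherwise; (3) for {weak D, DEL} the image-level result is chosen;
    (4) in any other discordant case the sample-level result is chosen.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    pair = {m1_label, m2_label}
    if m1_label == m2_label:
        label, rule = m1_label, Rule.CONCORDANT
    elif pair == {RhDLabel.D_NEG, RhDLabel.DEL}:
        if n_images >= image_count_threshold:
            label, rule = m1_label, Rule.DNEG_DEL_IMAGES_GE_11
        else:
            label, rule = m2_label, Rule.DNEG_DEL_IMAGES_LT_11
    elif pair == {RhDLabel.WEAK_D, RhDLabel.DEL}:
        label, rule = m1_label, Rule.WEAKD_DEL_IMAGE_LEVEL
    else:
        label, rule = m2_label, Rule.DEFAULT_SAMPLE_LEVEL
    return FinalAssignment(
        sample_id=sample_id,
        label=label,
        m1_label=m1_label,
        m2_label=m2_label,
        n_images=n_images,
        rule_fired=rule,
    )


def confusion_matrix(
    assignments: list[FinalAssignment], actual: dict[str, RhDLabel]
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Counts and per-actual-class percentage confusion matrices
    (rows: predicted, columns: actual) plus overall accuracy."""
    order = [lab.name for lab in RhDLabel]
    counts = pd.DataFrame(0, index=order, columns=order)
    correct = 0
    for a in assignments:
        truth = actual[a.sample_id]
        counts.loc[a.label.name, truth.name] += 1
        if a.label is truth:
            correct += 1
    col_sums = counts.sum(axis=0).replace(0, np.nan)
    percent = (100.0 * counts / col_sums).fillna(0.0)
    accuracy = correct / len(assignments) if assignments else float("nan")
    return counts, percent, accuracy


def classify_cohort(
    image_table: pd.DataFrame,
    sample_table: pd.DataFrame,
    cfg: CVConfig,
    image_count_threshold: int = DEFAULT_IMAGE_COUNT_THRESHOLD,
) -> tuple[list[FinalAssignment], pd.DataFrame, pd.DataFrame, float]:
    """Run both classification methods independently, fuse per sample, and
    report the confusion matrix against the tables' labels."""
    image_samples = set(map(str, image_table["sample_id"]))
    sample_samples = set(map(str, sample_table["sample_id"]))
    if image_samples != sample_samples:
        odd = image_samples.symmetric_difference(sample_samples)
        raise ValueError(f"tables cover different samples: {sorted(odd)}")

    m1 = {r.sample_id: r for r in classify_method1(image_table, cfg)}
    m2 = {r.sample_id: r for r in classify_method2(sample_table, cfg)}
    n_images = image_table.groupby("sample_id").size().to_dict()

    assignments = [
        combine(
            m1[sid].label,
            m2[sid].label,
            int(n_images[sid]),
            image_count_threshold,
            sample_id=sid,
        )
        for sid in sorted(m1)
    ]
    actual = {
        str(row["sample_id"]): (
            row["label"]
            if isinstance(row["label"], RhDLabel)
            else RhDLabel.from_string(str(row["label"]))
        )
        for _, row in sample_table.iterrows()
    }
    counts, percent, accuracy = confusion_matrix(assignments, actual)
    return assignments, counts, percent, accuracy
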