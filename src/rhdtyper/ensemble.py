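"""Repeated cross-validated voting ensembles.

Four classifier families (random forest, RBF support vector machine,
k-nearest neighbours, genetic programming) are each run under repeated
stratified 5-fold cross-validation; every held-out item collects one vote per
(algorithm, repeat), so the per-item tally always sums to
``len(algorithms) * n_repeats``.

Tie-breaking of majority votes uses the fixed priority
DEL > weak D > D- > D+: when votes tie, the lower-expression (more
immunogenic-risk) class is preferred so the sample is flagged for
confirmatory testing.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .features import FEATURE_NAMES
from .gp import GPClassifier, GPConfig
from .types import RhDLabel

__all__ = [
    "ALGORITHMS",
    "TIE_BREAK_PRIORITY",
    "CVConfig",
    "VoteTally",
    "MethodResult",
    "majority_vote",
    "train_vote",
    "classify_method1",
    "classify_method2",
]

ALGORITHMS = ("rf", "svm", "knn", "gp")

TIE_BREAK_PRIORITY = (
    RhDLabel.DEL,
    RhDLabel.WEAK_D,
    RhDLabel.D_NEG,
    RhDLabel.D_POS,
)


@dataclass
class CVConfig:
    n_folds: int = 5
    n_repeats: int = 40
    algorithms: tuple[str, ...] = ALGORITHMS
    seed: int = 0
    group_by_sample: bool = True
    max_fold_retries: int = 20
    gp: GPConfig = field(default_factory=GPConfig)

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if not self.algorithms:
            raise ValueError("need at least one algorithm")
        unknown = set(self.algorithms) - set(ALGORITHMS)
        if unknown:
            raise ValueError(f"unknown algorithms: {sorted(unknown)}")


@dataclass
class VoteTally:
    votes: dict[RhDLabel, int] = field(default_factory=dict)

    def add(self, label: RhDLabel, count: int = 1) -> None:
        self.votes[label] = self.votes.get(label, 0) + count

    def merge(self, other: "VoteTally") -> None:
        for label, count in other.votes.items():
            self.add(label, count)

    @property
    def total(self) -> int:
        return sum(self.votes.values())


@dataclass
class MethodResult:
    sample_id: str
    label: RhDLabel
    tally: VoteTally
    n_items: int


def majority_vote(tally: VoteTally) -> RhDLabel:
    """Class with the most votes; ties resolved by the fixed priority order."""
    if tally.total < 1:
        raise ValueError("cannot take a majority of an empty tally")
    best = max(tally.votes.values())
    for label in TIE_BREAK_PRIORITY:
        if tally.votes.get(label, 0) == best:
            return label
    raise AssertionError("unreachable")


def _as_label(value) -> RhDLabel:
    return value if isinstance(value, RhDLabel) else RhDLabel.from_string(str(value))


def _draw_folds(
    y: np.ndarray,
    groups: np.ndarray | None,
    n_folds: int,
    seed: int,
    max_retries: int,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified fold indices; grouped drawing keeps all items of a group in
    one fold.  Redraws (new seed) until every training fold contains every
    class, then fails explicitly."""
    n = len(y)
    for attempt in range(max_retries):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed + attempt)
        try:
            if groups is None:
                folds = list(skf.split(np.zeros(n), y))
            else:
                uniq, first = np.unique(groups, return_index=True)
                group_y = y[first]
                folds = []
                for g_train, g_test in skf.split(np.zeros(len(uniq)), group_y):
                    train_groups = set(uniq[g_train])
                    mask = np.array([g in train_groups for g in groups])
                    folds.append((np.nonzero(mask)[0], np.nonzero(~mask)[0]))
        except ValueError:
            continue
        if all(len(set(y[tr])) == len(set(y)) for tr, _ in folds):
            return folds
    raise RuntimeError(
        f"could not draw stratified folds with all classes present "
        f"after {max_retries} attempts"
    )


def _fit_predict(
    algorithm: str,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    seed: int,
    gp_config: GPConfig,
) -> np.ndarray:
    d = X_train.shape[1]
    if algorithm == "rf":
        model = RandomForestClassifier(
            n_estimators=100, max_features="sqrt", random_state=seed, n_jobs=1
        )
    elif algorithm == "svm":
        model = SVC(kernel="rbf", C=1.0, gamma=1.0 / d)
    elif algorithm == "knn":
        model = KNeighborsClassifier(n_neighbors=min(5, len(y_train)))
    elif algorithm == "gp":
        model = GPClassifier(gp_config, random_state=seed)
    else:  # pragma: no cover - guarded by CVConfig
        raise ValueError(f"unknown algorithm {algorithm!r}")
    model.fit(X_train, y_train)
    return model.predict(X_test)


def train_vote(
    table: pd.DataFrame, level: str, cfg: CVConfig
) -> dict[str, VoteTally]:
    """Accumulate held-out votes for every item of a feature table.

    ``table`` needs columns ``item_id``, ``sample_id``, ``label`` and the
    seven feature columns.  Features are z-scored with training-fold
    statistics only.  Image-level runs group folds by sample when configured,
    so no fold ever tests an image whose sibling images were trained on.
    """
    if level not in ("image", "sample"):
        raise ValueError("level must be 'image' or 'sample'")
    missing = {"item_id", "sample_id", "label", *FEATURE_NAMES} - set(table.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    X = table[list(FEATURE_NAMES)].to_numpy(dtype=float)
    y = np.array([_as_label(v).name for v in table["label"]])
    item_ids = table["item_id"].to_numpy()
    if len(set(y)) < 2:
        raise ValueError("need at least two classes to train")
    groups = (
        table["sample_id"].to_numpy()
        if (level == "image" and cfg.group_by_sample)
        else None
    )

    tallies: dict[str, VoteTally] = {str(i): VoteTally() for i in item_ids}
    for a_idx, algorithm in enumerate(cfg.algorithms):
        for rep in range(cfg.n_repeats):
            fold_seed = int(
                np.random.SeedSequence([cfg.seed, a_idx, rep]).generate_state(1)[0]
                % (2**31 - 1)
            )
            folds = _draw_folds(y, groups, cfg.n_folds, fold_seed, cfg.max_fold_retries)
            for f_idx, (train, test) in enumerate(folds):
                mu = X[train].mean(axis=0)
                sd = X[train].std(axis=0)
                sd[sd == 0] = 1.0
                Xz = (X - mu) / sd
                preds = _fit_predict(
                    algorithm,
                    Xz[train],
                    y[train],
                    Xz[test],
                    seed=fold_seed + f_idx,
                    gp_config=cfg.gp,
                )
                for idx, pred in zip(test, preds):
                    tallies[str(item_ids[idx])].add(RhDLabel.from_string(str(pred)))
    return tallies


def classify_method1(image_table: pd.DataFrame, cfg: CVConfig) -> list[MethodResult]:
    """Image-level classification: per-image held-out votes are summed over
    each sample's images and resolved by majority."""
    tallies = train_vote(image_table, level="image", cfg=cfg)
    results = []
    for sample_id, sub in image_table.groupby("sample_id", sort=True):
        combined = VoteTally()
        for item in sub["item_id"]:
            combined.merge(tallies[str(item)])
        results.append(
            MethodResult(
                sample_id=str(sample_id),
                label=majority_vote(combined),
                tally=combined,
                n_items=len(sub),
            )
        )
    return results


def classify_method2(sample_table: pd.DataFrame, cfg: CVConfig) -> list[MethodResult]:
    """Sample-level classification on per-sample feature averages."""
    if sample_table["sample_id"].duplicated().any():
        raise ValueError("sample table must have one row per sample")
    tallies = train_vote(sample_table, level="sample", cfg=cfg)
    results = []
    for _, row in sample_table.sort_values("sample_id").iterrows():
        tally = tallies[str(row["item_id"])]
        results.append(
            MethodResult(
                sample_id=str(row["sample_id"]),
                label=majority_vote(tally),
                tally=tally,
                n_items=1,
            )
        )
    return results
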