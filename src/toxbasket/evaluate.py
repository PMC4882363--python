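"""Fivefold cross-validation, confusion matrices, and classification rates.

The default rate counts only the chemicals the rules could classify (the
model abstains on the rest); ``include_surrogate=True`` switches to
all-chemicals accounting with the Tanimoto surrogate filling the gaps.  The
reported mean is the unweighted mean of per-fold rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from .classify import UNCLASSIFIABLE, MarketBasketGHSClassifier, Prediction
from .hazard import CATEGORIES, HazardRecord, category_index

__all__ = [
    "ConfusionMatrix",
    "CVResult",
    "kfold_split",
    "cross_validate",
    "classification_rate",
]


@dataclass
class ConfusionMatrix:
    """4×4 ground-truth (rows) × predicted (columns) counts, plus an
    "unclassified" spill column for chemicals no mode could categorize."""

    counts: np.ndarray = field(
        default_factory=lambda: np.zeros((4, 4), dtype=int)
    )
    unclassified: np.ndarray = field(default_factory=lambda: np.zeros(4, dtype=int))

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        self.unclassified = np.asarray(self.unclassified, dtype=int)
        if self.counts.shape != (4, 4) or self.unclassified.shape != (4,):
            raise ValueError("confusion matrix must be 4x4 with a length-4 spill column")
        if (self.counts < 0).any() or (self.unclassified < 0).any():
            raise ValueError("counts must be non-negative")

    def add(self, truth: str, predicted: str) -> None:
        i = category_index(truth)
        if predicted == UNCLASSIFIABLE:
            self.unclassified[i] += 1
        else:
            self.counts[i, category_index(predicted)] += 1

    @property
    def total(self) -> int:
        return int(self.counts.sum() + self.unclassified.sum())

    @property
    def total_classified(self) -> int:
        return int(self.counts.sum())

    def to_csv(self) -> str:
        header = "truth," + ",".join(CATEGORIES) + ",unclassified"
        lines = [header]
        for i, cat in enumerate(CATEGORIES):
            row = ",".join(str(int(c)) for c in self.counts[i])
            lines.append(f"{cat},{row},{int(self.unclassified[i])}")
        return "\n".join(lines) + "\n"


def classification_rate(cm: ConfusionMatrix) -> float:
    """Fraction of classified chemicals on the diagonal (correct category)."""
    classified = cm.total_classified
    if classified == 0:
        raise ValueError("classification rate undefined: no classified chemicals")
    return float(np.trace(cm.counts)) / classified


def kfold_split(
    ids: Sequence[str], categories: Sequence[str], k: int, seed: int
) -> dict[str, int]:
    """Deterministic stratified k-fold assignment: id → fold in [0, k).

    Stratifies by category where class counts permit (classes smaller than k
    are spread as evenly as sklearn's stratifier manages); fold sizes differ
    by at most one.
    """
    n = len(ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of chemicals ({n})")
    y = np.asarray(categories)
    assignment: dict[str, int] = {}
    with warnings.catch_warnings():
        # tiny classes (fewer members than folds) are expected here
        warnings.simplefilter("ignore", UserWarning)
        try:
            splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
            splits = list(splitter.split(np.zeros(n), y))
        except ValueError:
            # class counts cannot support stratification (e.g. leave-one-out)
            splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
            splits = list(splitter.split(np.zeros(n)))
        for fold, (_, test_idx) in enumerate(splits):
            for i in test_idx:
                assignment[ids[i]] = fold
    return assignment


@dataclass
class CVResult:
    """Cross-validation outcome: per-fold rates and confusion matrices."""

    fold_rates: list[Optional[float]]
    confusion: list[ConfusionMatrix]
    assignment: dict[str, int]
    predictions: list[Prediction]
    denominator: str  # "rule-classified" or "all-classified"

    @property
    def mean_rate(self) -> float:
        defined = [r for r in self.fold_rates if r is not None]
        if not defined:
            raise ValueError("no fold produced a defined classification rate")
        return float(np.mean(defined))

    def pooled_confusion(self) -> ConfusionMatrix:
        total = ConfusionMatrix()
        for cm in self.confusion:
            total.counts += cm.counts
            total.unclassified += cm.unclassified
        return total


def cross_validate(
    records: Sequence[HazardRecord],
    k: int = 5,
    seed: int = 0,
    include_surrogate: bool = False,
    estimator: Optional[MarketBasketGHSClassifier] = None,
) -> CVResult:
    """Stratified k-fold cross-validation of the market-basket classifier.

    Per fold: rules are mined on the training chemicals only, and the held-out
    chemicals are predicted.  By default only rule-mode predictions enter the
    fold rate (the model abstains on the rest, mirroring a rules-only reading);
    with ``include_surrogate=True`` surrogate predictions count too.  A fold
    whose training set yields no rules gets an undefined (None) rate, excluded
    from the mean with a warning.
    """
    base = estimator if estimator is not None else MarketBasketGHSClassifier()
    ids = [r.id for r in records]
    cats = [r.category for r in records]
    assignment = kfold_split(ids, cats, k, seed)

    fold_rates: list[Optional[float]] = []
    matrices: list[ConfusionMatrix] = []
    all_preds: list[Prediction] = []
    for fold in range(k):
        train = [r for r in records if assignment[r.id] != fold]
        test = [r for r in records if assignment[r.id] == fold]
        model = MarketBasketGHSClassifier(**base.get_params())
        model.set_params(use_surrogate=include_surrogate)
        model.fit(
            [r.smiles for r in train],
            [r.category for r in train],
            ids=[r.id for r in train],
        )
        preds = model.predict_detail([r.smiles for r in test], ids=[r.id for r in test])
        all_preds.extend(preds)

        cm = ConfusionMatrix()
        correct = 0
        counted = 0
        for rec, pred in zip(test, preds):
            cm.add(rec.category, pred.category)
            if pred.mode == "rule" or (include_surrogate and pred.mode == "surrogate"):
                counted += 1
                if pred.category == rec.category:
                    correct += 1
        matrices.append(cm)
        if len(model.ruleset_) == 0 or counted == 0:
            warnings.warn(
                f"fold {fold}: no rule-classified chemicals; rate undefined",
                stacklevel=2,
            )
            fold_rates.append(None)
        else:
            fold_rates.append(correct / counted)

    return CVResult(
        fold_rates=fold_rates,
        confusion=matrices,
        assignment=assignment,
        predictions=all_preds,
        denominator="all-classified" if include_surrogate else "rule-classified",
    )
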