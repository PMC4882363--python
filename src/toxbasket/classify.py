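"""Rule-based GHS category prediction with a Tanimoto nearest-neighbor surrogate.

A chemical is classified by the mined association rules when any rule's full
antecedent is contained in its fingerprint; among matching rules the one with
the highest confidence wins (ties: higher lift, then the more hazardous
category, then the deterministic total rule order).  Chemicals no rule
covers fall back to a surrogate: the *rule-predicted* (not ground-truth)
category of the Tanimoto-nearest training chemical that itself has a rule
prediction.  Chemicals with an empty fingerprint, or a model whose training
set has no rule-covered chemical, are "unclassifiable".

:class:`MarketBasketGHSClassifier` packages the whole pipeline — SMILES →
fingerprints → Apriori rules → prediction — as a scikit-learn estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .fingerprint import (
    DEFAULT_MAX_DISTANCE,
    Fingerprint,
    atom_pairs,
    tanimoto_distance,
)
from .hazard import CATEGORIES, HazardRecord, category_index, ghs_category
from .molgraph import parse_smiles
from .rulemining import (
    AssociationRule,
    RuleSet,
    build_transactions,
    mine_rules,
)

__all__ = [
    "UNCLASSIFIABLE",
    "Prediction",
    "predict_by_rules",
    "nearest_neighbor",
    "predict",
    "MarketBasketGHSClassifier",
]

UNCLASSIFIABLE = "unclassifiable"


@dataclass(frozen=True)
class Prediction:
    """Outcome for one query chemical, with its evidence."""

    id: str
    category: str  # a GHS category or UNCLASSIFIABLE
    mode: Optional[str]  # "rule", "surrogate", or None when unclassifiable
    rule: Optional[AssociationRule] = None
    neighbor_id: Optional[str] = None
    neighbor_distance: Optional[float] = None


def _rule_choice_key(rule: AssociationRule):
    # highest confidence, then highest lift, then most hazardous category,
    # then the deterministic total rule order
    return (
        -rule.confidence,
        -rule.lift,
        category_index(rule.rhs),
        rule.sort_key(),
    )


def _choice_ordered(ruleset: RuleSet) -> list[AssociationRule]:
    # rules sorted once per ruleset by the selection order, cached on the instance
    cache = getattr(ruleset, "_choice_order", None)
    if cache is None:
        cache = sorted(ruleset.rules, key=_rule_choice_key)
        ruleset._choice_order = cache  # type: ignore[attr-defined]
    return cache


def predict_by_rules(fp: Fingerprint, ruleset: RuleSet) -> Optional[Prediction]:
    """Best matching rule's category, or None when no antecedent is contained in fp."""
    for best in _choice_ordered(ruleset):
        if best.lhs <= fp.features:
            return Prediction(id=fp.id, category=best.rhs, mode="rule", rule=best)
    return None


def nearest_neighbor(
    fp: Fingerprint, training: Mapping[str, Fingerprint]
) -> tuple[str, float]:
    """Training chemical at minimum Tanimoto distance from the query.

    Ties break by larger fingerprint intersection, then lexicographic id.
    Pairs where both fingerprints are empty have undefined similarity and are
    skipped; if no comparison is defined, raises ValueError.
    """
    if not training:
        raise ValueError("empty training set")
    best: Optional[tuple[float, int, str]] = None
    for cid, tfp in sorted(training.items()):
        if cid == fp.id:
            continue
        if not fp.features and not tfp.features:
            continue
        d = tanimoto_distance(fp, tfp)
        key = (d, -len(fp.features & tfp.features), cid)
        if best is None or key < best:
            best = key
    if best is None:
        raise ValueError(
            f"no defined Tanimoto distance between {fp.id!r} and any training chemical"
        )
    return best[2], best[0]


def predict(
    fp: Fingerprint,
    ruleset: RuleSet,
    training_fps: Mapping[str, Fingerprint],
    training_rule_predictions: Mapping[str, str],
    use_surrogate: bool = True,
) -> Prediction:
    """Full prediction: rules first, Tanimoto surrogate as fallback.

    ``training_rule_predictions`` maps training ids to their *rule-based*
    categories; only those chemicals can serve as surrogate neighbors.
    """
    p = predict_by_rules(fp, ruleset)
    if p is not None:
        return p
    if not use_surrogate or not fp.features:
        return Prediction(id=fp.id, category=UNCLASSIFIABLE, mode=None)
    covered = {
        cid: f for cid, f in training_fps.items() if cid in training_rule_predictions
    }
    if not covered:
        return Prediction(id=fp.id, category=UNCLASSIFIABLE, mode=None)
    nid, dist = nearest_neighbor(fp, covered)
    return Prediction(
        id=fp.id,
        category=training_rule_predictions[nid],
        mode="surrogate",
        neighbor_id=nid,
        neighbor_distance=dist,
    )


class MarketBasketGHSClassifier(ClassifierMixin, BaseEstimator):
    """Apriori market-basket classifier for GHS acute aquatic toxicity.

    ``fit`` takes SMILES strings and either LC50 values (mg/L, discretized
    internally) or category labels; it fingerprints the training chemicals,
    mines category-consequent association rules, and records each training
    chemical's own rule prediction for surrogate lookups.  ``predict`` maps
    SMILES to category labels (``"unclassifiable"`` when neither a rule nor a
    surrogate neighbor applies).

    Parameters
    ----------
    min_support : float, default 0.05
        Minimum itemset support; with a few dozen chemicals this keeps
        itemsets occurring in at least a handful of them.
    min_confidence : float, default 0.75
        Minimum rule confidence (conditional probability of the category).
    max_len : int, default 5
        Maximum itemset size (antecedent + consequent).
    max_distance : int, default 15
        Maximum topological distance of an atom pair.
    min_feature_count : int, default 1
        Drop features occurring in fewer training chemicals than this.
    use_surrogate : bool, default True
        Fall back to the nearest rule-covered neighbor's rule prediction.
    """

    def __init__(
        self,
        min_support: float = 0.05,
        min_confidence: float = 0.75,
        max_len: int = 5,
        max_distance: int = DEFAULT_MAX_DISTANCE,
        min_feature_count: int = 1,
        use_surrogate: bool = True,
    ):
        self.min_support = min_support
        self.min_confidence = min_confidence
        self.max_len = max_len
        self.max_distance = max_distance
        self.min_feature_count = min_feature_count
        self.use_surrogate = use_surrogate

    # -- fitting -----------------------------------------------------------

    def fit(self, X: Sequence[str], y: Sequence, ids: Optional[Sequence[str]] = None):
        """Mine rules from training chemicals.

        Parameters
        ----------
        X : sequence of SMILES strings
        y : sequence of category labels ("CAT1".."CAT4") or LC50 values (mg/L)
        ids : optional chemical identifiers (default: positional)
        """
        X = list(X)
        y = list(y)
        if len(X) != len(y):
            raise ValueError(f"X and y length mismatch: {len(X)} vs {len(y)}")
        if not X:
            raise ValueError("cannot fit on an empty training set")
        if ids is None:
            ids = [str(i) for i in range(len(X))]
        categories = [self._as_category(v) for v in y]

        fps = {}
        records = []
        for cid, smiles, cat in zip(ids, X, categories):
            g = parse_smiles(smiles, cid)
            fps[cid] = atom_pairs(g, max_distance=self.max_distance)
            # records carry a synthetic in-band LC50 so HazardRecord's
            # category/LC50 consistency invariant holds
            records.append(
                HazardRecord(cid, smiles, _REPRESENTATIVE_LC50[cat], cat)
            )

        txns = build_transactions(records, fps, min_feature_count=self.min_feature_count)
        ruleset = mine_rules(
            txns,
            CATEGORIES,
            self.min_support,
            self.min_confidence,
            max_len=self.max_len,
        )

        self.ruleset_ = ruleset
        self.fingerprints_ = fps
        self.train_rule_predictions_ = {}
        for cid in fps:
            p = predict_by_rules(fps[cid], ruleset)
            if p is not None:
                self.train_rule_predictions_[cid] = p.category
        self.classes_ = np.asarray(sorted(set(categories)))
        self.n_features_in_ = 1
        return self

    @staticmethod
    def _as_category(value) -> str:
        if isinstance(value, str):
            if value not in CATEGORIES:
                raise ValueError(f"unknown category label {value!r}")
            return value
        return ghs_category(float(value))

    # -- prediction --------------------------------------------------------

    def predict_detail(
        self, X: Sequence[str], ids: Optional[Sequence[str]] = None
    ) -> list[Prediction]:
        """Per-chemical :class:`Prediction` objects with evidence."""
        check_is_fitted(self, "ruleset_")
        if ids is None:
            ids = [f"query{i}" for i in range(len(X))]
        out = []
        for cid, smiles in zip(ids, X):
            g = parse_smiles(smiles, cid)
            fp = atom_pairs(g, max_distance=self.max_distance)
            out.append(
                predict(
                    fp,
                    self.ruleset_,
                    self.fingerprints_,
                    self.train_rule_predictions_,
                    use_surrogate=self.use_surrogate,
                )
            )
        return out

    def predict(self, X: Sequence[str]) -> np.ndarray:
        return np.asarray([p.category for p in self.predict_detail(X)], dtype=object)

    def score(self, X: Sequence[str], y: Sequence) -> float:
        """Accuracy over all queries (unclassifiable counts as wrong)."""
        truth = np.asarray([self._as_category(v) for v in y], dtype=object)
        pred = self.predict(X)
        return float(np.mean(pred == truth))


# in-band LC50 representatives used when fitting from category labels
_REPRESENTATIVE_LC50 = {"CAT1": 0.5, "CAT2": 5.0, "CAT3": 50.0, "CAT4": 500.0}
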