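"""From-scratch Apriori mining of atom-pair → GHS-category association rules.

Chemicals are market-basket transactions: the items are a chemical's
atom-pair features plus exactly one hazard-category label item.  Frequent
itemsets are mined level-wise with downward-closure pruning, and rules are
restricted to a single category consequent:

    atom-pair X AND atom-pair Y  =>  GHS category

with the standard interestingness statistics

* support     — fraction of chemicals containing antecedent ∪ consequent,
* confidence  — P(category | antecedent) = support(lhs ∪ rhs) / support(lhs),
* lift        — confidence / support(category); 1 means no better than chance.

Supports are exact rationals (Fractions over the transaction count)
internally so that equality comparisons — in particular the redundant-rule
minimization used for toxicophore extraction — are exact; the public float
attributes expose them as reals.

Items may be :class:`~toxbasket.fingerprint.AtomPairFeature` instances,
category strings, or (for the abstract miner) any hashable; ordering is by
the canonical rendered string, which makes mining output byte-stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache
from typing import Hashable, Iterable, Mapping, Sequence

from .fingerprint import AtomPairFeature, Fingerprint, parse_feature, render_feature
from .hazard import CATEGORIES, HazardRecord

__all__ = [
    "Transaction",
    "AssociationRule",
    "RuleSet",
    "build_transactions",
    "frequent_itemsets",
    "mine_rules",
    "generate_rules",
    "minimize_rule",
    "top_rules",
]

Item = Hashable
ItemSet = frozenset


@lru_cache(maxsize=None)
def item_key(item: Item) -> str:
    """Canonical string key of an item (total order for deterministic output)."""
    if isinstance(item, AtomPairFeature):
        return render_feature(item)
    return str(item)


def itemset_key(items: Iterable[Item]) -> tuple[str, ...]:
    return tuple(sorted(item_key(i) for i in items))


@dataclass(frozen=True)
class Transaction:
    """One chemical's basket: its atom-pair features plus one category item."""

    id: str
    items: frozenset

    def __post_init__(self) -> None:
        n_cat = sum(1 for i in self.items if i in CATEGORIES)
        if n_cat != 1:
            raise ValueError(
                f"transaction {self.id!r} must contain exactly one category item, "
                f"found {n_cat}"
            )


@dataclass(frozen=True)
class AssociationRule:
    """lhs (feature set) ⇒ rhs (single category), with exact statistics."""

    lhs: frozenset
    rhs: Item
    support: Fraction
    confidence: Fraction
    lift: Fraction

    def __post_init__(self) -> None:
        if not self.lhs:
            raise ValueError("rule antecedent must be non-empty")
        if self.rhs in self.lhs:
            raise ValueError("consequent may not appear in the antecedent")
        if not (0 < self.support <= self.confidence <= 1):
            raise ValueError(
                f"need 0 < support <= confidence <= 1, got "
                f"support={self.support}, confidence={self.confidence}"
            )
        if self.lift <= 0:
            raise ValueError("lift must be positive")

    @property
    def lhs_key(self) -> tuple[str, ...]:
        return itemset_key(self.lhs)

    def sort_key(self):
        """Total order: lift desc, confidence desc, shorter antecedent, lexicographic."""
        return (-self.lift, -self.confidence, len(self.lhs), self.lhs_key, item_key(self.rhs))

    def stats(self) -> tuple[Fraction, Fraction, Fraction]:
        return (self.support, self.confidence, self.lift)

    def to_json(self) -> dict:
        return {
            "antecedent": [item_key(i) for i in sorted(self.lhs, key=item_key)],
            "consequent": item_key(self.rhs),
            "support": float(self.support),
            "confidence": float(self.confidence),
            "lift": float(self.lift),
            "support_exact": str(self.support),
            "confidence_exact": str(self.confidence),
            "lift_exact": str(self.lift),
        }

    @classmethod
    def from_json(cls, obj: dict) -> "AssociationRule":
        return cls(
            lhs=frozenset(parse_feature(s) for s in obj["antecedent"]),
            rhs=obj["consequent"],
            support=Fraction(obj["support_exact"]),
            confidence=Fraction(obj["confidence_exact"]),
            lift=Fraction(obj["lift_exact"]),
        )


@dataclass
class RuleSet:
    """Mined rules plus the mining parameters and category base rates."""

    rules: list[AssociationRule]
    min_support: float
    min_confidence: float
    max_len: int
    category_supports: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = set()
        for r in self.rules:
            key = (r.lhs, r.rhs)
            if key in seen:
                raise ValueError(f"duplicate rule {r.lhs_key} => {r.rhs}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self):
        return iter(self.rules)

    def for_category(self, category: str) -> list[AssociationRule]:
        return [r for r in self.rules if r.rhs == category]

    def to_json(self) -> dict:
        return {
            "params": {
                "min_support": self.min_support,
                "min_confidence": self.min_confidence,
                "max_len": self.max_len,
            },
            "category_supports": {
                item_key(c): str(s) for c, s in sorted(self.category_supports.items(), key=lambda kv: item_key(kv[0]))
            },
            "rules": [r.to_json() for r in sorted(self.rules, key=AssociationRule.sort_key)],
        }

    @classmethod
    def from_json(cls, obj: dict) -> "RuleSet":
        return cls(
            rules=[AssociationRule.from_json(r) for r in obj["rules"]],
            min_support=obj["params"]["min_support"],
            min_confidence=obj["params"]["min_confidence"],
            max_len=obj["params"]["max_len"],
            category_supports={c: Fraction(s) for c, s in obj["category_supports"].items()},
        )


def build_transactions(
    records: Sequence[HazardRecord],
    fps: Mapping[str, Fingerprint],
    min_feature_count: int = 1,
) -> list[Transaction]:
    """Turn hazard records + fingerprints into market-basket transactions.

    Each transaction holds the chemical's atom-pair features and its category
    label.  Features occurring in fewer than ``min_feature_count`` chemicals
    are dropped from every basket.
    """
    missing = [r.id for r in records if r.id not in fps]
    if missing:
        raise ValueError(f"missing fingerprint(s) for chemical(s) {missing}")
    if min_feature_count > 1:
        counts: dict[AtomPairFeature, int] = {}
        for r in records:
            for f in fps[r.id].features:
                counts[f] = counts.get(f, 0) + 1
        keep = {f for f, c in counts.items() if c >= min_feature_count}
    else:
        keep = None
    txns = []
    for r in records:
        feats = fps[r.id].features
        if keep is not None:
            feats = feats & keep
        txns.append(Transaction(id=r.id, items=frozenset(feats) | {r.category}))
    return txns


def _mine_counts(
    baskets: list[frozenset], min_count: int, max_len: int
) -> tuple[list, dict[tuple[int, ...], int]]:
    """Level-wise Apriori core on integer item indices.

    Items are re-indexed by canonical key; transaction covers are integer
    bitmasks, so cover(A ∪ B) = cover(A) & cover(B) and support counting is a
    popcount.  Candidates come from joining two frequent (k-1)-itemsets that
    share a (k-2)-prefix — the classic downward-closure join, which generates
    every frequent k-itemset exactly once; the count filter then discards the
    infrequent ones.  Returns the item list and {index tuple: count}.
    """
    items = sorted({i for b in baskets for i in b}, key=item_key)
    index = {it: k for k, it in enumerate(items)}
    masks = [0] * len(items)
    for tid, basket in enumerate(baskets):
        bit = 1 << tid
        for it in basket:
            masks[index[it]] |= bit

    counts: dict[tuple[int, ...], int] = {}
    level: list[tuple[tuple[int, ...], int]] = []
    for k, mask in enumerate(masks):
        c = mask.bit_count()
        if c >= min_count:
            counts[(k,)] = c
            level.append(((k,), mask))

    size = 2
    while level and size <= max_len:
        next_level = []
        start = 0
        m = len(level)
        while start < m:
            end = start
            prefix = level[start][0][:-1]
            while end < m and level[end][0][:-1] == prefix:
                end += 1
            for a in range(start, end):
                ta, ma = level[a]
                for b in range(a + 1, end):
                    tb, mb = level[b]
                    mask = ma & mb
                    c = mask.bit_count()
                    if c >= min_count:
                        cand = ta + (tb[-1],)
                        counts[cand] = c
                        next_level.append((cand, mask))
            start = end
        level = next_level
        size += 1
    return items, counts


def _as_baskets(txns: Sequence[Transaction | frozenset]) -> list[frozenset]:
    return [t.items if isinstance(t, Transaction) else frozenset(t) for t in txns]


def _min_count(min_support: float | Fraction, n: int) -> tuple[Fraction, int]:
    min_frac = (
        Fraction(min_support).limit_denominator(10**9)
        if not isinstance(min_support, Fraction)
        else min_support
    )
    # smallest count c with c/n >= min_frac
    return min_frac, -((-min_frac.numerator * n) // min_frac.denominator)


def frequent_itemsets(
    txns: Sequence[Transaction | frozenset],
    min_support: float | Fraction,
    max_len: int = 5,
) -> dict[frozenset, Fraction]:
    """Level-wise Apriori enumeration of frequent itemsets.

    Returns every itemset of size ≤ ``max_len`` whose support — the fraction
    of transactions containing it — is ≥ ``min_support``, mapped to its exact
    support.
    """
    if not txns:
        raise ValueError("no transactions to mine")
    if not (0 < min_support <= 1):
        raise ValueError(f"min_support must be in (0, 1], got {min_support}")
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    baskets = _as_baskets(txns)
    n = len(baskets)
    _, mc = _min_count(min_support, n)
    items, counts = _mine_counts(baskets, max(mc, 1), max_len)
    return {
        frozenset(items[k] for k in t): Fraction(c, n) for t, c in counts.items()
    }


def mine_rules(
    txns: Sequence[Transaction | frozenset],
    category_items: Iterable[Item],
    min_support: float | Fraction,
    min_confidence: float | Fraction,
    max_len: int = 5,
) -> RuleSet:
    """Mine category-consequent rules directly from transactions.

    Equivalent to ``generate_rules(frequent_itemsets(txns, ...), ...)`` but
    skips materializing the full itemset table, which matters on dense
    chemical baskets.
    """
    if not txns:
        raise ValueError("no transactions to mine")
    if not (0 < min_support <= 1):
        raise ValueError(f"min_support must be in (0, 1], got {min_support}")
    if not (0 < min_confidence <= 1):
        raise ValueError(f"min_confidence must be in (0, 1], got {min_confidence}")
    baskets = _as_baskets(txns)
    n = len(baskets)
    _, mc = _min_count(min_support, n)
    min_conf, _ = _min_count(min_confidence, 1)
    items, counts = _mine_counts(baskets, max(mc, 1), max_len)

    cats = set(category_items)
    cat_indices = {k for k, it in enumerate(items) if it in cats}
    cat_counts = {k: counts[(k,)] for k in cat_indices if (k,) in counts}
    rules = []
    for t, c in counts.items():
        if len(t) < 2:
            continue
        in_cats = [k for k in t if k in cat_indices]
        if len(in_cats) != 1:
            continue
        rk = in_cats[0]
        lhs_t = tuple(x for x in t if x != rk)
        lhs_c = counts[lhs_t]
        if c * min_conf.denominator < min_conf.numerator * lhs_c:
            continue
        rules.append(
            AssociationRule(
                lhs=frozenset(items[x] for x in lhs_t),
                rhs=items[rk],
                support=Fraction(c, n),
                confidence=Fraction(c, lhs_c),
                lift=Fraction(c * n, lhs_c * cat_counts[rk]),
            )
        )
    rules.sort(key=AssociationRule.sort_key)
    return RuleSet(
        rules=rules,
        min_support=float(Fraction(min_support).limit_denominator(10**9)),
        min_confidence=float(min_conf),
        max_len=max_len,
        category_supports={items[k]: Fraction(c, n) for k, c in cat_counts.items()},
    )


def generate_rules(
    itemsets: Mapping[frozenset, Fraction],
    category_items: Iterable[Item],
    min_confidence: float | Fraction,
    min_support: float = 0.0,
    max_len: int = 5,
) -> RuleSet:
    """Category-consequent rules from a frequent-itemset table.

    For every frequent itemset containing exactly one category item and at
    least one non-category item, emit ``features ⇒ category`` when its
    confidence reaches ``min_confidence``.  Confidence and lift follow the
    standard identities; both are exact rationals.
    """
    if not (0 < min_confidence <= 1):
        raise ValueError(f"min_confidence must be in (0, 1], got {min_confidence}")
    cats = set(category_items)
    min_conf = Fraction(min_confidence).limit_denominator(10**9) if not isinstance(min_confidence, Fraction) else min_confidence
    cat_supports = {
        next(iter(s)): sup for s, sup in itemsets.items() if len(s) == 1 and next(iter(s)) in cats
    }
    rules = []
    for itemset, sup in itemsets.items():
        in_cats = itemset & cats
        if len(in_cats) != 1 or len(itemset) < 2:
            continue
        rhs = next(iter(in_cats))
        lhs = itemset - in_cats
        lhs_sup = itemsets.get(lhs)
        if lhs_sup is None:
            # cannot happen for a true Apriori table (downward closure)
            raise ValueError(f"antecedent {itemset_key(lhs)} missing from itemset table")
        confidence = sup / lhs_sup
        if confidence < min_conf:
            continue
        rhs_sup = cat_supports.get(rhs)
        if rhs_sup is None:
            continue
        lift = confidence / rhs_sup
        rules.append(
            AssociationRule(lhs=lhs, rhs=rhs, support=sup, confidence=confidence, lift=lift)
        )
    rules.sort(key=AssociationRule.sort_key)
    return RuleSet(
        rules=rules,
        min_support=float(min_support),
        min_confidence=float(min_conf),
        max_len=max_len,
        category_supports=dict(cat_supports),
    )


def minimize_rule(rule: AssociationRule, ruleset: RuleSet) -> AssociationRule:
    """Strip redundant antecedent items from a rule.

    Returns the rule with the smallest antecedent among rules in the set with
    the same consequent, an antecedent that is a subset of the input's, and
    identical support, confidence and lift — a longer rule whose extra items
    leave all three statistics unchanged adds no information to the
    toxicophore.  A rule with no such sub-rule is its own minimizer; the
    operation is idempotent.
    """
    best = rule
    for cand in ruleset.rules:
        if cand.rhs != rule.rhs or not cand.lhs <= rule.lhs:
            continue
        if cand.stats() != rule.stats():
            continue
        if (len(cand.lhs), cand.lhs_key) < (len(best.lhs), best.lhs_key):
            best = cand
    return best


def top_rules(ruleset: RuleSet, category: str) -> list[AssociationRule]:
    """Rules predicting ``category``, best (largest lift) first.

    Ties break by higher confidence, then smaller antecedent, then
    lexicographic antecedent rendering — a total order, so the output is
    deterministic.  Categories with no rules yield an empty list.
    """
    return sorted(ruleset.for_category(category), key=AssociationRule.sort_key)


def transactions_to_basket_csv(txns: Sequence[Transaction]) -> str:
    """Basket CSV export (id, semicolon-joined items) for external cross-checks."""
    lines = ["id,items"]
    for t in txns:
        items = ";".join(sorted(item_key(i) for i in t.items))
        lines.append(f'{t.id},"{items}"')
    return "\n".join(lines) + "\n"
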