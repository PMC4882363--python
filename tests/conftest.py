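"""Shared fixtures: a planted-motif dataset and the models mined from it.

The expensive artifacts (fingerprints, ruleset, cross-validation) are
session-scoped so every test file can assert against the same pipeline run.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations

import pytest

import toxbasket as tb
from toxbasket.rulemining import build_transactions, mine_rules


def brute_force_itemsets(baskets, min_support, max_len):
    """Independent oracle: enumerate the power set of observed items."""
    n = len(baskets)
    items = sorted({i for b in baskets for i in b}, key=str)
    ms = Fraction(min_support).limit_denominator(10**9)
    out = {}
    for k in range(1, max_len + 1):
        for combo in combinations(items, k):
            s = frozenset(combo)
            c = sum(1 for b in baskets if s <= b)
            if c and Fraction(c, n) >= ms:
                out[s] = Fraction(c, n)
    return out


def brute_force_rules(baskets, category_items, min_support, min_confidence, max_len):
    """Oracle rules: every (antecedent, category) split of every frequent itemset."""
    n = len(baskets)
    itemsets = brute_force_itemsets(baskets, min_support, max_len)
    cats = set(category_items)
    mc = Fraction(min_confidence).limit_denominator(10**9)
    rules = {}
    for s, sup in itemsets.items():
        inside = s & cats
        if len(inside) != 1 or len(s) < 2:
            continue
        rhs = next(iter(inside))
        lhs = s - inside
        conf = sup / itemsets[lhs]
        if conf < mc:
            continue
        if frozenset([rhs]) not in itemsets:
            continue
        lift = conf / itemsets[frozenset([rhs])]
        rules[(lhs, rhs)] = (sup, conf, lift)
    return rules


@pytest.fixture(scope="session")
def planted_dataset():
    """60-chemical dataset where every chemical carries its category's motif."""
    return tb.generate_dataset(tb.SynthConfig(fidelity=1.0, seed=1))


@pytest.fixture(scope="session")
def planted_fingerprints(planted_dataset):
    return {
        r.id: tb.atom_pairs(tb.parse_smiles(r.smiles, r.id))
        for r in planted_dataset.records
    }


@pytest.fixture(scope="session")
def planted_transactions(planted_dataset, planted_fingerprints):
    return build_transactions(planted_dataset.records, planted_fingerprints)


@pytest.fixture(scope="session")
def planted_ruleset(planted_transactions):
    return mine_rules(planted_transactions, tb.CATEGORIES, 0.05, 0.75, 5)


@pytest.fixture(scope="session")
def planted_cv(planted_dataset):
    return tb.cross_validate(planted_dataset.records, k=5, seed=1)
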